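"""Seeded synthetic inputs: TFBS hit tables, expression matrices, module labels.

The generator emulates, at configurable scale, the three inputs of a
promoterome analysis: (1) a sparse binary TF -> target-gene incidence whose TF
out-degrees follow a heavy-tailed (discrete power-law) distribution, as seen
in real promoter scans; (2) a genes x conditions expression matrix in which
target-gene profiles are driven by latent TF profiles through signed
activator/repressor/dual effects plus Gaussian noise; and (3) per-gene module
labels, optionally enriched for one TF's targets.  Every draw flows from a
single seed, so downstream stages are testable with bit-reproducible inputs
and a known regulatory ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .promoterome import HIT_COLUMNS, PMatrix, build_pmatrix

ROLE_ACTIVATOR = "activator"
ROLE_REPRESSOR = "repressor"
ROLE_DUAL = "dual"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Defaults mirror the study design being emulated: 26 experimental
    conditions, six functional modules, and a power-law TF out-degree, at a
    reduced 1,000-gene / 60-TF scale.  ``dual_fraction`` defaults to 0.75, the
    midpoint of the 70-80% bipotential-TF range the co-expression signal of
    the real tissue is consistent with.
    """

    n_genes: int = 1000
    n_tfs: int = 60
    n_conditions: int = 26
    tf_degree_exponent: float = 2.0
    dual_fraction: float = 0.75
    effect_sd_units: float = 1.0
    noise_sd: float = 1.0
    n_modules: int = 6
    seed: int = 0
    # fraction of hits whose core/matrix similarity falls below the 1.0
    # high-confidence threshold, and whose promoter lacks orthology support
    similarity_fail_fraction: float = 0.1
    ortholog_fail_fraction: float = 0.1
    baseline_log2: float = 8.0

    def __post_init__(self):
        if not 0 <= self.dual_fraction <= 1:
            raise ValueError("dual_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_tfs", "n_conditions"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.tf_degree_exponent <= 1:
            raise ValueError("tf_degree_exponent must exceed 1 for a normalizable power law")
        for name in ("similarity_fail_fraction", "ortholog_fail_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so stages draw independently from one seed."""
        key = zlib.crc32(stream.encode())  # stable across processes, unlike hash()
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """What the generator actually did — for parameter-recovery tests."""

    tf_role: dict  # TF id -> activator | repressor | dual
    effect_map: dict  # (tf, gene) -> signed effect size, nonzero iff incidence 1
    module_of: dict = field(default_factory=dict)  # gene -> module label


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"G{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _tf_ids(n: int) -> np.ndarray:
    width = max(2, len(str(n)))
    return np.array([f"TF{j:0{width}d}" for j in range(1, n + 1)], dtype=object)


def sample_power_law_degrees(n: int, exponent: float, k_max: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Sample discrete power-law out-degrees, pmf ~ k^-exponent on 1..k_max."""
    if exponent <= 1:
        raise ValueError("power-law exponent must exceed 1")
    ks = np.arange(1, k_max + 1, dtype=float)
    pmf = ks ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n, p=pmf)


def generate_tfbs_hits(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic TFBS hit table.

    Each TF draws a power-law out-degree and targets that many distinct
    genes.  Each hit lands on one of the gene's (two) promoters; a
    configurable fraction of hits receives a sub-threshold core/matrix
    similarity, and a configurable fraction fails the orthology-conservation
    flag, so the downstream high-confidence filters have work to do.
    """
    rng = config.rng("tfbs")
    genes = _gene_ids(config.n_genes)
    tfs = _tf_ids(config.n_tfs)
    degrees = sample_power_law_degrees(config.n_tfs, config.tf_degree_exponent,
                                       config.n_genes, rng)
    rows = []
    for j, tf in enumerate(tfs):
        targets = rng.choice(config.n_genes, size=int(degrees[j]), replace=False)
        for gi in targets:
            rows.append((genes[gi], tf))
    hits = pd.DataFrame(rows, columns=["gene_id", "tf"])
    n = len(hits)
    # each gene has up to two annotated promoters; hits split between them
    promoter_no = rng.integers(1, 3, size=n)
    hits["promoter_id"] = hits["gene_id"] + "_p" + promoter_no.astype(str)
    core = np.ones(n)
    matrix = np.ones(n)
    fail = rng.random(n) < config.similarity_fail_fraction
    which = rng.integers(0, 2, size=n)  # which score falls short
    sub = rng.uniform(0.70, 0.99, size=n)
    core[fail & (which == 0)] = sub[fail & (which == 0)]
    matrix[fail & (which == 1)] = sub[fail & (which == 1)]
    hits["core_sim"] = core
    hits["matrix_sim"] = matrix
    hits["ortholog_ok"] = rng.random(n) >= config.ortholog_fail_fraction
    return hits[HIT_COLUMNS]


def assign_tf_roles(config: GeneratorConfig, tfs) -> dict:
    """Label floor(dual_fraction * n) TFs dual; split the rest act/rep evenly."""
    rng = config.rng("roles")
    tfs = list(tfs)
    n = len(tfs)
    n_dual = int(np.floor(config.dual_fraction * n))
    order = rng.permutation(n)
    roles = {}
    mono = [ROLE_ACTIVATOR, ROLE_REPRESSOR]
    for rank, idx in enumerate(order):
        if rank < n_dual:
            roles[tfs[idx]] = ROLE_DUAL
        else:
            roles[tfs[idx]] = mono[(rank - n_dual) % 2]
    return roles


def generate_expression(config: GeneratorConfig, incidence: PMatrix
                        ) -> tuple["ExpressionMatrix", GroundTruth]:
    """Generate expression driven by the incidence, with known ground truth.

    Each TF gets an i.i.d. standard-normal latent profile across conditions;
    each target gene is the signed sum of its regulators' profiles (activator
    +e, repressor -e, dual: independent random sign per target, magnitude
    ``effect_sd_units``) plus ``noise_sd`` Gaussian noise, on a log2-like
    scale around ``baseline_log2``.  TF rows (the latent profiles themselves)
    are included so TF-target correlations are computable.
    """
    from .coexpression import ExpressionMatrix

    if incidence.n_tfs > config.n_tfs or incidence.n_genes > config.n_genes:
        raise ValueError("incidence dimensions exceed the generator configuration")
    rng = config.rng("expression")
    tfs = incidence.tfs
    genes = incidence.genes
    T, G, C = len(tfs), len(genes), config.n_conditions
    profiles = rng.standard_normal((T, C))
    roles = assign_tf_roles(config, tfs)
    e = config.effect_sd_units
    effects = np.zeros((G, T))
    effect_map = {}
    for j, tf in enumerate(tfs):
        targets = np.flatnonzero(incidence.values[:, j])
        if roles[tf] == ROLE_ACTIVATOR:
            signs = np.ones(len(targets))
        elif roles[tf] == ROLE_REPRESSOR:
            signs = -np.ones(len(targets))
        else:
            signs = rng.choice([-1.0, 1.0], size=len(targets))
        effects[targets, j] = signs * e
        for i, s in zip(targets, signs):
            effect_map[(tf, genes[i])] = float(s * e)
    gene_values = config.baseline_log2 + effects @ profiles
    gene_values += config.noise_sd * rng.standard_normal((G, C))
    tf_values = config.baseline_log2 + profiles
    all_ids = np.concatenate([tfs, genes])
    values = np.vstack([tf_values, gene_values])
    conditions = np.array([f"C{c:02d}" for c in range(1, C + 1)], dtype=object)
    E = ExpressionMatrix(all_ids, conditions, values)
    return E, GroundTruth(tf_role=roles, effect_map=effect_map)


def generate_module_labels(config: GeneratorConfig, incidence: PMatrix,
                           enrich_tf: Optional[str] = None,
                           enrich_rate: float = 0.9) -> pd.Series:
    """Assign each gene a module label ``M1..Mk``, uniformly at random.

    When ``enrich_tf`` is given, each of that TF's targets is redirected into
    module ``M1`` with probability ``enrich_rate`` (over-sampling that makes
    the TF genuinely module-specific, for enrichment-recovery tests).
    """
    if config.n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = config.rng("modules")
    genes = incidence.genes
    labels = np.array([f"M{k + 1}" for k in rng.integers(0, config.n_modules, size=len(genes))],
                      dtype=object)
    if enrich_tf is not None:
        target_mask = incidence.tf_column(enrich_tf) == 1  # raises KeyError if unknown
        redirect = rng.random(len(genes)) < enrich_rate
        labels[target_mask & redirect] = "M1"
    out = pd.Series(labels, index=genes, name="module")
    out.index.name = "gene_id"
    return out


@dataclass
class SyntheticDataset:
    """One complete synthetic study: hits, incidence, expression, truth, modules."""

    config: GeneratorConfig
    hits: pd.DataFrame
    pmatrix: PMatrix
    expression: "object"
    truth: GroundTruth
    modules: pd.Series


def generate_dataset(config: GeneratorConfig, enrich_tf: Optional[str] = None,
                     enrich_rate: float = 0.9) -> SyntheticDataset:
    """Run the full generator: hits -> filtered incidence -> expression -> modules."""
    from .promoterome import filter_hits

    hits = generate_tfbs_hits(config)
    kept = filter_hits(hits, core_min=1.0, matrix_min=1.0, require_ortholog=True)
    P = build_pmatrix(kept)
    E, truth = generate_expression(config, P)
    P = PMatrix(P.genes, P.tfs, P.values, expressed_tfs=frozenset(P.tfs))
    modules = generate_module_labels(config, P, enrich_tf=enrich_tf, enrich_rate=enrich_rate)
    truth.module_of = modules.to_dict()
    return SyntheticDataset(config, hits, P, E, truth, modules)


# ---------------------------------------------------------------- writers

def write_expression_tsv(E, path) -> None:
    pd.DataFrame(E.values, index=E.genes, columns=E.conditions).to_csv(path, sep="\t")


def write_modules_tsv(modules: pd.Series, path) -> None:
    modules.rename("module").to_csv(path, sep="\t", header=True)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "tf_role": truth.tf_role,
        "effect_map": {f"{tf}\t{gene}": v for (tf, gene), v in truth.effect_map.items()},
        "module_of": truth.module_of,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_config_json(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=1)
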