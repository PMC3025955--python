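"""End-to-end orchestration: generate or load inputs, run every stage, write a report.

Stage order follows the analysis: filter hits -> P-matrix -> pairwise
correlations -> co-expression statistics (and optional TRM/LOD profile) ->
regulation-type simulation -> module enrichment -> TF network.  All
randomness flows from one top-level seed through named substreams, so
toggling one stage does not perturb another's draws.  The gene universes of
the expression matrix and the P-matrix are reconciled by intersection, with
the number of dropped genes logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import regsim as rs
from . import synthetic_data as sd
from . import tfnet as tn
from .promoterome import (build_pmatrix, cross_product, filter_hits, pair_count,
                          read_hits_tsv, shared_tfbs_distribution,
                          tfbs_per_gene_histogram, write_hits_tsv, write_pmatrix_tsv)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a synthetic-generator config."""

    out_dir: str = "coregnet_run"
    seed: int = 0
    # file inputs (all three or none)
    hits_path: Optional[str] = None
    expression_path: Optional[str] = None
    modules_path: Optional[str] = None
    # generator settings (used when no file inputs are given)
    generator: Optional[sd.GeneratorConfig] = None
    # filters
    core_min: float = 1.0
    matrix_min: float = 1.0
    require_ortholog: bool = True
    # stage toggles
    run_coexpression: bool = True
    run_trm: bool = False
    run_simulation: bool = False
    run_enrichment: bool = True
    run_network: bool = True
    simulation: rs.SimulationConfig = field(default_factory=rs.SimulationConfig)
    log_level: str = "INFO"

    def __post_init__(self):
        paths = [self.hits_path, self.expression_path]
        has_files = any(p is not None for p in paths)
        if has_files and self.generator is not None:
            raise ValueError("give either input paths or generator settings, not both")
        if not has_files and self.generator is None:
            self.generator = sd.GeneratorConfig(seed=self.seed)

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stage.encode()),)).generate_state(1)[0] % (2**31))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _to_jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns (and writes) the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    with open(out / "run_config.yaml", "w") as fh:
        cfg = dataclasses.asdict(config)
        yaml.safe_dump(_to_jsonable(cfg), fh)
    report: dict = {"seed": config.seed}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.hits_path is not None:
            hits = read_hits_tsv(config.hits_path)
            E = (cx.read_expression_tsv(config.expression_path)
                 if config.expression_path else None)
            modules = (en.read_modules_tsv(config.modules_path).labels
                       if config.modules_path else None)
            truth = None
        else:
            gen = dataclasses.replace(config.generator, seed=config.stage_seed("generate"))
            data = sd.generate_dataset(gen)
            hits, E, modules, truth = data.hits, data.expression, data.modules, data.truth
            write_hits_tsv(hits, out / "tfbs_hits.tsv")
            sd.write_expression_tsv(E, out / "expression.tsv")
            sd.write_modules_tsv(modules, out / "modules.tsv")
            sd.write_ground_truth_json(truth, out / "ground_truth.json")
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    # ---- P-matrix ---------------------------------------------------------
    stage = "pmatrix"
    try:
        kept = filter_hits(hits, config.core_min, config.matrix_min, config.require_ortholog)
        expressed = frozenset(E.genes) if E is not None else frozenset()
        P = build_pmatrix(kept)
        P = dataclasses.replace(P, expressed_tfs=frozenset(t for t in P.tfs if t in expressed))
        X = cross_product(P)
        write_pmatrix_tsv(P, out / "pmatrix.tsv")
        hist = tfbs_per_gene_histogram(P)
        hist.counts.to_csv(out / "tfbs_per_gene_hist.tsv", sep="\t")
        shared = shared_tfbs_distribution(P)
        shared.counts.to_csv(out / "shared_tfbs_distribution.tsv", sep="\t")
        report["pmatrix"] = {
            "n_hits_raw": len(hits), "n_hits_kept": len(kept),
            "n_genes": P.n_genes, "n_tfs": P.n_tfs,
            "n_expressed_tfs": len(P.expressed_tfs),
            "n_gene_pairs": pair_count(P.n_genes) if P.n_genes >= 2 else 0,
            "tfbs_per_gene_95pct": hist.interval_95,
            "mean_shared_tfbs": shared.mean,
            "frac_pairs_ge2_shared": float(shared.frac_ge.get(2, 0.0)),
        }
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    acc = None
    if E is not None:
        stage = "correlations"
        try:
            common = [g for g in E.genes if g in P._gene_index or g in set(P.tfs)]
            dropped = len(E.genes) - len(common)
            if dropped:
                logger.warning("dropping %d expression genes absent from the P-matrix "
                               "universe", dropped)
            p_genes = set(P.genes)
            missing_expr = sum(1 for g in P.genes if g not in set(E.genes))
            if missing_expr:
                logger.warning("%d P-matrix genes lack expression; proceeding on the "
                               "intersection", missing_expr)
            acc = cx.pearson_all_pairs(E.subset(common))
            report["correlations"] = {"n_genes": len(common),
                                      "n_dropped_expression": dropped,
                                      "n_pmatrix_without_expression": missing_expr}
        except Exception as err:
            raise StageError(stage, err) from err

    if config.run_coexpression and acc is not None:
        stage = "coexpression"
        try:
            summ = cx.summarize(acc, P)
            for v, tab in summ.ratio_tables.items():
                tab.to_csv(out / f"tf_target_ratios_{v}.tsv", sep="\t", index=False)
            curve = cx.percent_increase_by_shared(acc, P, "absolute")
            curve.to_csv(out / "pct_increase_by_shared.tsv", sep="\t", index=False)
            report["coexpression"] = {
                "n_pairs": summ.n_pairs,
                "positive_fraction": summ.positive_fraction,
                "negative_fraction": summ.negative_fraction,
                "mu_abs": summ.mu_abs, "mu_pos": summ.mu_pos, "mu_neg": summ.mu_neg,
                "ratio_tests": {
                    v: {kind: dataclasses.asdict(res) for kind, res in tests.items()}
                    for v, tests in summ.ratio_tests.items()},
            }
        except Exception as err:
            raise StageError(stage, err) from err

    if config.run_trm and acc is not None:
        stage = "trm"
        try:
            prof = cx.trm_lod_profile(acc, P)
            prof.lod_table.to_csv(out / "trm_lod_profile.tsv", sep="\t")
            report["trm"] = {
                "extreme_contrast": prof.extreme_contrast.to_dict(),
                "n_pairs": prof.n_pairs.to_dict(),
            }
        except Exception as err:
            raise StageError(stage, err) from err

    if config.run_simulation:
        stage = "simulation"
        try:
            sim_cfg = dataclasses.replace(config.simulation,
                                          seed=config.stage_seed("simulation"))
            sweep = rs.sweep_dual_fraction(P, sim_cfg)
            sweep.summary_table().to_csv(out / "simulation_summary.tsv", sep="\t",
                                         index=False)
            sweep.curve_table().to_csv(out / "simulation_curves.tsv", sep="\t",
                                       index=False)
            report["simulation"] = {
                row["dual_fraction"]: {"corr_mean": row["corr_mean"],
                                       "n_pairs": int(row["n_pairs"])}
                for _, row in sweep.summary_table().iterrows()}
        except Exception as err:
            raise StageError(stage, err) from err

    if config.run_enrichment and modules is not None:
        stage = "enrichment"
        try:
            mods = en.ModuleSet(modules.reindex(P.genes).dropna(), universe=P.n_genes)
            table = en.enrichment_table(P, mods)
            classified = en.classify_module_specific(table,
                                                     expressed_tfs=P.expressed_tfs)
            classified.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            n_spec = classified.groupby("module")["module_specific"].sum()
            report["enrichment"] = {
                "module_specific_per_module": {k: int(v) for k, v in n_spec.items()},
                "n_module_specific_tfs":
                    int(classified[classified["module_specific"]]["tf"].nunique()),
            }
        except Exception as err:
            raise StageError(stage, err) from err

    if config.run_network:
        stage = "network"
        try:
            module_of = {}
            if config.run_enrichment and modules is not None:
                best = classified[classified["best_module"]]
                module_of = dict(zip(best["tf"], best["module"]))
            G = tn.build_network(P, corr_accessor=acc, module_of=module_of, X=X)
            tn.write_edge_list_tsv(G, out / "tf_network_edges.tsv")
            tn.write_graphml(G, out / "tf_network.graphml")
            report["network"] = {"n_nodes": G.number_of_nodes(),
                                 "n_edges": G.number_of_edges()}
            if G.number_of_edges():
                hub = tn.hubs(G)
                report["network"]["hubs"] = hub.hubs
                report["network"]["hub_min_degree"] = hub.min_degree
            labelled = {n: m for n, m in module_of.items() if m}
            edges = [(a, b) for a, b in G.edges
                     if a in labelled and b in labelled]
            mods_present = {labelled[x] for e in edges for x in e}
            if len(edges) >= 2 and len(mods_present) >= 2:
                chi = en.assortment_chi_square(edges, labelled)
                report["network"]["assortment"] = {
                    "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value,
                    "n_edges_tested": len(edges)}
        except Exception as err:
            raise StageError(stage, err) from err

    report_clean = _to_jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report_clean, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out / "report.json")
    return report_clean
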