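"""Promoterome matrix (P-matrix) construction and summary statistics.

The P-matrix is a binary gene x transcription-factor (TF) incidence matrix:
``P[i, j] = 1`` iff the promoter region of gene *i* carries at least one
predicted binding site (TFBS) for TF *j*.  Everything downstream — shared-site
distributions, TF co-occurrence, enrichment and the TF network — is derived
from this object and its cross-product ``P.T @ P``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar
from scipy.special import zeta

logger = logging.getLogger(__name__)

#: Canonical column order of a TFBS hit table.
HIT_COLUMNS = ["gene_id", "promoter_id", "tf", "core_sim", "matrix_sim", "ortholog_ok"]


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Check a TFBS hit table for the canonical columns and score ranges.

    Returns the table unchanged on success; raises ``ValueError`` otherwise.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if len(hits):
        if hits["gene_id"].isna().any() or hits["tf"].isna().any():
            raise ValueError("hit table contains null gene or TF identifiers")
        for col in ("core_sim", "matrix_sim"):
            vals = hits[col].to_numpy(dtype=float)
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{col} must lie in [0, 1]")
    return hits


def read_hits_tsv(path) -> pd.DataFrame:
    """Read a TFBS hit table from TSV (columns as :data:`HIT_COLUMNS`)."""
    hits = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "promoter_id": str, "tf": str})
    hits["ortholog_ok"] = hits["ortholog_ok"].astype(bool)
    return validate_hits(hits)


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def filter_hits(
    hits: pd.DataFrame,
    core_min: float = 1.0,
    matrix_min: float = 1.0,
    require_ortholog: bool = True,
) -> pd.DataFrame:
    """Apply the high-confidence TFBS filters.

    A hit survives iff ``core_sim >= core_min`` and ``matrix_sim >= matrix_min``
    and, when ``require_ortholog`` is set, its promoter is flagged as
    phylogenetically conserved.  Row order is preserved; the number of removed
    rows is logged.  An empty table passes through unchanged.
    """
    if not 0 <= core_min <= 1 or not 0 <= matrix_min <= 1:
        raise ValueError("similarity thresholds must lie in [0, 1]")
    validate_hits(hits)
    if len(hits) == 0:
        return hits.copy()
    keep = (hits["core_sim"].to_numpy(dtype=float) >= core_min) & (
        hits["matrix_sim"].to_numpy(dtype=float) >= matrix_min
    )
    if require_ortholog:
        keep &= hits["ortholog_ok"].to_numpy(dtype=bool)
    removed = int((~keep).sum())
    logger.info("filter_hits: removed %d of %d rows", removed, len(hits))
    return hits.loc[keep].copy()


@dataclass
class PMatrix:
    """Binary target-gene x TF incidence matrix.

    Attributes
    ----------
    genes : ordered gene identifiers (rows); every row has at least one 1.
    tfs : ordered TF identifiers (columns).
    values : ``(n_genes, n_tfs)`` uint8 array of 0/1 cells.
    expressed_tfs : subset of ``tfs`` with expression data (may be empty).
    """

    genes: np.ndarray
    tfs: np.ndarray
    values: np.ndarray
    expressed_tfs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.tfs = np.asarray(self.tfs, dtype=object)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.genes), len(self.tfs)):
            raise ValueError("incidence shape does not match gene/TF labels")
        if len(self.values) and not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence cells must be 0/1")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._tf_index = {t: j for j, t in enumerate(self.tfs)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    def gene_row(self, gene) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def tf_column(self, tf) -> np.ndarray:
        try:
            return self.values[:, self._tf_index[tf]]
        except KeyError:
            raise KeyError(f"unknown TF id: {tf!r}") from None

    def tf_targets(self, tf) -> np.ndarray:
        """Gene identifiers targeted by ``tf``."""
        return self.genes[self.tf_column(tf) == 1]

    def target_counts(self) -> pd.Series:
        """Per-TF target count (column sums), the TF out-degree."""
        return pd.Series(self.values.sum(axis=0, dtype=np.int64), index=self.tfs, name="n_targets")

    def subset_genes(self, genes: Sequence) -> "PMatrix":
        idx = [self._gene_index[g] for g in genes]
        return PMatrix(np.asarray(genes, dtype=object), self.tfs, self.values[idx], self.expressed_tfs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tfs)


def build_pmatrix(hits: pd.DataFrame, expressed_tfs: Sequence = ()) -> PMatrix:
    """Build the binary incidence from a (filtered) hit table.

    Multiple hits of one TF on one gene — including hits on different
    promoters of that gene — collapse to a single 1; rows and columns appear
    in order of first appearance in the table.  Genes with no surviving hits
    simply do not appear.
    """
    validate_hits(hits)
    if len(hits) == 0:
        return PMatrix(np.empty(0, object), np.empty(0, object), np.zeros((0, 0), np.uint8),
                       frozenset(expressed_tfs))
    genes = pd.unique(hits["gene_id"])
    tfs = pd.unique(hits["tf"])
    gidx = pd.Categorical(hits["gene_id"], categories=genes).codes
    tidx = pd.Categorical(hits["tf"], categories=tfs).codes
    values = np.zeros((len(genes), len(tfs)), dtype=np.uint8)
    values[gidx, tidx] = 1
    return PMatrix(genes, tfs, values, frozenset(expressed_tfs))


@dataclass
class CrossProduct:
    """TF x TF co-occurrence counts, ``P.T @ P``.

    The diagonal holds per-TF target counts ``n_j``; off-diagonal entry
    ``(j, j')`` counts genes whose promoters carry sites for both TFs.
    """

    tfs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.tfs = np.asarray(self.tfs, dtype=object)
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.tfs), len(self.tfs)):
            raise ValueError("cross-product shape does not match TF labels")
        if len(self.values) and not np.array_equal(self.values, self.values.T):
            raise ValueError("cross-product must be symmetric")
        self._tf_index = {t: j for j, t in enumerate(self.tfs)}

    def shared_targets(self, tf_a, tf_b) -> int:
        return int(self.values[self._tf_index[tf_a], self._tf_index[tf_b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tfs, columns=self.tfs)


def cross_product(P: PMatrix) -> CrossProduct:
    """Compute ``P.T @ P`` over the binary incidence."""
    M = P.values.astype(np.int64)
    return CrossProduct(P.tfs, M.T @ M)


def shared_tfbs_count(P: PMatrix, gene_a, gene_b) -> int:
    """Number of TFs with predicted sites in the promoters of both genes."""
    return int(np.dot(P.gene_row(gene_a).astype(np.int64), P.gene_row(gene_b).astype(np.int64)))


def pair_count(n: int) -> int:
    """Number of unordered pairs among ``n`` items, ``n(n-1)/2``."""
    if n < 2:
        raise ValueError("pair_count requires n >= 2")
    return comb(n, 2)


@dataclass
class Histogram:
    counts: pd.Series  # index: value, data: frequency
    interval_95: tuple  # empirical central 95% interval (2.5th, 97.5th pct)


def tfbs_per_gene_histogram(P: PMatrix) -> Histogram:
    """Histogram of per-gene TFBS counts (distinct TFs per promoter region).

    Also reports the empirical central 95% interval of the row sums.
    """
    if P.n_genes == 0:
        return Histogram(pd.Series(dtype=np.int64), (np.nan, np.nan))
    row_sums = P.values.sum(axis=1, dtype=np.int64)
    counts = pd.Series(row_sums).value_counts().sort_index()
    counts.index.name = "n_tfbs"
    lo, hi = np.percentile(row_sums, [2.5, 97.5])
    return Histogram(counts, (float(lo), float(hi)))


@dataclass
class SharedDistribution:
    """Distribution of the shared-TF count over all unordered gene pairs."""

    counts: pd.Series  # index: shared count k, data: number of pairs
    mean: float
    frac_ge: pd.Series  # fraction of pairs sharing >= k sites, k = 0..max

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def shared_tfbs_distribution(P: PMatrix, block: int = 512) -> SharedDistribution:
    """Tally shared-TFBS counts over all C(G, 2) gene pairs.

    Works blockwise on the gene-side product ``P @ P.T`` so memory stays
    bounded for large gene sets.
    """
    G = P.n_genes
    if G < 2:
        raise ValueError("need at least two genes")
    M = P.values.astype(np.int64)
    max_k = int(M.sum(axis=1).max())
    tally = np.zeros(max_k + 1, dtype=np.int64)
    for start in range(0, G, block):
        stop = min(start + block, G)
        S = M[start:stop] @ M.T  # (b, G) shared counts
        for r, i in enumerate(range(start, stop)):
            tally += np.bincount(S[r, i + 1:], minlength=max_k + 1)
    counts = pd.Series(tally, index=np.arange(max_k + 1), name="n_pairs")
    counts.index.name = "shared"
    total = counts.sum()
    mean = float((counts.index.to_numpy() * tally).sum() / total)
    frac_ge = pd.Series(tally[::-1].cumsum()[::-1] / total, index=counts.index, name="frac_ge")
    return SharedDistribution(counts, mean, frac_ge)


def partner_counts(X: CrossProduct) -> pd.Series:
    """Per-TF number of partners: TFs co-occurring on at least one promoter."""
    off = X.values.copy()
    np.fill_diagonal(off, 0)
    return pd.Series((off >= 1).sum(axis=1).astype(np.int64), index=X.tfs, name="n_partners")


@dataclass
class SaturationFit:
    """Least-squares fit of the partner-saturation curve.

    Model: ``y = a * (1 - exp(-b * x)) (+ c)`` — an exponential-saturation
    growth curve; ``c`` is present only when the origin is not forced.
    """

    a: float
    b: float
    c: float
    r_squared: float
    force_origin: bool
    model: str = "y = a*(1 - exp(-b*x)) + c"


def fit_saturation_curve(x, y, force_origin: bool = True) -> SaturationFit:
    """Fit partner count as an exponential-saturation function of target count."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if (x < 0).any():
        raise ValueError("x must be nonnegative")
    try:
        if force_origin:
            popt, _ = curve_fit(lambda x, a, b: a * (1 - np.exp(-b * x)), x, y,
                                p0=(max(y.max(), 1.0), 0.01), maxfev=20000)
            a, b, c = float(popt[0]), float(popt[1]), 0.0
            fitted = a * (1 - np.exp(-b * x))
        else:
            popt, _ = curve_fit(lambda x, a, b, c: a * (1 - np.exp(-b * x)) + c, x, y,
                                p0=(max(y.max(), 1.0), 0.01, 0.0), maxfev=20000)
            a, b, c = map(float, popt)
            fitted = a * (1 - np.exp(-b * x)) + c
    except RuntimeError as err:  # pragma: no cover - scipy diagnostics pass through
        raise RuntimeError(f"saturation-curve fit did not converge: {err}") from err
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # constant y: define R^2 = 0 (no variance explained)
    if ss_tot == 0:
        r2 = 0.0
    return SaturationFit(a, b, c, r2, force_origin)


@dataclass
class PowerLawFit:
    exponent: float
    x_min: int
    n_tail: int
    log_likelihood: float
    loglog: pd.DataFrame  # columns: degree, n_tfs (for log-log plotting)


def fit_power_law(degrees, x_min: int = 1) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit of the TF out-degree tail.

    Maximises the zeta likelihood ``P(X=x) = x^-alpha / zeta(alpha, x_min)``
    over the degrees ``>= x_min``.  Discrete ML is used rather than a
    regression on binned log-log counts, which is biased.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    degrees = degrees[degrees > 0]
    if len(degrees) < 10:
        raise ValueError("need at least 10 nonzero degrees")
    tail = degrees[degrees >= x_min]
    if len(tail) == 0 or x_min > degrees.max():
        raise ValueError("x_min exceeds the maximum degree")
    if len(np.unique(tail)) < 3:
        raise ValueError("degenerate degree sequence: fewer than 3 distinct values")
    n = len(tail)
    sum_log = float(np.log(tail).sum())

    def nll(alpha):
        return alpha * sum_log + n * np.log(zeta(alpha, x_min))

    res = minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    alpha = float(res.x)
    vals, cnts = np.unique(degrees, return_counts=True)
    loglog = pd.DataFrame({"degree": vals, "n_tfs": cnts})
    return PowerLawFit(alpha, x_min, n, -float(res.fun), loglog)


def write_pmatrix_tsv(P: PMatrix, path) -> None:
    P.to_frame().to_csv(path, sep="\t")


def write_pmatrix_mtx(P: PMatrix, prefix: str) -> None:
    """Write the incidence as Matrix Market plus row/column label files."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(f"{prefix}.mtx", csr_matrix(P.values))
    pd.Series(P.genes).to_csv(f"{prefix}.rows.txt", index=False, header=False)
    pd.Series(P.tfs).to_csv(f"{prefix}.cols.txt", index=False, header=False)
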