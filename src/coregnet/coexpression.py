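"""Correlation statistics linking co-expression to co-regulation.

Given a genes x conditions expression matrix and a P-matrix, this module
computes every pairwise-correlation summary the analysis rests on: sign
fractions of all gene-pair correlations, the average correlation mu, the
percent-increase of co-expression with the number of shared promoter sites,
TF-pair co-expression versus shared-target counts, per-TF target/background
correlation ratios with exact binomial enrichment tests, and log-odds (LOD)
profiles stratified by transcriptional regulatory motif order TRM_n (gene
pairs sharing exactly n TFs).

Conventions (fixed across the package):
- Pearson correlation over condition means; self-pairs always excluded.
- Zero correlations count with the positive class, so the positive/negative
  sign split is exhaustive.
- The binomial tail is strict-greater, P(X > k); the inclusive tail is
  exposed alongside for audit.
- Correlation bins are width 0.1 on [-1, 1], right-closed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .promoterome import CrossProduct, PMatrix

logger = logging.getLogger(__name__)

DEFAULT_BINS = np.round(np.linspace(-1.0, 1.0, 21), 10)


@dataclass
class ExpressionMatrix:
    """Genes x conditions normalized expression values (log2-like scale)."""

    genes: np.ndarray
    conditions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("expression shape does not match labels")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if len(self.conditions) < 3:
            raise ValueError("need at least 3 conditions for correlation")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def subset(self, genes: Sequence) -> "ExpressionMatrix":
        idx = [self._index[g] for g in genes]
        return ExpressionMatrix(np.asarray(genes, dtype=object), self.conditions,
                                self.values[idx])


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.index.to_numpy(object), df.columns.to_numpy(object),
                            df.to_numpy(float))


class CorrelationAccessor:
    """All-pairs Pearson correlations with zero-variance genes flagged.

    Rows are standardized once (``z_i = (x_i - mean) / (sd * sqrt(C))``) so
    any correlation is a dot product ``r(i, j) = z_i . z_j``; the full matrix
    is materialised blockwise on demand.  Zero-variance genes yield undefined
    correlations (NaN) and are excluded from every summary.
    """

    def __init__(self, E: ExpressionMatrix):
        self.genes = E.genes
        self._index = {g: i for i, g in enumerate(E.genes)}
        X = E.values
        mu = X.mean(axis=1, keepdims=True)
        centred = X - mu
        norms = np.linalg.norm(centred, axis=1)
        self.defined = norms > 0
        if not self.defined.all():
            logger.warning("%d zero-variance genes: correlations undefined",
                           int((~self.defined).sum()))
        safe = np.where(self.defined, norms, 1.0)
        self._z = centred / safe[:, None]
        self._matrix: Optional[np.ndarray] = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def matrix(self) -> np.ndarray:
        """Dense correlation matrix (NaN rows/cols for zero-variance genes)."""
        if self._matrix is None:
            R = np.clip(self._z @ self._z.T, -1.0, 1.0)
            R[~self.defined, :] = np.nan
            R[:, ~self.defined] = np.nan
            np.fill_diagonal(R, np.where(self.defined, 1.0, np.nan))
            self._matrix = R
        return self._matrix

    def r(self, gene_a, gene_b) -> float:
        i, j = self._index[gene_a], self._index[gene_b]
        if not (self.defined[i] and self.defined[j]):
            return float("nan")
        if i == j:
            return 1.0
        return float(np.clip(self._z[i] @ self._z[j], -1.0, 1.0))

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Correlation sub-block by integer index, for blockwise sweeps."""
        R = np.clip(self._z[rows] @ self._z[cols].T, -1.0, 1.0)
        R[~self.defined[rows], :] = np.nan
        R[:, ~self.defined[cols]] = np.nan
        return R

    def upper_triangle(self) -> np.ndarray:
        """All defined unordered-pair correlations as a flat vector."""
        iu = np.triu_indices(self.n_genes, k=1)
        vals = self.matrix()[iu]
        return vals[~np.isnan(vals)]


def pearson_all_pairs(E: ExpressionMatrix, pairs=None) -> CorrelationAccessor:
    """Build the all-pairs correlation accessor (``pairs`` kept for API
    symmetry; the accessor itself is lazy/blockwise)."""
    return CorrelationAccessor(E)


def sign_fractions(acc: CorrelationAccessor) -> tuple[float, float]:
    """Percent positive / negative over all defined unordered pairs.

    Zero correlations count as positive, so the two percentages sum to 100.
    """
    vals = acc.upper_triangle() if isinstance(acc, CorrelationAccessor) else np.asarray(acc, float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no defined gene pairs")
    pos = float((vals >= 0).mean() * 100.0)
    return pos, 100.0 - pos


def mean_correlation(acc, variant: str = "absolute") -> float:
    """Average pairwise correlation mu under a sign variant.

    absolute: mean |r| over all pairs; positive: mean r over pairs with
    r >= 0; negative: mean r over pairs with r < 0.
    """
    vals = acc.upper_triangle() if isinstance(acc, CorrelationAccessor) else np.asarray(acc, float)
    vals = vals[~np.isnan(vals)]
    if variant == "absolute":
        return float(np.abs(vals).mean())
    if variant == "positive":
        return float(vals[vals >= 0].mean())
    if variant == "negative":
        return float(vals[vals < 0].mean())
    raise ValueError(f"unknown variant: {variant!r}")


def _align(acc: CorrelationAccessor, P: PMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Integer indices of genes common to the accessor and the P-matrix."""
    common = [g for g in P.genes if g in acc._index and acc.defined[acc._index[g]]]
    if len(common) < 2:
        raise ValueError("fewer than 2 genes shared between expression and P-matrix")
    e_idx = np.array([acc._index[g] for g in common])
    p_idx = np.array([P._gene_index[g] for g in common])
    return e_idx, p_idx


def percent_increase_by_shared(acc: CorrelationAccessor, P: PMatrix,
                               variant: str = "absolute",
                               max_k: int = 10) -> pd.DataFrame:
    """Percent increase of co-expression with >= k shared promoter sites.

    For each threshold k = 0..max_k, the mean correlation among gene pairs
    sharing at least k TFs, relative to the mean over all pairs:
    ``100 * (mean_k / mean_all - 1)``.  ``variant='absolute'`` uses |r|;
    ``'positive'`` restricts both means to r > 0 pairs.  Empty bins are
    reported as NaN, not zero.
    """
    if variant not in ("absolute", "positive"):
        raise ValueError("variant must be 'absolute' or 'positive'")
    e_idx, p_idx = _align(acc, P)
    M = P.values[p_idx].astype(np.int64)
    shared = M @ M.T
    iu = np.triu_indices(len(e_idx), k=1)
    shared_pairs = shared[iu]
    r_pairs = acc.matrix()[np.ix_(e_idx, e_idx)][iu]
    ok = ~np.isnan(r_pairs)
    shared_pairs, r_pairs = shared_pairs[ok], r_pairs[ok]
    if variant == "absolute":
        vals = np.abs(r_pairs)
        mask = np.ones(len(vals), bool)
    else:
        mask = r_pairs > 0
        vals = r_pairs
    overall = vals[mask].mean()
    rows = []
    for k in range(0, max_k + 1):
        sel = (shared_pairs >= k) & mask
        n = int(sel.sum())
        if n == 0:
            rows.append((k, 0, np.nan, np.nan))
            continue
        m = vals[sel].mean()
        rows.append((k, n, m, 100.0 * (m / overall - 1.0)))
    return pd.DataFrame(rows, columns=["min_shared", "n_pairs", "mean_corr", "pct_increase"])


def tf_pair_trend(acc: CorrelationAccessor, X: CrossProduct,
                  expressed_tfs: Sequence, thresholds: Optional[Sequence[int]] = None
                  ) -> pd.DataFrame:
    """Co-expression of TF pairs versus the number of targets they share.

    For each threshold t on the shared-target count, the mean |r| among
    expressed-TF pairs with ``PtP >= t`` relative to all expressed-TF pairs
    (percent increase), plus the cumulative frequency of pairs at >= t.
    """
    tfs = [t for t in expressed_tfs if t in acc._index and acc.defined[acc._index[t]]]
    if len(tfs) < 2:
        raise ValueError("need at least 2 expressed TFs")
    e_idx = np.array([acc._index[t] for t in tfs])
    x_idx = np.array([X._tf_index[t] for t in tfs])
    shared = X.values[np.ix_(x_idx, x_idx)]
    iu = np.triu_indices(len(tfs), k=1)
    shared_pairs = shared[iu]
    r_pairs = np.abs(acc.matrix()[np.ix_(e_idx, e_idx)][iu])
    ok = ~np.isnan(r_pairs)
    shared_pairs, r_pairs = shared_pairs[ok], r_pairs[ok]
    overall = r_pairs.mean()
    total = len(r_pairs)
    if thresholds is None:
        thresholds = range(0, int(shared_pairs.max()) + 1)
    rows = []
    for t in thresholds:
        sel = shared_pairs >= t
        n = int(sel.sum())
        mean_r = r_pairs[sel].mean() if n else np.nan
        pct = 100.0 * (mean_r / overall - 1.0) if n else np.nan
        rows.append((t, n, mean_r, pct, n / total))
    return pd.DataFrame(rows, columns=["min_shared_targets", "n_pairs", "mean_abs_corr",
                                       "pct_increase", "cum_freq"])


@dataclass
class TFTargetRatio:
    tf: str
    variant: str
    ratio: float
    mean_target_corr: float
    mean_background_corr: float
    n_targets: int
    defined: bool
    reason: str = ""


def tf_target_ratio(acc: CorrelationAccessor, P: PMatrix, tf,
                    variant: str = "absolute") -> TFTargetRatio:
    """Ratio of a TF's mean correlation with its targets over all genes.

    Numerator: mean correlation between the TF and its predicted targets;
    denominator: mean over all P-matrix genes except the TF itself.  The
    positive (negative) variant restricts both averages to pairs with r > 0
    (r < 0); when the restriction empties the target set the ratio is
    returned undefined with a reason — this is what shrinks the per-variant
    TF denominators in the full-scale analysis.
    """
    if variant not in ("absolute", "positive", "negative"):
        raise ValueError(f"unknown variant: {variant!r}")
    if tf not in acc._index or not acc.defined[acc._index[tf]]:
        raise ValueError(f"TF {tf!r} has no (usable) expression data")
    e_idx, p_idx = _align(acc, P)
    genes = P.genes[p_idx]
    not_self = genes != tf
    genes, e_idx, p_idx = genes[not_self], e_idx[not_self], p_idx[not_self]
    t_row = acc._index[tf]
    r = acc.block(np.array([t_row]), e_idx)[0]
    ok = ~np.isnan(r)
    r, p_idx2 = r[ok], p_idx[ok]
    is_target = P.values[p_idx2, P._tf_index[tf]] == 1
    if is_target.sum() == 0:
        raise ValueError(f"TF {tf!r} has no expressed target")
    if variant == "absolute":
        sel = np.ones(len(r), bool)
        vals = np.abs(r)
    elif variant == "positive":
        sel = r > 0
        vals = r
    else:
        sel = r < 0
        vals = r
    tgt = sel & is_target
    n_targets = int(tgt.sum())
    if n_targets == 0 or sel.sum() == 0:
        return TFTargetRatio(tf, variant, np.nan, np.nan, np.nan, 0, False,
                             f"no {variant} pairs in target/background set")
    num = vals[tgt].mean()
    den = vals[sel].mean()
    return TFTargetRatio(tf, variant, float(num / den), float(num), float(den),
                         n_targets, True)


def tf_ratio_table(acc: CorrelationAccessor, P: PMatrix,
                   tfs: Optional[Sequence] = None,
                   variant: str = "absolute") -> pd.DataFrame:
    """Per-TF ratio table over all expressed TFs with >= 1 expressed target."""
    if tfs is None:
        tfs = sorted(P.expressed_tfs) if P.expressed_tfs else list(P.tfs)
    rows = []
    for tf in tfs:
        try:
            res = tf_target_ratio(acc, P, tf, variant)
        except ValueError:
            continue
        rows.append((tf, res.ratio, res.mean_target_corr, res.mean_background_corr,
                     res.n_targets, res.defined, res.reason))
    return pd.DataFrame(rows, columns=["tf", "ratio", "mean_target_corr",
                                       "mean_background_corr", "n_targets",
                                       "defined", "reason"])


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability, strict-greater: P(X > k).

    This is the convention under which the enrichment p-values of the
    target-ratio analysis are exact (e.g. 74 of 149 at p=1/2 gives exactly
    0.5 by the symmetry of an odd-n binomial).
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < p < 1:
        raise ValueError("require 0 < p < 1")
    return float(binom.sf(k, n, p))


def binomial_tail_inclusive(k: int, n: int, p: float) -> float:
    """P(X >= k), exposed for audit next to the strict tail."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return float(binom.sf(k - 1, n, p))


@dataclass
class RatioTestResult:
    n_above: int
    n_total: int
    p_value: float  # strict-greater tail
    p_value_inclusive: float
    mu: Optional[float] = None


def ratio_enrichment_test(table: pd.DataFrame, restrict_above_mu: bool = False,
                          mu: Optional[float] = None) -> RatioTestResult:
    """Sign test on the per-TF ratio table: is ratio > 1 for more than half?

    Counts TFs with ratio > 1 among those with a defined ratio, optionally
    restricted to TFs whose mean target correlation exceeds (in magnitude,
    for the negative variant) the supplied average correlation mu, and
    applies the exact binomial tail at p = 1/2.
    """
    tab = table[table["defined"]].copy()
    if restrict_above_mu:
        if mu is None:
            raise ValueError("restrict_above_mu requires mu")
        tab = tab[np.abs(tab["mean_target_corr"]) > abs(mu)]
    n = len(tab)
    if n == 0:
        raise ValueError("no TFs left after restriction")
    k = int((tab["ratio"] > 1).sum())
    return RatioTestResult(k, n, binomial_tail(k, n, 0.5),
                           binomial_tail_inclusive(k, n, 0.5), mu)


def lod(cond_hits: int, cond_total: int, marg_hits: int, marg_total: int) -> float:
    """Natural-log odds of a co-expression event given co-regulation.

    ``ln[(cond_hits / cond_total) / (marg_hits / marg_total)]`` — the log
    ratio of the event frequency among co-regulated pairs to its marginal
    frequency over all pairs.  Zero counts make the LOD undefined (NaN
    with a logged flag) rather than +/-inf.
    """
    if cond_total <= 0 or marg_total <= 0:
        raise ValueError("totals must be positive")
    if cond_hits == 0 or marg_hits == 0:
        logger.info("lod: zero count (cond=%d, marg=%d) — undefined", cond_hits, marg_hits)
        return float("nan")
    return math.log((cond_hits / cond_total) / (marg_hits / marg_total))


def _bin_right_closed(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index with right-closed bins (edges[i], edges[i+1]]; -1.0 -> bin 0."""
    idx = np.searchsorted(edges, vals, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class TRMProfile:
    """LOD-by-correlation-bin profile per regulatory-motif order TRM_n.

    ``lod_table`` rows are motif orders (exact shared-TF count 0..9, then
    '10+'); columns are correlation bins.  ``extreme_contrast`` is the LOD in
    the (0.8, 1.0] bin minus the LOD in the [-1.0, -0.8] bin, per order.
    ``n_pairs`` gives the TRM class sizes.
    """

    lod_table: pd.DataFrame
    extreme_contrast: pd.Series
    n_pairs: pd.Series
    bin_edges: np.ndarray
    variant: str


def trm_lod_profile(acc: CorrelationAccessor, P: PMatrix,
                    bins: Optional[np.ndarray] = None,
                    variant: str = "absolute",
                    max_n: int = 10) -> TRMProfile:
    """LOD of each correlation bin within each TRM_n class vs all pairs.

    TRM_n is the class of gene pairs sharing exactly n predicted TFs
    (n = 0..max_n-1, then >= max_n pooled).  For each class and bin the LOD
    compares the bin frequency within the class to the marginal bin
    frequency; empty classes are flagged (all-NaN row).  The 'absolute' and
    'positive'/'negative' variants change only which pairs enter (absolute
    keeps all; positive keeps r > 0; negative keeps r < 0) — binning is
    always on the signed correlation.
    """
    if bins is None:
        bins = DEFAULT_BINS
    bins = np.asarray(bins, float)
    if bins[0] > -1 or bins[-1] < 1:
        raise ValueError("bins must cover [-1, 1]")
    e_idx, p_idx = _align(acc, P)
    M = P.values[p_idx].astype(np.int64)
    shared = (M @ M.T)[np.triu_indices(len(e_idx), k=1)]
    r_pairs = acc.matrix()[np.ix_(e_idx, e_idx)][np.triu_indices(len(e_idx), k=1)]
    ok = ~np.isnan(r_pairs)
    shared, r_pairs = shared[ok], r_pairs[ok]
    if variant == "positive":
        keep = r_pairs > 0
    elif variant == "negative":
        keep = r_pairs < 0
    elif variant == "absolute":
        keep = np.ones(len(r_pairs), bool)
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    shared, r_pairs = shared[keep], r_pairs[keep]
    n_bins = len(bins) - 1
    bin_idx = _bin_right_closed(r_pairs, bins)
    marg = np.bincount(bin_idx, minlength=n_bins).astype(float)
    total = marg.sum()
    order = np.clip(shared, 0, max_n)
    labels = [str(n) for n in range(max_n)] + [f"{max_n}+"]
    lod_rows, n_class = [], []
    for n in range(max_n + 1):
        sel = order == n
        cnt = np.bincount(bin_idx[sel], minlength=n_bins).astype(float)
        tot = cnt.sum()
        n_class.append(int(tot))
        if tot == 0:
            logger.info("trm_lod_profile: empty TRM_%d class", n)
            lod_rows.append(np.full(n_bins, np.nan))
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.log((cnt / tot) / (marg / total))
        row[(cnt == 0) | (marg == 0)] = np.nan
        lod_rows.append(row)
    cols = [f"({bins[i]:+.1f},{bins[i + 1]:+.1f}]" for i in range(n_bins)]
    table = pd.DataFrame(lod_rows, index=labels, columns=cols)
    table.index.name = "trm"
    hi = _bin_right_closed(np.array([0.9]), bins)[0]
    lo = _bin_right_closed(np.array([-0.9]), bins)[0]
    contrast = table.iloc[:, hi] - table.iloc[:, lo]
    contrast.name = "extreme_lod_contrast"
    return TRMProfile(table, contrast, pd.Series(n_class, index=labels, name="n_pairs"),
                      bins, variant)


@dataclass
class CoexpressionSummary:
    """Headline numbers of the co-expression vs co-regulation analysis."""

    n_pairs: int
    positive_fraction: float
    negative_fraction: float
    mu_abs: float
    mu_pos: float
    mu_neg: float
    ratio_tables: dict  # variant -> per-TF ratio DataFrame
    ratio_tests: dict  # variant -> {unrestricted, above_mu} RatioTestResult


def summarize(acc: CorrelationAccessor, P: PMatrix,
              variants: Sequence[str] = ("absolute", "positive", "negative")
              ) -> CoexpressionSummary:
    """Compute the full Table-1-style summary on one dataset."""
    pos, neg = sign_fractions(acc)
    mu = {v: mean_correlation(acc, v) for v in ("absolute", "positive", "negative")}
    tables, tests = {}, {}
    for v in variants:
        tab = tf_ratio_table(acc, P, variant=v)
        tables[v] = tab
        if len(tab) and tab["defined"].any():
            tests[v] = {
                "unrestricted": ratio_enrichment_test(tab),
                "above_mu": ratio_enrichment_test(tab, restrict_above_mu=True, mu=mu[v]),
            }
    n_defined = len(acc.upper_triangle())
    return CoexpressionSummary(n_defined, pos, neg, mu["absolute"], mu["positive"],
                               mu["negative"], tables, tests)
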