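"""Module enrichment of TF target sets and network assortment testing.

A TF is called *module-specific* for a functional module when its predicted
targets are over-represented among the module's genes: hypergeometric upper
tail below alpha AND odds ratio (m_j/n_j)/(m_k/N) above 1 (the second
condition guards against low tail probabilities caused by under-enrichment).
The module assignment of a whole TF network is then tested for non-random
pairing with a chi-square test of independence on the module x module
edge-endpoint contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .promoterome import PMatrix


@dataclass
class ModuleSet:
    """Module labels for a subset of genes within a universe of size N."""

    labels: pd.Series  # gene -> module label (each gene in at most one module)
    universe: int  # N, total number of genes

    def __post_init__(self):
        if self.labels.index.has_duplicates:
            raise ValueError("a gene may belong to at most one module")
        sizes = self.labels.value_counts()
        if (sizes < 1).any() or sizes.sum() > self.universe:
            raise ValueError("module sizes must be >= 1 and sum to at most N")

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def modules(self) -> list:
        return sorted(self.labels.unique())


def read_modules_tsv(path, universe: Optional[int] = None) -> ModuleSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = df.iloc[:, 0]
    return ModuleSet(labels, universe if universe is not None else len(labels))


def _check_support(N, n_j, m_k, m_j):
    if not (0 <= m_k <= N and 0 <= n_j <= N):
        raise ValueError("require 0 <= n_j, m_k <= N")
    if not (max(0, n_j - (N - m_k)) <= m_j <= min(n_j, m_k)):
        raise ValueError(f"m_j={m_j} outside the hypergeometric support")


def hypergeom_tail(N: int, n_j: int, m_k: int, m_j: int) -> float:
    """Upper-tail P(X >= m_j): X = module genes among n_j draws from N.

    The over-representation probability of seeing at least the observed
    number of module genes among a TF's targets by chance.
    """
    _check_support(N, n_j, m_k, m_j)
    return float(hypergeom.sf(m_j - 1, N, m_k, n_j))


def hypergeom_point(N: int, n_j: int, m_k: int, m_j: int) -> float:
    """Point mass P(X = m_j), exposed for audit next to the tail."""
    _check_support(N, n_j, m_k, m_j)
    return float(hypergeom.pmf(m_j, N, m_k, n_j))


def odds_ratio(N: int, n_j: int, m_k: int, m_j: int) -> float:
    """(m_j / n_j) / (m_k / N): module share among targets vs overall."""
    if n_j <= 0 or m_k <= 0 or N <= 0:
        raise ValueError("n_j, m_k and N must be positive")
    return (m_j / n_j) / (m_k / N)


def enrichment_table(P: PMatrix, modules: ModuleSet) -> pd.DataFrame:
    """Hypergeometric tail and odds ratio for every TF x module pair."""
    N = modules.universe
    module_sizes = modules.module_sizes
    gene_module = modules.labels.reindex(P.genes)
    rows = []
    for j, tf in enumerate(P.tfs):
        targets = P.values[:, j] == 1
        n_j = int(targets.sum())
        target_modules = gene_module[targets].dropna()
        for mod, m_k in module_sizes.items():
            m_j = int((target_modules == mod).sum())
            H = hypergeom_tail(N, n_j, int(m_k), m_j)
            OR = odds_ratio(N, n_j, int(m_k), m_j) if n_j > 0 else np.nan
            rows.append((tf, mod, n_j, m_j, int(m_k), N, H, OR,
                         hypergeom_point(N, n_j, int(m_k), m_j)))
    return pd.DataFrame(rows, columns=["tf", "module", "n_targets", "m_in_module",
                                       "module_size", "universe", "hyper_tail",
                                       "odds_ratio", "hyper_point"])


def classify_module_specific(results: pd.DataFrame, alpha: float = 0.05,
                             expressed_tfs: Sequence = (),
                             bh_correct: bool = False) -> pd.DataFrame:
    """Flag module-specific TF x module pairs: tail < alpha and odds ratio > 1.

    No multiple-testing correction by default (Benjamini-Hochberg available
    behind ``bh_correct``).  A TF may qualify for several modules; the
    ``best_module`` column marks, per TF, the qualifying module with the
    smallest tail probability.  ``module_specific_expressed`` additionally
    requires the TF to have expression data.
    """
    out = results.copy()
    pvals = out["hyper_tail"].to_numpy(float)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
        out["hyper_tail_bh"] = pvals
    out["module_specific"] = (pvals < alpha) & (out["odds_ratio"] > 1)
    expressed = set(expressed_tfs)
    out["module_specific_expressed"] = out["module_specific"] & out["tf"].isin(expressed)
    out["best_module"] = False
    spec = out[out["module_specific"]]
    if len(spec):
        best_idx = spec.groupby("tf")["hyper_tail"].idxmin()
        out.loc[best_idx, "best_module"] = True
    return out


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame


def assortment_chi_square(edges: Sequence[tuple], module_of: dict) -> ChiSquareResult:
    """Chi-square independence test of module pairing over network edges.

    Each edge contributes one unordered module pair (within-module edges sit
    on the diagonal, counted once).  Expected counts come from the
    edge-endpoint module frequencies p_k = (2 * within_k + between_k) / 2E:
    E * p_k^2 on the diagonal and 2E * p_k * p_l off it — the independent-
    pairing null.  Degrees of freedom: number of unordered cells minus the
    K - 1 fitted frequencies minus 1, i.e. K(K+1)/2 - K.
    """
    pairs = []
    for a, b in edges:
        try:
            ma, mb = module_of[a], module_of[b]
        except KeyError as err:
            raise ValueError(f"network node without module label: {err}") from None
        pairs.append(tuple(sorted((ma, mb))))
    if not pairs:
        raise ValueError("network has no edges")
    mods = sorted({m for p in pairs for m in p})
    K = len(mods)
    if K < 2:
        raise ValueError("assortment test requires >= 2 modules among endpoints")
    idx = {m: i for i, m in enumerate(mods)}
    obs = np.zeros((K, K))
    for ma, mb in pairs:
        obs[idx[ma], idx[mb]] += 1  # upper triangle incl. diagonal
    E = len(pairs)
    endpoint = np.zeros(K)
    for i in range(K):
        endpoint[i] = 2 * obs[i, i] + (obs[i, :].sum() - obs[i, i]) + (obs[:, i].sum() - obs[i, i])
    p = endpoint / (2 * E)
    stat = 0.0
    exp = np.zeros((K, K))
    for i in range(K):
        for j in range(i, K):
            e = E * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            exp[i, j] = e
            if e > 0:
                stat += (obs[i, j] - e) ** 2 / e
    df = K * (K + 1) // 2 - K
    pval = float(chi2.sf(stat, df))
    return ChiSquareResult(float(stat), df, pval,
                           pd.DataFrame(obs, index=mods, columns=mods),
                           pd.DataFrame(exp, index=mods, columns=mods))
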