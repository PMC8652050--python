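"""Gene-set analyses of irAE-associated features.

Three complementary views:

- :func:`hypergeom_overlap` — exact over-representation of screen hits in a
  gene category (e.g. autoantigen genes) against a stated universe;
- :func:`preranked_gsea` — classic weighted Kolmogorov–Smirnov running-sum
  enrichment on a list ranked by correlation with irAE ROR, with a
  gene-label permutation null;
- :func:`sample_set_score` + :func:`group_compare` — a per-sample rank-based
  gene-set activity score (a deliberately simple single-sample statistic,
  not the GSVA kernel estimator) contrasted between high- and low-ROR cancer
  types by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from irsplice.descriptors import ExpressionMatrix
from irsplice.errors import GroupingError, InputError

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_overlap",
    "preranked_gsea",
    "sample_set_score",
    "group_compare",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe.

    Members outside the universe are dropped with a warning at construction.
    """

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        cleaned = {}
        for name, members in self.sets.items():
            inside = [g for g in members if g in uni]
            dropped = len(members) - len(inside)
            if dropped:
                warnings.warn(f"gene set {name!r}: dropped {dropped} member(s) outside universe")
            cleaned[name] = inside
        self.sets = cleaned


@dataclass
class EnrichmentResult:
    set_name: str
    statistic: float  # hypergeometric overlap count or enrichment score
    p_value: float
    n_overlap: int
    q_value: float = float("nan")
    nes: float = float("nan")


def hypergeom_overlap(hits, category, universe, set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test.

    With N = |universe|, K = |category| and n = |hits|, the p-value is
    P(X >= n_overlap) for X ~ Hypergeometric(N, K, n).
    """
    hits, category, universe = set(hits), set(category), set(universe)
    stray = hits - universe
    if stray:
        raise InputError(f"hits outside universe: {sorted(stray)[:5]}")
    stray = category - universe
    if stray:
        raise InputError(f"category genes outside universe: {sorted(stray)[:5]}")
    k = len(hits & category)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(category), len(hits)))
    return EnrichmentResult(
        set_name=set_name, statistic=float(k), p_value=min(p, 1.0), n_overlap=k
    )


def preranked_gsea(
    ranked: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    set_name: str = "",
) -> EnrichmentResult:
    """Preranked gene-set enrichment by the weighted running-sum statistic.

    ``ranked`` maps gene -> score (here: Spearman Rs with irAE ROR); genes are
    walked in decreasing score order, incrementing by |score|^weight
    (normalized over in-set genes) at set members and decrementing by
    1/(N-K) elsewhere.  ES is the maximum-magnitude excursion; NES and the
    p-value come from ``n_perm`` seeded gene-label permutations (same-sign
    null ES values, as in the standard two-sided convention).
    """
    ranked = ranked.dropna().astype(float)
    members = set(gene_set) & set(ranked.index)
    if len(members) < 3:
        warnings.warn(f"gene set {set_name!r}: fewer than 3 members in the ranked list; skipped")
        return EnrichmentResult(set_name=set_name, statistic=float("nan"),
                                p_value=float("nan"), n_overlap=len(members))
    order = ranked.sort_values(ascending=False, kind="mergesort")
    scores = order.to_numpy()
    is_hit = order.index.isin(members)
    es = _running_sum_es(scores, is_hit, weight)

    rng = np.random.default_rng(seed)
    K, N = int(is_hit.sum()), len(scores)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.zeros(N, dtype=bool)
        perm[rng.choice(N, size=K, replace=False)] = True
        null[b] = _running_sum_es(scores, perm, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        p, nes = 1.0 / (n_perm + 1), float("nan")
    else:
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        nes = es / np.mean(np.abs(same_sign))
    return EnrichmentResult(
        set_name=set_name, statistic=float(es), p_value=float(p),
        n_overlap=len(members), nes=float(nes),
    )


def _running_sum_es(scores: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    w = np.abs(scores) ** weight
    hit_norm = w[is_hit].sum()
    if hit_norm == 0:  # all in-set scores zero: fall back to equal weights
        steps_hit = np.where(is_hit, 1.0 / is_hit.sum(), 0.0)
    else:
        steps_hit = np.where(is_hit, w / hit_norm, 0.0)
    n_miss = len(scores) - int(is_hit.sum())
    steps_miss = np.where(is_hit, 0.0, 1.0 / n_miss) if n_miss else 0.0
    running = np.cumsum(steps_hit - steps_miss)
    return float(running[np.argmax(np.abs(running))])


def sample_set_score(expr: ExpressionMatrix, gene_set) -> pd.Series:
    """Per-sample rank-based gene-set activity score.

    Within each sample, all features are average-ranked; the score is the
    mean rank of set genes, centered at the null mean (N+1)/2 and scaled by
    the standard deviation of a mean of K ranks drawn without replacement,
    sqrt((N+1)(N-K)/(12K)).  Under exchangeable expression the score is
    approximately standard normal; it is invariant to any within-sample
    monotone transform of expression.  This is a simple single-sample
    statistic, not the GSVA kernel estimator.
    """
    members = [g for g in expr.tpm.index if g in set(gene_set)]
    if len(members) < 3:
        raise InputError("gene set shares fewer than 3 features with the matrix")
    ranks = expr.tpm.rank(axis=0)
    N = expr.tpm.shape[0]
    K = len(members)
    mean_rank = ranks.loc[members].mean(axis=0)
    null_mean = (N + 1) / 2.0
    null_sd = np.sqrt((N + 1) * (N - K) / (12.0 * K))
    if null_sd == 0:  # set == universe: score is identically 0
        return pd.Series(0.0, index=expr.tpm.columns)
    return (mean_rank - null_mean) / null_sd


def group_compare(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of high- vs low-ROR groups.

    Exact p for combined n <= 20 without ties; normal approximation with tie
    correction otherwise.  Returns (Mann-Whitney U of the 'high' group, p).
    """
    groups = groups.reindex(values.index)
    hi = values[groups == "high"].dropna()
    lo = values[groups == "low"].dropna()
    if hi.empty or lo.empty:
        raise GroupingError("both groups must be non-empty")
    n = len(hi) + len(lo)
    has_ties = pd.concat([hi, lo]).duplicated().any()
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
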