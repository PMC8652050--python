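"""Pan-cancer univariate screen: Spearman correlation of descriptors with irAE ROR.

Every descriptor (one value per cancer type) is correlated with the irAE
reporting odds ratio across cancer types with the tie-aware Spearman rank
correlation Rs.  Selection follows the raw-p rule (p < alpha, default 0.05);
Benjamini–Hochberg q-values are also reported, computed within one family per
descriptor class so that the huge gene/isoform families do not dilute the
small load/covariate families.

With ~19 cancer types these are small-n correlations: features are screened
only if at least ``min_pairs`` complete (descriptor, ROR) pairs remain after
pairwise deletion of missing values, and constant features are skipped with
an undefined-correlation flag rather than reported as Rs = 0.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from irsplice.descriptors import DescriptorTable
from irsplice.errors import InsufficientDataError

__all__ = ["spearman", "screen", "bh_adjust", "overlap_with_gene_level"]


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation and its p-value.

    Rs is the Pearson correlation of average ranks.  The p-value uses the
    t approximation t = Rs * sqrt((n-2)/(1-Rs^2)) on n-2 degrees of freedom;
    with ``exact=True`` (n <= 9 only) the p-value is instead the exact
    permutation tail probability P(|Rs_perm| >= |Rs|).

    Missing values are removed pairwise; fewer than 4 complete pairs raise
    :class:`InsufficientDataError`, and a zero-variance vector raises
    ``ValueError`` (callers treat it as an undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rs) - 1e-12:
                count += 1
            total += 1
        return rs, count / total
    return rs, _t_approx_p(rs, n)


def _t_approx_p(rs, n):
    """Two-sided p from the t approximation; vectorized over rs."""
    rs = np.asarray(rs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rs) >= 1.0, 0.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def screen(
    d: DescriptorTable,
    ror: pd.Series,
    alpha: float = 0.05,
    min_pairs: int = 8,
) -> pd.DataFrame:
    """Screen every descriptor against the ROR vector.

    Returns a DataFrame indexed by feature with columns ``rs``, ``p_value``,
    ``q_value`` (BH within the feature's class family), ``n_used``,
    ``direction`` and ``selected``, sorted by Rs descending.  Features with
    fewer than ``min_pairs`` complete pairs or with zero variance are
    excluded (a warning reports how many were skipped).
    """
    common = d.values.index.intersection(ror.index)
    if len(common) < min_pairs:
        warnings.warn("no feature passes min_pairs; empty screen result")
        return _empty_screen()
    X = d.values.loc[common]
    y = ror.loc[common].astype(float)

    rows = []
    n_skipped = 0
    complete = X.columns[X.notna().all(axis=0)]
    if len(complete) and y.notna().all():
        rs, p, n = _vectorized_spearman(X[complete].to_numpy(dtype=float), y.to_numpy())
        for j, feat in enumerate(complete):
            if math.isnan(rs[j]):
                n_skipped += 1
                continue
            rows.append((feat, rs[j], p[j], n))
    else:
        complete = pd.Index([])
    for feat in X.columns.difference(complete):
        xv = X[feat].to_numpy(dtype=float)
        ok = ~(np.isnan(xv) | y.isna().to_numpy())
        if ok.sum() < min_pairs:
            n_skipped += 1
            continue
        try:
            rs_f, p_f = spearman(xv[ok], y.to_numpy()[ok])
        except (ValueError, InsufficientDataError):
            n_skipped += 1
            continue
        rows.append((feat, rs_f, p_f, int(ok.sum())))
    if n_skipped:
        warnings.warn(f"screen skipped {n_skipped} feature(s): "
                      "insufficient pairs or undefined correlation")
    if not rows:
        warnings.warn("no feature passes min_pairs; empty screen result")
        return _empty_screen()

    res = pd.DataFrame(rows, columns=["feature_id", "rs", "p_value", "n_used"])
    res = res.set_index("feature_id")
    res["class"] = d.classes.reindex(res.index)
    res["q_value"] = np.nan
    for _, idx in res.groupby("class", dropna=False).groups.items():
        res.loc[idx, "q_value"] = bh_adjust(res.loc[idx, "p_value"].to_numpy())
    res["direction"] = np.where(res["rs"] >= 0, "positive", "negative")
    res["selected"] = res["p_value"] < alpha
    return res.sort_values("rs", ascending=False)


def _vectorized_spearman(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Column-wise tie-aware Rs of X against y, shared complete index."""
    n = y.size
    ry = stats.rankdata(y)
    rX = stats.rankdata(X, axis=0)
    rXc = rX - rX.mean(axis=0)
    ryc = ry - ry.mean()
    denom = np.sqrt((rXc**2).sum(axis=0) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (rXc * ryc[:, None]).sum(axis=0) / denom
    rs = np.where(denom == 0, np.nan, rs)
    p = _t_approx_p(rs, n)
    return rs, p, n


def _empty_screen() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["rs", "p_value", "n_used", "class", "q_value", "direction", "selected"],
        index=pd.Index([], name="feature_id"),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input p-values must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_with_gene_level(
    gene_hits: set[str], isoform_hits: set[tuple[str, str]]
) -> dict[str, set[str]]:
    """Partition genes by the analysis level at which they were hit.

    ``isoform_hits`` are (isoform_id, parent_gene) pairs.  Returns the genes
    significant only at gene level, only at isoform level, and at both —
    isoform-only genes are exactly those a gene-level analysis would miss.
    """
    for pair in isoform_hits:
        if len(pair) != 2 or not pair[1]:
            raise ValueError(f"isoform hit without parent gene: {pair!r}")
    iso_genes = {parent for _, parent in isoform_hits}
    return {
        "gene_only": set(gene_hits) - iso_genes,
        "isoform_only": iso_genes - set(gene_hits),
        "both": set(gene_hits) & iso_genes,
    }
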