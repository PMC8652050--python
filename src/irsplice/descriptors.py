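"""Per-cancer-type splicing descriptors from PSI and TPM matrices.

Four classes of splicing characteristics are computed at the cancer-type
level (the unit of the downstream correlation screen):

1. expression of splicing factors (median log2(TPM + 0.001) per type);
2. splicing levels: splicing load (events per sample — total, per splicing
   mode, per PSI inclusion category) and splicing frequency (per gene, the
   proportion of samples with any detected event of that gene);
3. neoantigen-related: neojunction load and autoantigen splicing load;
4. expression of splicing isoforms.

PSI (percent spliced in) is the fraction of transcripts including a splicing
element, in [0, 1]; a missing PSI value means the event was not quantified
("detected") in that sample.  Events are one of five modes: AS3/AS5
(alternative 3'/5' splice site), EX (exon skipping), MEX (mutually exclusive
exons), RI (intron retention).

The fixed pipeline order for expression classes is: low-abundance filter on
raw TPM -> per-type median of raw TPM -> log2(median + 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from irsplice.errors import InputError

AS_MODES = ("AS3", "AS5", "EX", "MEX", "RI")

PSI_CATEGORIES = (
    "highly_excluded",  # psi <= 0.20
    "mid_excluded",     # 0.20 < psi <= 0.40
    "mid_included",     # 0.40 < psi <= 0.80
    "highly_included",  # psi > 0.80
)


@dataclass(frozen=True)
class AsEvent:
    event_id: str
    gene: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in AS_MODES:
            raise ValueError(f"unknown AS mode {self.mode!r}; expected one of {AS_MODES}")


@dataclass
class PsiMatrix:
    """Alternative-splicing events x samples PSI values.

    ``psi`` is events x samples with NaN for unquantified observations;
    ``events`` is indexed by event_id with columns ``gene`` and ``mode``.
    """

    psi: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.psi.index.is_unique:
            raise InputError("duplicate event ids in PSI matrix")
        if not self.psi.index.equals(self.events.index):
            raise InputError("PSI rows and event annotations do not align")
        vals = self.psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise InputError("PSI values must lie in [0, 1]")
        bad = set(self.events["mode"]) - set(AS_MODES)
        if bad:
            raise InputError(f"unknown AS modes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)


@dataclass
class ExpressionMatrix:
    """Features x samples TPM matrix (genes, isoforms or splicing factors).

    Isoform matrices carry a ``parent_gene`` series mapping isoform id to its
    gene.
    """

    tpm: pd.DataFrame
    kind: str = "gene"  # gene | isoform | splicing_factor
    parent_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy(dtype=float) < 0).any():
            raise InputError("TPM values must be non-negative")
        if self.parent_gene is not None:
            self.parent_gene = self.parent_gene.reindex(self.tpm.index)
            if self.parent_gene.isna().any():
                missing = list(self.parent_gene[self.parent_gene.isna()].index[:5])
                raise InputError(f"isoforms without parent gene: {missing}")


@dataclass
class DescriptorTable:
    """Cancer types x descriptor features, the design matrix of the screen.

    ``classes`` tags every feature with its descriptor class
    (splicing_factor_expr, gene_expr, isoform_expr, splicing_frequency,
    splicing_load_*, neojunction_load, autoantigen_load, covariate);
    ``parent`` optionally maps a feature to its parent gene.
    """

    values: pd.DataFrame
    classes: pd.Series
    parent: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise InputError("duplicate descriptor feature ids")
        self.classes = self.classes.reindex(self.values.columns)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def join(self, other: "DescriptorTable") -> "DescriptorTable":
        """Column-concatenate two descriptor tables over the same cancer types."""
        values = self.values.join(other.values, how="outer")
        classes = pd.concat([self.classes, other.classes])
        parent = pd.concat([self.parent, other.parent])
        return DescriptorTable(values=values, classes=classes, parent=parent)


# ---------------------------------------------------------------------------
# expression-side operations


def filter_low_abundance(
    m: ExpressionMatrix, max_gt: float = 10.0, median_gt: float = 2.0
) -> ExpressionMatrix:
    """Drop low-abundance features: keep max TPM > ``max_gt`` AND median TPM > ``median_gt``.

    Both inequalities are strict. Idempotent.
    """
    tpm = m.tpm
    keep = (tpm.max(axis=1) > max_gt) & (tpm.median(axis=1) > median_gt)
    parent = m.parent_gene[keep] if m.parent_gene is not None else None
    return ExpressionMatrix(tpm=tpm.loc[keep], kind=m.kind, parent_gene=parent)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 0.001).

    The 0.001 offset keeps unexpressed features finite (log2(0.001) ~ -9.97).
    Output is no longer a TPM matrix; negative values are expected.
    """
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.tpm = np.log2(m.tpm + 0.001)
    out.kind = m.kind
    out.parent_gene = m.parent_gene
    return out


def median_by_cancer_type(m: ExpressionMatrix, sample_map: pd.Series) -> pd.DataFrame:
    """Per-(feature, cancer type) median: cancer types x features.

    ``sample_map`` maps sample id -> cancer type and must cover every sample
    in the matrix.
    """
    missing = [s for s in m.tpm.columns if s not in sample_map.index]
    if missing:
        raise InputError(f"samples absent from sample map: {missing[:5]}")
    groups = sample_map.loc[m.tpm.columns]
    return m.tpm.T.groupby(groups).median()


_CLASS_BY_KIND = {
    "gene": "gene_expr",
    "isoform": "isoform_expr",
    "splicing_factor": "splicing_factor_expr",
}


def expression_descriptors(
    m: ExpressionMatrix,
    sample_map: pd.Series,
    prefix: str | None = None,
    max_gt: float = 10.0,
    median_gt: float = 2.0,
) -> DescriptorTable:
    """Full expression pipeline: abundance filter -> per-type median -> log2(x+0.001)."""
    kept = filter_low_abundance(m, max_gt=max_gt, median_gt=median_gt)
    med = median_by_cancer_type(kept, sample_map)
    med = np.log2(med + 0.001)
    cls = _CLASS_BY_KIND.get(m.kind, m.kind)
    prefix = prefix if prefix is not None else {"gene": "gene", "isoform": "iso",
                                               "splicing_factor": "sf"}.get(m.kind, m.kind)
    values = med.rename(columns=lambda f: f"{prefix}:{f}")
    classes = pd.Series(cls, index=values.columns)
    if kept.parent_gene is not None:
        parent = kept.parent_gene.rename(index=lambda f: f"{prefix}:{f}")
    else:
        parent = pd.Series({f"{prefix}:{f}": f for f in kept.tpm.index})
    return DescriptorTable(values=values, classes=classes, parent=parent)


# ---------------------------------------------------------------------------
# PSI-side operations


def filter_as_events(
    p: PsiMatrix,
    min_samples: int = 10,
    psi_low: float = 0.05,
    psi_high: float = 0.95,
) -> PsiMatrix:
    """Confidence filter for AS events, in fixed order.

    Step 1 keeps events detected (non-missing) in strictly more than
    ``min_samples`` samples.  Step 2 masks individual observations with
    PSI < ``psi_low`` or PSI > ``psi_high`` (near-constitutive inclusion or
    exclusion, likely quantification noise).  Events left with no retained
    observation are dropped.  Idempotent.
    """
    detected = p.psi.notna().sum(axis=1) > min_samples
    psi = p.psi.loc[detected]
    psi = psi.where((psi >= psi_low) & (psi <= psi_high))
    nonempty = psi.notna().any(axis=1)
    psi = psi.loc[nonempty]
    return PsiMatrix(psi=psi, events=p.events.loc[psi.index])


def _check_filtered(p: PsiMatrix, psi_low: float, psi_high: float) -> None:
    vals = p.psi.to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size and (obs.min() < psi_low or obs.max() > psi_high):
        raise InputError(
            "PSI matrix contains observations outside "
            f"[{psi_low}, {psi_high}]; run filter_as_events first"
        )


def psi_category(psi: np.ndarray | float) -> np.ndarray:
    """Inclusion category of each PSI value.

    Boundaries are closed on the upper end so the four categories partition
    [0, 1]: psi <= 0.20 highly_excluded; <= 0.40 mid_excluded; <= 0.80
    mid_included; > 0.80 highly_included.
    """
    arr = np.asarray(psi, dtype=float)
    idx = np.digitize(arr, [0.20, 0.40, 0.80], right=True)
    return np.asarray(PSI_CATEGORIES, dtype=object)[idx]


def splicing_load(
    p: PsiMatrix, psi_low: float = 0.05, psi_high: float = 0.95
) -> pd.DataFrame:
    """Per-sample splicing load: total, per AS mode, and per PSI category.

    The load is the count of retained (non-missing) event observations in the
    sample; mode counts and category counts each partition the total.  The
    matrix must already have passed :func:`filter_as_events`.
    """
    _check_filtered(p, psi_low, psi_high)
    detected = p.psi.notna()
    out = pd.DataFrame(index=p.psi.columns)
    out["total"] = detected.sum(axis=0)
    for mode in AS_MODES:
        out[f"mode:{mode}"] = detected.loc[p.events["mode"] == mode].sum(axis=0)
    vals = p.psi.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cat_idx = np.digitize(vals, [0.20, 0.40, 0.80], right=True)
    for i, cat in enumerate(PSI_CATEGORIES):
        out[f"cat:{cat}"] = ((cat_idx == i) & detected.to_numpy()).sum(axis=0)
    return out


def splicing_frequency(p: PsiMatrix, sample_map: pd.Series) -> pd.DataFrame:
    """Per (cancer type, gene): proportion of samples with any detected event of the gene.

    Multiple events of one gene detected in the same sample count once.
    Returns cancer types x genes in [0, 1]; a gene with no retained events is
    0 everywhere.
    """
    missing = [s for s in p.psi.columns if s not in sample_map.index]
    if missing:
        raise InputError(f"samples absent from sample map: {missing[:5]}")
    detected = p.psi.notna()
    # sample has the gene spliced iff any of its events is detected
    by_gene = detected.groupby(p.events["gene"]).any()
    groups = sample_map.loc[by_gene.columns]
    return by_gene.T.groupby(groups).mean()


def neojunction_load(counts: pd.Series, sample_map: pd.Series) -> pd.Series:
    """Per-cancer-type median of per-sample neojunction counts.

    Neojunctions are tumor-specific splice junctions; their per-sample counts
    are taken as an input (pre-computed upstream).
    """
    if (counts < 0).any():
        raise InputError("neojunction counts must be non-negative")
    missing = [s for s in counts.index if s not in sample_map.index]
    if missing:
        raise InputError(f"samples absent from sample map: {missing[:5]}")
    return counts.groupby(sample_map.loc[counts.index]).median()


def autoantigen_load(
    p: PsiMatrix,
    autoantigens: set[str],
    sample_map: pd.Series,
    psi_low: float = 0.05,
    psi_high: float = 0.95,
) -> pd.Series:
    """Per-cancer-type median of the per-sample count of autoantigen-gene AS events.

    Restriction of the total splicing load to events whose gene is on the
    autoantigen list; the empty list yields all-zero loads.
    """
    _check_filtered(p, psi_low, psi_high)
    in_set = p.events["gene"].isin(autoantigens)
    per_sample = p.psi.loc[in_set].notna().sum(axis=0)
    return per_sample.groupby(sample_map.loc[per_sample.index]).median()


def splicing_level_descriptors(
    p: PsiMatrix, sample_map: pd.Series, autoantigens: set[str] | None = None
) -> DescriptorTable:
    """Type-level descriptors of splicing level: load medians and splicing frequency."""
    load = splicing_load(p)
    groups = sample_map.loc[load.index]
    load_med = load.groupby(groups).median()
    cols, classes = {}, {}
    cols["load:total"] = load_med["total"]
    classes["load:total"] = "splicing_load_total"
    for mode in AS_MODES:
        cols[f"load:{mode}"] = load_med[f"mode:{mode}"]
        classes[f"load:{mode}"] = "splicing_load_mode"
    for cat in PSI_CATEGORIES:
        cols[f"load:{cat}"] = load_med[f"cat:{cat}"]
        classes[f"load:{cat}"] = "splicing_load_category"
    values = pd.DataFrame(cols)
    if autoantigens is not None:
        values["autoantigen_load"] = autoantigen_load(p, autoantigens, sample_map)
        classes["autoantigen_load"] = "autoantigen_load"
    freq = splicing_frequency(p, sample_map).rename(columns=lambda g: f"freq:{g}")
    values = values.join(freq)
    for col in freq.columns:
        classes[col] = "splicing_frequency"
    parent = pd.Series({col: col.split(":", 1)[1] for col in freq.columns})
    return DescriptorTable(values=values, classes=pd.Series(classes), parent=parent)


# ---------------------------------------------------------------------------
# file IO (tab-separated text formats)


def read_psi(path) -> PsiMatrix:
    """Read a wide PSI table: event_id, gene, mode, then one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col="event_id")
    events = df[["gene", "mode"]]
    psi = df.drop(columns=["gene", "mode"]).astype(float)
    return PsiMatrix(psi=psi, events=events)


def write_psi(p: PsiMatrix, path) -> None:
    p.events.join(p.psi).to_csv(path, sep="\t", index_label="event_id")


def read_expression(path, kind: str = "gene") -> ExpressionMatrix:
    """Read a wide TPM table; isoform tables carry a parent_gene column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    parent = None
    if "parent_gene" in df.columns:
        parent = df.pop("parent_gene")
    return ExpressionMatrix(tpm=df.astype(float), kind=kind, parent_gene=parent)


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.tpm
    if m.parent_gene is not None:
        df = pd.concat([m.parent_gene.rename("parent_gene"), df], axis=1)
    df.to_csv(path, sep="\t", index_label=f"{m.kind}_id")


def read_sample_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")["cancer_type"]


def write_descriptors(d: DescriptorTable, path, features_path=None) -> None:
    d.values.to_csv(path, sep="\t", index_label="cancer_type")
    if features_path is not None:
        side = pd.DataFrame(
            {"class": d.classes, "parent_gene": d.parent.reindex(d.classes.index)}
        )
        side.to_csv(features_path, sep="\t", index_label="feature_id")


def read_descriptors(path, features_path=None) -> DescriptorTable:
    values = pd.read_csv(path, sep="\t", index_col="cancer_type")
    if features_path is not None:
        side = pd.read_csv(features_path, sep="\t", index_col="feature_id")
        classes = side["class"]
        parent = side["parent_gene"].dropna()
    else:
        classes = pd.Series("covariate", index=values.columns)
        parent = pd.Series(dtype=object)
    return DescriptorTable(values=values, classes=classes, parent=parent)
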