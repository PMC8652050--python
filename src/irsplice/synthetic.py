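"""Synthetic study inputs with planted ground truth.

Generates every input the pipeline consumes — PSI event matrices, gene /
isoform / splicing-factor TPM matrices, per-sample neojunction counts,
adverse-event report tables, covariates and gene-set collections — for a
configurable number of cancer types with a known, planted monotone link
between cancer-type-level descriptors and the true log reporting odds ratio
(log-ROR).

The signal is injected at the cancer-type level, the unit of the downstream
correlation screen: each type t has a latent true log-ROR; for a planted
feature with direction s, the per-type location of that feature is shifted
by ``s * effect_size * z_t`` where z_t is the standardized true log-ROR.
Within-type sampling noise comes on top.  Concretely:

- expression features (gene/isoform/splicing-factor): log2-TPM is Gaussian
  around a feature baseline plus the planted shift (log-normal TPM);
- splicing frequency: planted genes' events have a per-type detection
  probability that is logit-shifted by the planted term;
- PSI values: Beta-distributed given detection, with per-event mean and a
  common concentration;
- adverse-event reports: per-type irAE counts are binomial with the irAE
  log-odds shifted by the true log-ROR, against one shared comparator table,
  so the estimated log-ROR is a consistent estimate of the truth;
- covariates emulate PD-L1 protein (negative direction), fPD1 (positive)
  and TMB (null); neojunction counts are Poisson with a weak positive link.

With ``effect_size = 0`` every feature is null (exchangeable across types).
All draws are pure functions of ``(config, seed)`` via independent named
substreams, so adding draws to one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from irsplice import descriptors as de
from irsplice.descriptors import AS_MODES, ExpressionMatrix, PsiMatrix
from irsplice.enrichment import GeneSetCollection, write_gmt
from irsplice.errors import ConfigError
from irsplice.pharmacovigilance import ReportTable2x2

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_cohort",
    "generate_reports",
    "generate_gene_sets",
    "generate_neojunctions",
    "generate_covariates",
    "simulate_study",
    "write_study",
]

# the 19 TCGA cancer-type codes retained by the >= 1000-ICI-report filter
TCGA_19 = (
    "BLCA", "BRCA", "CESC", "CHOL", "COAD", "ESCA", "GBM", "HNSC", "LIHC",
    "LUAD", "LUSC", "MESO", "OV", "PAAD", "PRAD", "SARC", "SKCM", "STAD",
    "UCEC",
)

# substream ids: one per generator, so draw counts never cross-contaminate
_STREAMS = {
    "truth": 0, "psi": 1, "gene": 2, "isoform": 3, "sf": 4,
    "reports": 5, "gene_sets": 6, "neojunction": 7, "covariates": 8,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    ``effect_size`` is the per-standard-deviation-of-log-ROR shift of a
    planted feature's cancer-type location, in log2-TPM units for expression
    features and logit units for detection probabilities; the default 1.0
    gives planted type-level signal well above the within-type median noise
    at 40 samples per type.  ``log_ror_sd`` sets the spread of true
    log-RORs across cancer types (0.6 spans RORs of roughly 0.3 to 3).
    """

    n_cancer_types: int = 19
    samples_per_type: int = 40
    n_events: int = 300
    n_genes: int = 500
    n_isoforms: int = 300
    n_splicing_factors: int = 120
    frac_planted: float = 0.1
    effect_size: float = 1.0
    psi_concentration: float = 20.0
    reports_per_type: int = 5000
    base_irae_rate: float = 0.2
    log_ror_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer_types", "samples_per_type", "n_events", "n_genes",
                     "n_isoforms", "n_splicing_factors", "reports_per_type"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_planted", "base_irae_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.psi_concentration <= 0:
            raise ConfigError(
                f"psi_concentration must be > 0, got {self.psi_concentration}"
            )
        if self.log_ror_sd < 0:
            raise ConfigError(f"log_ror_sd must be >= 0, got {self.log_ror_sd}")


@dataclass
class GroundTruth:
    """Planted feature directions and the latent per-type log-ROR."""

    planted_features: dict[str, int]  # feature_id -> +1 / -1
    true_log_ror: pd.Series  # cancer_type -> real

    @property
    def z(self) -> pd.Series:
        """Standardized true log-ROR (the planted covariate)."""
        t = self.true_log_ror
        sd = t.std(ddof=0)
        return (t - t.mean()) / sd if sd > 0 else t * 0.0


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), _STREAMS[stream]))
    )


def _cancer_types(config: SimConfig) -> list[str]:
    if config.n_cancer_types == len(TCGA_19):
        return list(TCGA_19)
    return [f"CT{i + 1:02d}" for i in range(config.n_cancer_types)]


def _ground_truth(config: SimConfig) -> GroundTruth:
    rng = _rng(config, "truth")
    types = _cancer_types(config)
    tlr = pd.Series(rng.normal(0.0, config.log_ror_sd, len(types)), index=types)
    return GroundTruth(planted_features={}, true_log_ror=tlr)


def _plant(rng, ids, frac) -> dict[str, int]:
    k = int(round(frac * len(ids)))
    chosen = rng.choice(len(ids), size=k, replace=False)
    dirs = rng.choice([-1, 1], size=k)
    return {ids[i]: int(d) for i, d in zip(sorted(chosen), dirs)}


def _expression(rng, ids, planted, z, config, baseline_mean, baseline_sd,
                within_sd=1.0) -> pd.DataFrame:
    """Log-normal TPM: log2-TPM Gaussian around baseline + planted shift."""
    types = z.index
    S = config.samples_per_type
    samples = [f"{ct}_{i:03d}" for ct in types for i in range(S)]
    base = rng.normal(baseline_mean, baseline_sd, len(ids))
    shift = np.zeros((len(ids), len(types)))
    for j, fid in enumerate(ids):
        s = planted.get(fid, 0)
        if s:
            shift[j] = s * config.effect_size * z.to_numpy()
    shift_per_sample = np.repeat(shift, S, axis=1)
    log2tpm = base[:, None] + shift_per_sample + rng.normal(0, within_sd,
                                                            (len(ids), len(samples)))
    return pd.DataFrame(2.0 ** log2tpm, index=ids, columns=samples)


def generate_cohort(
    config: SimConfig,
) -> tuple[PsiMatrix, ExpressionMatrix, ExpressionMatrix, ExpressionMatrix,
           pd.Series, GroundTruth]:
    """Generate the transcriptomic cohort and its ground truth.

    Returns (psi, gene expression, isoform expression, splicing-factor
    expression, sample map, ground truth).  Deterministic given the config
    seed; with ``effect_size = 0`` no feature location covaries with the
    true log-ROR.
    """
    truth = _ground_truth(config)
    z = truth.z
    types = list(z.index)
    S = config.samples_per_type
    samples = [f"{ct}_{i:03d}" for ct in types for i in range(S)]
    sample_map = pd.Series(
        np.repeat(types, S), index=samples, name="cancer_type"
    )

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    isoforms = [f"{genes[i % config.n_genes]}-2{i // config.n_genes + 1:02d}"
                for i in range(config.n_isoforms)]
    iso_parent = pd.Series(
        {iso: iso.rsplit("-", 1)[0] for iso in isoforms}, name="parent_gene"
    )
    sfs = [f"SF{i + 1:04d}" for i in range(config.n_splicing_factors)]

    rng_g, rng_i, rng_s = (_rng(config, k) for k in ("gene", "isoform", "sf"))
    planted = {}
    planted.update(_plant(rng_g, [f"gene:{g}" for g in genes], config.frac_planted))
    planted.update(_plant(rng_i, [f"iso:{i}" for i in isoforms], config.frac_planted))
    planted.update(_plant(rng_s, [f"sf:{s}" for s in sfs], config.frac_planted))

    expr_gene = ExpressionMatrix(
        tpm=_expression(rng_g, genes, {k.split(":", 1)[1]: v for k, v in planted.items()
                                       if k.startswith("gene:")},
                        z, config, baseline_mean=5.0, baseline_sd=1.5),
        kind="gene",
    )
    expr_iso = ExpressionMatrix(
        tpm=_expression(rng_i, isoforms, {k.split(":", 1)[1]: v for k, v in planted.items()
                                          if k.startswith("iso:")},
                        z, config, baseline_mean=4.5, baseline_sd=1.5),
        kind="isoform",
        parent_gene=iso_parent,
    )
    expr_sf = ExpressionMatrix(
        tpm=_expression(rng_s, sfs, {k.split(":", 1)[1]: v for k, v in planted.items()
                                     if k.startswith("sf:")},
                        z, config, baseline_mean=5.5, baseline_sd=1.2),
        kind="splicing_factor",
    )

    psi, freq_planted = _generate_psi(config, z, genes, sample_map)
    planted.update(freq_planted)
    truth.planted_features = planted
    return psi, expr_gene, expr_iso, expr_sf, sample_map, truth


def _generate_psi(config, z, genes, sample_map):
    """PSI matrix with frequency-planted genes.

    Planted genes receive two dedicated events whose per-type detection
    probability is logit-shifted by the planted term; all other events have a
    constant detection probability, so with effect_size = 0 splicing
    frequency is exchangeable across types.
    """
    rng = _rng(config, "psi")
    samples = list(sample_map.index)
    n_ev = config.n_events
    n_freq = int(round(config.frac_planted * len(genes)))
    n_freq = min(n_freq, n_ev // 4)  # each planted gene needs 2 events
    freq_gene_idx = rng.choice(len(genes), size=n_freq, replace=False)
    freq_dirs = rng.choice([-1, 1], size=n_freq)

    event_genes = []
    planted_dir = np.zeros(n_ev)
    for j, (gi, d) in enumerate(zip(freq_gene_idx, freq_dirs)):
        event_genes += [genes[gi], genes[gi]]
        planted_dir[2 * j] = planted_dir[2 * j + 1] = d
    rest = rng.integers(0, len(genes), size=n_ev - len(event_genes))
    event_genes += [genes[i] for i in rest]

    event_ids = [f"EV{i + 1:06d}" for i in range(n_ev)]
    modes = rng.choice(AS_MODES, size=n_ev, p=[0.15, 0.15, 0.40, 0.10, 0.20])
    means = rng.uniform(0.15, 0.85, size=n_ev)
    base_det = np.where(planted_dir != 0, 0.6, rng.uniform(0.4, 0.9, size=n_ev))

    z_per_sample = z.loc[sample_map.to_numpy()].to_numpy()
    det_logit = (logit(base_det)[:, None]
                 + planted_dir[:, None] * config.effect_size * z_per_sample[None, :])
    detected = rng.random((n_ev, len(samples))) < expit(det_logit)

    kappa = config.psi_concentration
    a = means * kappa
    b = (1.0 - means) * kappa
    vals = rng.beta(a[:, None], b[:, None], size=(n_ev, len(samples)))
    vals = np.where(detected, vals, np.nan)

    psi = PsiMatrix(
        psi=pd.DataFrame(vals, index=event_ids, columns=samples),
        events=pd.DataFrame({"gene": event_genes, "mode": modes},
                            index=pd.Index(event_ids, name="event_id")),
    )
    freq_planted = {f"freq:{genes[gi]}": int(d)
                    for gi, d in zip(freq_gene_idx, freq_dirs)}
    return psi, freq_planted


def generate_reports(config: SimConfig, truth: GroundTruth) -> list[ReportTable2x2]:
    """Binomial adverse-event report tables, one per cancer type.

    Per-type irAE probability is ``expit(logit(base_irae_rate) +
    true_log_ror)``, so the population log-ROR against the shared comparator
    (whose irAE rate is the base rate) equals the true log-ROR exactly; the
    estimate from finite counts is a consistent, noisy version of it.
    """
    rng = _rng(config, "reports")
    # one shared "entire database" comparator stratum for all cancer types
    comparator_total = 50 * config.reports_per_type
    c = int(rng.binomial(comparator_total, config.base_irae_rate))
    d = comparator_total - c
    tables = []
    base_logit = logit(config.base_irae_rate)
    for ct, tlr in truth.true_log_ror.items():
        p = expit(base_logit + tlr)
        a = int(rng.binomial(config.reports_per_type, p))
        tables.append(ReportTable2x2(cancer_type=str(ct), a=a,
                                     b=config.reports_per_type - a, c=c, d=d))
    return tables


def generate_neojunctions(config: SimConfig, truth: GroundTruth) -> pd.Series:
    """Per-sample neojunction counts, Poisson with a weak positive planted link."""
    rng = _rng(config, "neojunction")
    z = truth.z
    samples = [f"{ct}_{i:03d}" for ct in z.index for i in range(config.samples_per_type)]
    lam = 20.0 * np.exp(0.15 * config.effect_size
                        * z.loc[[s.rsplit("_", 1)[0] for s in samples]].to_numpy())
    counts = pd.Series(rng.poisson(lam), index=samples, name="count")
    if config.effect_size > 0:
        truth.planted_features.setdefault("neojunction_load", 1)
    return counts


def generate_covariates(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-type covariates: PD-L1 protein (negative), fPD1 (positive), TMB (null)."""
    rng = _rng(config, "covariates")
    z = truth.z
    e = config.effect_size
    pdl1 = 1.5 - 0.4 * e * z + rng.normal(0, 0.15, len(z))
    fpd1 = np.clip(0.4 + 0.1 * e * z + rng.normal(0, 0.04, len(z)), 0.0, 1.0)
    tmb = rng.lognormal(1.5, 0.5, len(z))
    if e > 0:
        truth.planted_features.setdefault("PDL1_protein", -1)
        truth.planted_features.setdefault("fPD1", 1)
    return pd.DataFrame({"PDL1_protein": pdl1, "fPD1": fpd1, "TMB": tmb},
                        index=z.index)


def generate_gene_sets(
    config: SimConfig,
    truth: GroundTruth,
    n_sets: int = 8,
    set_size: int = 40,
    enrichment_fraction: float = 0.8,
    autoantigen_size: int = 50,
) -> tuple[GeneSetCollection, list[str]]:
    """Gene-set collection plus an autoantigen gene list.

    The first set, ``planted_enriched``, draws ``enrichment_fraction`` of its
    members from planted gene-expression features (for enrichment-recovery
    tests); the remaining sets and the autoantigen list are uniform draws
    from the gene universe.
    """
    rng = _rng(config, "gene_sets")
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    set_size = min(set_size, config.n_genes)
    planted_genes = sorted(
        k.split(":", 1)[1] for k in truth.planted_features if k.startswith("gene:")
    )
    n_from_planted = min(int(round(enrichment_fraction * set_size)), len(planted_genes))
    others = [g for g in genes if g not in set(planted_genes)]
    n_from_others = min(set_size - n_from_planted, len(others))
    sets = {}
    first = list(rng.choice(planted_genes, size=n_from_planted, replace=False)) if n_from_planted else []
    first += list(rng.choice(others, size=n_from_others, replace=False))
    sets["planted_enriched"] = sorted(first)
    for k in range(1, n_sets):
        sets[f"random_set_{k:02d}"] = sorted(
            rng.choice(genes, size=set_size, replace=False)
        )
    autoantigens = sorted(rng.choice(genes, size=min(autoantigen_size, len(genes)),
                                     replace=False))
    return GeneSetCollection(sets=sets, universe=genes), autoantigens


@dataclass
class SimulatedStudy:
    """Bundle of every synthetic pipeline input plus the ground truth."""

    config: SimConfig
    psi: PsiMatrix
    expr_gene: ExpressionMatrix
    expr_isoform: ExpressionMatrix
    expr_sf: ExpressionMatrix
    sample_map: pd.Series
    truth: GroundTruth
    reports: list[ReportTable2x2]
    neojunction_counts: pd.Series
    covariates: pd.DataFrame
    gene_sets: GeneSetCollection = None
    autoantigens: list[str] = field(default_factory=list)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate every pipeline input in one call (deterministic given seed)."""
    psi, eg, ei, es, sample_map, truth = generate_cohort(config)
    reports = generate_reports(config, truth)
    neo = generate_neojunctions(config, truth)
    cov = generate_covariates(config, truth)
    gsets, aag = generate_gene_sets(config, truth)
    return SimulatedStudy(
        config=config, psi=psi, expr_gene=eg, expr_isoform=ei, expr_sf=es,
        sample_map=sample_map, truth=truth, reports=reports,
        neojunction_counts=neo, covariates=cov, gene_sets=gsets,
        autoantigens=aag,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the standard pipeline input files (all tab-separated text)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    de.write_psi(study.psi, out / "psi.tsv")
    de.write_expression(study.expr_gene, out / "expr_gene.tsv")
    de.write_expression(study.expr_isoform, out / "expr_isoform.tsv")
    de.write_expression(study.expr_sf, out / "expr_sf.tsv")
    study.sample_map.rename_axis("sample_id").to_frame().to_csv(
        out / "samples.tsv", sep="\t"
    )
    study.neojunction_counts.rename_axis("sample_id").to_frame().to_csv(
        out / "neojunctions.tsv", sep="\t"
    )
    study.covariates.rename_axis("cancer_type").to_csv(out / "covariates.tsv", sep="\t")
    pd.DataFrame(
        [{"cancer_type": t.cancer_type, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
         for t in study.reports]
    ).to_csv(out / "reports.tsv", sep="\t", index=False)
    (out / "autoantigens.txt").write_text("\n".join(study.autoantigens) + "\n")
    write_gmt(study.gene_sets.sets, out / "gene_sets.gmt")
    pd.Series(study.truth.planted_features, name="planted_direction").rename_axis(
        "feature_id"
    ).to_frame().to_csv(out / "ground_truth.tsv", sep="\t")
    (out / "sim_config.yaml").write_text(yaml.safe_dump(asdict(study.config)))
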