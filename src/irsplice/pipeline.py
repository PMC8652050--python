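"""End-to-end convenience layer: inputs -> descriptors -> ROR -> screen.

Thin orchestration over the stage modules, used by the examples, the CLI and
the acceptance script.  Each helper takes the in-memory containers, so the
same code path serves synthetic studies and files read from disk.
"""

from __future__ import annotations

import pandas as pd

from irsplice import descriptors as de
from irsplice.descriptors import DescriptorTable
from irsplice.pharmacovigilance import (
    RorRecord,
    compute_ror,
    filter_cancer_types,
)
from irsplice.screen import screen

__all__ = ["build_descriptor_table", "ror_series", "run_screen"]


def build_descriptor_table(
    psi,
    expr_gene,
    expr_isoform,
    expr_sf,
    sample_map: pd.Series,
    neojunction_counts: pd.Series | None = None,
    autoantigens=None,
    covariates: pd.DataFrame | None = None,
) -> DescriptorTable:
    """Assemble the full cancer-type x feature descriptor table.

    Applies the expression pipeline (abundance filter, per-type median,
    log2(x+0.001)) to the three expression matrices, the AS-event filters to
    the PSI matrix, and appends load/frequency descriptors, neojunction and
    autoantigen loads, and any external covariates.
    """
    d = de.expression_descriptors(expr_sf, sample_map)
    d = d.join(de.expression_descriptors(expr_gene, sample_map))
    d = d.join(de.expression_descriptors(expr_isoform, sample_map))
    psi_f = de.filter_as_events(psi)
    d = d.join(
        de.splicing_level_descriptors(
            psi_f, sample_map, autoantigens=set(autoantigens) if autoantigens else None
        )
    )
    extras = {}
    classes = {}
    if neojunction_counts is not None:
        extras["neojunction_load"] = de.neojunction_load(neojunction_counts, sample_map)
        classes["neojunction_load"] = "neojunction_load"
    if covariates is not None:
        for col in covariates.columns:
            extras[col] = covariates[col]
            classes[col] = "covariate"
    if extras:
        d = d.join(DescriptorTable(values=pd.DataFrame(extras),
                                   classes=pd.Series(classes)))
    return d


def ror_series(
    reports, min_reports: int = 1000, scale: str = "natural"
) -> tuple[pd.Series, list[RorRecord]]:
    """Per-type ROR estimates from report tables, after the report-count filter.

    ``scale='natural'`` returns the ROR itself (the default regression
    response); ``'log'`` returns log-ROR.
    """
    records = filter_cancer_types([compute_ror(t) for t in reports], min_reports)
    key = "log_ror" if scale == "log" else "ror"
    series = pd.Series({r.cancer_type: getattr(r, key) for r in records}, name=key)
    return series, records


def run_screen(study, alpha: float = 0.05, min_reports: int = 1000) -> pd.DataFrame:
    """Full pipeline on a simulated study: descriptors, ROR, Spearman screen."""
    d = build_descriptor_table(
        study.psi, study.expr_gene, study.expr_isoform, study.expr_sf,
        study.sample_map, study.neojunction_counts, study.autoantigens,
        study.covariates,
    )
    y, _ = ror_series(study.reports, min_reports=min_reports)
    return screen(d, y, alpha=alpha)
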