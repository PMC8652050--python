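"""Reporting odds ratios (ROR) for irAE disproportionality, per cancer type.

The ROR is the classic pharmacovigilance disproportionality statistic for a
2x2 table of spontaneous safety reports::

                      irAE      no irAE
    ICI reports        a           b
    comparator         c           d

    ROR = (a/b) / (c/d) = a*d / (b*c)

The comparator stratum is the rest of the reporting database (all non-ICI
reports), so a ROR of 1 means irAEs are reported for checkpoint inhibitors at
the same rate as for every other drug.  Confidence intervals use the
log-normal approximation with se(log ROR) = sqrt(1/a + 1/b + 1/c + 1/d).
Zero cells receive the Haldane–Anscombe 0.5 continuity correction, flagged in
the output record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from irsplice.errors import GroupingError, UndefinedStratumError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ReportTable2x2:
    """Report counts for one cancer type.

    a: ICI reports with an irAE; b: ICI reports without; c/d: the same split
    for the comparator (all other drugs in the database).
    """

    cancer_type: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"report count {cell!r} must be >= 0")

    @property
    def n_ici_reports(self) -> int:
        return self.a + self.b


@dataclass(frozen=True)
class RorRecord:
    cancer_type: str
    ror: float
    log_ror: float
    se_log_ror: float
    ci95_low: float
    ci95_high: float
    n_ici_reports: int
    corrected: bool


def compute_ror(table: ReportTable2x2) -> RorRecord:
    """Estimate the reporting odds ratio for one cancer type.

    Applies the 0.5 continuity correction to all four cells when any cell is
    zero (``corrected=True`` in the result).

    Raises
    ------
    UndefinedStratumError
        If the ICI stratum (a+b) or the comparator stratum (c+d) is empty.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedStratumError(
            f"{table.cancer_type}: empty exposure or comparator stratum"
        )
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    log_ror = math.log(ror)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorRecord(
        cancer_type=table.cancer_type,
        ror=ror,
        log_ror=log_ror,
        se_log_ror=se,
        ci95_low=math.exp(log_ror - Z_95 * se),
        ci95_high=math.exp(log_ror + Z_95 * se),
        n_ici_reports=table.n_ici_reports,
        corrected=corrected,
    )


def filter_cancer_types(
    records: list[RorRecord], min_reports: int = 1000
) -> list[RorRecord]:
    """Keep cancer types with at least ``min_reports`` ICI reports.

    Cohorts with few exposed reports give unstable ROR estimates; the study
    design retains only cancer types with >= 1000 ICI reports. Order is
    preserved; an empty input yields an empty output.
    """
    return [r for r in records if r.n_ici_reports >= min_reports]


def split_high_low(records: list[RorRecord]) -> dict[str, str]:
    """Median split of cancer types into ``high`` and ``low`` ROR groups.

    Ties at the median are assigned to ``low``, so with an odd number of
    types the median element itself lands in ``low``.
    """
    if len(records) < 2:
        raise GroupingError("need at least 2 cancer types for a high/low split")
    rors = pd.Series({r.cancer_type: r.ror for r in records})
    med = rors.median()
    return {ct: ("high" if v > med else "low") for ct, v in rors.items()}


def ror_table(records: list[RorRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame indexed by cancer type."""
    return pd.DataFrame([r.__dict__ for r in records]).set_index("cancer_type")


def read_reports(path) -> list[ReportTable2x2]:
    """Read a tab-separated report summary with columns cancer_type, a, b, c, d."""
    df = pd.read_csv(path, sep="\t")
    required = {"cancer_type", "a", "b", "c", "d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reports file missing columns: {sorted(missing)}")
    return [
        ReportTable2x2(
            cancer_type=str(row.cancer_type),
            a=int(row.a),
            b=int(row.b),
            c=int(row.c),
            d=int(row.d),
        )
        for row in df.itertuples()
    ]


def write_ror(records: list[RorRecord], path) -> None:
    ror_table(records).to_csv(path, sep="\t")
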