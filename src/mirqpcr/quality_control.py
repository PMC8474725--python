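"""Per-sample quality control for PCR-array plates.

Two checks are applied, in this order:

1. **Missingness** — the fraction of "not detected" wells per sample must not
   exceed a user threshold (by default computed over miRNA wells only, so
   control dropout is handled by the dedicated control check below).
2. **Reverse-transcription efficiency** — the RTC wells detect an artificial
   RNA template added before reverse transcription, the PPC wells a
   pre-dispensed DNA template that bypasses RT.  Their Ct difference
   (mean RTC Ct − mean PPC Ct) isolates RT failure from PCR inhibition; a
   sample passes when the statistic is below the threshold (default 5 cycles).

Samples failing either check are excluded from all downstream stages, with
the reason recorded in the QC report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QCError
from .plate_io import CtMatrix, PlateLayout, Role


@dataclass
class QCConfig:
    """Thresholds for sample-level quality control.

    Attributes
    ----------
    max_na_fraction:
        Maximum tolerated fraction of not-detected wells per sample
    rt_threshold:
        Pass bound (cycles) for the RT-efficiency statistic.
    na_over_mirna_wells_only:
        Restrict the missingness denominator to miRNA wells.
    rt_statistic_form:
        ``"difference"`` (mean RTC Ct − mean PPC Ct, the default) or
        ``"quotient"`` (mean RTC Ct / mean PPC Ct) — Ct is a log-scale
        quantity, so the difference is the meaningful form, but the
        quotient is offered for strict compatibility with vendor wording.
    """

    max_na_fraction: float = 0.10
    rt_threshold: float = 5.0
    na_over_mirna_wells_only: bool = True
    rt_statistic_form: str = "difference"

    def __post_init__(self):
        if not 0.0 <= self.max_na_fraction <= 1.0:
            raise ValueError("max_na_fraction must be in [0, 1]")
        if self.rt_threshold <= 0:
            raise ValueError("rt_threshold must be positive")
        if self.rt_statistic_form not in ("difference", "quotient"):
            raise ValueError("rt_statistic_form must be 'difference' or 'quotient'")


@dataclass
class QCReport:
    """Per-sample QC outcomes; ``excluded`` ⇔ not (na_pass and rt_pass)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def excluded_samples(self) -> list[str]:
        return self.table.index[self.table["excluded"]].tolist()

    @property
    def passed_samples(self) -> list[str]:
        return self.table.index[~self.table["excluded"]].tolist()

    def to_csv(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path)


def na_fraction(ct: CtMatrix, layout: PlateLayout, config: QCConfig | None = None) -> pd.Series:
    """Fraction of not-detected wells per sample.

    With the default config the denominator counts miRNA wells only.
    """
    config = config or QCConfig()
    mask = ct.missing_mask
    if config.na_over_mirna_wells_only:
        roles = layout.role_of().reindex(ct.well_index)
        mask = mask.loc[roles == Role.MIRNA.value]
    return mask.mean(axis=0).rename("na_fraction")


def rt_statistic(
    ct: CtMatrix, layout: PlateLayout, config: QCConfig | None = None
) -> pd.Series:
    """RT-efficiency statistic per sample.

    Default form: mean Ct over RTC wells minus mean Ct over PPC wells.
    Samples for which all RTC or all PPC wells are missing get NaN (they
    fail QC with reason "controls missing" rather than raising).
    """
    config = config or QCConfig()
    roles = layout.role_of().reindex(ct.well_index)
    rtc = ct.values.loc[roles == Role.RTC.value]
    ppc = ct.values.loc[roles == Role.PPC.value]
    if rtc.empty or ppc.empty:
        raise QCError("layout contains no RTC or no PPC wells")
    rtc_mean = rtc.mean(axis=0)  # skips NaN; NaN iff all wells missing
    ppc_mean = ppc.mean(axis=0)
    if config.rt_statistic_form == "quotient":
        stat = rtc_mean / ppc_mean
    else:
        stat = rtc_mean - ppc_mean
    return stat.rename("rt_statistic")


def apply_qc(
    ct: CtMatrix, layout: PlateLayout, config: QCConfig | None = None
) -> tuple[CtMatrix, QCReport]:
    """Run both QC checks and drop failing samples.

    Returns the Ct matrix restricted to passing samples and a report that
    covers *all* input samples, each exclusion with its reason.

    Raises
    ------
    QCError
        If no sample survives; the error carries the full report.
    """
    config = config or QCConfig()
    if ct.n_samples == 0:
        raise QCError("Ct matrix has no samples")
    naf = na_fraction(ct, layout, config)
    rts = rt_statistic(ct, layout, config)
    na_pass = naf <= config.max_na_fraction
    rt_pass = rts.notna() & (rts < config.rt_threshold)

    reasons = []
    for s in ct.sample_ids:
        why = []
        if not na_pass[s]:
            why.append(f"NA fraction {naf[s]:.3f} > {config.max_na_fraction:g}")
        if not rt_pass[s]:
            if np.isnan(rts[s]):
                why.append("controls missing")
            else:
                why.append(
                    f"RT statistic {rts[s]:.2f} >= {config.rt_threshold:g}"
                )
        reasons.append("; ".join(why))

    report = QCReport(
        pd.DataFrame(
            {
                "na_fraction": naf,
                "rt_statistic": rts,
                "na_pass": na_pass,
                "rt_pass": rt_pass,
                "excluded": ~(na_pass & rt_pass),
                "exclusion_reason": reasons,
            },
            index=pd.Index(ct.sample_ids, name="sample_id"),
        )
    )
    kept = report.passed_samples
    if not kept:
        raise QCError("all samples excluded by quality control", report=report)
    return ct.select_samples(kept), report


def na_overlap_summary(ct: CtMatrix, layout: PlateLayout) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts of per-sample missing-miRNA sets.

    For every non-empty subset of samples that is the *exact* missingness
    pattern of at least one miRNA assay, report how many assays are missing
    in precisely those samples.  This is the data behind an upset plot of
    the NA structure; counts sum to the number of assays missing in at
    least one sample.
    """
    roles = layout.role_of().reindex(ct.well_index)
    assays = layout.assay_of().reindex(ct.well_index)
    mirna_mask = ct.missing_mask.loc[roles == Role.MIRNA.value]
    mirna_assays = assays.loc[roles == Role.MIRNA.value]
    # an assay is missing for a sample iff all of its wells are missing
    missing_by_assay = mirna_mask.groupby(mirna_assays.values).all()
    counts: dict[tuple[str, ...], int] = {}
    samples = np.asarray(ct.sample_ids)
    for _, row in missing_by_assay.iterrows():
        subset = tuple(sorted(samples[row.values]))
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
    return counts


def na_overlap_frame(summary: dict[tuple[str, ...], int]) -> pd.DataFrame:
    """Upset-plot data as a two-column frame (subset, count)."""
    rows = [
        {"samples": "|".join(subset), "count": n}
        for subset, n in sorted(summary.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["samples", "count"])
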