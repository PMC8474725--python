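"""Control-based ΔCt normalization.

A Ct value is the PCR cycle at which a well's fluorescence crosses the
detection threshold; one cycle corresponds to a two-fold difference in
template amount, so Ct lives on a log2 scale with *lower* meaning *more
abundant*.  Normalization subtracts each sample's reference Ct — the mean Ct
of a chosen control panel — from every miRNA Ct and negates:

    value(m, s) = reference_ct(s) − Ct(m, s)   (−ΔCt)

so larger normalized values mean higher relative expression and downstream
log-fold-changes have the conventional "positive = up" orientation.  The
reference panel is either the endogenous snoRNA/snRNA set (SNORD61/68/72/95/
96A + RNU6B) or the exogenous cel-miR-39 spike-in (used for biofluid samples
where no endogenous RNA is reliable).

Because the same reference is subtracted from every well of a sample, any
global per-sample Ct offset (input-quantity differences, RT efficiency)
cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .plate_io import (
    CtMatrix,
    ENDOGENOUS_CONTROL_ASSAYS,
    EXOGENOUS_CONTROL_ASSAYS,
    PlateLayout,
    Role,
    canonical_assay,
)


@dataclass
class NormalizationConfig:
    """Choice of reference controls.

    ``mode`` selects between the endogenous panel and the exogenous spike-in;
    the assay lists can be overridden (e.g. to drop an unstable control).
    """

    mode: str = "endogenous"  # "endogenous" | "exogenous"
    endogenous_assays: tuple[str, ...] = ENDOGENOUS_CONTROL_ASSAYS
    exogenous_assays: tuple[str, ...] = EXOGENOUS_CONTROL_ASSAYS

    def __post_init__(self):
        if self.mode not in ("endogenous", "exogenous"):
            raise ValueError("mode must be 'endogenous' or 'exogenous'")
        if not self.selected_assays:
            raise ValueError("selected control assay list is empty")

    @property
    def selected_assays(self) -> tuple[str, ...]:
        return (
            self.endogenous_assays
            if self.mode == "endogenous"
            else self.exogenous_assays
        )


@dataclass
class NormalizedMatrix:
    """miRNA × sample matrix of −ΔCt (log2 relative expression).

    ``values`` rows are miRNA assays only; ``reference_ct`` is the per-sample
    control mean (cycles) that was subtracted; ``controls_used`` records, per
    sample, which control assays contributed to the reference.
    """

    values: pd.DataFrame
    reference_ct: pd.Series
    controls_used: dict[str, list[str]] = field(default_factory=dict)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_tsv(self, path) -> None:
        self.values.rename_axis("mirna_id").to_csv(path, sep="\t")


def collapse_replicates(ct: CtMatrix, layout: PlateLayout) -> pd.DataFrame:
    """Average replicate wells into one row per assay.

    Returns an assay × sample Ct frame (assay ids keep the spelling of their
    first occurrence; matching is case-insensitive).  A cell is the
    arithmetic mean of the non-missing replicate wells and missing only when
    every replicate is missing.
    """
    assays = layout.assay_of().reindex(ct.well_index)
    canon = assays.map(canonical_assay)
    # preserve first-seen spelling and plate order
    first_spelling: dict[str, str] = {}
    for a in assays:
        first_spelling.setdefault(canonical_assay(a), a)
    collapsed = ct.values.groupby(canon.values, sort=False).mean()
    collapsed.index = [first_spelling[c] for c in collapsed.index]
    collapsed.index.name = "assay_id"
    return collapsed


def reference_ct(
    collapsed: pd.DataFrame, config: NormalizationConfig | None = None
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Per-sample reference Ct: mean over the selected control assays.

    Controls missing in a sample are dropped from that sample's mean (control
    dropout is common and should not abort a run); a sample in which *every*
    selected control is missing raises :class:`NormalizationError`.

    Returns the reference series and a per-sample record of the controls used.
    """
    config = config or NormalizationConfig()
    wanted = {canonical_assay(a): a for a in config.selected_assays}
    canon_index = collapsed.index.map(canonical_assay)
    present = [c for c in wanted if c in set(canon_index)]
    if not present:
        raise NormalizationError(
            f"none of the selected controls {list(config.selected_assays)} are on the plate"
        )
    ctrl = collapsed.loc[[c in wanted for c in canon_index]]
    ref = ctrl.mean(axis=0)
    used = {
        s: ctrl.index[ctrl[s].notna()].tolist() for s in collapsed.columns
    }
    empty = [s for s, u in used.items() if not u]
    if empty:
        raise NormalizationError(
            f"all selected controls missing in sample(s): {empty}"
        )
    return ref.rename("reference_ct"), used


def delta_ct_normalize(
    collapsed: pd.DataFrame,
    reference: pd.Series,
    layout: PlateLayout,
    controls_used: dict[str, list[str]] | None = None,
) -> NormalizedMatrix:
    """Compute −ΔCt = reference − Ct for every miRNA assay.

    Control rows are excluded from the output; missingness propagates.
    """
    roles = layout.assay_roles()
    is_mirna = [roles.get(canonical_assay(a)) is Role.MIRNA for a in collapsed.index]
    mirna = collapsed.loc[is_mirna]
    values = mirna.rsub(reference, axis=1)
    return NormalizedMatrix(
        values=values,
        reference_ct=reference.copy(),
        controls_used=controls_used or {},
    )


def normalize(
    ct: CtMatrix, layout: PlateLayout, config: NormalizationConfig | None = None
) -> NormalizedMatrix:
    """Replicate collapse → reference Ct → −ΔCt, in one call."""
    config = config or NormalizationConfig()
    collapsed = collapse_replicates(ct, layout)
    ref, used = reference_ct(collapsed, config)
    return delta_ct_normalize(collapsed, ref, layout, controls_used=used)


def relative_expression(nm: NormalizedMatrix) -> pd.DataFrame:
    """Linear-scale relative quantities, 2^(−ΔCt)."""
    return np.power(2.0, nm.values)


def boxplot_data(
    ct: CtMatrix, layout: PlateLayout, nm: NormalizedMatrix
) -> pd.DataFrame:
    """Long-format per-sample distributions before and after normalization.

    Columns: sample_id, stage ("raw_ct" | "normalized"), value.  Intended for
    the before/after boxplot figures.
    """
    roles = layout.role_of().reindex(ct.well_index)
    raw = ct.values.loc[roles == Role.MIRNA.value]
    frames = []
    for stage, frame in (("raw_ct", raw), ("normalized", nm.values)):
        long = frame.melt(var_name="sample_id", value_name="value").dropna()
        long.insert(1, "stage", stage)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
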