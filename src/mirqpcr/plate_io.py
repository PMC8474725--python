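"""Readers, writers and containers for miRNA PCR-array plate data.

The plate technology targeted here is a 384-well miRNA PCR array: each well
holds a primer assay for one mature miRNA or for one of a small panel of
controls.  The standard single-plate layout comprises 372 miRNA assays and 12
control wells — 2 replicate wells of the *C. elegans* spike-in cel-miR-39,
6 wells of small nucleolar/nuclear RNA normalizers (SNORD61, SNORD68, SNORD72,
SNORD95, SNORD96A and RNU6B), 2 reverse-transcription control (RTC) wells and
2 positive PCR control (PPC) wells.

Three delimited text files describe an experiment:

* a **Ct table** — wells on rows, samples on columns, threshold-cycle values
  with "not detected" markers for failed wells;
* a **well annotation** — well position → assay name (and optionally an
  explicit role and plate id);
* a **sample sheet** — sample id → group label.

All readers auto-detect comma/tab delimiters and are tolerant of vendor
case/whitespace variation in assay names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CtParseError, FormatError, SampleSheetError

#: Cell contents treated as "not detected" by default.
DEFAULT_MISSING_MARKERS = frozenset({"Undetermined", "N/A", "NA", ""})

#: Ct values above this many cycles are treated as not detected.
DEFAULT_CT_CEILING = 35.0

DEFAULT_PLATE_ID = "plate1"


class Role(str, Enum):
    """Functional role of a well on the array."""

    MIRNA = "MIRNA"
    CE_SPIKE = "CE_SPIKE"
    SNORNA_SNRNA = "SNORNA_SNRNA"
    RTC = "RTC"
    PPC = "PPC"


CONTROL_ROLES = (Role.CE_SPIKE, Role.SNORNA_SNRNA, Role.RTC, Role.PPC)

#: Endogenous normalizer panel bundled with the standard layout.
ENDOGENOUS_CONTROL_ASSAYS = (
    "SNORD61",
    "SNORD68",
    "SNORD72",
    "SNORD95",
    "SNORD96A",
    "RNU6B",
)

#: Exogenous spike-in normalizer.
EXOGENOUS_CONTROL_ASSAYS = ("cel-miR-39",)

_SNO_NAMES = {a.casefold() for a in ENDOGENOUS_CONTROL_ASSAYS} | {"rnu6-2", "rnu6-6p"}


def canonical_assay(assay_id: str) -> str:
    """Canonical form used for assay matching: trimmed and case-folded."""
    return assay_id.strip().casefold()


def infer_role(assay_id: str) -> Role:
    """Infer a well's role from its assay name.

    The standard control names are recognised case-insensitively:
    ``cel-miR-39`` → spike-in, ``SNORD*``/``RNU6B`` → endogenous
    snoRNA/snRNA normalizer, ``miRTC`` → reverse-transcription control,
    ``PPC`` → positive PCR control.  Anything else is a miRNA assay.
    """
    name = canonical_assay(assay_id)
    if "cel-mir-39" in name:
        return Role.CE_SPIKE
    if name.startswith("snord") or name.startswith("rnu6") or name in _SNO_NAMES:
        return Role.SNORNA_SNRNA
    if "mirtc" in name:
        return Role.RTC
    if name == "ppc" or name.startswith("ppc"):
        return Role.PPC
    return Role.MIRNA


@dataclass(frozen=True)
class WellAnnotation:
    """One row of the well annotation: a well and the assay it carries."""

    well_position: str
    assay_id: str
    role: Role
    plate_id: str = DEFAULT_PLATE_ID

    def __post_init__(self):
        if not self.assay_id or not self.assay_id.strip():
            raise FormatError(
                f"empty assay id at well {self.well_position!r} on plate {self.plate_id!r}"
            )


class PlateLayout:
    """Mapping of wells to assays and roles, possibly spanning several plates.

    Parameters
    ----------
    wells:
        Iterable of :class:`WellAnnotation`.  Well positions must be unique
        within each plate.
    """

    def __init__(self, wells: Iterable[WellAnnotation]):
        wells = list(wells)
        if not wells:
            raise FormatError("plate layout has no wells")
        seen: set[tuple[str, str]] = set()
        for w in wells:
            key = (w.plate_id, w.well_position)
            if key in seen:
                raise FormatError(
                    f"duplicate well {w.well_position!r} on plate {w.plate_id!r}"
                )
            seen.add(key)
        self.wells: list[WellAnnotation] = wells

    @property
    def plate_ids(self) -> set[str]:
        return {w.plate_id for w in self.wells}

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def to_frame(self) -> pd.DataFrame:
        """Layout as a DataFrame indexed by (plate_id, well_position)."""
        df = pd.DataFrame(
            {
                "plate_id": [w.plate_id for w in self.wells],
                "well_position": [w.well_position for w in self.wells],
                "assay_id": [w.assay_id for w in self.wells],
                "role": [w.role.value for w in self.wells],
            }
        )
        return df.set_index(["plate_id", "well_position"])

    def role_of(self) -> pd.Series:
        """Role per well, indexed by (plate_id, well_position)."""
        return self.to_frame()["role"]

    def assay_of(self) -> pd.Series:
        """Assay id per well, indexed by (plate_id, well_position)."""
        return self.to_frame()["assay_id"]

    def assay_roles(self) -> Mapping[str, Role]:
        """Map canonical assay id → role (roles are consistent per assay)."""
        out: dict[str, Role] = {}
        for w in self.wells:
            key = canonical_assay(w.assay_id)
            prev = out.setdefault(key, w.role)
            if prev is not w.role:
                raise FormatError(
                    f"assay {w.assay_id!r} annotated with conflicting roles "
                    f"{prev.value} and {w.role.value}"
                )
        return out

    def wells_with_role(self, role: Role) -> list[WellAnnotation]:
        return [w for w in self.wells if w.role is role]


@dataclass(frozen=True)
class LayoutSummary:
    """Per-role well counts of a layout."""

    total: int
    counts: Mapping[str, int]

    def __getitem__(self, role) -> int:
        key = role.value if isinstance(role, Role) else str(role)
        return self.counts.get(key, 0)


@dataclass
class CtMatrix:
    """Wells × samples matrix of threshold-cycle values.

    ``values`` is a float DataFrame whose row index is the MultiIndex
    (plate_id, well_position) and whose columns are sample ids.  Missing
    ("not detected") measurements are stored as NaN; :attr:`missing_mask`
    exposes them as a boolean frame.
    """

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate well keys: {dupes}")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def well_index(self) -> pd.MultiIndex:
        return self.values.index

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_wells(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        return CtMatrix(self.values.loc[:, list(sample_ids)].copy())


@dataclass
class SampleSheet:
    """Sample id → experimental group assignment."""

    group_of: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_of)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet({s: self.group_of[s] for s in sample_ids})


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    """Read CSV/TSV with delimiter sniffing; raise FormatError if empty."""
    import csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False, **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    except csv.Error as exc:
        # the delimiter sniffer fails on empty/degenerate content
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    return df


def read_ct_table(
    path,
    *,
    plate_id: str = DEFAULT_PLATE_ID,
    missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS,
    ct_ceiling: float | None = DEFAULT_CT_CEILING,
) -> CtMatrix:
    """Read a Ct count table (wells on rows, samples on columns).

    Parameters
    ----------
    path:
        Delimited text file.  The first column holds well positions; the
        header row holds sample ids.
    plate_id:
        Plate id assigned to every well of this file.
    missing_markers:
        Cell strings mapped to "not detected" (compared after trimming).
    ct_ceiling:
        Ct values above this many cycles are masked as not detected
        (``None`` disables the ceiling).

    Raises
    ------
    FormatError
        Empty file or duplicate well key.
    CtParseError
        A cell that is neither numeric nor a recognised marker; the message
        names the offending well and sample.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a well column plus >=1 sample column")
    markers = {m.strip() for m in missing_markers}
    well_col = df.columns[0]
    wells = df[well_col].astype(str).str.strip()
    if wells.duplicated().any():
        dupes = wells[wells.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate well key(s): {dupes}")
    sample_ids = [str(c).strip() for c in df.columns[1:]]

    parsed = np.full((len(df), len(sample_ids)), np.nan)
    for j, col in enumerate(df.columns[1:]):
        for i, raw in enumerate(df[col].astype(str)):
            cell = raw.strip()
            if cell in markers:
                continue
            try:
                parsed[i, j] = float(cell)
            except ValueError as exc:
                raise CtParseError(
                    f"{path}: cannot parse Ct value {cell!r} at well "
                    f"{wells.iloc[i]!r}, sample {sample_ids[j]!r}"
                ) from exc
    if ct_ceiling is not None:
        parsed[parsed > ct_ceiling] = np.nan

    index = pd.MultiIndex.from_arrays(
        [[plate_id] * len(wells), wells.tolist()], names=["plate_id", "well_position"]
    )
    return CtMatrix(pd.DataFrame(parsed, index=index, columns=sample_ids))


def read_annotation(path, *, default_plate_id: str = DEFAULT_PLATE_ID) -> PlateLayout:
    """Read the well annotation linking each well to its assay.

    Required columns: ``well_position`` and ``assay_id`` (first two columns
    are used if headers differ).  Optional columns ``role`` and ``plate_id``;
    when ``role`` is absent or blank it is inferred from the assay name via
    :func:`infer_role`.
    """
    df = _read_delimited(path)
    cols = {c.strip().casefold(): c for c in df.columns}
    well_col = cols.get("well_position", df.columns[0])
    assay_col = cols.get("assay_id", df.columns[1] if df.shape[1] > 1 else None)
    if assay_col is None:
        raise FormatError(f"{path}: annotation needs well_position and assay_id columns")
    role_col = cols.get("role")
    plate_col = cols.get("plate_id")

    valid_roles = {r.value for r in Role}
    wells = []
    for i, row in df.iterrows():
        assay = str(row[assay_col]).strip()
        explicit = str(row[role_col]).strip() if role_col else ""
        if explicit:
            if explicit.upper() not in valid_roles:
                raise FormatError(
                    f"{path}: unknown role {explicit!r} at row {i + 2}"
                )
            role = Role(explicit.upper())
        else:
            role = infer_role(assay)
        plate = str(row[plate_col]).strip() if plate_col else default_plate_id
        wells.append(
            WellAnnotation(
                well_position=str(row[well_col]).strip(),
                assay_id=assay,
                role=role,
                plate_id=plate or default_plate_id,
            )
        )
    return PlateLayout(wells)


def read_sample_sheet(path, ct: CtMatrix | None = None) -> SampleSheet:
    """Read the sample sheet (sample id, group label).

    When ``ct`` is given, every Ct-table sample must appear in the sheet
    (:class:`SampleSheetError` otherwise); sheet rows for samples absent
    from the Ct table are dropped with a warning.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise SampleSheetError(f"{path}: sample sheet needs >=2 columns (sample, group)")
    ids = df.iloc[:, 0].astype(str).str.strip()
    groups = df.iloc[:, 1].astype(str).str.strip()
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise SampleSheetError(f"{path}: duplicate sample id(s): {dupes}")
    mapping = dict(zip(ids, groups))
    if ct is not None:
        missing = [s for s in ct.sample_ids if s not in mapping]
        if missing:
            raise SampleSheetError(
                f"{path}: sample(s) in Ct table missing from sheet: {missing}"
            )
        extra = [s for s in mapping if s not in set(ct.sample_ids)]
        if extra:
            warnings.warn(
                f"sample sheet rows without Ct data dropped: {extra}", stacklevel=2
            )
            mapping = {s: g for s, g in mapping.items() if s not in set(extra)}
    return SampleSheet(mapping)


# ---------------------------------------------------------------------------
# writers (round-trip companions of the readers)


def write_ct_table(ct: CtMatrix, path, *, missing_marker: str = "Undetermined") -> None:
    out = ct.values.copy()
    out.index = out.index.get_level_values("well_position")
    out.index.name = "well_position"
    out = out.astype(object).where(~ct.values.isna().values, missing_marker)
    out.to_csv(path)


def write_annotation(layout: PlateLayout, path) -> None:
    layout.to_frame().reset_index()[
        ["well_position", "assay_id", "role", "plate_id"]
    ].to_csv(path, index=False)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    pd.DataFrame(
        {"sample_id": sheet.sample_ids, "group": [sheet.group_of[s] for s in sheet.sample_ids]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# multi-plate merge and summaries


def merge_plates(
    matrices: Sequence[CtMatrix], layouts: Sequence[PlateLayout]
) -> tuple[CtMatrix, PlateLayout]:
    """Concatenate plates measured on the same samples.

    Rows are keyed by (plate_id, well_position), so the merged matrix has as
    many rows as the inputs combined; an assay present on several plates
    keeps all of its wells (replicate averaging happens at normalization).

    Raises
    ------
    FormatError
        If the plates' sample sets differ (message carries the symmetric
        difference).
    """
    if not matrices:
        raise FormatError("no plates to merge")
    if len(matrices) != len(layouts):
        raise FormatError("matrices and layouts must pair up")
    ref = list(matrices[0].sample_ids)
    for m in matrices[1:]:
        if list(m.sample_ids) != ref:
            diff = sorted(set(m.sample_ids) ^ set(ref))
            raise FormatError(f"plates measure different samples: {diff}")
    if len(matrices) == 1:
        return matrices[0], layouts[0]
    merged_values = pd.concat([m.values for m in matrices], axis=0)
    merged_layout = PlateLayout([w for lay in layouts for w in lay])
    return CtMatrix(merged_values), merged_layout


def summarize_layout(layout: PlateLayout) -> LayoutSummary:
    """Count wells per role; counts always sum to the layout size."""
    counts = {r.value: 0 for r in Role}
    for w in layout:
        counts[w.role.value] += 1
    return LayoutSummary(total=len(layout), counts=counts)
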