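"""Offline miRNA → target-gene mapping.

Interaction evidence is read from a local TSV (columns ``mirna``, ``gene``,
``source``, ``evidence`` and optional ``score``) whose rows emulate the
records of validated (miRTarBase, TarBase) and predicted (DIANA-microT,
TargetScan, ...) target databases.  Keeping the tables local makes the stage
deterministic and runnable without network access; a converter exporting any
real database to this four-column format plugs straight in.

miRNA names are matched exactly after case-folding — no -3p/-5p arm
expansion, which would silently change results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError

VALID_EVIDENCE = ("VALIDATED", "PREDICTED")


@dataclass
class TargetTable:
    """Deduplicated interaction records with a case-folded miRNA index."""

    records: pd.DataFrame  # columns: mirna, gene, source, evidence[, score]

    @property
    def mirnas(self) -> set[str]:
        return set(self.records["mirna_key"])

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])

    def source_counts(self) -> pd.Series:
        return self.records["source"].value_counts()


def load_target_table(path) -> TargetTable:
    """Read and validate a miRNA→gene interaction TSV.

    Duplicate (mirna, gene, source) rows collapse to one; an evidence string
    outside {VALIDATED, PREDICTED} raises :class:`FormatError` naming the row.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    required = ["mirna", "gene", "source", "evidence"]
    cols = {c.strip().casefold(): c for c in df.columns}
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df.rename(columns={cols[c]: c for c in cols})
    for c in required:
        df[c] = df[c].str.strip()
    bad = ~df["evidence"].str.upper().isin(VALID_EVIDENCE)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based, counting the header
        raise FormatError(
            f"{path}: unknown evidence {df.loc[bad, 'evidence'].iloc[0]!r} at row {row}"
        )
    if (df["mirna"] == "").any() or (df["gene"] == "").any():
        raise FormatError(f"{path}: empty mirna or gene field")
    df["evidence"] = df["evidence"].str.upper()
    df["mirna_key"] = df["mirna"].str.casefold()
    n_before = len(df)
    df = df.drop_duplicates(subset=["mirna_key", "gene", "source"]).reset_index(drop=True)
    if df.empty:
        warnings.warn(f"{path}: target table has no records", stacklevel=2)
    elif len(df) < n_before:
        warnings.warn(
            f"{path}: dropped {n_before - len(df)} duplicate record(s)", stacklevel=2
        )
    return TargetTable(records=df)


def targets_for(
    mirnas,
    table: TargetTable,
    evidence_filter: str = "both",
    min_sources: int = 1,
) -> pd.DataFrame:
    """Genes targeted by any query miRNA, with provenance.

    Parameters
    ----------
    mirnas:
        Query miRNA names (typically the significant set from differential
        expression); matched case-insensitively.
    evidence_filter:
        ``"validated"``, ``"predicted"`` or ``"both"``.
    min_sources:
        Keep only genes supported by at least this many distinct source
        databases (across all supporting miRNAs).

    Returns a frame indexed by gene with columns ``mirnas``, ``sources``
    (both "|"-joined sorted lists) and ``n_sources``.  Empty with a warning
    when no query miRNA appears in the table.
    """
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("query miRNA list is empty")
    if evidence_filter not in ("validated", "predicted", "both"):
        raise ValueError("evidence_filter must be 'validated', 'predicted' or 'both'")
    keys = {m.strip().casefold() for m in mirnas}
    rec = table.records
    hit = rec[rec["mirna_key"].isin(keys)]
    if evidence_filter != "both":
        hit = hit[hit["evidence"] == evidence_filter.upper()]
    if hit.empty:
        warnings.warn(
            "no query miRNA matched the target table under the current filter",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["mirnas", "sources", "n_sources"]).rename_axis("gene")

    grouped = hit.groupby("gene").agg(
        mirnas=("mirna", lambda v: "|".join(sorted(set(v)))),
        sources=("source", lambda v: "|".join(sorted(set(v)))),
        n_sources=("source", "nunique"),
    )
    grouped = grouped[grouped["n_sources"] >= min_sources]
    return grouped.sort_index()
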