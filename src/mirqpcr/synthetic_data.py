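"""Synthetic plate generator with known ground truth.

Emits standard-layout 384-well plates (372 miRNA assays + 12 controls) whose
Ct values carry planted group effects, per-sample global offsets (emulating
input-RNA quantity differences, the main nuisance ΔCt normalization is meant
to remove), Gaussian measurement noise, dropout, and optional RT-control
failures — everything a downstream stage might have to cope with, but with
the truth recorded so recovery can be scored.

The miRNA assay names (``hsa-miR-001`` ... ``hsa-miR-372``) are synthetic
placeholders, not real miRBase entries; the control assay names are the real
ones found on the standard array.  Companion helpers build matching toy
miRNA→target tables and GMT gene-set files so the functional stages are
testable offline as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_io import (
    CtMatrix,
    ENDOGENOUS_CONTROL_ASSAYS,
    PlateLayout,
    Role,
    SampleSheet,
    WellAnnotation,
    write_annotation,
    write_ct_table,
    write_sample_sheet,
)

N_MIRNA_WELLS = 372

# fixed control baselines (cycles): spike-in bright, RTC-PPC difference 2 (< 5, passes)
_CONTROL_BASELINES = {
    "cel-miR-39": 18.0,
    "SNORD61": 19.5,
    "SNORD68": 19.8,
    "SNORD72": 20.0,
    "SNORD95": 20.2,
    "SNORD96A": 20.5,
    "RNU6B": 20.0,
    "miRTC": 21.0,
    "PPC": 19.0,
}

_RT_FAIL_SHIFT = 10.0  # added to RTC wells of samples meant to fail the RT check


@dataclass
class SimulationScenario:
    """Knobs of the plate simulation; all rates/effects in natural units.

    ``effect_size`` is in cycles (one cycle = two-fold); planted miRNAs are
    shifted by that amount in the test group, half up and half down.
    ``sample_shift_sd`` is the SD of the per-sample global Ct offset applied
    to every well, controls included.
    """

    n_samples_per_group: int = 6
    groups: tuple[str, str] = ("normal", "tumor")
    n_de: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    na_rate: float = 0.02
    sample_shift_sd: float = 1.0
    structured_dropout: bool = False
    rt_fail_samples: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.na_rate < 1.0:
            raise ValueError("na_rate must be in [0, 1); full dropout leaves nothing to analyse")
        if self.noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.n_de <= N_MIRNA_WELLS:
            raise ValueError(f"n_de must be in [0, {N_MIRNA_WELLS}]")
        if self.n_samples_per_group < 1:
            raise ValueError("need >=1 sample per group")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("exactly two distinct group labels required")


@dataclass
class GroundTruth:
    """What was planted: effects on the −ΔCt scale, shifts, NAs, QC failures."""

    planted_effects: dict[str, float] = field(default_factory=dict)
    sample_shifts: dict[str, float] = field(default_factory=dict)
    na_positions: list[tuple[str, str]] = field(default_factory=list)
    rt_fail_samples: list[str] = field(default_factory=list)

    @property
    def de_mirnas(self) -> set[str]:
        return set(self.planted_effects)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "planted_effects": self.planted_effects,
                    "sample_shifts": self.sample_shifts,
                    "na_positions": [list(p) for p in self.na_positions],
                    "rt_fail_samples": self.rt_fail_samples,
                },
                fh,
                indent=2,
            )


def mirna_assay_names() -> list[str]:
    """The 372 synthetic miRNA assay names used by the standard layout."""
    return [f"hsa-miR-{i:03d}" for i in range(1, N_MIRNA_WELLS + 1)]


def generate_standard_layout(plate_id: str = "plate1") -> PlateLayout:
    """The standard 384-well layout: 372 miRNA wells followed by 12 controls.

    Control block: 2× cel-miR-39, the six-assay endogenous panel, 2× miRTC,
    2× PPC.  Deterministic — repeated calls return identical layouts.
    """
    positions = [f"{row}{col}" for row in "ABCDEFGHIJKLMNOP" for col in range(1, 25)]
    assays = mirna_assay_names()
    assays += ["cel-miR-39", "cel-miR-39"]
    assays += list(ENDOGENOUS_CONTROL_ASSAYS)
    assays += ["miRTC", "miRTC", "PPC", "PPC"]
    assert len(assays) == len(positions) == 384
    return PlateLayout(
        WellAnnotation(
            well_position=pos,
            assay_id=assay,
            role=_role_for(assay),
            plate_id=plate_id,
        )
        for pos, assay in zip(positions, assays)
    )


def _role_for(assay: str) -> Role:
    if assay == "cel-miR-39":
        return Role.CE_SPIKE
    if assay in ENDOGENOUS_CONTROL_ASSAYS:
        return Role.SNORNA_SNRNA
    if assay == "miRTC":
        return Role.RTC
    if assay == "PPC":
        return Role.PPC
    return Role.MIRNA


def simulate_plates(
    scenario: SimulationScenario,
) -> tuple[CtMatrix, PlateLayout, SampleSheet, GroundTruth]:
    """Simulate one standard plate per sample set, with ground truth.

    Generative model per well w of sample s:

        Ct(w, s) = baseline(assay) − 1{planted, s in test group}·signed_effect
                   + shift(s) + ε,   ε ~ N(0, noise_sd²)

    miRNA baselines are Uniform(20, 32); control baselines are fixed values
    chosen so a clean sample passes the RT check (RTC − PPC = 2 cycles).
    Planted effects are ±effect_size (half up, half down) on the Ct scale;
    on the −ΔCt scale an "up" miRNA gains +effect_size in the test group.
    Dropout is injected uniformly over miRNA cells at ``na_rate`` (or biased
    toward high-Ct cells when ``structured_dropout``).  Samples named in
    ``rt_fail_samples`` get their RTC wells inflated past the pass threshold.
    Fully reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    layout = generate_standard_layout()
    g1, g2 = scenario.groups
    samples = [f"{g1}_{i}" for i in range(1, scenario.n_samples_per_group + 1)]
    samples += [f"{g2}_{i}" for i in range(1, scenario.n_samples_per_group + 1)]
    sheet = SampleSheet({s: (g1 if s.startswith(g1) else g2) for s in samples})
    test_samples = [s for s in samples if sheet.group_of[s] == g2]
    unknown_rt = set(scenario.rt_fail_samples) - set(samples)
    if unknown_rt:
        raise ValueError(f"rt_fail_samples not in simulated samples: {sorted(unknown_rt)}")

    mirnas = mirna_assay_names()
    baseline = dict(zip(mirnas, rng.uniform(20.0, 32.0, size=len(mirnas))))
    baseline.update(_CONTROL_BASELINES)

    planted_ids = rng.choice(mirnas, size=scenario.n_de, replace=False)
    signs = np.ones(scenario.n_de)
    signs[1::2] = -1.0  # alternate up/down
    planted = {m: float(s * scenario.effect_size) for m, s in zip(planted_ids, signs)}

    shifts = {s: float(rng.normal(0.0, scenario.sample_shift_sd)) for s in samples}

    wells = list(layout)
    values = np.empty((len(wells), len(samples)))
    for j, s in enumerate(samples):
        for i, w in enumerate(wells):
            ct = baseline[w.assay_id]
            if w.assay_id in planted and s in test_samples:
                # up-regulated (positive −ΔCt effect) ⇒ lower Ct in test group
                ct -= planted[w.assay_id]
            if w.role is Role.RTC and s in scenario.rt_fail_samples:
                ct += _RT_FAIL_SHIFT
            values[i, j] = ct + shifts[s]
    values += rng.normal(0.0, scenario.noise_sd, size=values.shape)

    # dropout over miRNA wells
    mirna_rows = np.array([w.role is Role.MIRNA for w in wells])
    na_positions: list[tuple[str, str]] = []
    if scenario.na_rate > 0:
        sub = values[mirna_rows]
        if scenario.structured_dropout:
            # abundance-dependent: probability proportional to softmax of Ct
            w = np.exp((sub - sub.mean()) / 2.0)
            prob = scenario.na_rate * w / w.mean()
            drop = rng.random(sub.shape) < np.clip(prob, 0.0, 1.0)
        else:
            drop = rng.random(sub.shape) < scenario.na_rate
        sub[drop] = np.nan
        values[mirna_rows] = sub
        idx = np.flatnonzero(mirna_rows)
        for ii, jj in zip(*np.nonzero(drop)):
            na_positions.append((wells[idx[ii]].well_position, samples[jj]))

    index = pd.MultiIndex.from_arrays(
        [[w.plate_id for w in wells], [w.well_position for w in wells]],
        names=["plate_id", "well_position"],
    )
    ct = CtMatrix(pd.DataFrame(values, index=index, columns=samples))
    truth = GroundTruth(
        planted_effects=planted,
        sample_shifts=shifts,
        na_positions=na_positions,
        rt_fail_samples=list(scenario.rt_fail_samples),
    )
    return ct, layout, sheet, truth


def write_scenario(outdir, scenario: SimulationScenario) -> dict[str, Path]:
    """Simulate and write the three input files plus the ground-truth JSON.

    The files are written in exactly the formats the readers accept, so a
    simulated study can be replayed through the full pipeline from disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ct, layout, sheet, truth = simulate_plates(scenario)
    paths = {
        "counts": outdir / "counts.csv",
        "annotation": outdir / "annotation.csv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_ct_table(ct, paths["counts"])
    write_annotation(layout, paths["annotation"])
    write_sample_sheet(sheet, paths["metadata"])
    truth.to_json(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# toy functional-analysis inputs


def make_target_table(
    mirnas,
    seed: int = 0,
    n_genes: int = 400,
    targets_per_mirna: int = 8,
) -> pd.DataFrame:
    """Random miRNA→gene interactions in the offline target-table format.

    Each miRNA targets ``targets_per_mirna`` genes drawn from a pool of
    ``n_genes`` synthetic symbols; each interaction is assigned to one of
    three emulated source databases with matching evidence class.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    sources = [("mirtarbase", "VALIDATED"), ("tarbase", "VALIDATED"),
               ("diana_microt", "PREDICTED")]
    rows = []
    for m in mirnas:
        picked = rng.choice(genes, size=min(targets_per_mirna, n_genes), replace=False)
        for g in picked:
            src, ev = sources[int(rng.integers(len(sources)))]
            rows.append({"mirna": m, "gene": g, "source": src, "evidence": ev})
    return pd.DataFrame(rows, columns=["mirna", "gene", "source", "evidence"])


def make_gene_sets(
    genes,
    seed: int = 0,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
) -> dict[str, list[str]]:
    """Random gene sets over ``genes``, GMT-ready (name → member list)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    out = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False))
        out[f"PATHWAY_{i:03d}"] = members
    return out


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic set") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_target_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
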