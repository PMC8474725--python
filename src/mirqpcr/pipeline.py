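"""End-to-end pipeline: load → QC → normalize → differential → functional.

``run_pipeline`` drives all stages from a :class:`RunConfig`, writing stage
tables under ``qc/``, ``normalized/``, ``de/`` and ``functional/``, figures
under ``figures/``, and the run report at the output root.  Later stages
short-circuit gracefully (no significant miRNAs → functional analysis and
heatmap are skipped with a note in the report); partial outputs from earlier
stages are always retained.
"""

from __future__ import annotations

import datetime
import resource
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential_expression import (
    DesignSpec,
    differential_expression,
    hierarchical_clustering,
)
from .enrichment import default_universe, enrich, load_gmt
from .errors import MirqpcrError
from .normalization import NormalizationConfig, boxplot_data, normalize, relative_expression
from .plate_io import (
    CtMatrix,
    PlateLayout,
    SampleSheet,
    merge_plates,
    read_annotation,
    read_ct_table,
    read_sample_sheet,
    summarize_layout,
)
from .quality_control import QCConfig, apply_qc, na_overlap_frame, na_overlap_summary
from .report import RunReport, write_report


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``counts``/``annotation`` accept one path per plate (paired in order);
    ``targets`` and ``gene_sets`` are optional — without them the pipeline
    stops after differential expression.
    """

    counts: list[str]
    annotation: list[str]
    metadata: str
    outdir: str
    contrast: tuple[str, str] | None = None
    alpha: float = 0.05
    adjust: str = "bh"
    qc: QCConfig = field(default_factory=QCConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    targets: str | None = None
    gene_sets: list[str] = field(default_factory=list)
    evidence_filter: str = "both"
    min_sources: int = 1
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.counts) != len(self.annotation):
            raise MirqpcrError("one annotation file is required per counts file")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        qc = QCConfig(**raw.pop("qc", {})) if isinstance(raw.get("qc"), dict) else raw.pop("qc", QCConfig())
        norm = raw.pop("normalization", {})
        if isinstance(norm, str):
            norm = NormalizationConfig(mode=norm)
        elif isinstance(norm, dict):
            norm = NormalizationConfig(**norm)
        if isinstance(raw.get("counts"), str):
            raw["counts"] = [raw["counts"]]
        if isinstance(raw.get("annotation"), str):
            raw["annotation"] = [raw["annotation"]]
        if raw.get("contrast") is not None:
            raw["contrast"] = tuple(raw["contrast"])
        missing = [k for k in ("counts", "annotation", "metadata", "outdir") if k not in raw]
        if missing:
            raise MirqpcrError(f"config missing required key(s): {missing}")
        return cls(qc=qc, normalization=norm, **raw)

    def parameters_echo(self) -> dict:
        return {
            "counts": list(self.counts),
            "annotation": list(self.annotation),
            "metadata": self.metadata,
            "contrast": list(self.contrast) if self.contrast else None,
            "alpha": self.alpha,
            "adjust": self.adjust,
            "max_na_fraction": self.qc.max_na_fraction,
            "rt_threshold": self.qc.rt_threshold,
            "normalization_mode": self.normalization.mode,
            "control_assays": list(self.normalization.selected_assays),
            "targets": self.targets,
            "gene_sets": list(self.gene_sets),
            "evidence_filter": self.evidence_filter,
            "min_sources": self.min_sources,
            "seed": self.seed,
        }


def _load_inputs(config: RunConfig) -> tuple[CtMatrix, PlateLayout, SampleSheet]:
    mats, lays = [], []
    for i, (cpath, apath) in enumerate(zip(config.counts, config.annotation), start=1):
        plate_id = f"plate{i}"
        mats.append(read_ct_table(cpath, plate_id=plate_id))
        lays.append(read_annotation(apath, default_plate_id=plate_id))
    ct, layout = merge_plates(mats, lays)
    sheet = read_sample_sheet(config.metadata, ct)
    return ct, layout, sheet


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and return the run report (also written to disk)."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    for sub in ("qc", "normalized", "de", "figures"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    notes: list[str] = []
    counts: dict = {}

    # --- phase 1: load, QC, normalize -------------------------------------
    ct, layout, sheet = _load_inputs(config)
    counts["samples_in"] = ct.n_samples
    counts["wells"] = ct.n_wells
    counts["mirna_assays"] = summarize_layout(layout)["MIRNA"]

    ct_pass, qc_report = apply_qc(ct, layout, config.qc)
    qc_report.to_csv(outdir / "qc" / "qc_report.csv")
    na_overlap = na_overlap_frame(na_overlap_summary(ct, layout))
    na_overlap.to_csv(outdir / "qc" / "na_overlap.csv", index=False)
    counts["samples_passed_qc"] = ct_pass.n_samples
    sheet = sheet.subset(ct_pass.sample_ids)

    nm = normalize(ct_pass, layout, config.normalization)
    nm.to_tsv(outdir / "normalized" / "normalized_matrix.tsv")
    nm.reference_ct.rename_axis("sample_id").to_csv(outdir / "normalized" / "reference_ct.csv")
    relative_expression(nm).rename_axis("mirna_id").to_csv(
        outdir / "normalized" / "relative_expression.tsv", sep="\t"
    )
    box = boxplot_data(ct_pass, layout, nm)
    box.to_csv(outdir / "normalized" / "boxplot_data.csv", index=False)

    # --- phase 2: differential expression ---------------------------------
    design = DesignSpec.from_sample_sheet(sheet, config.contrast, config.alpha)
    de_table, fit, params = differential_expression(nm, design, adjust=config.adjust)
    de_table.rename_axis("mirna_id").to_csv(outdir / "de" / "de_table.tsv", sep="\t")
    (outdir / "de" / "dropped_mirnas.txt").write_text(
        "\n".join(fit.dropped) + ("\n" if fit.dropped else ""), encoding="utf-8"
    )
    counts["mirnas_tested"] = len(de_table)
    counts["mirnas_dropped"] = len(fit.dropped)
    sig = de_table.index[de_table["significant"]].tolist()
    counts["significant_mirnas"] = len(sig)

    clustering = None
    if len(sig) >= 2:
        clustering = hierarchical_clustering(nm.values.loc[sig])
    if clustering is not None:
        clustering.matrix.rename_axis("mirna_id").to_csv(
            outdir / "de" / "heatmap_matrix.csv"
        )
        pd.DataFrame({"row_order": clustering.row_order}).to_csv(
            outdir / "de" / "heatmap_row_order.csv", index=False
        )
        pd.DataFrame({"col_order": clustering.col_order}).to_csv(
            outdir / "de" / "heatmap_col_order.csv", index=False
        )
    else:
        notes.append("heatmap skipped: fewer than 2 significant miRNAs")

    # --- phase 3: functional analysis --------------------------------------
    if not sig:
        notes.append("functional analysis skipped: no significant miRNAs at alpha")
    elif config.targets is None:
        notes.append("functional analysis skipped: no target table provided")
    else:
        from .target_mapping import load_target_table, targets_for

        (outdir / "functional").mkdir(exist_ok=True)
        table = load_target_table(config.targets)
        genes = targets_for(
            sig, table, evidence_filter=config.evidence_filter,
            min_sources=config.min_sources,
        )
        genes.to_csv(outdir / "functional" / "target_genes.tsv", sep="\t")
        counts["target_genes"] = len(genes)
        counts["sets_tested"] = 0
        for gmt_path in config.gene_sets:
            coll = load_gmt(gmt_path)
            uni = default_universe(coll, table.genes)
            result = enrich(list(genes.index), coll, uni)
            stem = Path(gmt_path).stem
            result.to_csv(outdir / "functional" / f"enrichment_{stem}.tsv",
                          sep="\t", index=False)
            counts["sets_tested"] += int(len(result))
            if config.make_figures:
                _barplot(result, outdir / "figures" / f"enrichment_{stem}.png")

    if config.make_figures:
        _boxplots(box, outdir / "figures" / "normalization_boxplots.png")
        _upset_bars(na_overlap, outdir / "figures" / "na_upset.png")
        if clustering is not None:
            _heatmap(clustering, outdir / "figures" / "heatmap.png")

    # --- report ------------------------------------------------------------
    dur = time.perf_counter() - t0
    peak_mb = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss / 1024.0
    report = RunReport(
        version=__version__,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        parameters=config.parameters_echo(),
        sample_qc=qc_report.table.rename_axis("sample_id").reset_index().to_dict("records"),
        counts=counts,
        notes=notes,
        duration_seconds=dur,
        peak_memory_mb=peak_mb,
    )
    write_report(report, outdir)
    return report


# ---------------------------------------------------------------------------
# figures (static files; the data behind each one is also written as CSV)


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _boxplots(box: pd.DataFrame, path) -> None:
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, stage, title in zip(
        axes, ("raw_ct", "normalized"), ("Raw Ct", "Normalized (−ΔCt)")
    ):
        sub = box[box["stage"] == stage]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("sample_id", sort=False)]
        labels = list(dict.fromkeys(sub["sample_id"]))
        ax.boxplot(groups, tick_labels=labels)
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _upset_bars(na_overlap: pd.DataFrame, path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(8, 4))
    if len(na_overlap):
        ax.bar(na_overlap["samples"], na_overlap["count"])
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.set_ylabel("miRNAs missing in exactly this sample subset")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _heatmap(clustering, path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(clustering.matrix.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(clustering.col_order)))
    ax.set_xticklabels(clustering.col_order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(clustering.row_order)))
    ax.set_yticklabels(clustering.row_order, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score of −ΔCt")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _barplot(result: pd.DataFrame, path, top: int = 15) -> None:
    plt = _mpl()
    sub = result.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(sub), 4) + 1))
    if len(sub):
        import numpy as np

        ax.barh(sub["set_name"], -np.log10(sub["adj_p_value"].clip(lower=1e-300)))
    ax.set_xlabel("−log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
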