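"""Run report: a human-readable summary plus a machine-readable JSON twin.

The report captures everything needed to audit one execution: the tool
version, the user-defined criteria actually in force, every excluded sample
with its rationale, stage-by-stage counts, and resource usage.  Every number
in it is re-derivable from the stage tables written alongside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunReport:
    version: str
    timestamp: str
    parameters: dict = field(default_factory=dict)
    sample_qc: list[dict] = field(default_factory=list)  # one dict per input sample
    counts: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    duration_seconds: float = 0.0
    peak_memory_mb: float = 0.0

    @property
    def excluded(self) -> list[dict]:
        return [s for s in self.sample_qc if s.get("excluded")]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)

    def to_markdown(self) -> str:
        lines = [
            "# Analysis run report",
            "",
            f"- tool version: {self.version}",
            f"- timestamp: {self.timestamp}",
            f"- wall-clock duration: {self.duration_seconds:.2f} s",
            f"- peak memory: {self.peak_memory_mb:.1f} MB",
            "",
            "## Parameters",
        ]
        for k, v in self.parameters.items():
            lines.append(f"- {k}: {v}")
        lines += ["", "## Sample quality control"]
        if self.excluded:
            for s in self.excluded:
                lines.append(
                    f"- EXCLUDED {s['sample_id']}: {s['exclusion_reason']}"
                )
        else:
            lines.append("- none excluded")
        kept = [s["sample_id"] for s in self.sample_qc if not s.get("excluded")]
        lines.append(f"- retained samples ({len(kept)}): {', '.join(kept)}")
        lines += ["", "## Stage counts"]
        for k, v in self.counts.items():
            lines.append(f"- {k}: {v}")
        if self.notes:
            lines += ["", "## Notes"]
            for n in self.notes:
                lines.append(f"- {n}")
        return "\n".join(lines) + "\n"


def write_report(report: RunReport, outdir) -> tuple[Path, Path]:
    """Write the markdown report and its JSON twin; returns both paths."""
    outdir = Path(outdir)
    md = outdir / "report.md"
    js = outdir / "report.json"
    md.write_text(report.to_markdown(), encoding="utf-8")
    with open(js, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return md, js


def read_report(path) -> RunReport:
    with open(path, encoding="utf-8") as fh:
        return RunReport.from_dict(json.load(fh))
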