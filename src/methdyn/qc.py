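"""Three-step quality control of amplicon methylation calls.

The filter cascade mirrors standard practice for very deep amplicon
bisulfite data:

0. whole-amplicon exclusion on run-wide metrics (mean per-sample reads too
   low, or mean CHH methylation too high — a PCR/conversion artifact);
1. PCR-artifact cells: site x sample cells whose coverage falls below a
   fraction of that amplicon's median coverage in the sample *and* whose
   level is exactly 0 or 100% (false CpGs introduced by low-level
   mispriming);
2. sample exclusion on bisulfite conversion rate estimated from CHH
   context (non-CpG methylation in blood is ~0, so any apparent CHH signal
   measures conversion failure); samples under the threshold are dropped;
3. site x sample cells under the absolute coverage floor.

Steps run strictly in the order 0 -> 1 -> 2 -> 3 and every removal is
attributed to exactly one step, so the report reconciles with the
before/after matrix dimensions cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsproc import MethCallMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCError",
    "estimate_conversion",
    "conversion_table",
    "apply_qc",
]


class QCError(RuntimeError):
    """Fatal QC condition (e.g. every sample failed conversion)."""


@dataclass(frozen=True)
class QCThresholds:
    min_conversion: float = 95.0  # percent
    min_site_coverage: int = 1000  # reads per site x sample cell
    artifact_low_coverage_frac: float = 0.1  # of amplicon median in sample
    amplicon_min_reads: float = 1000.0  # mean reads per sample
    amplicon_max_chh_level: float = 5.0  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_conversion <= 100.0:
            raise ValueError("min_conversion must be in [0, 100]")
        for nm in (
            "min_site_coverage",
            "artifact_low_coverage_frac",
            "amplicon_min_reads",
            "amplicon_max_chh_level",
        ):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")


@dataclass
class QCReport:
    conversion: dict[str, float]  # percent per sample (NaN = unassessable)
    removed_amplicons: dict[str, str] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)
    removed_cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cpg_id", "context", "sample_id", "step", "reason"]
        )
    )
    n_cells_in: int = 0
    n_cells_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_sites_in: int = 0
    n_sites_out: int = 0

    def summary(self) -> str:
        lines = [
            f"cells: {self.n_cells_in} -> {self.n_cells_out}",
            f"samples: {self.n_samples_in} -> {self.n_samples_out}",
            f"sites: {self.n_sites_in} -> {self.n_sites_out}",
            f"amplicons removed: {self.removed_amplicons or 'none'}",
            f"samples removed (conversion): {self.removed_samples or 'none'}",
        ]
        by_step = self.removed_cells.groupby("step").size().to_dict()
        lines.append(f"cells removed by step: {by_step or 'none'}")
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.removed_cells.to_csv(path, sep="\t", index=False)


def estimate_conversion(m: MethCallMatrix, sample: str) -> float:
    """Bisulfite conversion rate (percent) for one sample, pooled over CHH.

    conversion = 100 - 100 * sum(meth) / sum(meth + unmeth) over the
    sample's covered CHH sites.  Pooling weights sites by coverage, giving
    a lower-variance estimate than averaging per-site levels.  Returns NaN
    (conversion unassessable) when the sample has no covered CHH calls.
    """
    sub = m.data[(m.data["sample_id"] == sample) & (m.data["context"] == "CHH")]
    tot = float(sub["coverage"].sum())
    if tot == 0:
        return float("nan")
    return 100.0 - 100.0 * float(sub["meth"].sum()) / tot


def conversion_table(m: MethCallMatrix) -> pd.Series:
    return pd.Series(
        {s: estimate_conversion(m, s) for s in m.samples}, name="conversion_pct"
    )


def apply_qc(
    m: MethCallMatrix, t: QCThresholds = QCThresholds()
) -> tuple[MethCallMatrix, QCReport]:
    """Run the full QC cascade; returns the filtered matrix and a report.

    Raises :class:`QCError` if no sample survives.  The operation is
    idempotent: a matrix that already passed QC passes unchanged.
    """
    df = m.data.copy()
    report = QCReport(
        conversion={},
        n_cells_in=len(df),
        n_samples_in=df["sample_id"].nunique(),
        n_sites_in=df["cpg_id"].nunique(),
    )
    removed_frames: list[pd.DataFrame] = []

    def _record(sub: pd.DataFrame, step: str, reason: str) -> None:
        if len(sub):
            rec = sub[["cpg_id", "context", "sample_id"]].copy()
            rec["step"] = step
            rec["reason"] = reason
            removed_frames.append(rec)

    # step 0: whole-amplicon exclusion on run-wide metrics
    for amp, g in df.groupby("amplicon"):
        cpg = g[g["context"] == "CpG"]
        mean_reads = (
            cpg.groupby("sample_id")["coverage"].mean().mean() if len(cpg) else 0.0
        )
        chh = g[g["context"] == "CHH"]
        chh_cov = float(chh["coverage"].sum())
        chh_level = (
            100.0 * float(chh["meth"].sum()) / chh_cov if chh_cov > 0 else 0.0
        )
        if mean_reads < t.amplicon_min_reads:
            report.removed_amplicons[amp] = "low_coverage"
        elif chh_level > t.amplicon_max_chh_level:
            report.removed_amplicons[amp] = "high_chh"
    if report.removed_amplicons:
        drop = df["amplicon"].isin(report.removed_amplicons)
        _record(df[drop], "amplicon", "amplicon_excluded")
        df = df[~drop]

    # step 1: PCR-artifact cells (low relative coverage at exactly 0/100%)
    med = df.groupby(["sample_id", "amplicon"])["coverage"].transform("median")
    extreme = df["level"].isin([0.0, 100.0])
    artifact = (df["coverage"] < t.artifact_low_coverage_frac * med) & extreme
    _record(df[artifact], "1", "artifact")
    df = df[~artifact]

    # step 2: sample-level conversion filter on the artifact-cleaned calls
    inter = MethCallMatrix(df[MethCallMatrix.COLUMNS])
    report.conversion = conversion_table(inter).to_dict()
    failed = [
        s
        for s, c in report.conversion.items()
        if not np.isnan(c) and c < t.min_conversion
    ]
    report.removed_samples = sorted(failed)
    if failed:
        drop = df["sample_id"].isin(failed)
        _record(df[drop], "2", "low_conversion")
        df = df[~drop]
    if df.empty or df["sample_id"].nunique() == 0:
        report.removed_cells = (
            pd.concat(removed_frames, ignore_index=True)
            if removed_frames
            else report.removed_cells
        )
        raise QCError("no samples survive QC:\n" + report.summary())

    # step 3: absolute coverage floor per cell
    low = df["coverage"] < t.min_site_coverage
    _record(df[low], "3", "low_coverage")
    df = df[~low]

    if removed_frames:
        report.removed_cells = pd.concat(removed_frames, ignore_index=True)
    out = MethCallMatrix(df[MethCallMatrix.COLUMNS])
    report.n_cells_out = len(out.data)
    report.n_samples_out = out.data["sample_id"].nunique()
    report.n_sites_out = out.data["cpg_id"].nunique()
    assert report.n_cells_in == report.n_cells_out + len(report.removed_cells)
    return out, report
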