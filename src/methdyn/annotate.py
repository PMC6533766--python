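"""Regulatory-feature annotation of CpG sites.

Maps each CpG to its nearest feature per class (transcription-factor
binding motifs, ChIP-defined binding regions, TSS, enhancers, TAD
boundaries), records the signed distance from the CpG to the feature
centre (negative = CpG left of centre in + orientation), and flags
whether the site lies inside the feature span (``in_motif``) or within a
+/- window of its centre (``in_window``, default 50 bp).  Both overlap
readings are emitted because "located in a binding site" can reasonably
mean either.

Feature intervals live in BED6 on disk (0-based half-open) and 1-based
inclusive in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureInterval",
    "FEATURE_CLASSES",
    "read_bed",
    "write_bed",
    "annotate_sites",
    "summarize_localization",
    "filter_manifest",
    "write_bedgraph",
]

FEATURE_CLASSES = (
    "GR_motif",
    "CTCF_motif",
    "GR_chip",
    "CTCF_chip",
    "TSS",
    "proximal_enhancer",
    "intronic_enhancer",
    "TAD_boundary",
)


@dataclass(frozen=True)
class FeatureInterval:
    """One feature; start/end are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"feature {self.name!r}: start > end")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def half_length(self) -> float:
        return (self.end - self.start + 1) / 2.0


def read_bed(path, feature_class: str | None = None) -> list[FeatureInterval]:
    """Read BED6; the name column supplies the class unless one is given."""
    out: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, b_start, b_end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            score = int(f[4]) if len(f) > 4 and f[4] != "." else 0
            strand = f[5] if len(f) > 5 else "."
            cls = feature_class if feature_class is not None else name
            out.append(
                FeatureInterval(chrom, b_start + 1, b_end, name, score, strand, cls)
            )
    return out


def write_bed(features: list[FeatureInterval], path) -> None:
    """Write BED6 (0-based half-open); class is preserved via the name
    column when it equals the name, else lost to the file format."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.name}\t{f.score}\t{f.strand}\n"
            )


def annotate_sites(
    sites: pd.DataFrame,
    features: list[FeatureInterval],
    window: int = 50,
) -> pd.DataFrame:
    """Nearest feature per class for every site.

    ``sites`` needs columns cpg_id, chrom, pos (the forward-strand C).
    Distance is |pos - centre|; ties go to the feature with the lower
    start coordinate.  Sites on chromosomes with no feature of a class
    are left unannotated for that class.
    """
    by_class: dict[str, list[FeatureInterval]] = {}
    for f in features:
        by_class.setdefault(f.feature_class, []).append(f)
    rows = []
    for rec in sites.itertuples(index=False):
        for cls, feats in sorted(by_class.items()):
            cands = [f for f in feats if f.chrom == rec.chrom]
            if not cands:
                continue
            best = min(cands, key=lambda f: (abs(rec.pos - f.center), f.start))
            dist = rec.pos - best.center
            rows.append(
                (
                    rec.cpg_id,
                    cls,
                    best.name,
                    dist,
                    best.start <= rec.pos <= best.end,
                    abs(dist) <= window,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cpg_id",
            "feature_class",
            "feature_name",
            "signed_distance",
            "in_motif",
            "in_window",
        ],
    )


def summarize_localization(
    dmc_table: pd.DataFrame,
    annotations: pd.DataFrame,
    overlap: str = "in_motif",
) -> pd.DataFrame:
    """DMC counts and effect sizes per feature class.

    ``dmc_table`` needs cpg_id, is_dmc and (optionally) per-time-point
    delta columns; ``overlap`` chooses the membership flag (``in_motif``
    span overlap or ``in_window`` centre distance).  Per class: number of
    sites in/out of the feature, DMCs among them, the increase/decrease
    split and mean +/- sd of the peak signed delta of member DMCs.
    """
    delta_cols = [c for c in dmc_table.columns if c.startswith("delta_")]

    def _peak_delta(row) -> float:
        vals = row[delta_cols].astype(float).dropna()
        if vals.empty:
            return float("nan")
        return float(vals.iloc[np.argmax(np.abs(vals.to_numpy()))])

    dm = dmc_table.copy()
    dm["peak_delta"] = dm.apply(_peak_delta, axis=1) if delta_cols else np.nan
    merged = annotations.merge(
        dm[["cpg_id", "is_dmc", "peak_delta"]], on="cpg_id", how="inner"
    )
    rows = []
    for cls, g in merged.groupby("feature_class", sort=True):
        inside = g[g[overlap]]
        outside = g[~g[overlap]]
        d = inside[inside["is_dmc"]]
        deltas = d["peak_delta"].dropna()
        rows.append(
            (
                cls,
                len(inside),
                len(outside),
                int(inside["is_dmc"].sum()),
                int(outside["is_dmc"].sum()),
                int((deltas > 0).sum()),
                int((deltas < 0).sum()),
                float(deltas.mean()) if len(deltas) else float("nan"),
                float(deltas.std(ddof=1)) if len(deltas) > 1 else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_class",
            "n_in",
            "n_out",
            "n_dmc_in",
            "n_dmc_out",
            "n_increase",
            "n_decrease",
            "mean_delta",
            "sd_delta",
        ],
    )


def filter_manifest(
    manifest: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
    id_col: str = "probe_id",
) -> tuple[pd.DataFrame, int]:
    """Probes of an array manifest inside a 1-based inclusive interval.

    Malformed rows (non-numeric or missing position) are skipped and
    counted.  Returns (subset ordered by position then probe id,
    n_skipped).
    """
    df = manifest.copy()
    pos = pd.to_numeric(df[pos_col], errors="coerce")
    bad = pos.isna() | df[chrom_col].isna()
    n_skipped = int(bad.sum())
    df = df[~bad]
    pos = pos[~bad]
    keep = (df[chrom_col].astype(str) == str(chrom)) & (pos >= start) & (pos <= end)
    sub = df[keep].copy()
    sub["_pos"] = pos[keep].astype(int)
    sub = sub.sort_values(["_pos", id_col], kind="stable").drop(columns="_pos")
    return sub.reset_index(drop=True), n_skipped


def write_bedgraph(
    sites: pd.DataFrame, values: pd.Series, path, track_name: str = "max_abs_delta"
) -> None:
    """Per-CpG track (e.g. peak |delta| percent) as bedGraph."""
    df = sites.set_index("cpg_id")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for cpg_id, v in values.items():
            if pd.isna(v) or cpg_id not in df.index:
                continue
            rec = df.loc[cpg_id]
            fh.write(f"{rec['chrom']}\t{rec['pos'] - 1}\t{rec['pos']}\t{v:g}\n")
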