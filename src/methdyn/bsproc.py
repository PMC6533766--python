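"""Restricted-reference processing of paired bisulfite reads.

Reads are assigned to the amplicon panel by edit distance in "three-letter"
space: both the reference and the read are collapsed on the bisulfite-variable
base (C/T for top-strand assays, G/A for bottom-strand assays) so that the
methylation state of a molecule cannot affect where it maps.  Mates are then
stitched into a single fused record — inside the overlap each position takes
the base of the mate with the higher Phred quality (ties go to mate 1) — and
per-site methylated/unmethylated counts are accumulated from the original,
uncollapsed bases.

Edit distances come from edlib (infix alignment of the read against the
converted amplicon reference); amplicon reads are near-exact, so ungapped
interpretation of the resulting offsets is adequate for calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd
import pysam

from .panel import AmpliconPanel, convert_read, convert_reference, reverse_complement

__all__ = [
    "AssignedPair",
    "FusedRead",
    "MethCallMatrix",
    "PanelIndex",
    "assign_pair",
    "stitch_pair",
    "call_sites",
    "process_fastq_pair",
    "build_matrix",
]

DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_MARGIN = 2


@dataclass
class AssignedPair:
    """Outcome of mapping one read pair against the panel."""

    amplicon: str | None
    offset1: int  # 1-based start of mate 1 within the amplicon
    offset2: int
    edits1: int
    edits2: int
    orient1: str  # 'fwd' = read given in amplicon orientation, 'rc' = reverse
    orient2: str
    status: str  # assigned | ambiguous | unmapped | discordant


@dataclass
class FusedRead:
    """A stitched read pair in amplicon coordinates.

    ``start`` is 1-based within the amplicon; ``gap`` marks the half-open
    slice of ``bases`` that is unobserved filler between disjoint mates
    (never counted).
    """

    amplicon: str
    start: int
    bases: str
    quals: np.ndarray
    gap: tuple[int, int] | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.bases) - 1

    def observed(self, amplicon_offset: int) -> bool:
        """Is this 0-based amplicon offset covered by an actual base?"""
        i = amplicon_offset - (self.start - 1)
        if i < 0 or i >= len(self.bases):
            return False
        if self.gap is not None and self.gap[0] <= i < self.gap[1]:
            return False
        return True


class PanelIndex:
    """Converted references and per-site call masks, precomputed once."""

    def __init__(self, panel: AmpliconPanel):
        self.panel = panel
        self.converted: dict[str, str] = {}
        self.call_info: dict[str, list[tuple[int, str, str, str, str]]] = {}
        for a in panel:
            self.converted[a.name] = convert_reference(a, methylation_free=True)
            meth_base = "C" if a.template_strand == "top" else "G"
            unmeth_base = "T" if a.template_strand == "top" else "A"
            info = []
            for s in panel.amplicon_sites(a.name):
                off = s.template_pos - a.start
                info.append((off, s.cpg_id, s.context, meth_base, unmeth_base))
            self.call_info[a.name] = info

    def strand(self, name: str) -> str:
        return self.panel[name].template_strand


def _best_alignment(read: str, ref: str, strand: str) -> tuple[int, int, str]:
    """Best infix alignment of a read against one converted reference,
    trying both orientations.  Returns (edits, 0-based offset, orientation)."""
    best = (len(read) + len(ref), 0, "fwd")
    for orient in ("fwd", "rc"):
        seq = read if orient == "fwd" else reverse_complement(read)
        conv = convert_read(seq, strand)
        res = edlib.align(conv, ref, mode="HW", task="locations")
        ed = res["editDistance"]
        if ed >= 0 and ed < best[0]:
            loc = res["locations"][0]
            best = (ed, loc[0] if loc[0] is not None else 0, orient)
    return best


def assign_pair(
    r1: str,
    r2: str,
    index: PanelIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_margin: int = DEFAULT_MIN_MARGIN,
) -> AssignedPair:
    """Assign a read pair to its best amplicon in converted space.

    Status rules: ``unmapped`` if either mate is empty or the best
    per-mate identity falls below ``min_identity``; ``discordant`` if the
    mates individually prefer different amplicons; ``ambiguous`` if the
    best total edit distance beats the runner-up amplicon by less than
    ``min_margin``.
    """
    if not r1 or not r2:
        return AssignedPair(None, 0, 0, -1, -1, "fwd", "fwd", "unmapped")

    per_amp: dict[str, tuple] = {}
    for name, ref in index.converted.items():
        strand = index.strand(name)
        e1, o1, or1 = _best_alignment(r1, ref, strand)
        e2, o2, or2 = _best_alignment(r2, ref, strand)
        per_amp[name] = (e1 + e2, e1, e2, o1, o2, or1, or2)

    ranked = sorted(per_amp.items(), key=lambda kv: (kv[1][0], kv[0]))
    best_name, (tot, e1, e2, o1, o2, or1, or2) = ranked[0]

    best1 = min(per_amp, key=lambda n: (per_amp[n][1], n))
    best2 = min(per_amp, key=lambda n: (per_amp[n][2], n))

    id1 = 1.0 - e1 / len(r1)
    id2 = 1.0 - e2 / len(r2)
    if id1 < min_identity or id2 < min_identity:
        status = "unmapped"
    elif best1 != best2:
        status = "discordant"
    elif len(ranked) > 1 and ranked[1][1][0] - tot < min_margin:
        status = "ambiguous"
    else:
        status = "assigned"
    return AssignedPair(best_name, o1 + 1, o2 + 1, e1, e2, or1, or2, status)


def stitch_pair(
    a: AssignedPair,
    r1: str,
    q1: np.ndarray,
    r2: str,
    q2: np.ndarray,
    amplicon_length: int,
) -> FusedRead | None:
    """Fuse an assigned pair into one record in amplicon coordinates.

    Within the mate overlap each position takes the base of the
    higher-quality mate (tie -> mate 1) with the max of the two qualities;
    outside it, bases pass through.  Disjoint mates produce a record with a
    flagged internal gap so no position is double-counted.  Pairs whose
    mates extend beyond the amplicon are discarded (returns None).
    """
    if a.status != "assigned":
        raise ValueError("stitch_pair requires an assigned pair")
    s1 = r1 if a.orient1 == "fwd" else reverse_complement(r1)
    s2 = r2 if a.orient2 == "fwd" else reverse_complement(r2)
    qq1 = q1 if a.orient1 == "fwd" else q1[::-1]
    qq2 = q2 if a.orient2 == "fwd" else q2[::-1]

    b1, e1 = a.offset1 - 1, a.offset1 - 1 + len(s1)  # 0-based half-open
    b2, e2 = a.offset2 - 1, a.offset2 - 1 + len(s2)
    if e1 > amplicon_length or e2 > amplicon_length:
        return None

    lo, hi = min(b1, b2), max(e1, e2)
    bases = np.full(hi - lo, ord("N"), dtype=np.uint8)
    quals = np.full(hi - lo, -1, dtype=np.int16)

    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    bases[b2 - lo : e2 - lo] = a2
    quals[b2 - lo : e2 - lo] = qq2
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    seg = bases[b1 - lo : e1 - lo]  # view
    segq = quals[b1 - lo : e1 - lo]
    take1 = segq <= qq1  # mate 1 wins ties and non-overlap
    seg[take1] = a1[take1]
    np.maximum(segq, qq1, out=segq)

    gap = None
    if b1 >= e2 and b1 > b2:  # mate 2 first, then a hole, then mate 1
        gap = (e2 - lo, b1 - lo)
    elif b2 >= e1 and b2 > b1:
        gap = (e1 - lo, b2 - lo)
    return FusedRead(a.amplicon, lo + 1, bases.tobytes().decode("ascii"), quals, gap)


def call_sites(
    fused: Iterable[FusedRead],
    index: PanelIndex,
) -> pd.DataFrame:
    """Count methylated/unmethylated/other calls per site for one sample.

    At each interrogated cytosine the template base (C on top-strand
    amplicons, G on bottom-strand ones) counts as methylated, the converted
    base (T/A) as unmethylated, anything else as ``other``.  Counts from
    amplicons sharing a site are summed.  Sites with no coverage are
    absent from the output (missing, not 0%).
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for fr in fused:
        for off, cpg_id, context, mb, ub in index.call_info[fr.amplicon]:
            if not fr.observed(off):
                continue
            base = fr.bases[off - (fr.start - 1)]
            key = (cpg_id, context)
            c = counts.setdefault(key, [0, 0, 0])
            if base == mb:
                c[0] += 1
            elif base == ub:
                c[1] += 1
            else:
                c[2] += 1
    site_meta = {}
    for a in index.panel:
        for off, cpg_id, context, _, _ in index.call_info[a.name]:
            site_meta.setdefault((cpg_id, context), a.name)
    rows = [
        (cpg_id, context, site_meta[(cpg_id, context)], c[0], c[1], c[2])
        for (cpg_id, context), c in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["cpg_id", "context", "amplicon", "meth", "unmeth", "other"]
    )
    return df.sort_values(["cpg_id", "context"], kind="stable").reset_index(drop=True)


class MethCallMatrix:
    """Long-format per-site x per-sample methylation counts.

    Columns: cpg_id, context, amplicon, sample_id, meth, unmeth, other,
    coverage (= meth + unmeth) and level (percent).  Cells absent from the
    frame are missing, never 0%.
    """

    COLUMNS = ["cpg_id", "context", "amplicon", "sample_id", "meth", "unmeth", "other"]

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"matrix missing columns: {sorted(missing)}")
        df = data.copy()
        df["coverage"] = df["meth"] + df["unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df["level"] = 100.0 * df["meth"] / df["coverage"]
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["cpg_id"].unique())

    def subset(self, mask) -> "MethCallMatrix":
        return MethCallMatrix(self.data.loc[mask, self.COLUMNS])

    def cpg(self) -> pd.DataFrame:
        return self.data[self.data["context"] == "CpG"]

    def wide(self, value: str = "level", context: str = "CpG") -> pd.DataFrame:
        sub = self.data[self.data["context"] == context]
        return sub.pivot_table(
            index="cpg_id", columns="sample_id", values=value, aggfunc="first"
        )

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "MethCallMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df[cls.COLUMNS])

    def __len__(self) -> int:
        return len(self.data)


def _iter_pairs(fq1, fq2) -> Iterator[tuple[str, str, np.ndarray, str, np.ndarray]]:
    with pysam.FastxFile(str(fq1)) as f1, pysam.FastxFile(str(fq2)) as f2:
        for e1, e2 in zip(f1, f2):
            q1 = np.array(e1.get_quality_array(), dtype=np.int16)
            q2 = np.array(e2.get_quality_array(), dtype=np.int16)
            yield e1.name, e1.sequence, q1, e2.sequence, q2


def process_fastq_pair(
    fq1,
    fq2,
    index: PanelIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_margin: int = DEFAULT_MIN_MARGIN,
    truth_from_names: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Process one sample's FASTQ pair into per-site counts plus a log.

    The log counts assigned/ambiguous/unmapped/discordant pairs (and, when
    ``truth_from_names`` and read names follow the simulator's
    ``sample|amplicon|molecule`` convention, correct assignments).
    """
    log = {
        "assigned": 0,
        "ambiguous": 0,
        "unmapped": 0,
        "discordant": 0,
        "discarded_stitch": 0,
        "true_amplicon_matches": 0,
    }
    fused_reads: list[FusedRead] = []
    for name, s1, q1, s2, q2 in _iter_pairs(fq1, fq2):
        ap = assign_pair(s1, s2, index, min_identity, min_margin)
        log[ap.status] += 1
        if ap.status != "assigned":
            continue
        if truth_from_names and "|" in name:
            true_amp = name.split("|")[1]
            if true_amp == ap.amplicon:
                log["true_amplicon_matches"] += 1
        fr = stitch_pair(ap, s1, q1, s2, q2, index.panel[ap.amplicon].length)
        if fr is None:
            log["discarded_stitch"] += 1
            continue
        fused_reads.append(fr)
    return call_sites(fused_reads, index), log


def build_matrix(per_sample: dict[str, pd.DataFrame]) -> MethCallMatrix:
    """Combine per-sample count frames into one MethCallMatrix."""
    frames = []
    for sample_id, df in per_sample.items():
        d = df.copy()
        d["sample_id"] = sample_id
        frames.append(d)
    allc = pd.concat(frames, ignore_index=True)
    return MethCallMatrix(allc[MethCallMatrix.COLUMNS])
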