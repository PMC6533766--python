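"""Amplicon panel model for targeted bisulfite sequencing.

An amplicon panel is a set of PCR targets on a reference genome, each
interrogating one bisulfite-converted strand.  This module loads panel
definitions (TSV + FASTA), performs in-silico bisulfite conversion of the
reference (the "three-letter" representation used for read assignment), and
classifies every cytosine on the interrogated strand into its sequence
context (CpG, CHG or CHH; H = A, C or T).

Coordinates are 1-based inclusive throughout, matching position-style CpG
identifiers such as ``chr6:35558710``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "Amplicon",
    "CytosineSite",
    "AmpliconPanel",
    "PanelError",
    "load_panel",
    "convert_reference",
    "classify_contexts",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
_H = frozenset("ACT")  # IUPAC H: not G


class PanelError(ValueError):
    """Raised for malformed panel definitions."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Amplicon:
    """A single bisulfite PCR target.

    ``template_strand`` names the strand the assay interrogates: ``top``
    amplicons read C/T state directly, ``bottom`` amplicons interrogate the
    reverse complement (their cytosines appear as G on the top strand).
    ``sequence`` is always the untreated top-strand reference over
    ``[start, end]`` (1-based, inclusive).
    """

    name: str
    chrom: str
    start: int
    end: int
    template_strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PanelError(
                f"amplicon {self.name!r}: end < start ({self.end} < {self.start})"
            )
        if self.template_strand not in ("top", "bottom"):
            raise PanelError(
                f"amplicon {self.name!r}: template_strand must be 'top' or "
                f"'bottom', got {self.template_strand!r}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise PanelError(
                f"amplicon {self.name!r}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start + 1}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise PanelError(
                f"amplicon {self.name!r}: invalid bases {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CytosineSite:
    """A cytosine on the interrogated strand of one amplicon.

    ``pos`` is the canonical site position used for identifiers and
    de-duplication: for CpG sites it is the forward-strand C of the dyad
    (so a top-strand C at p and the paired bottom-strand C read as G at
    p+1 collapse onto one site); for CHG/CHH it is the interrogated
    cytosine itself.  ``template_pos`` is the top-strand coordinate of the
    base actually read from the template (equals ``pos`` for top-strand
    amplicons; ``pos + 1`` for bottom-strand CpGs).
    """

    chrom: str
    pos: int
    context: str
    amplicon: str
    template_pos: int

    @property
    def cpg_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def convert_reference(a: Amplicon, methylation_free: bool = True) -> str:
    """In-silico bisulfite conversion of the amplicon reference.

    For ``top`` amplicons every C becomes T; for ``bottom`` amplicons the
    conversion acts on the opposite strand, which in top-strand coordinates
    turns every G into A.  With ``methylation_free=False`` cytosines in CpG
    context are protected (a fully methylated template), which is useful
    for constructing test reads.  The operation is idempotent.
    """
    seq = a.sequence
    if a.template_strand == "top":
        if methylation_free:
            return seq.replace("C", "T")
        return re.sub(r"C(?!G)", "T", seq)
    if methylation_free:
        return seq.replace("G", "A")
    # bottom-strand CpG cytosine shows as G preceded by C on the top strand
    return re.sub(r"(?<!C)G", "A", seq)


def convert_read(seq: str, template_strand: str) -> str:
    """Collapse the bisulfite-variable base of a read (three-letter space)."""
    if template_strand == "top":
        return seq.replace("C", "T")
    return seq.replace("G", "A")


def classify_contexts(
    a: Amplicon,
    flank_left: str = "",
    flank_right: str = "",
) -> list[CytosineSite]:
    """Classify every interrogated-strand cytosine of an amplicon.

    ``flank_left``/``flank_right`` are up to two reference bases beyond the
    amplicon boundaries (untreated top strand), used to resolve the context
    of cytosines whose 3' neighbours fall outside the amplicon.  Cytosines
    whose context cannot be resolved even with the provided flanks are
    dropped.
    """
    chrom, start = a.chrom, a.start
    ext = flank_left + a.sequence + flank_right
    off = len(flank_left)  # index of amplicon base 0 within ext
    sites: list[CytosineSite] = []

    if a.template_strand == "top":
        for i in range(a.length):
            j = off + i
            if ext[j] != "C":
                continue
            ctx = _context_forward(ext, j)
            if ctx is None:
                continue
            pos = start + i
            sites.append(CytosineSite(chrom, pos, ctx, a.name, pos))
    else:
        # interrogated cytosines are on the bottom strand: classify on the
        # reverse complement, 3' neighbours lie leftward on the top strand
        for i in range(a.length):
            j = off + i
            if ext[j] != "G":
                continue
            ctx = _context_reverse(ext, j)
            if ctx is None:
                continue
            tpos = start + i
            pos = tpos - 1 if ctx == "CpG" else tpos
            sites.append(CytosineSite(chrom, pos, ctx, a.name, tpos))
    return sites


def _context_forward(seq: str, j: int) -> str | None:
    n1 = seq[j + 1] if j + 1 < len(seq) else None
    if n1 is None or n1 == "N":
        return None
    if n1 == "G":
        return "CpG"
    n2 = seq[j + 2] if j + 2 < len(seq) else None
    if n2 is None or n2 == "N":
        return None
    if n2 == "G":
        return "CHG"
    return "CHH"


def _context_reverse(seq: str, j: int) -> str | None:
    # bottom-strand C at top position j; its 3' neighbours are the
    # complements of top positions j-1, j-2
    n1 = seq[j - 1] if j - 1 >= 0 else None
    if n1 is None or n1 == "N":
        return None
    if n1 == "C":  # complement G
        return "CpG"
    n2 = seq[j - 2] if j - 2 >= 0 else None
    if n2 is None or n2 == "N":
        return None
    if n2 == "C":
        return "CHG"
    return "CHH"


@dataclass
class AmpliconPanel:
    """An ordered collection of amplicons with their cytosine site table."""

    amplicons: list[Amplicon]
    flanks: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise PanelError(f"duplicate amplicon names: {sorted(dup)}")
        self.amplicons = sorted(self.amplicons, key=lambda a: (a.chrom, a.start))
        self._by_name = {a.name: a for a in self.amplicons}

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        return self._by_name[name]

    def amplicon_sites(self, name: str) -> list[CytosineSite]:
        a = self._by_name[name]
        fl, fr = self.flanks.get(name, ("", ""))
        return classify_contexts(a, fl, fr)

    def site_table(self, dedup: bool = True) -> pd.DataFrame:
        """All cytosine sites as a DataFrame.

        With ``dedup`` (default) sites shared by overlapping amplicons are
        listed once, attributed to the first amplicon in (chrom, start)
        order; counts from distinct amplicons over the same site are summed
        downstream.
        """
        rows = []
        for a in self.amplicons:
            for s in self.amplicon_sites(a.name):
                rows.append(
                    (s.cpg_id, s.chrom, s.pos, s.context, s.amplicon, s.template_pos)
                )
        df = pd.DataFrame(
            rows,
            columns=["cpg_id", "chrom", "pos", "context", "amplicon", "template_pos"],
        )
        if dedup and not df.empty:
            df = df.drop_duplicates(subset=["chrom", "pos", "context"], keep="first")
        return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    def n_cpgs(self) -> int:
        t = self.site_table()
        return int((t["context"] == "CpG").sum())

    def write_site_table(self, path) -> None:
        self.site_table().drop(columns="template_pos").to_csv(
            path, sep="\t", index=False
        )


def load_panel(panel_table, reference) -> AmpliconPanel:
    """Load a panel TSV (name, chrom, start, end, template_strand) plus
    a reference FASTA, extracting per-amplicon sequences and 2-bp context
    flanks.

    Missing contigs, out-of-bounds intervals and duplicate names are fatal.
    """
    df = pd.read_csv(panel_table, sep="\t", dtype={"chrom": str})
    required = {"name", "chrom", "start", "end", "template_strand"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel table missing columns: {sorted(missing)}")

    fa = Fasta(str(reference), as_raw=True, sequence_always_upper=True)
    amplicons: list[Amplicon] = []
    flanks: dict[str, tuple[str, str]] = {}
    for rec in df.itertuples(index=False):
        if rec.chrom not in fa:
            raise PanelError(f"amplicon {rec.name!r}: contig {rec.chrom!r} not in reference")
        contig = fa[rec.chrom]
        clen = len(contig)
        start, end = int(rec.start), int(rec.end)
        if end < start:
            raise PanelError(f"amplicon {rec.name!r}: end < start")
        if start < 1 or end > clen:
            raise PanelError(
                f"amplicon {rec.name!r}: interval [{start},{end}] out of bounds "
                f"for contig {rec.chrom!r} of length {clen}"
            )
        seq = str(contig[start - 1 : end])
        amplicons.append(
            Amplicon(str(rec.name), rec.chrom, start, end, str(rec.template_strand), seq)
        )
        fl = str(contig[max(0, start - 3) : start - 1])
        fr = str(contig[end : min(clen, end + 2)])
        flanks[str(rec.name)] = (fl, fr)
    return AmpliconPanel(amplicons, flanks)


def write_panel_table(panel: AmpliconPanel, path) -> None:
    pd.DataFrame(
        [
            (a.name, a.chrom, a.start, a.end, a.template_strand)
            for a in panel.amplicons
        ],
        columns=["name", "chrom", "start", "end", "template_strand"],
    ).to_csv(path, sep="\t", index=False)
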