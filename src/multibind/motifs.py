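"""Polyproline SH3-ligand motif scanning and alignment conservation.

SH3 domains recognise short proline-rich peptides in one of two
orientations.  In the N-to-C reading of the ligand, class I motifs carry
the basic residue first ([RK]xxPxxP) while class II motifs carry it last
(PxxPx[RK]); the two classes bind the same groove in opposite
directions.  This module finds such motifs in disordered sequence,
records the lengths of the linkers separating adjacent motifs (the
quantity that sets the contour length of the tether in the polymer
model), and scores per-column identity conservation of a multiple
sequence alignment.

Coordinates are 1-based and inclusive, following the residue-numbering
convention of protein sequence databases.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "MotifClass",
    "MotifSite",
    "MotifLayout",
    "ConservationProfile",
    "scan_motifs",
    "build_layout",
    "column_conservation",
    "read_fasta",
    "read_alignment",
    "write_motif_report",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"


class MotifClass(str, Enum):
    """Orientation class of a polyproline SH3 ligand."""

    I = "I"
    II = "II"


#: Minimal-window consensus patterns.  Class II: PxxPx[RK]; class I:
#: [RK]xxPxxP.  Lookahead makes overlapping candidate windows visible so
#: that the leftmost-maximal merge rule below is order-independent.
_PATTERNS: dict[MotifClass, re.Pattern[str]] = {
    MotifClass.II: re.compile(r"(?=(P..P.[RK]))"),
    MotifClass.I: re.compile(r"(?=([RK]..P..P))"),
}


@dataclass(frozen=True)
class MotifSite:
    """One matched motif window on a source sequence.

    ``start``/``end`` are 1-based inclusive residue positions;
    ``matched_subsequence`` equals the source slice over that window.
    """

    motif_id: str
    motif_class: MotifClass
    start: int
    end: int
    matched_subsequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"site {self.motif_id}: start {self.start} > end {self.end}")
        if len(self.matched_subsequence) != self.end - self.start + 1:
            raise ValueError(
                f"site {self.motif_id}: subsequence length "
                f"{len(self.matched_subsequence)} does not span {self.start}-{self.end}"
            )

    def overlaps(self, other: "MotifSite") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class MotifLayout:
    """Ordered motif sites on one sequence plus inter-motif linker lengths.

    ``linker_lengths[k]`` is the number of residues strictly between
    site ``k`` and site ``k+1``.
    """

    sequence_id: str
    sites: list[MotifSite]
    linker_lengths: list[int] = field(default_factory=list)

    @property
    def classes(self) -> list[MotifClass]:
        return [s.motif_class for s in self.sites]


@dataclass
class ConservationProfile:
    """Per-column majority-identity fractions of an alignment."""

    fractions: list[float]
    n_columns: int
    n_sequences: int

    def __post_init__(self) -> None:
        if len(self.fractions) != self.n_columns:
            raise ValueError("profile length does not match alignment width")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions):
            raise ValueError("conservation fractions must lie in [0, 1]")


def _validate_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"non-amino-acid character {ch!r} at position {pos}"
            )


def scan_motifs(
    sequence: str,
    classes: Iterable[MotifClass | str] = (MotifClass.I, MotifClass.II),
) -> list[MotifSite]:
    """Find class I/II polyproline motifs in an amino-acid sequence.

    Each reported site is the minimal window matching its class
    consensus.  When two candidate windows of the same class overlap,
    the leftmost is kept and any window overlapping an accepted one is
    dropped, so the result is a deterministic, non-overlapping set per
    class.  Sites are returned sorted by start position.

    Parameters
    ----------
    sequence:
        Protein sequence using the 20 standard one-letter codes.
    classes:
        Which orientation classes to scan for (default: both).

    Raises
    ------
    ValueError
        If the sequence contains a non-amino-acid character; the message
        names the offending position.
    """
    _validate_sequence(sequence)
    wanted = [MotifClass(c) for c in classes]
    sites: list[MotifSite] = []
    for mclass in wanted:
        pattern = _PATTERNS[mclass]
        accepted_end = -1  # 0-based end of last accepted window of this class
        count = 0
        for m in pattern.finditer(sequence):
            window = m.group(1)
            s0 = m.start()  # 0-based
            e0 = s0 + len(window) - 1
            if s0 <= accepted_end:
                continue  # overlaps the previously accepted match: merge leftmost
            count += 1
            sites.append(
                MotifSite(
                    motif_id=f"{mclass.value}{count}",
                    motif_class=mclass,
                    start=s0 + 1,
                    end=e0 + 1,
                    matched_subsequence=window,
                )
            )
            accepted_end = e0
    sites.sort(key=lambda s: (s.start, s.motif_class.value))
    return sites


def build_layout(sequence_id: str, sites: Sequence[MotifSite]) -> MotifLayout:
    """Assemble ordered sites into a layout with inter-motif linker lengths.

    Raises
    ------
    ValueError
        If any two sites overlap.
    """
    ordered = sorted(sites, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(
                f"overlapping sites {a.motif_id} ({a.start}-{a.end}) and "
                f"{b.motif_id} ({b.start}-{b.end})"
            )
    linkers = [b.start - a.end - 1 for a, b in zip(ordered, ordered[1:])]
    return MotifLayout(sequence_id=sequence_id, sites=list(ordered), linker_lengths=linkers)


def column_conservation(alignment: Sequence[str]) -> ConservationProfile:
    """Per-column identity conservation of a gapped alignment.

    For each column, the fraction of non-gap rows carrying the column's
    majority non-gap residue.  Columns that are entirely gaps score 0.
    Ties are broken toward the alphabetically first residue, which does
    not change the majority fraction.

    Raises
    ------
    ValueError
        If rows have unequal lengths or the alignment is empty.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment: rows have unequal lengths")
    fractions: list[float] = []
    for j in range(width):
        column = [row[j] for row in alignment if row[j] != GAP]
        if not column:
            fractions.append(0.0)
            continue
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        fractions.append(best[1] / len(column))
    return ConservationProfile(
        fractions=fractions, n_columns=width, n_sequences=len(alignment)
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA file; returns the gapped rows in file order."""
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no sequences in alignment file {path}")
    return rows


def write_motif_report(
    layouts: Iterable[MotifLayout], site_path: str | Path, linker_path: str | Path | None = None
) -> None:
    """Write TSV reports: one row per site, and optionally one per linker."""
    layouts = list(layouts)
    with open(site_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sequence_id", "motif_id", "class", "start", "end", "subsequence"])
        for layout in layouts:
            for s in layout.sites:
                w.writerow(
                    [layout.sequence_id, s.motif_id, s.motif_class.value, s.start, s.end, s.matched_subsequence]
                )
    if linker_path is not None:
        with open(linker_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["sequence_id", "site_pair", "linker_aa"])
            for layout in layouts:
                for (a, b), n in zip(zip(layout.sites, layout.sites[1:]), layout.linker_lengths):
                    w.writerow([layout.sequence_id, f"{a.motif_id}-{b.motif_id}", n])
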