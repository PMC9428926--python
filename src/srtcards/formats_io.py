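"""File formats and the TTAA motif index.

Calling-card data lives in a small family of plain-text formats: genomes as
FASTA, insertion events as qBED (née .ccf — a BED-like TSV with a count in
column 4 and an optional strand and barcode in columns 5–6), and called peaks
as a TSV table.  This module provides readers/writers for each, plus the
:class:`TTAAIndex`, the sorted per-chromosome catalogue of TTAA motif starts
that serves as the universe of possible piggyBac insertion sites.

Coordinates are 0-based, half-open throughout; an insertion occupies exactly
its TTAA interval ``[p, p + 4)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TTAAIndex",
    "Insertion",
    "Peak",
    "FormatError",
    "MOTIF",
    "PEAK_COLUMNS",
    "read_fasta",
    "write_fasta",
    "build_ttaa_index",
    "read_qbed",
    "write_qbed",
    "peaks_to_frame",
    "write_peaks",
]

MOTIF = "TTAA"

#: Column order of the peak table: nine primary columns, then diagnostics.
PEAK_COLUMNS = [
    "Chr",
    "Start",
    "End",
    "Center",
    "Experiment Hops",
    "Fraction Experiment",
    "Background Hops",
    "Fraction Background",
    "Poisson P-value",
    "Lambda",
    "Lambda Type",
    "TTAAs in Peak",
    "BH Q-value",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed record in one of the supported text formats."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: a name and an uppercase DNA string over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("empty sequence name")
        if not self.seq:
            raise FormatError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Insertion:
    """One transposon insertion event (a qBED record).

    ``count`` is the number of supporting reads (or deduplicated molecules —
    whatever the upstream collapse produced); ``barcode`` is the in-TR SRT
    barcode, empty for non-barcoded transposons.
    """

    chrom: str
    start: int
    end: int
    count: int = 1
    strand: str = "."
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != 4:
            raise FormatError(
                f"insertion {self.chrom}:{self.start}-{self.end} does not span "
                "a 4 bp TTAA interval"
            )
        if self.count < 1:
            raise FormatError(f"insertion count must be >= 1, got {self.count}")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")
        if not re.fullmatch(r"[ACGT]*", self.barcode):
            raise FormatError(f"barcode {self.barcode!r} is not a DNA string")


@dataclass(frozen=True)
class Peak:
    """A called binding region with the peak table's primary and diagnostic
    fields.  ``lambda_used`` is the background rate (hops per TTAA) the
    Poisson test actually used, ``n_ttaa`` the TTAA count inside the peak."""

    chrom: str
    start: int
    end: int
    center: int
    exp_hops: int
    frac_exp: float
    bg_hops: int
    frac_bg: float
    pvalue: float
    lambda_used: float
    lambda_type: str
    n_ttaa: int
    qvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.start <= self.center <= self.end):
            raise ValueError("peak center outside peak interval")
        if not (0.0 <= self.frac_exp <= 1.0 and 0.0 <= self.frac_bg <= 1.0):
            raise ValueError("hop fractions must lie in [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


class TTAAIndex:
    """Sorted TTAA motif-start positions per chromosome.

    TTAA is its own reverse complement, so the index is strandless.  Positions
    are 0-based motif starts, strictly increasing per chromosome (the motif
    cannot overlap itself, but the construction scan is single-step and
    exhaustive regardless).
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: Dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(pos), dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"duplicate TTAA positions on {chrom}")
            self._pos[chrom] = arr
        self.total_sites = int(sum(a.size for a in self._pos.values()))

    @property
    def chroms(self) -> List[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of TTAA starts in the half-open window [start, end)."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def has_site(self, chrom: str, start: int, slack: int = 0) -> bool:
        """Is there a TTAA start within ±slack of ``start``?"""
        pos = self.positions(chrom)
        lo = np.searchsorted(pos, start - slack)
        return lo < pos.size and pos[lo] <= start + slack

    def nearest_site(self, chrom: str, start: int, slack: int = 0):
        """The TTAA start closest to ``start`` within ±slack, or None."""
        pos = self.positions(chrom)
        if pos.size == 0:
            return None
        i = int(np.searchsorted(pos, start))
        best = None
        for j in (i - 1, i):
            if 0 <= j < pos.size and abs(int(pos[j]) - start) <= slack:
                if best is None or abs(int(pos[j]) - start) < abs(best - start):
                    best = int(pos[j])
        return best


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> List[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records, in file order.

    Sequences are uppercased.  Duplicate record names or empty sequences
    raise :class:`FormatError` naming the offending record.
    """
    records: List[GenomeSequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise FormatError(f"duplicate FASTA record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {name!r} has an empty sequence")
        seen.add(name)
        records.append(GenomeSequence(name=name, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(genome: Iterable[GenomeSequence], path: PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in genome:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TTAA index
# ---------------------------------------------------------------------------

def build_ttaa_index(genome: Iterable[GenomeSequence]) -> TTAAIndex:
    """Scan every chromosome for TTAA occurrences (exhaustive single-step
    scan; N never matches) and return the motif index."""
    positions: Dict[str, List[int]] = {}
    for rec in genome:
        hits: List[int] = []
        start = rec.seq.find(MOTIF)
        while start != -1:
            hits.append(start)
            start = rec.seq.find(MOTIF, start + 1)
        positions[rec.name] = hits
    if not positions:
        raise ValueError("cannot index an empty genome")
    return TTAAIndex(positions)


# ---------------------------------------------------------------------------
# qBED
# ---------------------------------------------------------------------------

def read_qbed(path: PathLike) -> List[Insertion]:
    """Read a qBED/.ccf file.

    Tab-separated, >= 4 columns: chrom, start, end, count; optional column 5
    is the strand ('.' if absent), column 6 the barcode (empty if absent).
    Header lines starting with '#' or 'track' are skipped.
    """
    insertions: List[Insertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                count = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[4] if len(fields) > 4 and fields[4] else "."
            barcode = fields[5] if len(fields) > 5 else ""
            try:
                insertions.append(
                    Insertion(chrom, start, end, count, strand, barcode)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return insertions


def write_qbed(insertions: Iterable[Insertion], path: PathLike,
               header_lines: Sequence[str] = ()) -> None:
    """Write insertions as 6-column qBED.

    ``header_lines`` (already '#'-prefixed) may carry provenance; the plain
    writer emits none by default, so write/read round trips are byte-stable.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        for ins in insertions:
            fh.write(
                f"{ins.chrom}\t{ins.start}\t{ins.end}\t{ins.count}\t"
                f"{ins.strand}\t{ins.barcode}\n"
            )


# ---------------------------------------------------------------------------
# Peak table
# ---------------------------------------------------------------------------

def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    rows = [
        {
            "Chr": p.chrom,
            "Start": p.start,
            "End": p.end,
            "Center": p.center,
            "Experiment Hops": p.exp_hops,
            "Fraction Experiment": p.frac_exp,
            "Background Hops": p.bg_hops,
            "Fraction Background": p.frac_bg,
            "Poisson P-value": p.pvalue,
            "Lambda": p.lambda_used,
            "Lambda Type": p.lambda_type,
            "TTAAs in Peak": p.n_ttaa,
            "BH Q-value": p.qvalue,
        }
        for p in peaks
    ]
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_peaks(peaks: Sequence[Peak], path: PathLike,
                header_lines: Sequence[str] = ()) -> None:
    frame = peaks_to_frame(peaks)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        frame.to_csv(fh, sep="\t", index=False)
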