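"""Parsing raw SRT reads against a declarative read layout.

A self-reporting-transposon (SRT) calling-card read runs, 5' to 3':

    [stagger / library barcode] [TR prefix] [SRT barcode] [TR suffix]
    [TTAA junction] [genomic sequence at the insertion site]

The stagger is one of a small set of fixed sequences of different lengths
that diversify low-complexity libraries and identify the library; the TR
segments are fixed transposon terminal-repeat sequence flanking the short
in-TR barcode; the TTAA is the piggyBac insertion motif at the transposon /
genome junction.  :func:`parse_srt_read` matches this structure with a
configurable substitution tolerance in the TR segments (no indels — the TR
has a strict length constraint), extracts the barcode, and returns the
trimmed genomic fragment.  :func:`trim_fastq` applies it to whole FASTQ
files, carrying the barcode in the read name using the UMI-tools underscore
convention (``read_id + '_' + barcode``).

A second, simpler layout handles BRB-seq-style tag reads (16 bp sample
barcode + 10 bp UMI) via :func:`parse_tag_read`.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadLayout",
    "ParsedRead",
    "ParseReport",
    "DEFAULT_LAYOUT",
    "DEFAULT_STAGGERS",
    "NEXTERA_ADAPTOR",
    "parse_srt_read",
    "parse_tag_read",
    "trim_fastq",
]

PathLike = Union[str, Path]

#: Nextera read-through adaptor, trimmed from the genomic fragment.
NEXTERA_ADAPTOR = "CTGTCTCTTATACACATCT"

#: Default stagger / library-barcode set: six sequences of lengths 1..6.
#: "TGC" is the published stagger-1; the others are this package's defaults.
DEFAULT_STAGGERS = ("C", "GA", "TGC", "ACTG", "GACTG", "CGATCG")

_STATUSES = ("ok", "no_stagger", "tr_mismatch", "no_junction", "too_short")


@dataclass(frozen=True)
class ReadLayout:
    """Declarative description of the SRT read structure.

    An empty ``staggers`` list means the layout has no stagger region.
    ``barcode_len`` 0 describes a non-barcoded SRT.  ``keep_junction``
    controls whether the emitted genomic fragment retains the TTAA junction
    (default) or starts just after it.
    """

    staggers: Tuple[str, ...] = DEFAULT_STAGGERS
    tr_prefix: str = "GTCAATTTTACGCAGACTATCTTT"
    barcode_len: int = 4
    tr_suffix: str = "GG"
    junction: str = "TTAA"
    max_mismatch_prefix: int = 1
    max_mismatch_suffix: int = 0
    min_genomic_len: int = 20
    keep_junction: bool = True
    adaptor: str = NEXTERA_ADAPTOR

    def __post_init__(self) -> None:
        if not (self.tr_prefix or self.tr_suffix):
            raise ValueError("tr_prefix + tr_suffix must be non-empty")
        if len(self.junction) != 4:
            raise ValueError("junction must be 4 nt")
        if self.barcode_len < 0:
            raise ValueError("barcode_len must be >= 0")
        if self.max_mismatch_prefix < 0 or self.max_mismatch_suffix < 0:
            raise ValueError("mismatch allowances must be >= 0")

    @property
    def min_read_len(self) -> int:
        """Shortest read that can possibly parse ok (shortest stagger)."""
        shortest = min((len(s) for s in self.staggers), default=0)
        return (
            shortest + len(self.tr_prefix) + self.barcode_len
            + len(self.tr_suffix) + len(self.junction) + self.min_genomic_len
        )

    @classmethod
    def from_dict(cls, d: Dict) -> "ReadLayout":
        d = dict(d)
        if "staggers" in d:
            d["staggers"] = tuple(d["staggers"])
        return cls(**d)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["staggers"] = list(d["staggers"])
        return d


#: The package default SRT layout (the documented barcoded-TR read design).
DEFAULT_LAYOUT = ReadLayout()


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    status: str
    genomic_seq: str = ""
    genomic_qual: str = ""
    library_barcode: str = ""
    srt_barcode: str = ""
    junction_seen: bool = False

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def _mismatches(observed: str, expected: str, budget: int) -> int:
    """Substitution count, short-circuiting once over budget."""
    n = 0
    for a, b in zip(observed, expected):
        if a != b:
            n += 1
            if n > budget:
                return n
    return n


def _match_stagger(seq: str, staggers: Sequence[str]) -> Optional[str]:
    """Exact stagger match at the read start; longest match wins on ties."""
    best: Optional[str] = None
    for s in staggers:
        if seq.startswith(s) and (best is None or len(s) > len(best)):
            best = s
    return best


def parse_srt_read(read_id: str, seq: str, layout: ReadLayout,
                   qual: str = "") -> ParsedRead:
    """Parse one read against an SRT layout.

    Failures are reported as statuses, never exceptions: ``no_stagger``
    (start matches no allowed stagger), ``tr_mismatch`` (too many
    substitutions in a TR segment), ``no_junction`` (the 4 bases after the
    TR are not the insertion motif), ``too_short`` (read truncated before
    the junction, or residual genomic sequence below the minimum).
    """
    seq = seq.upper()
    if layout.staggers:
        stagger = _match_stagger(seq, layout.staggers)
        if stagger is None:
            return ParsedRead(read_id, "no_stagger")
    else:
        stagger = ""
    off = len(stagger)

    tr_len = (len(layout.tr_prefix) + layout.barcode_len
              + len(layout.tr_suffix) + len(layout.junction))
    if len(seq) < off + tr_len:
        return ParsedRead(read_id, "too_short", library_barcode=stagger)

    p = layout.tr_prefix
    if _mismatches(seq[off:off + len(p)], p, layout.max_mismatch_prefix) \
            > layout.max_mismatch_prefix:
        return ParsedRead(read_id, "tr_mismatch", library_barcode=stagger)
    off += len(p)

    barcode = seq[off:off + layout.barcode_len]
    off += layout.barcode_len

    s = layout.tr_suffix
    if _mismatches(seq[off:off + len(s)], s, layout.max_mismatch_suffix) \
            > layout.max_mismatch_suffix:
        return ParsedRead(read_id, "tr_mismatch", library_barcode=stagger,
                          srt_barcode=barcode)
    off += len(s)

    if seq[off:off + len(layout.junction)] != layout.junction:
        return ParsedRead(read_id, "no_junction", library_barcode=stagger,
                          srt_barcode=barcode)
    genomic_start = off if layout.keep_junction else off + len(layout.junction)

    genomic = seq[genomic_start:]
    gqual = qual[genomic_start:] if qual else ""
    if layout.adaptor:
        cut = genomic.find(layout.adaptor)
        if cut != -1:
            genomic = genomic[:cut]
            gqual = gqual[:cut]
    if len(genomic) < layout.min_genomic_len + \
            (len(layout.junction) if layout.keep_junction else 0):
        return ParsedRead(read_id, "too_short", library_barcode=stagger,
                          srt_barcode=barcode, junction_seen=True)

    return ParsedRead(read_id, "ok", genomic_seq=genomic, genomic_qual=gqual,
                      library_barcode=stagger, srt_barcode=barcode,
                      junction_seen=True)


def parse_tag_read(read_id: str, seq: str, sample_bc_len: int = 16,
                   umi_len: int = 10) -> Tuple[str, str, str]:
    """Extract (status, sample_barcode, umi) from a BRB-seq-style tag read:
    a fixed-position sample barcode followed by a UMI; trailing bases are
    ignored.  Short reads return status 'too_short'."""
    seq = seq.upper()
    need = sample_bc_len + umi_len
    if len(seq) < need:
        return "too_short", "", ""
    return "ok", seq[:sample_bc_len], seq[sample_bc_len:need]


@dataclass
class ParseReport:
    """Per-status read counts from a trimming run."""

    counts: Dict[str, int] = field(default_factory=lambda: {
        s: 0 for s in _STATUSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ok(self) -> int:
        return self.counts["ok"]

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"total": self.total, **self.counts}, fh, indent=2)
            fh.write("\n")


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def trim_fastq(in_fastq: PathLike, layout: ReadLayout, out_fastq: PathLike,
               report_path: Optional[PathLike] = None) -> ParseReport:
    """Trim an SRT FASTQ file (gzip-transparent on both ends).

    Reads that parse ok are written with their genomic fragment and the
    matching quality slice; the SRT barcode is appended to the read name as
    ``_<barcode>`` (UMI-tools convention).  Returns per-status counts; the
    optional ``report_path`` receives them as JSON.
    """
    report = ParseReport()
    with _open_text(in_fastq) as fin, _open_text(out_fastq, "wt") as fout:
        for title, seq, qual in FastqGeneralIterator(fin):
            read_id = title.split()[0]
            parsed = parse_srt_read(read_id, seq, layout, qual)
            report.counts[parsed.status] += 1
            if parsed.status != "ok":
                continue
            name = read_id
            if layout.barcode_len:
                name = f"{read_id}_{parsed.srt_barcode}"
            out_qual = parsed.genomic_qual or "I" * len(parsed.genomic_seq)
            fout.write(f"@{name}\n{parsed.genomic_seq}\n+\n{out_qual}\n")
    if report_path is not None:
        report.to_json(report_path)
    return report
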