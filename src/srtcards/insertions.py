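"""From aligned reads to validated, collapsed, demultiplexed insertions.

piggyBac integrates exclusively at TTAA tetranucleotides, so an aligned
calling-card read only reports a genuine insertion if its transposon/genome
junction lands on a genomic TTAA.  This module validates aligned reads
against the motif index, collapses reads into unique insertion events keyed
by (chromosome, TTAA start, SRT barcode), demultiplexes events into
experiments by barcode (with optional single-substitution error correction),
and computes the barcode-level summaries used to characterise barcoded
transposon libraries: abundance (CPM), per-position nucleotide frequencies,
top-k position frequency matrices, and the species-mixing concordance rate
that quantifies barcode swapping.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .barcode_design import hamming, nearest_codeword
from .formats_io import Insertion, TTAAIndex

__all__ = [
    "AlignedRead",
    "BarcodeManifest",
    "ValidationResult",
    "read_aligned_tsv",
    "read_aligned_sam",
    "validate_insertions",
    "collapse_insertions",
    "demultiplex",
    "barcode_abundance",
    "combine_abundance",
    "nucleotide_frequency",
    "top_k_pfm",
    "species_mix_rate",
]

PathLike = Union[str, Path]

DEFAULT_MIN_MAPQ = 10


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read with its barcode tags.

    ``start``/``end`` delimit the aligned interval (0-based, half-open);
    the junction-side coordinate is ``start`` for '+' reads and ``end`` for
    '-' reads (a minus-strand read begins at its rightmost genomic base).
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    srt_barcode: str = ""
    library_barcode: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad aligned interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def junction_pos(self) -> int:
        """Genomic start of the TTAA the read's junction should sit on."""
        return self.start if self.strand == "+" else self.end - 4


def _barcode_from_name(read_id: str) -> str:
    # UMI-tools underscore convention: barcode is the suffix after the last
    # '_'; absent or non-DNA suffixes mean no barcode.
    if "_" not in read_id:
        return ""
    tag = read_id.rsplit("_", 1)[1]
    return tag if tag and all(c in "ACGT" for c in tag) else ""


def read_aligned_tsv(path: PathLike) -> List[AlignedRead]:
    """Read a 6-column TSV of aligned reads: read_id, chrom, start, end,
    strand, mapq.  The SRT barcode is parsed from the read name suffix."""
    reads: List[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            reads.append(AlignedRead(
                read_id=f[0], chrom=f[1], start=int(f[2]), end=int(f[3]),
                strand=f[4], mapq=int(f[5]),
                srt_barcode=_barcode_from_name(f[0]),
            ))
    return reads


def read_aligned_sam(path: PathLike) -> List[AlignedRead]:
    """Read mapped records from a SAM/BAM file; barcodes come from the
    read-name underscore tag."""
    import pysam

    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            reads.append(AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                srt_barcode=_barcode_from_name(rec.query_name),
            ))
    return reads


@dataclass
class ValidationResult:
    """Uncollapsed validated insertions plus per-category rejection counts."""

    insertions: List[Insertion]
    n_input: int
    n_valid: int
    n_low_mapq: int
    n_no_ttaa: int
    n_unknown_chrom: int


def validate_insertions(
    reads: Iterable[AlignedRead],
    index: TTAAIndex,
    slack: int = 0,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> ValidationResult:
    """Keep reads whose junction-side end sits on (within ±slack of) a
    genomic TTAA; each kept read becomes one uncollapsed Insertion taking the
    TTAA's own coordinates.  Reads below ``min_mapq`` or on chromosomes
    absent from the index are rejected and counted, never fatal."""
    out: List[Insertion] = []
    n_input = n_low = n_no = n_unknown = 0
    known = set(index.chroms)
    for read in reads:
        n_input += 1
        if read.mapq < min_mapq:
            n_low += 1
            continue
        if read.chrom not in known:
            n_unknown += 1
            continue
        site = index.nearest_site(read.chrom, read.junction_pos, slack)
        if site is None:
            n_no += 1
            continue
        out.append(Insertion(
            chrom=read.chrom, start=site, end=site + 4, count=1,
            strand=read.strand, barcode=read.srt_barcode,
        ))
    return ValidationResult(
        insertions=out, n_input=n_input, n_valid=len(out),
        n_low_mapq=n_low, n_no_ttaa=n_no, n_unknown_chrom=n_unknown,
    )


def collapse_insertions(raw: Iterable[Insertion]) -> List[Insertion]:
    """Collapse per-read insertions into unique events keyed by
    (chrom, TTAA start, barcode); count is the number of supporting reads
    and strand becomes '.' when supporting reads disagree.  Output sorted by
    (chrom, start, barcode)."""
    groups: Dict[Tuple[str, int, str], List[Insertion]] = defaultdict(list)
    for ins in raw:
        groups[(ins.chrom, ins.start, ins.barcode)].append(ins)
    out: List[Insertion] = []
    for (chrom, start, barcode) in sorted(groups):
        members = groups[(chrom, start, barcode)]
        strands = {m.strand for m in members}
        strand = strands.pop() if len(strands) == 1 else "."
        out.append(Insertion(
            chrom=chrom, start=start, end=start + 4,
            count=sum(m.count for m in members),
            strand=strand, barcode=barcode,
        ))
    return out


@dataclass(frozen=True)
class BarcodeManifest:
    """experiment name -> barcode set, with an assignment policy.

    Policies: 'exact' and 'detect' assign only exact members (any non-member
    is a detected error, left unassigned); 'correct' assigns a non-member to
    the unique barcode within ``max_correct_distance``, leaving ties and
    distant barcodes unassigned.  Barcode sets must be pairwise disjoint and
    all barcodes equal length.
    """

    experiments: Mapping[str, frozenset]
    policy: str = "exact"
    max_correct_distance: int = 1

    def __post_init__(self) -> None:
        if self.policy not in ("exact", "detect", "correct"):
            raise ValueError(f"unknown policy {self.policy!r}")
        all_bcs: List[str] = []
        for name, bcs in self.experiments.items():
            if not bcs:
                raise ValueError(f"experiment {name!r} has no barcodes")
            all_bcs.extend(bcs)
        if len(set(all_bcs)) != len(all_bcs):
            raise ValueError("barcode sets overlap across experiments")
        if len({len(b) for b in all_bcs}) > 1:
            raise ValueError("manifest barcodes have unequal lengths")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]], **kw) -> "BarcodeManifest":
        """Build from (experiment, barcode) pairs, e.g. a 2-column TSV."""
        d: Dict[str, set] = defaultdict(set)
        for exp, bc in pairs:
            d[exp].add(bc)
        return cls({k: frozenset(v) for k, v in d.items()}, **kw)

    @classmethod
    def from_tsv(cls, path: PathLike, **kw) -> "BarcodeManifest":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                exp, bc = line.split("\t")[:2]
                pairs.append((exp, bc))
        return cls.from_pairs(pairs, **kw)

    def barcode_to_experiment(self) -> Dict[str, str]:
        return {bc: exp for exp, bcs in self.experiments.items() for bc in bcs}


def demultiplex(
    insertions: Iterable[Insertion],
    manifest: BarcodeManifest,
) -> Tuple[Dict[str, List[Insertion]], List[Insertion]]:
    """Partition insertions into experiments by SRT barcode.

    Returns (assigned, unassigned); assignment conserves records exactly.
    Under the 'correct' policy a corrected insertion keeps its coordinates
    and count but its barcode is rewritten to the codeword it decoded to.
    """
    bc2exp = manifest.barcode_to_experiment()
    members = list(bc2exp)
    assigned: Dict[str, List[Insertion]] = {e: [] for e in manifest.experiments}
    unassigned: List[Insertion] = []
    for ins in insertions:
        bc = ins.barcode
        if bc in bc2exp:
            assigned[bc2exp[bc]].append(ins)
            continue
        if manifest.policy == "correct" and members and \
                len(bc) == len(members[0]):
            hit = nearest_codeword(bc, members, manifest.max_correct_distance)
            if hit is not None:
                assigned[bc2exp[hit]].append(Insertion(
                    chrom=ins.chrom, start=ins.start, end=ins.end,
                    count=ins.count, strand=ins.strand, barcode=hit,
                ))
                continue
        unassigned.append(ins)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Barcode-level summaries
# ---------------------------------------------------------------------------

def barcode_abundance(
    insertions: Iterable[Insertion],
    all_barcodes: Sequence[str],
) -> pd.DataFrame:
    """Unique-insertion counts per barcode with CPM and log2 CPM.

    count = number of distinct collapsed insertion records carrying the
    barcode.  CPM uses a 0.5 pseudocount so zero-count barcodes stay finite:
    CPM_i = 1e6 * (count_i + 0.5) / sum_j (count_j + 0.5), the sum running
    over ``all_barcodes``.  Insertions with barcodes outside ``all_barcodes``
    raise (demultiplex or filter first).
    """
    insertions = list(insertions)
    if not insertions:
        raise ValueError("no insertions to summarise")
    allowed = set(all_barcodes)
    counts: Counter = Counter()
    for ins in insertions:
        if ins.barcode not in allowed:
            raise ValueError(f"barcode {ins.barcode!r} not in all_barcodes")
        counts[ins.barcode] += 1
    raw = np.array([counts.get(b, 0) for b in all_barcodes], dtype=float)
    cpm = 1e6 * (raw + 0.5) / (raw + 0.5).sum()
    return pd.DataFrame({
        "barcode": list(all_barcodes),
        "count": raw.astype(int),
        "cpm": cpm,
        "log2_cpm": np.log2(cpm),
    })


def combine_abundance(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine replicate abundance tables: mean and standard error of the
    mean of log2 CPM per barcode (requires identical barcode universes)."""
    if not tables:
        raise ValueError("no tables to combine")
    base = list(tables[0]["barcode"])
    mat = np.empty((len(tables), len(base)))
    for i, t in enumerate(tables):
        if list(t["barcode"]) != base:
            raise ValueError("replicate tables cover different barcodes")
        mat[i] = t["log2_cpm"].to_numpy()
    n = len(tables)
    sem = mat.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(len(base))
    return pd.DataFrame({
        "barcode": base,
        "mean_log2_cpm": mat.mean(axis=0),
        "sem_log2_cpm": sem,
        "n_replicates": n,
    })


def nucleotide_frequency(abundance: pd.DataFrame, position: int) -> Dict[str, float]:
    """Abundance-weighted A/C/G/T frequency at one barcode position,
    weighting each barcode by its raw insertion count."""
    barcodes = abundance["barcode"].tolist()
    if not barcodes or position >= len(barcodes[0]):
        raise ValueError("position beyond barcode length")
    weights = abundance["count"].to_numpy(dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValueError("all barcode counts are zero")
    freq = {b: 0.0 for b in "ACGT"}
    for bc, w in zip(barcodes, weights):
        freq[bc[position]] += w
    return {b: v / total for b, v in freq.items()}


def top_k_pfm(abundance: pd.DataFrame, k: int) -> pd.DataFrame:
    """Position frequency matrix over the top-k barcodes by count.

    Each of the k barcodes contributes equally (unweighted, as for a
    sequence logo of a barcode list).  Ties at rank k break lexicographically.
    Returns a DataFrame indexed by position with columns A, C, G, T, each row
    summing to 1.
    """
    nonzero = abundance[abundance["count"] > 0]
    if k > len(nonzero):
        raise ValueError(f"k={k} exceeds the {len(nonzero)} nonzero barcodes")
    ranked = nonzero.sort_values(
        ["count", "barcode"], ascending=[False, True], kind="mergesort")
    top = ranked.head(k)["barcode"].tolist()
    length = len(top[0])
    mat = np.zeros((length, 4))
    cols = {b: i for i, b in enumerate("ACGT")}
    for bc in top:
        for pos, base in enumerate(bc):
            mat[pos, cols[base]] += 1
    mat /= k
    return pd.DataFrame(mat, columns=list("ACGT"),
                        index=pd.RangeIndex(length, name="position"))


@dataclass(frozen=True)
class SpeciesMixResult:
    rate: float
    n_total: int
    n_concordant: int
    per_genome: Mapping[str, Tuple[int, int]]  # genome -> (concordant, total)


def species_mix_rate(
    observations: Iterable[Tuple[str, str]],
    expected_genome: Mapping[str, str],
) -> SpeciesMixResult:
    """Barcode-swap concordance from a species-mixing experiment.

    ``observations`` are (barcode, genome-of-alignment) pairs for detected
    insertions; ``expected_genome`` maps each barcode to the genome of the
    cells it was transfected into.  Returns the fraction of insertions whose
    alignment genome matches the barcode's expected genome, with a
    per-genome breakdown.
    """
    total = conc = 0
    per: Dict[str, List[int]] = defaultdict(lambda: [0, 0])
    for barcode, genome in observations:
        if barcode not in expected_genome:
            raise ValueError(f"barcode {barcode!r} missing from manifest")
        exp = expected_genome[barcode]
        total += 1
        per[exp][1] += 1
        if genome == exp:
            conc += 1
            per[exp][0] += 1
    if total == 0:
        raise ValueError("no observations")
    return SpeciesMixResult(
        rate=conc / total, n_total=total, n_concordant=conc,
        per_genome={g: (c, t) for g, (c, t) in per.items()},
    )
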