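"""Synthetic calling-card data with full ground truth.

The simulator emulates the data-generating process the analysis assumes:
a genome carrying TTAA motifs, background insertions falling uniformly over
TTAA sites, experiment insertions falling with a multiplicative rate boost
on TTAAs inside planted "bound" regions, per-insertion barcodes drawn from a
configured set, and raw SRT reads built from the read layout with i.i.d.
substitution errors.  Every stage is deterministic given the seed and
returns a truth table that downstream tests compare against.

Two genome modes:

* grid — a TTAA every ``ttaa_spacing`` bp in motif-free filler (bases drawn
  from {A,C,G}, so no TTAA can arise by chance).  Analytic site counts make
  brute-force oracles exact; this is the default for oracle tests.
* random — i.i.d. bases under ``base_composition``; TTAAs occur naturally.

A naive exact-substring aligner (:func:`align_reads_exact`) exists purely as
test plumbing so the full pipeline can be exercised without a real aligner;
it requires a unique match and reports everything else as unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .formats_io import (
    GenomeSequence,
    Insertion,
    TTAAIndex,
    build_ttaa_index,
    write_fasta,
    write_qbed,
)
from .insertions import AlignedRead
from .read_structure import ReadLayout

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedInsertions",
    "simulate_genome",
    "simulate_insertions",
    "insertions_to_reads",
    "align_reads_exact",
    "write_simulation",
]

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory.

    ``enrichment`` multiplies the insertion rate on TTAAs inside planted
    peaks (1 = null, no enrichment).  ``barcodes``/``barcode_weights``
    define the per-insertion barcode multinomial.  ``depth_mean`` is the
    mean reads per insertion; every insertion gets at least one read
    (depth = 1 + Poisson(depth_mean - 1)).  ``error_region`` confines
    substitution errors to 'all' bases or the TR segments only ('tr_only').
    """

    seed: int
    n_chrom: int = 1
    chrom_len: int = 100_000
    genome_mode: str = "grid"  # grid | random
    ttaa_spacing: int = 100
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_bg_hops: int = 1000
    n_exp_hops: int = 1000
    n_peaks: int = 5
    peak_width: int = 1000
    enrichment: float = 10.0
    barcodes: Tuple[str, ...] = ("CTAG",)
    barcode_weights: Optional[Tuple[float, ...]] = None
    layout: ReadLayout = field(default_factory=ReadLayout)
    substitution_error_rate: float = 0.0
    error_region: str = "all"  # all | tr_only
    read_len: int = 80
    depth_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must lie in [0, 1)")
        if self.genome_mode not in ("grid", "random"):
            raise ValueError(f"unknown genome_mode {self.genome_mode!r}")
        if self.error_region not in ("all", "tr_only"):
            raise ValueError(f"unknown error_region {self.error_region!r}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.barcode_weights is not None and \
                len(self.barcode_weights) != len(self.barcodes):
            raise ValueError("barcode_weights must match barcodes")


@dataclass
class SimulatedGenome:
    genome: List[GenomeSequence]
    index: TTAAIndex
    peaks: List[Tuple[str, int, int]]  # planted (chrom, start, end)


@dataclass
class SimulatedInsertions:
    experiment: List[Insertion]
    background: List[Insertion]
    truth: pd.DataFrame  # chrom, start, strand, barcode, experiment, in_peak


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    # Independent streams per stage so adding reads never perturbs hops.
    return np.random.default_rng((config.seed, salt))


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome, its TTAA index, and disjoint planted peak
    intervals, each containing at least one TTAA."""
    rng = _rng(config, 0)
    genome: List[GenomeSequence] = []
    for c in range(config.n_chrom):
        name = f"chr{c + 1}"
        if config.genome_mode == "grid":
            filler = rng.choice(list("ACG"), size=config.chrom_len)
            seq = np.array(filler, dtype="<U1")
            for p in range(0, config.chrom_len - 4 + 1, config.ttaa_spacing):
                seq[p:p + 4] = list("TTAA")
            genome.append(GenomeSequence(name, "".join(seq)))
        else:
            bases = rng.choice(list("ACGT"), size=config.chrom_len,
                               p=config.base_composition)
            genome.append(GenomeSequence(name, "".join(bases)))
    index = build_ttaa_index(genome)

    peaks: List[Tuple[str, int, int]] = []
    if config.n_peaks:
        per_chrom = np.array_split(np.arange(config.n_peaks), config.n_chrom)
        for rec, chunk in zip(genome, per_chrom):
            k = len(chunk)
            if k == 0:
                continue
            # Evenly spaced, disjoint peak intervals with jitter.
            slot = config.chrom_len // (k + 1)
            if slot <= config.peak_width:
                raise ValueError("chromosome too short for requested peaks")
            for i in range(k):
                jitter = int(rng.integers(0, max(slot - config.peak_width, 1)))
                start = slot * i + slot // 2 + jitter - config.peak_width // 2
                start = max(0, min(start, config.chrom_len - config.peak_width))
                end = start + config.peak_width
                if index.count_in(rec.name, start, end) == 0:
                    continue  # random mode: skip TTAA-free intervals
                peaks.append((rec.name, start, end))
    peaks.sort()
    return SimulatedGenome(genome=genome, index=index, peaks=peaks)


def _site_table(index: TTAAIndex,
                peaks: Sequence[Tuple[str, int, int]]) -> Tuple[List[Tuple[str, int]], np.ndarray]:
    sites: List[Tuple[str, int]] = []
    in_peak: List[bool] = []
    for chrom in index.chroms:
        pos = index.positions(chrom)
        flags = np.zeros(pos.size, dtype=bool)
        for (pc, ps, pe) in peaks:
            if pc == chrom:
                flags |= (pos >= ps) & (pos < pe)
        sites.extend((chrom, int(p)) for p in pos)
        in_peak.extend(flags.tolist())
    return sites, np.asarray(in_peak)


def simulate_insertions(
    config: SimulationConfig,
    index: TTAAIndex,
    peaks: Sequence[Tuple[str, int, int]],
) -> SimulatedInsertions:
    """Draw hops: background uniform over TTAA sites; experiment with weight
    ``enrichment`` on in-peak TTAAs and 1 elsewhere.  Barcodes follow the
    configured multinomial.  Returned insertions are collapsed unique
    (site, barcode) events whose counts are the draw multiplicities; the
    truth table has one row per draw."""
    if index.total_sites == 0:
        raise ValueError("TTAA index is empty")
    rng = _rng(config, 1)
    sites, in_peak = _site_table(index, peaks)
    n_sites = len(sites)

    bc = list(config.barcodes)
    bw = np.asarray(config.barcode_weights, dtype=float) \
        if config.barcode_weights is not None else np.ones(len(bc))
    bw = bw / bw.sum()

    def draw(n: int, weights: Optional[np.ndarray], label: str) -> pd.DataFrame:
        probs = None
        if weights is not None:
            probs = weights / weights.sum()
        site_idx = rng.choice(n_sites, size=n, p=probs)
        bc_idx = rng.choice(len(bc), size=n, p=bw)
        strands = rng.choice(["+", "-"], size=n)
        # Insertions near a chromosome edge get the orientation whose read
        # extends into the chromosome, so reads are never truncated.
        starts = np.array([sites[i][1] for i in site_idx])
        strands = np.where(starts + 4 < config.read_len, "+", strands)
        strands = np.where(starts + config.read_len > config.chrom_len,
                           "-", strands)
        return pd.DataFrame({
            "chrom": pd.array([sites[i][0] for i in site_idx], dtype=str),
            "start": starts.astype(np.int64),
            "strand": pd.array(strands, dtype=str),
            "barcode": pd.array([bc[i] for i in bc_idx], dtype=str),
            "experiment": label,
            "in_peak": in_peak[site_idx].astype(bool),
        })

    exp_w = np.where(in_peak, config.enrichment, 1.0)
    truth = pd.concat(
        [draw(config.n_exp_hops, exp_w, "exp"),
         draw(config.n_bg_hops, None, "bg")],
        ignore_index=True,
    )

    def collapse(frame: pd.DataFrame) -> List[Insertion]:
        grouped = frame.groupby(["chrom", "start", "barcode"], sort=True)
        out = []
        for (chrom, start, barcode), grp in grouped:
            strands = set(grp["strand"])
            strand = strands.pop() if len(strands) == 1 else "."
            out.append(Insertion(chrom=chrom, start=int(start),
                                 end=int(start) + 4, count=len(grp),
                                 strand=strand, barcode=barcode))
        return out

    return SimulatedInsertions(
        experiment=collapse(truth[truth["experiment"] == "exp"]),
        background=collapse(truth[truth["experiment"] == "bg"]),
        truth=truth,
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float,
                  lo: int, hi: int) -> str:
    """Substitute bases i.i.d. at ``rate`` within [lo, hi)."""
    if rate == 0.0 or hi <= lo:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(hi - lo) < rate)[0]
    for i in hits:
        pos = lo + int(i)
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def insertions_to_reads(
    truth: pd.DataFrame,
    genome: Sequence[GenomeSequence],
    layout: ReadLayout,
    config: SimulationConfig,
) -> List[Tuple[str, str, str]]:
    """Construct raw SRT reads for every truth-table hop.

    Each read is stagger + tr_prefix + barcode + tr_suffix + TTAA + the
    genomic sequence flanking the insertion (downstream for '+', upstream
    reverse-complemented for '-'), truncated to ``read_len``, with i.i.d.
    substitution errors.  Read names encode the ground truth as
    ``sim|chrom|start|strand|barcode|serial``.  Returns (name, seq, qual)
    triples; reads per insertion is 1 + Poisson(depth_mean - 1).
    """
    rng = _rng(config, 2)
    chrom_seq = {g.name: g.seq for g in genome}
    staggers = layout.staggers or ("",)
    reads: List[Tuple[str, str, str]] = []
    serial = 0
    for row in truth.itertuples(index=False):
        seq = chrom_seq[row.chrom]
        depth = 1 + int(rng.poisson(config.depth_mean - 1.0)) \
            if config.depth_mean > 1 else 1
        for _ in range(depth):
            stagger = staggers[int(rng.integers(len(staggers)))]
            construct = (stagger + layout.tr_prefix + row.barcode
                         + layout.tr_suffix)
            tr_lo = len(stagger)
            tr_hi = len(construct)  # TR segments span [tr_lo, tr_hi) + junction
            if row.strand == "+":
                frag = seq[row.start:row.start + config.read_len]
            else:
                frag = revcomp(seq[max(row.start + 4 - config.read_len, 0):
                                   row.start + 4])
            read = (construct + frag)[:config.read_len]
            if config.error_region == "tr_only":
                lo, hi = tr_lo, min(tr_hi + 4, len(read))
                # skip the barcode span: errors on prefix, suffix, junction
                pre_hi = tr_lo + len(layout.tr_prefix)
                read = _apply_errors(read, rng, config.substitution_error_rate,
                                     lo, pre_hi)
                read = _apply_errors(read, rng, config.substitution_error_rate,
                                     pre_hi + len(row.barcode), hi)
            else:
                read = _apply_errors(read, rng, config.substitution_error_rate,
                                     0, len(read))
            name = f"sim|{row.chrom}|{row.start}|{row.strand}|{row.barcode}|{serial}"
            reads.append((name, read, "I" * len(read)))
            serial += 1
    return reads


def align_reads_exact(
    parsed_reads: Iterable[Tuple[str, str, str]],
    genome: Sequence[GenomeSequence],
    mapq: int = 60,
) -> List[AlignedRead]:
    """Test-fixture aligner: exact, unique substring placement.

    ``parsed_reads`` are (read_id, genomic_seq, srt_barcode) triples, e.g.
    trimmed reads whose fragment retains the TTAA junction.  A read aligns
    '+' when its fragment occurs exactly once forward; '-' when its reverse
    complement occurs exactly once (the aligned interval then ends at the
    junction TTAA).  Ambiguous or unplaceable reads are dropped.  Real
    alignment is out of scope; this exists so tests can run end to end.
    """
    out: List[AlignedRead] = []
    for read_id, frag, barcode in parsed_reads:
        hits: List[Tuple[str, int, str]] = []
        rc = revcomp(frag)
        for rec in genome:
            for strand, query in (("+", frag), ("-", rc)):
                start = rec.seq.find(query)
                while start != -1:
                    hits.append((rec.name, start, strand))
                    if len(hits) > 1:
                        break
                    start = rec.seq.find(query, start + 1)
            if len(hits) > 1:
                break
        if len(hits) != 1:
            continue
        chrom, start, strand = hits[0]
        out.append(AlignedRead(
            read_id=read_id, chrom=chrom, start=start,
            end=start + len(frag), strand=strand, mapq=mapq,
            srt_barcode=barcode,
        ))
    return out


def write_simulation(
    config: SimulationConfig,
    outdir: PathLike,
) -> Dict[str, Path]:
    """Run the full generator and write FASTA, FASTQ, experiment/background
    qBEDs, the truth table (TSV) and the planted-peaks BED to ``outdir``.
    Returns the paths keyed by artifact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_genome = simulate_genome(config)
    sim_ins = simulate_insertions(config, sim_genome.index, sim_genome.peaks)
    reads = insertions_to_reads(sim_ins.truth, sim_genome.genome,
                                config.layout, config)

    paths = {
        "fasta": outdir / "genome.fa",
        "fastq": outdir / "reads.fastq",
        "exp_qbed": outdir / "experiment.qbed",
        "bg_qbed": outdir / "background.qbed",
        "truth": outdir / "truth.tsv",
        "peaks_bed": outdir / "planted_peaks.bed",
    }
    write_fasta(sim_genome.genome, paths["fasta"])
    with open(paths["fastq"], "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    write_qbed(sim_ins.experiment, paths["exp_qbed"])
    write_qbed(sim_ins.background, paths["bg_qbed"])
    sim_ins.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["peaks_bed"], "w") as fh:
        for chrom, start, end in sim_genome.peaks:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return paths
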