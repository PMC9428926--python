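import numpy as np
import pytest

from srtcards import (
    GenomeSequence,
    Insertion,
    build_ttaa_index,
)


def grid_genome(name="chr1", length=10_000, spacing=100, seed=0):
    """One chromosome with a TTAA every ``spacing`` bp in motif-free filler
    (bases from {A,C,G}, so no TTAA arises by chance)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACG"), size=length).astype("<U1")
    for p in range(0, length - 3, spacing):
        seq[p:p + 4] = list("TTAA")
    return GenomeSequence(name, "".join(seq))


def ins(chrom, start, count=1, strand="+", barcode=""):
    return Insertion(chrom=chrom, start=start, end=start + 4, count=count,
                     strand=strand, barcode=barcode)


@pytest.fixture(scope="session")
def toy_instance():
    """The hand-checkable grid instance: 10 kb chromosome, TTAA every 100 bp
    (100 sites); background one hop per TTAA; experiment 40 hops on the 10
    TTAAs in [4500, 5500) (4 barcodes per site) plus 60 hops on the first 30
    and last 30 TTAAs outside.  Exactly one strong peak is expected."""
    genome = [grid_genome()]
    index = build_ttaa_index(genome)
    sites = [int(p) for p in index.positions("chr1")]
    bg = [ins("chr1", p) for p in sites]
    peak_sites = [p for p in sites if 4500 <= p < 5500]
    outside = [p for p in sites if not 4500 <= p < 5500]
    exp = [ins("chr1", p, barcode=b) for p in peak_sites
           for b in ("AAAA", "CCCC", "GGGG", "TTTT")]
    exp += [ins("chr1", p, barcode="AAAA")
            for p in outside[:30] + outside[-30:]]
    return {
        "genome": genome,
        "index": index,
        "exp": exp,
        "bg": bg,
        "peak_interval": (4500, 5500),
    }


def events(insertions):
    """srtcards Insertions -> oracle event tuples."""
    return [(i.chrom, i.start, i.strand, i.barcode) for i in insertions]


def ttaa_dict(index):
    return {c: [int(p) for p in index.positions(c)] for c in index.chroms}
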