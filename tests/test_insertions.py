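import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srtcards import (
    AlignedRead,
    BarcodeManifest,
    GenomeSequence,
    barcode_abundance,
    build_ttaa_index,
    collapse_insertions,
    combine_abundance,
    demultiplex,
    enumerate_barcodes,
    max_distance_set,
    nucleotide_frequency,
    species_mix_rate,
    top_k_pfm,
    validate_insertions,
)

from conftest import grid_genome, ins


def aread(chrom="chr1", start=0, end=40, strand="+", mapq=60, barcode="",
          read_id="r"):
    return AlignedRead(read_id=read_id, chrom=chrom, start=start, end=end,
                       strand=strand, mapq=mapq, srt_barcode=barcode)


class TestValidate:
    GENOME = [GenomeSequence("chr1", "GGTTAACC")]

    def test_plus_read_at_exact_ttaa(self):
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(start=2, end=8)], index, min_mapq=0)
        assert res.n_valid == 1
        (i,) = res.insertions
        assert (i.start, i.end) == (2, 6)

    def test_offset_read_rejected_at_zero_slack(self):
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(start=3, end=8)], index, min_mapq=0)
        assert res.n_valid == 0
        assert res.n_no_ttaa == 1

    def test_offset_read_recovered_with_slack(self):
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(start=3, end=8)], index, slack=1,
                                  min_mapq=0)
        assert res.n_valid == 1
        assert res.insertions[0].start == 2  # takes the TTAA's coordinates

    def test_minus_read_junction_at_aligned_end(self):
        # '-' read ends (junction side) at the TTAA: end - 4 == 2
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(start=0, end=6, strand="-")],
                                  index, min_mapq=0)
        assert res.n_valid == 1
        assert res.insertions[0].start == 2

    def test_low_mapq_dropped(self):
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(start=2, end=8, mapq=3)], index,
                                  min_mapq=10)
        assert res.n_valid == 0
        assert res.n_low_mapq == 1

    def test_unknown_chromosome_counted_not_fatal(self):
        index = build_ttaa_index(self.GENOME)
        res = validate_insertions([aread(chrom="chrX", start=2, end=8)],
                                  index, min_mapq=0)
        assert res.n_valid == 0
        assert res.n_unknown_chrom == 1

    def test_planted_reads_validated_decoys_rejected(self):
        genome = [grid_genome(length=100_000, spacing=100, seed=1)]
        index = build_ttaa_index(genome)
        sites = index.positions("chr1")
        rng = np.random.default_rng(2)
        reads = []
        for k in range(5000):
            p = int(sites[rng.integers(sites.size)])
            reads.append(aread(start=p, end=p + 40, read_id=f"hit{k}"))
        for k in range(500):  # decoys placed strictly between grid sites
            p = int(sites[rng.integers(sites.size - 1)]) + \
                int(rng.integers(5, 95))
            reads.append(aread(start=p, end=p + 40, read_id=f"decoy{k}"))
        res = validate_insertions(reads, index, min_mapq=0)
        assert res.n_valid == 5000
        assert res.n_no_ttaa == 500

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=60),
           st.integers(min_value=0, max_value=56))
    def test_zero_slack_equals_motif_check(self, seq, pos):
        """With slack 0, a '+' read validates iff genome[pos:pos+4] == TTAA."""
        genome = [GenomeSequence("c", seq)]
        index = build_ttaa_index(genome)
        if pos + 4 > len(seq):
            return
        res = validate_insertions(
            [aread(chrom="c", start=pos, end=pos + 4)], index, min_mapq=0)
        assert (res.n_valid == 1) == (seq[pos:pos + 4] == "TTAA")


class TestCollapse:
    def test_groups_by_site_and_barcode(self):
        raw = [ins("chr1", 100, barcode="CTAG"),
               ins("chr1", 100, barcode="CTAG"),
               ins("chr1", 100, barcode="GGAC")]
        out = collapse_insertions(raw)
        assert [(i.barcode, i.count) for i in out] == [("CTAG", 2), ("GGAC", 1)]

    def test_strand_conflict_becomes_dot(self):
        raw = [ins("chr1", 100, strand="+", barcode="CTAG"),
               ins("chr1", 100, strand="-", barcode="CTAG")]
        (out,) = collapse_insertions(raw)
        assert out.strand == "."
        assert out.count == 2

    def test_sorted_output_and_conservation(self):
        rng = np.random.default_rng(5)
        sites = rng.integers(0, 1000, size=300) * 4
        raw = [ins(f"chr{int(rng.integers(1, 3))}", int(s),
                   barcode=str(rng.choice(["CTAG", "GGAC", "AAAA"])))
               for s in sites]
        out = collapse_insertions(raw)
        keys = [(i.chrom, i.start, i.barcode) for i in out]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)
        assert sum(i.count for i in out) == len(raw)

    def test_poisson_depth_events_conserved(self):
        rng = np.random.default_rng(8)
        events = [(f"chr1", int(p) * 100, str(b))
                  for p, b in zip(range(200), rng.choice(
                      ["CTAG", "GGAC"], size=200))]
        raw = []
        for chrom, start, bc in events:
            for _ in range(1 + rng.poisson(2)):
                raw.append(ins(chrom, start, barcode=bc))
        out = collapse_insertions(raw)
        assert len(out) == len(set(events))
        assert sum(i.count for i in out) == len(raw)


class TestDemultiplex:
    MANIFEST = BarcodeManifest({"A": frozenset({"CTAG"}),
                                "B": frozenset({"GGAC"})})

    def test_exact_membership(self):
        assigned, unassigned = demultiplex(
            [ins("chr1", 0, barcode="CTAG")], self.MANIFEST)
        assert len(assigned["A"]) == 1
        assert not assigned["B"] and not unassigned

    def test_nonmember_goes_unassigned(self):
        assigned, unassigned = demultiplex(
            [ins("chr1", 0, barcode="TTTT")], self.MANIFEST)
        assert len(unassigned) == 1

    def test_correct_policy_rescues_distance_one(self):
        mani = BarcodeManifest({"A": frozenset({"CTAG"}),
                                "B": frozenset({"GGAC"})}, policy="correct")
        # CTAC is at distance 1 from CTAG and >= 2 from GGAC: unique rescue
        assert min(sum(a != b for a, b in zip("CTAC", m))
                   for m in ["GGAC"]) >= 2
        assigned, unassigned = demultiplex(
            [ins("chr1", 0, barcode="CTAC")], mani)
        assert len(assigned["A"]) == 1
        assert assigned["A"][0].barcode == "CTAG"  # rewritten to the codeword

    def test_equidistant_tie_goes_unassigned(self):
        mani = BarcodeManifest({"A": frozenset({"AAAA"}),
                                "B": frozenset({"AACC"})}, policy="correct")
        # AACA is at distance 1 from both AAAA and AACC
        assigned, unassigned = demultiplex(
            [ins("chr1", 0, barcode="AACA")], mani)
        assert len(unassigned) == 1

    def test_partition_is_exact(self):
        rng = np.random.default_rng(12)
        pool = ["CTAG", "GGAC", "TTTT", "ACGT"]
        records = [ins("chr1", int(i) * 4, barcode=str(rng.choice(pool)))
                   for i in range(500)]
        assigned, unassigned = demultiplex(records, self.MANIFEST)
        n_assigned = sum(len(v) for v in assigned.values())
        assert n_assigned + len(unassigned) == len(records)

    def test_overlapping_manifest_rejected(self):
        with pytest.raises(ValueError):
            BarcodeManifest({"A": frozenset({"CTAG"}),
                             "B": frozenset({"CTAG", "GGAC"})})

    def test_distance3_set_single_errors_fully_recovered(self):
        """Correct-policy demultiplexing with a distance->=3 code recovers
        every single-substitution corruption (exhaustive)."""
        code = max_distance_set(4, 3, mode="exact").sorted_members()
        mani = BarcodeManifest(
            {f"e{i}": frozenset({b}) for i, b in enumerate(code)},
            policy="correct")
        truth = {b: f"e{i}" for i, b in enumerate(code)}
        records, expected = [], []
        for b in code:
            for pos in range(4):
                for c in "ACGT":
                    if c == b[pos]:
                        continue
                    records.append(ins("chr1", 0, barcode=b[:pos] + c + b[pos + 1:]))
                    expected.append(truth[b])
        assigned, unassigned = demultiplex(records, mani)
        assert not unassigned
        for exp_name, got in assigned.items():
            assert len(got) == expected.count(exp_name)


class TestAbundance:
    def test_symmetric_counts_give_half_million_cpm(self):
        table = barcode_abundance(
            [ins("chr1", 0, barcode="AA"), ins("chr1", 4, barcode="CC")],
            ["AA", "CC"])
        assert table["cpm"].tolist() == [500000.0, 500000.0]

    def test_zero_count_barcodes_reported_finite(self):
        all_bcs = enumerate_barcodes(3)
        table = barcode_abundance(
            [ins("chr1", i * 4, barcode="AAA") for i in range(10)], all_bcs)
        assert len(table) == 64
        assert (table["count"] == 0).sum() == 63
        assert np.isfinite(table["log2_cpm"]).all()

    def test_count_is_distinct_insertions_not_reads(self):
        table = barcode_abundance(
            [ins("chr1", 0, count=50, barcode="AA"),
             ins("chr1", 4, count=1, barcode="AA")],
            ["AA", "CC"])
        assert int(table.set_index("barcode").loc["AA", "count"]) == 2

    def test_multinomial_weights_recovered_within_3_se(self):
        rng = np.random.default_rng(21)
        bcs = ["AAA", "CCC", "GGG", "TTT"]
        w = np.array([0.4, 0.3, 0.2, 0.1])
        n = 100_000
        draws = rng.choice(4, size=n, p=w)
        records = [ins("chr1", i * 4, barcode=bcs[d])
                   for i, d in enumerate(draws)]
        table = barcode_abundance(records, bcs).set_index("barcode")
        for b, p in zip(bcs, w):
            se = math.sqrt(p * (1 - p) / n)
            observed = table.loc[b, "count"] / n
            assert abs(observed - p) < 3 * se
            expected_cpm = 1e6 * (n * p + 0.5) / (n + 2)
            assert abs(table.loc[b, "cpm"] - expected_cpm) / expected_cpm < 0.05

    def test_replicates_combine_with_sem(self):
        t1 = barcode_abundance([ins("chr1", 0, barcode="AA")], ["AA", "CC"])
        t2 = barcode_abundance(
            [ins("chr1", 0, barcode="AA"), ins("chr1", 4, barcode="CC")],
            ["AA", "CC"])
        combined = combine_abundance([t1, t2])
        assert list(combined["barcode"]) == ["AA", "CC"]
        expected_mean = (t1["log2_cpm"] + t2["log2_cpm"]) / 2
        assert np.allclose(combined["mean_log2_cpm"], expected_mean)
        assert (combined["sem_log2_cpm"] >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            barcode_abundance([], ["AA"])


class TestNucleotideFrequency:
    def test_equal_counts_give_uniform(self):
        records = [ins("chr1", i * 4, barcode=b)
                   for i, b in enumerate(["AA", "CA", "GA", "TA"])]
        table = barcode_abundance(records, ["AA", "CA", "GA", "TA"])
        freq = nucleotide_frequency(table, 0)
        assert freq == {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

    def test_single_barcode_is_indicator(self):
        table = barcode_abundance([ins("chr1", 0, barcode="CG")],
                                  ["CG", "AT"])
        assert nucleotide_frequency(table, 0) == \
            {"A": 0.0, "C": 1.0, "G": 0.0, "T": 0.0}
        assert nucleotide_frequency(table, 1)["G"] == 1.0

    def test_weighted_by_insertion_counts(self):
        records = [ins("chr1", i * 4, barcode="AA") for i in range(3)] + \
                  [ins("chr1", 100, barcode="CC")]
        table = barcode_abundance(records, ["AA", "CC"])
        freq = nucleotide_frequency(table, 0)
        assert freq["A"] == 0.75 and freq["C"] == 0.25

    def test_planted_position_weights_recovered(self):
        rng = np.random.default_rng(31)
        w = {"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1}
        bases = list(w)
        n = 20_000
        first = rng.choice(bases, size=n, p=list(w.values()))
        second = rng.choice(bases, size=n)
        records = [ins("chr1", i * 4, barcode=f + s)
                   for i, (f, s) in enumerate(zip(first, second))]
        table = barcode_abundance(records, enumerate_barcodes(2))
        freq = nucleotide_frequency(table, 0)
        for b, p in w.items():
            assert abs(freq[b] - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_frequencies_sum_to_one(self):
        table = barcode_abundance(
            [ins("chr1", i * 4, barcode=b)
             for i, b in enumerate(["AC", "GT", "CC"])], ["AC", "GT", "CC"])
        assert math.isclose(sum(nucleotide_frequency(table, 1).values()), 1.0)


class TestTopKPfm:
    def _table(self, counts):
        records = []
        pos = 0
        for bc, n in counts.items():
            for _ in range(n):
                records.append(ins("chr1", pos * 4, barcode=bc))
                pos += 1
        return barcode_abundance(records, list(counts))

    def test_uniform_counts_give_uniform_pfm(self):
        bcs = ["AA", "CC", "GG", "TT"]
        pfm = top_k_pfm(self._table({b: 2 for b in bcs}), k=4)
        assert np.allclose(pfm.to_numpy(), 0.25)

    def test_k1_is_indicator_of_top_barcode(self):
        pfm = top_k_pfm(self._table({"AC": 5, "GG": 2}), k=1)
        assert pfm.loc[0, "A"] == 1.0
        assert pfm.loc[1, "C"] == 1.0

    def test_columns_sum_to_one(self):
        pfm = top_k_pfm(self._table({"AC": 3, "GG": 2, "TT": 2}), k=2)
        assert np.allclose(pfm.sum(axis=1), 1.0)

    def test_tie_at_rank_k_breaks_lexicographically(self):
        pfm = top_k_pfm(self._table({"CC": 3, "AA": 1, "GG": 1}), k=2)
        # AA and GG tie at rank 2; AA wins lexicographically
        assert pfm.loc[0, "A"] == 0.5 and pfm.loc[0, "C"] == 0.5
        assert pfm.loc[0, "G"] == 0.0

    def test_planted_preference_ordering_reproduced(self):
        """C favoured at positions 0-1 and T depleted at position 2 among
        the most-inserted barcodes shows up in the top-k PFM ordering."""
        rng = np.random.default_rng(41)
        records = []
        pos = 0
        for bc in enumerate_barcodes(4):
            rate = 5.0
            rate *= 3.0 if bc[0] == "C" else 1.0
            rate *= 3.0 if bc[1] == "C" else 1.0
            rate *= 0.1 if bc[2] == "T" else 1.0
            n = 1 + rng.poisson(rate)
            for _ in range(n):
                records.append(ins("chr1", pos * 4, barcode=bc))
                pos += 1
        table = barcode_abundance(records, enumerate_barcodes(4))
        pfm = top_k_pfm(table, k=100)
        assert pfm.loc[0, "C"] == pfm.loc[0].max()
        assert pfm.loc[1, "C"] == pfm.loc[1].max()
        assert pfm.loc[2, "T"] == pfm.loc[2].min()

    def test_k_beyond_nonzero_barcodes_rejected(self):
        with pytest.raises(ValueError):
            top_k_pfm(self._table({"AA": 1}), k=2)


class TestSpeciesMix:
    MAP = {"CTAG": "human", "GGAC": "mouse"}

    def test_all_concordant(self):
        obs = [("CTAG", "human")] * 5 + [("GGAC", "mouse")] * 5
        assert species_mix_rate(obs, self.MAP).rate == 1.0

    def test_all_swapped(self):
        obs = [("CTAG", "mouse"), ("GGAC", "human")]
        assert species_mix_rate(obs, self.MAP).rate == 0.0

    def test_three_in_a_thousand_discordant(self):
        obs = [("CTAG", "human")] * 997 + [("CTAG", "mouse")] * 3
        res = species_mix_rate(obs, self.MAP)
        assert res.rate == pytest.approx(0.997)
        assert res.per_genome["human"] == (997, 1000)

    def test_unknown_barcode_rejected(self):
        with pytest.raises(ValueError):
            species_mix_rate([("TTTT", "human")], self.MAP)
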