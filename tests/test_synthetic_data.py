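"""Generator truth: hairpin construction, genome planting, read simulation,
database redundancy and UTR site planting."""

import numpy as np
import pytest

from mirnovo import genome_align as ga
from mirnovo import synthetic_data as sd
from mirnovo._seq import extract, revcomp_dna, revcomp_rna, to_dna
from mirnovo.preprocess import CollapsedRead


class TestMakeHairpinLocus:
    def test_zero_wobble_gives_perfect_stem(self):
        hp = sd.make_hairpin_locus("ACGUACGUACGUACGUACGUAC", 8, 0.0, 1)
        mature = hp.precursor[hp.mature_start - 1 : hp.mature_end]
        star = hp.precursor[hp.star_start - 1 : hp.star_end]
        assert star == revcomp_rna(mature)
        assert hp.n_mismatches == 0

    def test_mature_embedded_verbatim_on_5p_arm(self):
        mature = "AGAGGCUGUCCGAGUGCUGAU"  # 21 nt
        hp = sd.make_hairpin_locus(mature, 10, 0.3, 2)
        assert mature in hp.precursor
        assert hp.precursor.index(mature) == hp.mature_start - 1
        assert hp.mature_end < hp.star_start  # 5' arm precedes the star

    def test_wobble_mismatch_count_matches_reenumeration(self):
        """Mismatches counted by the generator equal an independent
        per-position re-enumeration: a mismatch is a star position that can
        no longer pair (WC or G:U) with its opposing mature base."""
        from mirnovo.energy import can_pair
        mature = "AACCAAUUAACCAAUUAACCAA"
        hp = sd.make_hairpin_locus(mature, 8, 0.5, 3)
        star = hp.precursor[hp.star_start - 1 : hp.star_end]
        recount = sum(1 for t, b in enumerate(star)
                      if not can_pair(mature[len(mature) - 1 - t], b))
        assert recount == hp.n_mismatches
        assert hp.n_mismatches <= 6  # enforced cap

    def test_precursor_length_bounds(self):
        for seed in range(5):
            hp = sd.make_hairpin_locus("ACGUACGUACGUACGUACGUAC", 8, 0.0, seed)
            assert 60 <= len(hp.precursor) <= 100

    def test_mature_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            sd.make_hairpin_locus("ACGUACGUACGUACGUA"[:17], 8, 0.0, 1)
        with pytest.raises(ValueError):
            sd.make_hairpin_locus("A" * 27, 8, 0.0, 1)

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError):
            sd.make_hairpin_locus("ACGUACGUACGUACGUACGUAC", 2, 0.0, 1)


class TestMakeGenome:
    def test_no_loci_pure_random(self):
        genome, truth = sd.make_genome(2, 500, [], 7)
        assert truth.loci == []
        assert set("".join(genome.values())) <= set("ACGT")

    def test_planted_sequence_at_recorded_coordinates(self):
        hp = sd.make_hairpin_locus("ACGUACGUACGUACGUACGUAC", 8, 0.0, 1)
        spec = {"kind": "novel_mirna", "mature": "ACGUACGUACGUACGUACGUAC",
                "chrom": "chr1", "start": 1001, "strand": "+",
                "loop_len": 8, "wobble_rate": 0.0}
        genome, truth = sd.make_genome(1, 3000, [spec], 9)
        loc = truth.loci[0]
        assert (loc.start, loc.strand) == (1001, "+")
        assert loc.end - loc.start + 1 == len(
            extract(genome["chr1"], loc.start, loc.end))
        assert to_dna(loc.mature_seq) in extract(genome["chr1"], loc.start,
                                                 loc.end)

    def test_minus_strand_reverse_complemented(self):
        # wobbled stem: otherwise the star arm of a perfect hairpin is the
        # mature's reverse complement and the mature shows on both strands
        spec = {"kind": "novel_mirna", "mature": "AAGGCUGUCCGAGUGCUGAUAA",
                "chrom": "chr1", "start": 500, "strand": "-",
                "loop_len": 8, "wobble_rate": 0.3}
        genome, truth = sd.make_genome(1, 2000, [spec], 11)
        loc = truth.loci[0]
        sense = extract(genome["chr1"], loc.start, loc.end, "-")
        assert to_dna(loc.mature_seq) in sense
        assert to_dna(loc.mature_seq) not in genome["chr1"][loc.start - 1 : loc.end]

    def test_overlap_raises(self):
        spec = {"kind": "random", "chrom": "chr1", "start": 100}
        with pytest.raises(ValueError, match="overlap"):
            sd.make_genome(1, 2000, [spec, dict(spec)], 13)

    def test_fixed_seed_is_byte_identical(self):
        specs = [{"kind": "novel_mirna"} for _ in range(3)]
        g1, t1 = sd.make_genome(2, 2000, [dict(s) for s in specs], 17)
        g2, t2 = sd.make_genome(2, 2000, [dict(s) for s in specs], 17)
        assert g1 == g2
        assert [(l.chrom, l.start, l.end, l.mature_seq) for l in t1.loci] == \
               [(l.chrom, l.start, l.end, l.mature_seq) for l in t2.loci]

    def test_truth_coordinate_invariant(self, small_dataset):
        from Bio import SeqIO
        genome = {r.id: str(r.seq) for r in
                  SeqIO.parse(small_dataset["paths"]["genome"], "fasta")}
        for loc in small_dataset["truth"].loci:
            sense = extract(genome[loc.chrom], loc.start, loc.end, loc.strand)
            assert to_dna(loc.mature_seq) in sense


class TestSimulateReads:
    def _truth(self, abundance):
        spec = {"kind": "novel_mirna", "mature": "ACGUACGUACGUACGUACGUAC",
                "loop_len": 8, "wobble_rate": 0.0,
                "abundance": {"brain": abundance}}
        _, truth = sd.make_genome(1, 2000, [spec], 19, tissue_names=["brain"])
        return truth

    def test_zero_abundance_empty_fastq(self):
        assert sd.simulate_reads(self._truth(0.0), "brain", rng_seed=1) == []

    def test_error_free_reads_match_matures_after_adapter_removal(self):
        truth = self._truth(200)
        reads = sd.simulate_reads(truth, "brain", error_rate=0.0, rng_seed=2,
                                  end_trim_prob=0.0)
        mature_dna = to_dna(truth.loci[0].mature_seq)
        adapter = to_dna(truth.adapter_seq)
        for _, seq, qual in reads:
            insert = seq[: len(mature_dna)]
            assert insert == mature_dna
            assert seq[len(insert):] == adapter[: len(seq) - len(insert)]
            assert len(qual) == len(seq)

    def test_poisson_count_within_five_sd(self):
        reads = sd.simulate_reads(self._truth(1000), "brain", rng_seed=3)
        assert abs(len(reads) - 1000) <= 5 * np.sqrt(1000)

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ValueError, match="tissue"):
            sd.simulate_reads(self._truth(10), "kidney", rng_seed=4)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            sd.simulate_reads(self._truth(10), "brain", error_rate=0.2,
                              rng_seed=5)


class TestMakeKnownDb:
    def test_no_sharing_all_unique(self):
        recs = sd.make_known_db(["dre", "ola"], 0.0, 1, n_mirnas=8)
        assert len(recs) == 8
        assert len({seq for _, seq in recs}) == 8

    def test_full_sharing_counting_oracle(self):
        recs = sd.make_known_db(["dre", "ola", "ipu"], 1.0, 2, n_mirnas=10)
        assert len(recs) == 30
        assert len({seq for _, seq in recs}) == 10


class TestMakeUtrTargets:
    MIRNAS = {"m1": "ACGUACGUACGUACGUACGUAC", "m2": "UUGGAACCUUGGAACCUUGGAA"}

    def test_no_sites_requested(self):
        utrs, truth = sd.make_utr_targets(self.MIRNAS, 4, 0, 1)
        assert truth == [] and len(utrs) == 4

    def test_recorded_position_is_exact_reverse_complement(self):
        utrs, truth = sd.make_utr_targets(self.MIRNAS, 6, 2, 2)
        assert truth
        for utr_id, m_name, pos in truth:
            site = utrs[utr_id][pos - 1 : pos - 1 + len(self.MIRNAS[m_name])]
            assert site == revcomp_dna(to_dna(self.MIRNAS[m_name]))


class TestRoundTrip:
    def test_error_free_simulation_recovers_planted_loci(self, small_dataset):
        """Preprocess + exact alignment of error-free reads places >= 99%
        of expressed loci back at their planted coordinates."""
        truth = small_dataset["truth"]
        reads = sd.simulate_reads(truth, "brain", error_rate=0.0, rng_seed=8,
                                  end_trim_prob=0.0)
        from Bio import SeqIO
        genome = {r.id: str(r.seq) for r in
                  SeqIO.parse(small_dataset["paths"]["genome"], "fasta")}
        index = ga.GenomeIndex(genome)
        distinct = {seq[: len(to_dna(l.mature_seq))]
                    for _, seq, _ in reads for l in truth.loci
                    if seq.startswith(to_dna(l.mature_seq))}
        recovered = 0
        expressed = [l for l in truth.loci
                     if l.per_tissue_abundance.get("brain", 0) > 0]
        for loc in expressed:
            hits = ga.align_read(CollapsedRead(to_dna(loc.mature_seq), 1),
                                 index, 0)
            if any(h.chrom == loc.chrom and loc.start <= h.start
                   and h.end <= loc.end for h in hits):
                recovered += 1
        assert recovered / len(expressed) >= 0.99
        assert distinct  # the simulated library actually covered the loci
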