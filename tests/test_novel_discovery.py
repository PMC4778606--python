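"""Hairpin-candidate calling: clustering, window excision, the criterion
set, the MFEI filter and the report table."""

import numpy as np
import pytest

from mirnovo import novel_discovery as nd
from mirnovo import synthetic_data as sd
from mirnovo._seq import revcomp_dna, to_dna, to_rna
from mirnovo.genome_align import AlignmentHit


def _hit(seq="ACGTACGTACGTACGTACGTAC", chrom="chr1", start=1000,
         strand="+", count=10, mm=0, rid="r1"):
    return AlignmentHit(rid, seq, chrom, start, start + len(seq) - 1,
                        strand, mm, count)


class TestClusterLoci:
    def test_distant_reads_make_two_clusters(self):
        clusters = nd.cluster_loci([_hit(start=1000), _hit(start=501000,
                                                           rid="r2")])
        assert len(clusters) == 2

    def test_staggered_isomirs_merge_with_max_count_representative(self):
        a = _hit(start=1000, count=5, rid="a")
        b = _hit(start=1003, count=50, rid="b", seq="TGCATGCATGCATGCATGCATG")
        c = _hit(start=1010, count=7, rid="c")
        clusters = nd.cluster_loci([a, b, c])
        assert len(clusters) == 1
        assert clusters[0].representative is b
        assert clusters[0].total_count == 62

    def test_representative_tie_prefers_longer_then_lexicographic(self):
        short = _hit(seq="ACGTACGTACGTACGTACGT", count=5, rid="s")
        longer = _hit(seq="TACGTACGTACGTACGTACGTA", count=5, rid="l",
                      start=1002)
        assert nd.cluster_loci([short, longer])[0].representative is longer
        x = _hit(seq="CCGTACGTACGTACGTACGT", count=5, rid="x")
        y = _hit(seq="ACGTACGTACGTACGTACGG", count=5, rid="y", start=1001)
        assert nd.cluster_loci([x, y])[0].representative is y

    def test_empty_input(self):
        assert nd.cluster_loci([]) == []

    def test_strands_cluster_separately(self):
        clusters = nd.cluster_loci([_hit(), _hit(strand="-", rid="r2")])
        assert len(clusters) == 2


class TestFilterRepeats:
    def test_read_mapping_everywhere_is_discarded(self):
        hits = [_hit(start=1000 + 100 * i, rid="rep") for i in range(25)]
        hits.append(_hit(start=90000, rid="uniq"))
        kept = nd.filter_repeats(hits, uniqueness=20)
        assert {h.read_id for h in kept} == {"uniq"}


class TestExciseWindows:
    def test_examined_span_arithmetic(self):
        genome = {"chr1": "A" * 5000}
        cluster = nd.cluster_loci([_hit(start=1001)])[0]  # mature 1001..1022
        windows = nd.excise_windows(cluster, genome, flank=100)
        assert min(w[2] for w in windows) == 901
        assert max(w[3] for w in windows) == 1122

    def test_clipped_at_chromosome_start(self):
        genome = {"chr1": "A" * 5000}
        cluster = nd.cluster_loci([_hit(start=50)])[0]
        windows = nd.excise_windows(cluster, genome, flank=100)
        assert min(w[2] for w in windows) == 1

    def test_minus_strand_window_is_reverse_complement(self, rng):
        chrom = "".join(rng.choice(list("ACGT"), size=3000))
        genome = {"chr1": chrom}
        read = revcomp_dna(chrom[1000:1022])
        cluster = nd.cluster_loci([_hit(seq=read, start=1001, strand="-")])[0]
        for window_rna, off, gs, ge in nd.excise_windows(cluster, genome, 100):
            assert window_rna == to_rna(revcomp_dna(chrom[gs - 1 : ge]))
            assert window_rna[off : off + 22] == to_rna(read)


class TestComputeMfei:
    def test_direct_arithmetic(self):
        assert nd.compute_mfei(-43.24, 92, 51.09) == pytest.approx(-0.92, abs=0.005)

    def test_zero_mfe_gives_zero(self):
        assert nd.compute_mfei(0.0, 80, 50.0) == 0.0

    def test_length_doubling_halves_magnitude(self):
        one = nd.compute_mfei(-40.0, 80, 50.0)
        two = nd.compute_mfei(-40.0, 160, 50.0)
        assert two == pytest.approx(one / 2)

    def test_zero_gc_is_error(self):
        with pytest.raises(ValueError):
            nd.compute_mfei(-40.0, 80, 0.0)


class TestFilterMfei:
    def _cand(self, mfei):
        return nd.HairpinCandidate("n", "chr1", 1, 80, "+", "A" * 80,
                                   "A" * 22, "A" * 22, 100, 50.0, -40.0, mfei)

    @pytest.mark.parametrize("mfei,kept", [(-0.86, True), (-0.84, False),
                                           (-0.85, False), (0.9, True)])
    def test_strict_magnitude_threshold(self, mfei, kept):
        assert bool(nd.filter_mfei([self._cand(mfei)])) is kept


def _planted_window(seed=0, wobble=0.0, mature="AGAGGCUGUCCGAGUGCUGAU"):
    """Window RNA with a planted hairpin plus random flanks, and the
    mature's offset inside it."""
    rng = np.random.default_rng(seed)
    hp = sd.make_hairpin_locus(mature, 8, wobble, rng)
    left = sd.random_rna(rng, 40)
    right = sd.random_rna(rng, 40)
    window = left + hp.precursor + right
    return window, len(left) + hp.mature_start - 1, len(mature), hp


class TestEvaluate:
    def test_planted_hairpin_accepted_with_star_partner(self):
        window, off, mlen, hp = _planted_window(1)
        result, failed = nd.evaluate(window, off, mlen)
        assert failed == [] and result is not None
        s_lo, s_hi = result["star_span"]
        star = result["fold"].seq[s_lo - 1 : s_hi]
        planted_star = hp.precursor[hp.star_start - 1 : hp.star_end]
        assert star in planted_star or planted_star in star

    def test_loop_spanning_mature_rejected(self):
        window, off, mlen, hp = _planted_window(2)
        # center a pseudo-mature on the terminal loop
        loop_mid = off + mlen + 4
        result, failed = nd.evaluate(window, loop_mid - 10, 21)
        assert result is None
        assert {"mature_one_arm", "min_mature_pairs",
                "mature_star_disjoint"} & set(failed)

    def test_weak_au_stem_fails_energy(self):
        rng = np.random.default_rng(3)
        stem = "AUAUAAUU"  # 8 bp AU-only stem folds far above -18
        window = (sd.random_rna(rng, 30) + stem + "AAACAAA"
                  + "AAUUAUAU" + sd.random_rna(rng, 30))
        result, failed = nd.evaluate(window, 30, 20)
        assert result is None and failed

    def test_window_too_short_is_rejection(self):
        result, failed = nd.evaluate("ACGUACGUACGU", 0, 22)
        assert result is None
        assert failed  # at least one named criterion

    def test_mature_length_bounds(self):
        window, off, _, _ = _planted_window(4)
        result, failed = nd.evaluate(window, off, 17)
        assert result is None and "mature_length" in failed


def _make_truth_hits(n_novel=20, n_decoy=20, seed=5):
    """Genome with planted novels and decoys; hits placed from truth."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_novel):
        specs.append({"kind": "novel_mirna", "name": f"nov{i}",
                      "wobble_rate": float(rng.uniform(0, 0.1)),
                      "abundance": {"brain": 300.0}})
    for i in range(n_decoy):
        kind = ("trna_decoy", "rrna_decoy", "random")[i % 3]
        specs.append({"kind": kind, "name": f"dec{i}",
                      "abundance": {"brain": 300.0}})
    genome, truth = sd.make_genome(3, 30000, specs, rng,
                                   tissue_names=["brain"])
    hits = []
    for j, loc in enumerate(truth.loci):
        mat = to_dna(loc.mature_seq)
        chrom_seq = genome[loc.chrom]
        if loc.strand == "+":
            start = chrom_seq.find(mat, loc.start - 1) + 1
        else:
            start = chrom_seq.find(revcomp_dna(mat), loc.start - 1) + 1
        assert start > 0
        hits.append(AlignmentHit(f"read{j}", mat, loc.chrom, start,
                                 start + len(mat) - 1, loc.strand, 0, 300))
    return genome, truth, hits


@pytest.fixture(scope="module")
def discovery():
    genome, truth, hits = _make_truth_hits()
    cands, rejections = nd.discover(hits, genome)
    return genome, truth, cands, rejections


class TestDiscover:
    def test_sensitivity_and_decoy_exclusion(self, discovery):
        """>= 90% of planted hairpins recovered; no decoy locus reported."""
        genome, truth, cands, _ = discovery
        kept = nd.filter_mfei(cands)
        novel = [l for l in truth.loci if l.kind == "novel_mirna"]
        hit_loci = set()
        for c in kept:
            for l in truth.loci:
                if (l.chrom == c.chrom and not (c.precursor_end < l.start
                                                or c.precursor_start > l.end)):
                    assert l.kind == "novel_mirna", f"decoy {l.name} reported"
                    hit_loci.add(l.name)
        assert len(hit_loci) / len(novel) >= 0.90

    def test_candidates_repass_evaluation(self, discovery):
        """Idempotence: feeding a reported precursor back through the
        criteria accepts it again."""
        _, _, cands, _ = discovery
        for c in nd.filter_mfei(cands)[:10]:
            off = c.precursor_seq.find(c.mature_seq)
            assert off >= 0
            result, failed = nd.evaluate(c.precursor_seq, off,
                                         len(c.mature_seq))
            assert failed == []

    def test_mfei_self_consistency(self, discovery):
        _, _, cands, _ = discovery
        for c in cands:
            assert c.mfei == pytest.approx(
                nd.compute_mfei(c.mfe, c.precursor_len, c.gc_percent),
                abs=1e-9)

    def test_rejections_carry_failed_criteria(self, discovery):
        _, _, _, rejections = discovery
        for r in rejections:
            assert len(r.failed_criteria) >= 1


class TestReport:
    def _candidates(self):
        genome, truth, hits = _make_truth_hits(n_novel=4, n_decoy=0, seed=9)
        cands, _ = nd.discover(hits, genome)
        return nd.filter_mfei(cands)

    def test_single_candidate_named_nov1(self):
        cands = self._candidates()
        report = nd.name_and_report({"brain": cands[:1]})
        assert report["name"].tolist() == ["Dre-mir-nov1"]

    def test_renaming_is_deterministic(self):
        cands = self._candidates()
        r1 = nd.name_and_report({"brain": cands})
        r2 = nd.name_and_report({"brain": list(cands)})
        assert r1.equals(r2)

    def test_row_arithmetic_self_consistent(self):
        cands = self._candidates()
        report = nd.name_and_report({"brain": cands})
        assert not report.empty
        assert (report["precursor_end"] - report["precursor_start"] + 1
                == report["precursor_length"]).all()
        assert (report["sequence"].str.len() == report["mirna_length"]).all()

    def test_numbering_runs_across_tissues(self):
        cands = self._candidates()
        report = nd.name_and_report({"brain": cands[:2], "pineal": cands[2:4]})
        assert report["name"].tolist() == [f"Dre-mir-nov{i}" for i in
                                           range(1, len(report) + 1)]
        assert report["tissue"].tolist() == (["brain"] * 2 + ["pineal"] * 2)
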