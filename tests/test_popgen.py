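from __future__ import annotations

import math

import numpy as np
import pytest

import _oracles as oracle
from xenoscan.io import GeneFeature
from xenoscan.popgen import (
    NGCounts,
    PairwiseAlignment,
    dn_ds,
    nei_gojobori_counts,
    orf_dn_ds,
    snp_window_track,
)


class TestAlignment:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("ACGT", "ACG")

    def test_bad_mask(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("ACGT", "ACGT", mask=[(0, 9)])


class TestSnpTrack:
    def test_identical_pair(self):
        aln = PairwiseAlignment("A" * 500, "A" * 500)
        track = snp_window_track(aln)
        assert [w.percent for w in track.windows] == [0.0, 0.0]

    def test_five_substitutions_first_window(self):
        s1 = "A" * 500
        s2 = "C" * 5 + "A" * 495
        track = snp_window_track(PairwiseAlignment(s1, s2))
        assert [w.percent for w in track.windows] == [pytest.approx(2.0), 0.0]

    def test_mask_excludes_numerator_and_denominator(self):
        s1 = "A" * 500
        s2 = "C" * 10 + "A" * 490  # 10 mismatches inside [0, 100)
        track = snp_window_track(PairwiseAlignment(s1, s2, mask=[(0, 100)]))
        w0 = track.windows[0]
        assert (w0.comparable, w0.mismatches) == (150, 0)

    def test_gap_and_n_columns_excluded(self):
        s1 = "ACGT" * 100
        s2 = "A-GT" + "ACGN" + "TCGT" + "ACGT" * 97
        track = snp_window_track(PairwiseAlignment(s1, s2), window=400)
        (w,) = track.windows
        assert w.comparable == 398 and w.mismatches == 1

    def test_window_larger_than_alignment(self):
        track = snp_window_track(PairwiseAlignment("A" * 100, "A" * 100), window=250)
        assert len(track.windows) == 1 and track.windows[0].end == 100

    def test_sparse_window_reported_missing(self):
        aln = PairwiseAlignment("A" * 40 + "N" * 210, "A" * 250)
        (w,) = snp_window_track(aln).windows
        assert w.comparable == 40 and w.percent is None

    def test_bookkeeping_sums_to_alignment_total(self, genotype_pair):
        aln, truth = genotype_pair
        track = snp_window_track(aln)
        assert track.total_mismatches == len(truth.substitutions)

    def test_symmetry(self):
        rng = np.random.default_rng(51)
        s1 = "".join(rng.choice(list("ACGT"), size=1000))
        s2 = "".join(rng.choice(list("ACGT"), size=1000))
        t12 = snp_window_track(PairwiseAlignment(s1, s2))
        t21 = snp_window_track(PairwiseAlignment(s2, s1))
        assert t12 == t21


class TestNeiGojobori:
    def test_phe_codon_sites(self):
        c = nei_gojobori_counts("TTT", "TTT")
        assert c.Sd == 0 and c.Nd == 0
        assert c.S == pytest.approx(1 / 3)
        assert c.N == pytest.approx(8 / 3)

    def test_one_synonymous_difference(self):
        c = nei_gojobori_counts("TTTGGGGGG", "TTCGGGGGG")
        assert (c.Sd, c.Nd) == (1.0, 0.0)
        assert c.S == pytest.approx(7 / 3)  # 1/3 for TTT/TTC + 1 for each GGG
        assert c.N == pytest.approx(20 / 3)

    def test_ambiguous_codons_skipped(self):
        # second codon pair has N / gap, so only TTT/TTC is compared
        c = nei_gojobori_counts("TTTNNN", "TTC---")
        assert c.codons_compared == 1
        ref = nei_gojobori_counts("TTT", "TTC")
        assert (c.S, c.N, c.Sd, c.Nd) == (ref.S, ref.N, ref.Sd, ref.Nd)

    def test_premature_stop_named(self):
        with pytest.raises(ValueError, match="codon index 1"):
            nei_gojobori_counts("TTTTAAGGG", "TTTTAAGGG")

    def test_terminal_stop_skipped(self):
        c = nei_gojobori_counts("TTTTAA", "TTTTAA")
        assert c.codons_compared == 1

    def test_sites_plus_differences_invariant(self):
        rng = np.random.default_rng(52)
        s1, s2 = oracle.neutral_pair(rng, 100, 10)
        c = nei_gojobori_counts(s1, s2)
        assert c.S + c.N == pytest.approx(3 * c.codons_compared)
        ndiff = sum(a != b for a, b in zip(s1, s2))
        assert c.Sd + c.Nd == pytest.approx(ndiff)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pathway_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        s1 = oracle.random_orf(rng, 300)
        s2 = oracle.random_orf(rng, 300)
        c = nei_gojobori_counts(s1, s2)
        N, S, Nd, Sd = oracle.ng_counts(s1, s2)
        assert c.N == pytest.approx(N)
        assert c.S == pytest.approx(S)
        assert c.Nd == pytest.approx(Nd)
        assert c.Sd == pytest.approx(Sd)

    def test_symmetry(self):
        rng = np.random.default_rng(53)
        s1, s2 = oracle.neutral_pair(rng, 200, 20)
        c12 = nei_gojobori_counts(s1, s2)
        c21 = nei_gojobori_counts(s2, s1)
        assert c12 == c21


class TestDnDs:
    def test_no_differences_ratio_undefined(self):
        r = dn_ds(nei_gojobori_counts("TTTGGG", "TTTGGG"))
        assert r.dN == 0.0 and r.dS == 0.0 and math.isnan(r.ratio)

    def test_closed_form_jukes_cantor(self):
        r = dn_ds(nei_gojobori_counts("TTTGGGGGG", "TTCGGGGGG"))
        assert r.pS == pytest.approx(3 / 7)
        assert r.dS == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 7)))
        assert r.dS == pytest.approx(0.6354, abs=1e-4)
        assert r.dN == 0.0 and r.ratio == 0.0

    def test_uncorrected_equals_proportion_ratio(self):
        rng = np.random.default_rng(54)
        s1, s2 = oracle.neutral_pair(rng, 300, 20)
        c = nei_gojobori_counts(s1, s2)
        r = dn_ds(c, correction="none")
        assert r.ratio == pytest.approx((c.Nd / c.N) / (c.Sd / c.S))

    def test_saturated_proportion_is_nan(self):
        r = dn_ds(NGCounts(N=10.0, S=10.0, Nd=8.0, Sd=1.0))
        assert math.isnan(r.dN) and math.isnan(r.ratio)
        assert r.pN == pytest.approx(0.8)  # raw proportion retained

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            dn_ds(NGCounts(N=1.0, S=1.0, Nd=-1.0, Sd=0.0))

    def test_neutral_simulation_pooled_ratio_near_one(self):
        # 2% divergence on 500-codon ORFs: the pooled mean(dN)/mean(dS)
        # concentrates on 1 (the per-replicate ratio has a heavy right tail
        # from its noisy dS denominator and centres above 1)
        rng = np.random.default_rng(55)
        dns, dss = [], []
        for _ in range(50):
            r = dn_ds(nei_gojobori_counts(*oracle.neutral_pair(rng, 500, 30)))
            dns.append(r.dN)
            dss.append(r.dS)
        assert 0.85 <= float(np.mean(dns) / np.mean(dss)) <= 1.15

    def test_selection_regimes_recover_ratio_direction(self, planted_genome):
        # syn-biased and nonsyn-biased substitution mixes land on the right
        # side of 1 in >= 95% of replicates (2% divergence on real ORFs)
        from xenoscan import simulate as sim

        genome, genes, _ = planted_genome
        big = max(genes, key=len)
        for n_syn, n_nonsyn, purifying in ((12, 3, True), (3, 12, False)):
            good = 0
            for rep in range(20):
                aln, _ = sim.simulate_genotype_pair(
                    genome, [big], n_syn, n_nonsyn, 0, seed=700 + rep
                )
                ((_, r),) = orf_dn_ds(aln, [big])
                if not math.isnan(r.ratio):
                    good += (r.ratio < 1.0) if purifying else (r.ratio > 1.0)
            assert good >= 19


class TestOrfDnDs:
    def test_purifying_fixture_is_zero(self, planted_genome):
        from xenoscan import simulate as sim

        genome, genes, _ = planted_genome
        aln, truth = sim.simulate_genotype_pair(genome, genes, 10, 0, 0, seed=61)
        mutated_genes = {s.gene_id for s in truth.substitutions}
        results = {f.id: r for f, r in orf_dn_ds(aln, genes)}
        for gid in mutated_genes:
            assert results[gid].ratio == 0.0

    def test_minus_strand_orf(self):
        # minus-strand gene: genome carries the revcomp of TTT GGG / TTC GGG
        from xenoscan.io import revcomp

        s1 = "AA" + revcomp("TTTGGGGGG") + "AA"
        s2 = "AA" + revcomp("TTCGGGGGG") + "AA"
        f = GeneFeature("c", 2, 11, "-", id="g1")
        ((_, r),) = orf_dn_ds(PairwiseAlignment(s1, s2), [f])
        assert (r.Sd, r.Nd) == (1.0, 0.0)
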