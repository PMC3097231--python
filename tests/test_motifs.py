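from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_force_scan
from conftest import SITE, SITE_VARIANT, random_dna
from xenoscan.io import GenomeRecord
from xenoscan.motifs import (
    MotifPattern,
    SiteHit,
    build_pfm,
    consensus_from_pfm,
    count_mismatches,
    scan,
    two_pass_scan,
)

REFINED = "TCGANNAATT"


def hit_set(hits):
    return {(h.start, h.strand, h.mismatches) for h in hits}


class TestPattern:
    def test_budget_must_fit_fixed_positions(self):
        with pytest.raises(ValueError):
            MotifPattern("TCGANNAATT", max_mismatches=8)
        with pytest.raises(ValueError):
            MotifPattern("NNNN")
        with pytest.raises(ValueError):
            MotifPattern("ACG")  # too short

    def test_iupac_accepted(self):
        p = MotifPattern("TCGRNNAATT", 1)
        assert count_mismatches("TCGATTAATT", p) == 0
        assert count_mismatches("TCGGTTAATT", p) == 0
        assert count_mismatches("TCGCTTAATT", p) == 1


class TestCountMismatches:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ("TCGATTAATT", 0),  # N positions are free
            ("ACGATTAATT", 1),
            ("TCGANNAATT", 0),  # N in window at the pattern's own N positions
            ("NCGATTAATT", 1),  # N in window at a fixed position is a mismatch
            ("AAAAAAAAAA", 5),  # T,C,G at the start and the two trailing Ts
        ],
    )
    def test_examples(self, window, expected):
        assert count_mismatches(window, MotifPattern(REFINED)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_mismatches("ACGT", MotifPattern(REFINED))


class TestScan:
    def test_single_forward_hit(self):
        g = GenomeRecord("g", "TCGATTAATT")
        hits = scan(g, MotifPattern(REFINED), both_strands=True)
        assert hit_set(hits) == {(0, "+", 0)}

    def test_shorter_than_pattern(self):
        with pytest.raises(ValueError):
            scan(GenomeRecord("g", "ACGT"), MotifPattern(REFINED))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("budget", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed, budget):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 10_000)
        g = GenomeRecord("g", seq)
        got = hit_set(scan(g, MotifPattern(SITE, budget)))
        assert got == brute_force_scan(seq, SITE, budget)

    def test_oracle_with_ns_in_genome(self):
        rng = np.random.default_rng(5)
        seq = list(random_dna(rng, 5_000))
        for i in rng.integers(0, len(seq), size=200):
            seq[i] = "N"
        seq = "".join(seq)
        got = hit_set(scan(GenomeRecord("g", seq), MotifPattern(SITE, 2)))
        assert got == brute_force_scan(seq, SITE, 2)

    def test_strand_symmetry(self):
        from xenoscan.io import revcomp

        rng = np.random.default_rng(3)
        seq = random_dna(rng, 8_000)
        pat = MotifPattern(SITE, 2)
        fwd = hit_set(scan(GenomeRecord("g", seq), pat))
        rev = hit_set(scan(GenomeRecord("g", revcomp(seq)), pat))
        n, L = len(seq), len(SITE)
        mirrored = {(n - s - L, "+" if strand == "-" else "-", m) for s, strand, m in rev}
        assert fwd == mirrored

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(4)
        g = GenomeRecord("g", random_dna(rng, 20_000))
        sets = [hit_set(scan(g, MotifPattern(SITE, b))) for b in range(3)]
        positions = [{(s, strand) for s, strand, _ in hs} for hs in sets]
        assert positions[0] <= positions[1] <= positions[2]

    def test_palindromic_site_dedupe(self):
        # AATT is its own reverse complement
        g = GenomeRecord("g", "CCAATTCC")
        pat = MotifPattern("AATT", 0)
        both = scan(g, pat)
        assert hit_set(both) == {(2, "+", 0), (2, "-", 0)}
        assert hit_set(scan(g, pat, dedupe=True)) == {(2, "+", 0)}

    def test_background_rate_sanity(self):
        # exact-match rate of TCGANNAATT on uniform DNA: 2 strands x (1/4)^8 per window
        pat = MotifPattern(REFINED)
        L = 200_000
        expected = 2 * (L - 9) * 0.25**8
        sd = np.sqrt(expected)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            g = GenomeRecord("g", random_dna(rng, L))
            n = len(scan(g, pat))
            assert abs(n - expected) <= 4 * sd


def _hits(seqs):
    return [SiteHit("c", 100 * i, "+", s, 0) for i, s in enumerate(seqs)]


class TestPfm:
    def test_unanimous_counts(self):
        pfm = build_pfm(_hits([SITE] * 10))
        assert pfm.n_sites == 10
        assert (pfm.counts.sum(axis=0) == 10).all()
        assert (pfm.counts.max(axis=0) == 10).all()

    def test_split_column_counts(self):
        pfm = build_pfm(_hits([SITE] * 5 + [SITE_VARIANT] * 5))
        # the two variants differ at columns 4 and 5 (0-based)
        for j in range(10):
            col = pfm.column(j)
            if j in (4, 5):
                assert sorted(col.values(), reverse=True)[:2] == [5, 5]
            else:
                assert max(col.values()) == 10

    def test_column_sums_equal_n_sites(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(37)]
        pfm = build_pfm(_hits(seqs))
        assert (pfm.counts.sum(axis=0) == pfm.n_sites).all()

    def test_n_containing_hits_excluded(self):
        pfm = build_pfm(_hits([SITE] * 3 + ["TCGANAAATT"]))
        assert pfm.n_sites == 3
        assert pfm.n_excluded == 1

    def test_empty_hit_list(self):
        with pytest.raises(ValueError):
            build_pfm([])


class TestConsensus:
    def test_unanimous(self):
        assert consensus_from_pfm(build_pfm(_hits([SITE] * 10))).iupac == SITE

    def test_split_core_becomes_n(self):
        pfm = build_pfm(_hits([SITE] * 5 + [SITE_VARIANT] * 5))
        assert consensus_from_pfm(pfm).iupac == REFINED

    def test_threshold_one_requires_unanimity(self):
        pfm = build_pfm(_hits([SITE] * 9 + [SITE_VARIANT]))
        assert consensus_from_pfm(pfm, base_threshold=1.0).iupac == REFINED
        assert consensus_from_pfm(pfm, base_threshold=0.65).iupac == SITE


class TestTwoPass:
    def test_exact_plantings_recovered(self, planted_genome):
        genome, _, truth = planted_genome
        refined, final, pfm = two_pass_scan(genome, MotifPattern(SITE, 2))
        assert refined.iupac == SITE
        found = {(h.start, h.strand) for h in final}
        assert {(s.position, s.strand) for s in truth.sites} <= found

    def test_two_variant_planting_refines_to_degenerate_core(self, two_variant_genome):
        genome, _, truth = two_variant_genome
        refined, final, _ = two_pass_scan(genome, MotifPattern(SITE, 2))
        assert refined.iupac == REFINED
        found = {h.start for h in final}
        assert {s.position for s in truth.sites} <= found

    def test_zero_first_pass_hits(self):
        g = GenomeRecord("g", "A" * 2_000)
        with pytest.raises(ValueError, match="mismatch"):
            two_pass_scan(g, MotifPattern("TCGATCGATCGA", 0))
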