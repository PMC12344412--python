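import numpy as np
import pytest
from hypothesis import given, strategies as st

from gntmotif import (
    CDSRecord,
    ContextKey,
    ContextScheme,
    Genome,
    ReplichoreModel,
    census_t_sites,
    coding_effect,
    reverse_complement,
    scan_gnt,
    substitution_effects,
)

from conftest import random_genome, random_model
from oracles import census_oracle, regex_scan_oracle, translation_diff_oracle


def motif_set(motifs):
    return {
        (m.t_pos, m.strand, m.n, m.five_prime_dinuc, m.three_prime_1, m.three_prime_2)
        for m in motifs
    }


class TestScanGnt:
    def test_planted_atg5tc_variant(self):
        # the potent leading-strand variant AT-GGGGG-T-C
        g = Genome("t", "CCCCATGGGGGTCACCCC", circular=False)
        (m,) = scan_gnt(g, None, 3, 5)
        assert (m.n, m.five_prime_dinuc, m.three_prime_1) == (5, "AT", "C")
        assert m.motif_string.startswith("ATGGGGGTC")
        assert m.ref_alt_plus == ("T", "G")

    def test_no_g_run_gives_empty(self):
        g = Genome("t", "ACACACAC", circular=False)
        assert scan_gnt(g, None, 3, 5) == []

    def test_tract_longer_than_n_max_excluded(self):
        g = Genome("t", "AAATGGGGGGTCAAA", circular=False)  # 6 Gs
        assert scan_gnt(g, None, 3, 5) == []
        (m,) = scan_gnt(g, None, 3, 6)
        assert m.n == 6

    def test_minus_arc_motif_reported_in_plus_coordinates(self):
        motif = "GAGGGGTC"
        insert = reverse_complement(motif)
        seq = "A" * 10 + insert + "A" * 10
        g = Genome("t", seq, circular=True)
        L = g.length
        m_model = ReplichoreModel(oriC=L - 1, ter=0, genome_length=L)  # all but one '-'
        (m,) = scan_gnt(g, m_model, 3, 5)
        assert m.strand == "-"
        assert m.key.marginal() == ContextKey("GA", 4, "C")
        # the mutable T sits where the plus strand has an A
        assert g.sequence[m.t_pos] == "A"
        assert m.ref_alt_plus == ("A", "C")

    def test_matches_regex_oracle_on_random_genomes(self, rng):
        for _ in range(15):
            L = int(rng.integers(500, 3000))
            g = random_genome(rng, L, gc=float(rng.uniform(0.3, 0.7)))
            model = random_model(rng, L)
            got = motif_set(scan_gnt(g, model, 3, 5))
            want = regex_scan_oracle(g, model, 3, 5)
            assert got == want

    @given(st.integers(0, 10_000))
    def test_regex_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(80, 400))
        g = random_genome(rng, L, gc=float(rng.uniform(0.25, 0.75)))
        model = random_model(rng, L)
        assert motif_set(scan_gnt(g, model, 1, 5)) == regex_scan_oracle(g, model, 1, 5)

    def test_tract_maximality(self, rng):
        g = random_genome(rng, 4000, gc=0.65)
        model = random_model(rng, 4000)
        for m in scan_gnt(g, model, 1, 5):
            assert m.five_prime_dinuc[1] != "G"

    def test_strand_symmetry(self, rng):
        # scanning the reverse-complemented genome with the mirrored model
        # yields the mirrored motif set
        L = 1500
        g = random_genome(rng, L, gc=0.6)
        model = ReplichoreModel(oriC=100, ter=900, genome_length=L)
        mirrored = ReplichoreModel(oriC=(L - 100) % L, ter=(L - 900) % L, genome_length=L)
        g_rc = Genome("rc", reverse_complement(g.sequence), circular=True)
        fwd = motif_set(scan_gnt(g, model, 3, 5))
        rev = motif_set(scan_gnt(g_rc, mirrored, 3, 5))
        mapped = {
            (L - 1 - t, "-" if s == "+" else "+", n, d, t1, t2)
            for (t, s, n, d, t1, t2) in rev
        }
        assert fwd == mapped

    def test_n_in_context_window_drops_motif(self):
        g = Genome("t", "AAANTGGGGTCAAA", circular=False)
        assert scan_gnt(g, None, 3, 5) == []  # dinucleotide contains N
        g2 = Genome("t", "AAAATGGGGTCNAA", circular=False)
        assert scan_gnt(g2, None, 3, 5) == []  # +2 base is N
        assert len(scan_gnt(g2, None, 3, 5, scheme=ContextScheme(include_plus_two=False))) == 1

    def test_lagging_orientation_reported_when_requested(self):
        motif = "GAGGGGTC"
        seq = "A" * 8 + reverse_complement(motif) + "A" * 8
        g = Genome("t", seq, circular=True)
        model = ReplichoreModel(oriC=0, ter=g.length - 1, genome_length=g.length)
        assert scan_gnt(g, model, 3, 5) == []  # reads 5'->3' only on lagging
        both = scan_gnt(g, model, 3, 5, leading_only=False)
        assert [m.replication for m in both] == ["lagging"]


class TestCensus:
    def test_poly_t_baseline_counts_every_t(self):
        # each T in a run is its own site; 5' neighbour T or A is "no G"
        g = Genome("t", "AATTTTTTTA", circular=False)
        census = census_t_sites(g, None)
        assert census.baseline_sites == 7
        assert census.key_sites == {}

    def test_single_planted_motif_site(self):
        g = Genome("t", "CCACCGAGGGGTCACCACC", circular=False)
        census = census_t_sites(g, None)
        assert census.key_sites.get(ContextKey("GA", 4, "C")) == 1

    def test_matches_sliding_window_oracle(self, rng):
        g = random_genome(rng, 5000, gc=0.55)
        model = random_model(rng, 5000)
        census = census_t_sites(g, model)
        want_keys, want_base = census_oracle(g, model)
        got = {
            (k.five_prime_dinuc, k.n, k.three_prime_1, k.three_prime_2): v
            for k, v in census.key_sites.items()
        }
        assert got == want_keys
        assert census.baseline_sites == want_base

    def test_plus_two_scheme_matches_oracle(self, rng):
        g = random_genome(rng, 3000, gc=0.5)
        model = random_model(rng, 3000)
        census = census_t_sites(g, model, ContextScheme(include_plus_two=True))
        want_keys, want_base = census_oracle(g, model, include_plus_two=True)
        got = {
            (k.five_prime_dinuc, k.n, k.three_prime_1, k.three_prime_2): v
            for k, v in census.key_sites.items()
        }
        assert got == want_keys
        assert census.baseline_sites == want_base

    @given(st.integers(0, 10_000))
    def test_census_conservation(self, seed):
        # keyed sites + baseline = all leading-strand T sites with defined
        # context (cross-checked against the oracle's total)
        rng = np.random.default_rng(seed)
        L = int(rng.integers(100, 600))
        g = random_genome(rng, L, gc=float(rng.uniform(0.3, 0.7)))
        model = random_model(rng, L)
        census = census_t_sites(g, model)
        want_keys, want_base = census_oracle(g, model)
        assert census.total_defined == sum(want_keys.values()) + want_base


class TestCodingEffect:
    def test_tga_to_gga_is_stop_lost(self):
        # premature stop codon TGA; hotspot T->G at codon position 1 -> GGA
        g = Genome("t", "ATGAAATGACCC", circular=False)
        cds = [CDSRecord("g1", 0, 12, "+")]
        (eff,) = coding_effect(6, "+", cds, g)
        assert (eff.ref_codon, eff.alt_codon, eff.effect) == ("TGA", "GGA", "stop_lost")
        assert (eff.codon_index, eff.codon_position) == (2, 1)

    def test_ggt_to_ggg_synonymous(self):
        g = Genome("t", "ATGGGTTAA", circular=False)
        cds = [CDSRecord("g1", 0, 9, "+")]
        (eff,) = coding_effect(5, "+", cds, g)
        assert (eff.ref_codon, eff.alt_codon) == ("GGT", "GGG")
        assert eff.ref_aa == eff.alt_aa == "G"
        assert eff.effect == "synonymous"

    def test_intergenic(self):
        g = Genome("t", "TTTTTT", circular=False)
        (eff,) = coding_effect(1, "+", [], g)
        assert eff.effect == "intergenic" and eff.gene_id is None

    def test_minus_strand_cds(self):
        # gene on '-': plus-strand A->C is a T->G on the coding strand
        coding = "ATGAAATGACCC"  # codons ATG AAA TGA CCC on the minus strand
        g = Genome("t", reverse_complement(coding), circular=False)
        cds = [CDSRecord("g1", 0, 12, "-")]
        # plus-strand coordinate of the coding-strand T of TGA (index 6)
        pos = 12 - 1 - 6
        (eff,) = coding_effect(pos, "-", cds, g)
        assert (eff.ref_codon, eff.alt_codon, eff.effect) == ("TGA", "GGA", "stop_lost")

    def test_overlapping_cds_gives_one_record_each(self):
        g = Genome("t", "ATGATGAAATAA", circular=False)
        cds = [CDSRecord("a", 0, 12, "+"), CDSRecord("b", 3, 12, "+")]
        effs = coding_effect(9, "+", cds, g)
        assert sorted(e.gene_id for e in effs) == ["a", "b"]

    def test_non_codon_multiple_cds_skipped(self):
        g = Genome("t", "ATGAAATG", circular=False)
        cds = [CDSRecord("bad", 0, 8, "+")]
        with pytest.warns(UserWarning, match="not divisible by 3"):
            (eff,) = coding_effect(6, "+", cds, g)
        assert eff.effect == "intergenic"

    def test_ref_mismatch_rejected(self):
        g = Genome("t", "AAAA", circular=False)
        with pytest.raises(ValueError, match="mismatch"):
            coding_effect(1, "+", [], g)  # genome has A, T->G claims T

    def test_agrees_with_full_translation_oracle(self, rng):
        # random CDS and random T->G / A->C substitutions vs translating the
        # whole mutant CDS and diffing the protein
        checked = 0
        while checked < 300:
            L = 300
            g = random_genome(rng, L, gc=0.5)
            start = int(rng.integers(0, L - 120))
            length = 3 * int(rng.integers(10, 35))
            strand = "+" if rng.random() < 0.5 else "-"
            cds = CDSRecord(f"g{checked}", start, start + length, strand)
            pos = int(rng.integers(cds.start, cds.end))
            ref = g.sequence[pos]
            if ref == "T":
                lead = "+"
            elif ref == "A":
                lead = "-"
            else:
                continue
            (eff,) = coding_effect(pos, lead, [cds], g)
            alt = "G" if lead == "+" else "C"
            want_effect, want_index = translation_diff_oracle(g.sequence, cds, pos, alt)
            assert eff.effect == want_effect
            if want_index is not None:
                assert eff.codon_index == want_index
            checked += 1
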