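from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsvm import features as feat
from mirsvm.duplexer import (AccessibilityResult, DuplexStructure,
                             fold_duplex, accessibility)
from mirsvm.seqdata import GAP, GU, MISMATCH, WC, CandidateSite, MirnaSeq, UtrSeq
from mirsvm.sitefilter import align_seed_ungapped, scan_sites
from mirsvm.features import (NO_SCORE, SITE_FEATURE_NAMES, UTR_FEATURE_NAMES,
                             conservation_features, context_features,
                             extract_site_features, extract_utr_features,
                             location_features, max_sites_in_window,
                             pairwise_features, regional_features,
                             schema_hash, seed_match_features,
                             seed_match_types)

from .conftest import make_perfect_pair, revcomp
from .oracles import brute_force_seed_types, brute_force_window_max


def make_site(utr, mirna, start, span=8):
    aln = align_seed_ungapped(mirna.seq[:8], utr.seq[start:start + 8])
    return CandidateSite(utr_id=utr.id, mirna_id=mirna.id, start=start,
                         end=start + span, rule_id=1,
                         seed_statuses=aln.statuses, n_wc=aln.n_wc,
                         n_match=aln.n_match)


def make_duplex(statuses, mirna_seq="UGAGGUAGUAGGUUGUAUAGUU",
                bulges=None):
    L = min(len(mirna_seq), 20)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    dimers = tuple(4 * idx[mirna_seq[i]] + idx[mirna_seq[i + 1]] + 1
                   for i in range(L - 1))
    bulges = bulges or {"seed": (0, 0), "three_prime": (0, 0),
                        "total": (0, 0)}
    return DuplexStructure(status=tuple(statuses), dimer_code=dimers,
                           seed_boundary=8, e_seed=-5.0, e_three=-3.0,
                           e_total=-8.5, bulges=bulges)


class TestSeedMatchFeatures:
    def test_all_types_with_u_p1(self):
        """With p1 = U, q1 = A both pairs p1 and is literally A, so all
        six flags can be 1 simultaneously."""
        mirna = MirnaSeq(id="m", seq="UGAGGUAGUAGGUUGUAUAGUU")
        assert mirna.seq[0] == "U"
        seg = revcomp(mirna.seq[:8])  # q1 = complement(U) = A
        utr = UtrSeq(id="u", seq="C" * 20 + seg + "C" * 20)
        site = make_site(utr, mirna, 20)
        assert seed_match_features(site, utr) == [1.0] * 6

    def test_6mer_only(self):
        mirna = MirnaSeq(id="m", seq="UGAGGUAGUAGGUUGUAUAGUU")
        # complement p2..p7 only; break p1 and p8 pairing, q1 = G
        seg = "G" + revcomp(mirna.seq[1:7]) + "G"
        utr = UtrSeq(id="u", seq="C" * 20 + seg + "C" * 20)
        site = make_site(utr, mirna, 20)
        types = seed_match_types(site, utr)
        assert types["6mer"]
        assert not any(types[t] for t in
                       ("7mer_a1", "7mer_m1", "7mer_m8", "8mer_a1",
                        "8mer_m8"))

    def test_exhaustive_window_oracle(self):
        """All 4^8 site windows agree with an independent checker."""
        mirna = MirnaSeq(id="m", seq="UGAGGUAGUAGGUUGUAUAGUU")
        utr_template = "C" * 8
        for win in product("ACGU", repeat=8):
            window = "".join(win)
            utr = UtrSeq(id="u", seq=window)
            site = make_site(utr, mirna, 0)
            types = seed_match_types(site, utr)
            oracle = brute_force_seed_types(mirna.seq[:8], window)
            assert types == oracle, window


class TestPairwiseFeatures:
    def test_perfect_duplex_statuses(self):
        dup = make_duplex([WC] * 20)
        vals = pairwise_features(dup)
        assert len(vals) == 39
        assert vals[:20] == [1.0] * 20

    def test_dimer_encoding(self):
        dup = make_duplex([WC] * 20, mirna_seq="ACGUACGUACGUACGUACGUA")
        vals = pairwise_features(dup)
        # A,C -> 4*0+1+1 = 2; C,G -> 4*1+2+1 = 7; G,U -> 4*2+3+1 = 12;
        # U,A -> 4*3+0+1 = 13
        assert vals[20:24] == [2.0, 7.0, 12.0, 13.0]

    def test_status_dimer_mode(self):
        dup = make_duplex([WC, GU] + [MISMATCH] * 18)
        vals = pairwise_features(dup, dimer_mode="status")
        assert vals[20] == 4 * (1 - 1) + 2  # (WC, GU) -> 2

    def test_codes_in_range(self, tiny_corpus):
        mirnas, utrs, _, _ = tiny_corpus
        mirna = mirnas[0]
        for utr in utrs[:4]:
            for site in scan_sites(mirna, utr):
                dup = fold_duplex(mirna, utr, site)
                vals = pairwise_features(dup)
                assert len(vals) == 39
                assert all(1 <= v <= 4 for v in vals[:20])
                assert all(1 <= v <= 16 for v in vals[20:])


class TestRegionalFeatures:
    def test_perfect_duplex(self):
        dup = make_duplex([WC] * 20)
        vals = regional_features(dup)
        assert len(vals) == 18
        # per region: wc, gu, mismatch, gap, bulge_count, bulged_nt
        assert vals[0:6] == [8, 0, 0, 0, 0, 0]
        assert vals[6:12] == [12, 0, 0, 0, 0, 0]
        assert vals[12:18] == [20, 0, 0, 0, 0, 0]

    def test_three_prime_bulge(self):
        dup = make_duplex([WC] * 20,
                          bulges={"seed": (0, 0), "three_prime": (1, 2),
                                  "total": (1, 2)})
        vals = regional_features(dup)
        assert vals[10:12] == [1, 2]
        assert vals[16:18] == [1, 2]

    def test_region_sums(self, tiny_corpus):
        mirnas, utrs, _, _ = tiny_corpus
        mirna = mirnas[0]
        for utr in utrs[:6]:
            for site in scan_sites(mirna, utr):
                vals = regional_features(fold_duplex(mirna, utr, site))
                for k in range(4):  # wc/gu/mismatch/gap conserve
                    assert vals[k] + vals[6 + k] == vals[12 + k]


class TestConservationFeatures:
    def _utr_site(self, cons):
        utr = UtrSeq(id="u", seq="A" * 40, cons=cons, has_cons=True)
        site = CandidateSite(utr_id="u", mirna_id="m", start=16, end=24,
                             rule_id=1)
        return utr, site

    def test_uniform_track(self):
        utr, site = self._utr_site(np.full(40, 0.8))
        assert conservation_features(site, utr) == pytest.approx([0.8] * 3)

    def test_elevated_seed(self):
        cons = np.full(40, 0.1)
        cons[16:24] = 0.95
        utr, site = self._utr_site(cons)
        seed, c5, c3 = conservation_features(site, utr)
        assert seed > c5 and seed > c3

    def test_hand_computed_toy(self):
        # seed region indices 16..23 hold 0.1 .. 0.8
        cons = np.zeros(40)
        cons[16:24] = np.arange(1, 9) / 10
        utr, site = self._utr_site(cons)
        seed, c5, c3 = conservation_features(site, utr)
        assert seed == pytest.approx(0.45)  # mean of .1-.8
        assert c5 == 0.0 and c3 == 0.0

    def test_absent_positions_count_zero(self):
        cons = np.full(12, 0.6)
        utr = UtrSeq(id="u", seq="A" * 12, cons=cons, has_cons=True)
        site = CandidateSite(utr_id="u", mirna_id="m", start=2, end=10,
                             rule_id=1)
        _, c5, c3 = conservation_features(site, utr)
        assert c5 == pytest.approx(2 * 0.6 / 10)  # r1, r2 real; r3..r10 off
        assert c3 == pytest.approx(2 * 0.6 / 10)  # q0, q-1 real


class TestContextFeatures:
    def _site_mid(self, seq):
        utr = UtrSeq(id="u", seq=seq)
        site = CandidateSite(utr_id="u", mirna_id="m", start=15, end=23,
                             rule_id=1)
        return utr, site

    def test_polya_contexts(self):
        utr, site = self._site_mid("A" * 40)
        vals = context_features(site, utr)
        assert len(vals) == 40
        comp, positional = vals[:20], vals[20:]
        assert comp[0] == 20          # A count over both 10-nt regions
        assert comp[4] == 18          # AA dimers: 9 per region
        assert sum(comp) == 20 + 18
        assert positional == [1.0] * 20

    def test_boundary_truncation(self):
        utr = UtrSeq(id="u", seq="A" * 12)
        site = CandidateSite(utr_id="u", mirna_id="m", start=0, end=8,
                             rule_id=1)
        vals = context_features(site, utr)
        comp, positional = vals[:20], vals[20:]
        assert comp[0] == 4           # only q0..q-3 exist
        assert positional[:10] == [0.0] * 10  # r-side absent
        assert positional[10:14] == [1.0] * 4
        assert positional[14:] == [0.0] * 6

    def test_au_separates_from_gc(self):
        au_utr, au_site = self._site_mid("AU" * 20)
        gc_utr, gc_site = self._site_mid("GC" * 20)
        au = context_features(au_site, au_utr)
        gc = context_features(gc_site, gc_utr)
        au_frac = (au[0] + au[3]) / 20
        gc_frac = (gc[0] + gc[3]) / 20
        assert au_frac == 1.0 and gc_frac == 0.0

    def test_literal_3p_span(self):
        utr, site = self._site_mid("A" * 40)
        vals = context_features(site, utr, literal_3p=True)
        assert len(vals) == 40
        assert vals[0] == 19  # 10 + 9 nt pooled
        assert vals[20:][19] == 0.0  # q-9 absent in the literal reading

    def test_frequency_mode(self):
        utr, site = self._site_mid("A" * 40)
        vals = context_features(site, utr, frequencies=True)
        assert vals[0] == pytest.approx(1.0)
        assert vals[4] == pytest.approx(1.0)


class TestLocationFeatures:
    def test_site_at_utr_start(self):
        utr = UtrSeq(id="u", seq="A" * 50)
        site = CandidateSite(utr_id="u", mirna_id="m", start=0, end=8,
                             rule_id=1)
        assert location_features(site, utr) == [0.0, 0.0, 0.0]

    def test_mid_utr(self):
        utr = UtrSeq(id="u", seq="A" * 1000)
        site = CandidateSite(utr_id="u", mirna_id="m", start=400, end=420,
                             rule_id=1)
        assert location_features(site, utr) == [400.0, 400.0, 0.4]

    def test_ratio_bounded(self, rng):
        utr = UtrSeq(id="u", seq="A" * 500)
        for _ in range(100):
            start = int(rng.integers(0, 492))
            site = CandidateSite(utr_id="u", mirna_id="m", start=start,
                                 end=start + 8, rule_id=1)
            _, _, ratio = location_features(site, utr)
            assert 0.0 <= ratio <= 0.5


class TestExtractSiteFeatures:
    def test_length_113_and_deterministic(self):
        mirna, utr, _ = make_perfect_pair()
        site = scan_sites(mirna, utr)[0]
        dup = fold_duplex(mirna, utr, site)
        acc = accessibility(utr, site, dup.e_total, window_pad=20)
        v1 = extract_site_features(site, utr, dup, acc)
        v2 = extract_site_features(site, utr, dup, acc)
        assert len(v1.values) == 113
        assert np.array_equal(v1.values, v2.values)

    def test_group_sizes_sum(self):
        assert sum(feat.SITE_GROUP_SIZES.values()) == 113
        assert sum(feat.UTR_GROUP_SIZES.values()) == 30

    def test_names_unique_and_stable(self):
        assert len(set(SITE_FEATURE_NAMES)) == 113
        assert len(set(UTR_FEATURE_NAMES)) == 30
        assert schema_hash() == schema_hash()

    def test_energy_passthrough(self):
        dup = make_duplex([WC] * 20)
        acc = AccessibilityResult(ddg=-2.5, window=(0, 50))
        vals = feat.energy_features(dup, acc)
        assert vals == [-5.0, -3.0, -8.5, -2.5]


class TestExtractUtrFeatures:
    def test_zero_candidates(self):
        utr = UtrSeq(id="u", seq="A" * 120)
        vec = extract_utr_features(utr, [], [])
        assert len(vec.values) == 30
        assert vec["utr_length"] == 120
        assert vec["n_potential"] == 0
        assert vec["top_score"] == NO_SCORE
        assert vec["total_positive_score"] == 0.0

    def test_single_positive_8mer_a1(self):
        mirna = MirnaSeq(id="m", seq="UGAGGUAGUAGGUUGUAUAGUU")
        seg = revcomp(mirna.seq[:8])  # p1 = U so q1 = A: 8mer-A1 holds
        utr = UtrSeq(id="u", seq="C" * 30 + seg + "C" * 30)
        site = make_site(utr, mirna, 30)
        vec = extract_utr_features(utr, [site], [1.2])
        assert vec["n_potential_8mer_a1"] == 1
        assert vec["n_positive_8mer_a1"] == 1
        assert vec["top_score_8mer_a1"] == pytest.approx(1.2)
        assert vec["top_score"] == pytest.approx(1.2)
        assert vec["n_positive"] == 1
        assert vec["n_potential_no_perfect_seed"] == 0

    def test_no_perfect_seed_category(self):
        mirna = MirnaSeq(id="m", seq="UGAGGUAGUAGGUUGUAUAGUU")
        # rule-2 style site with a G:U in the 6mer core
        utr = UtrSeq(id="u", seq="C" * 30 + "ACUGCCUCA" + "C" * 30)
        sites = scan_sites(mirna, utr)
        negless = [s for s in sites
                   if not any(seed_match_types(s, utr).values())]
        if negless:
            vec = extract_utr_features(utr, negless,
                                       [-0.5] * len(negless))
            assert vec["n_potential_no_perfect_seed"] >= 1
            assert vec["n_positive_no_perfect_seed"] == 0

    def test_window_max_brute_force(self, rng):
        """Two-pointer window maxima equal brute force over all 100-nt
        windows on random layouts."""
        for _ in range(100):
            L = int(rng.integers(120, 1200))
            n = int(rng.integers(0, 15))
            starts = sorted(rng.integers(0, L - 8, size=n).tolist())
            assert max_sites_in_window(starts, L) == \
                brute_force_window_max(starts, L)

    @given(st.lists(st.integers(0, 600), max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_window_max_brute_force_hypothesis(self, starts):
        L = 700
        assert max_sites_in_window(starts, L) == \
            brute_force_window_max(starts, L)

    def test_density_exact_ratio(self, tiny_corpus):
        mirnas, utrs, _, _ = tiny_corpus
        mirna = mirnas[0]
        utr = utrs[0]
        sites = scan_sites(mirna, utr)
        vec = extract_utr_features(utr, sites, [0.5] * len(sites))
        assert vec["potential_density"] == pytest.approx(
            len(sites) / len(utr))
        assert vec["positive_density"] == pytest.approx(
            len(sites) / len(utr))

    def test_mismatched_lengths(self):
        utr = UtrSeq(id="u", seq="A" * 50)
        with pytest.raises(ValueError):
            extract_utr_features(utr, [], [1.0])
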