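import math

import pytest
from hypothesis import given, settings, strategies as st

from rnapal.noneq import (
    NoneqParams,
    accessible_strong_palindromes,
    characteristic_time,
    homo_vs_hetero_noneq,
    noneq_binding_strength,
    palindromic_noneq_weight,
    survival_probability,
)
from rnapal.fold import region_pfree

from conftest import random_rna

EXACT = dict(pfree_mode="exact")


class TestSurvival:
    def test_at_threshold_is_inverse_e(self, params):
        p = NoneqParams(dG_star=-12.0)
        assert survival_probability(-12.0, p, params.kBT) == pytest.approx(
            math.exp(-1)
        )

    def test_limits(self, params):
        p = NoneqParams(dG_star=-12.0)
        assert survival_probability(-1e9, p, params.kBT) == pytest.approx(1.0)
        assert survival_probability(1e9, p, params.kBT) == 0.0

    def test_five_kbt_above_threshold(self, params):
        p = NoneqParams(dG_star=-10.0)
        got = survival_probability(-10.0 + 5 * params.kBT, p, params.kBT)
        assert got == pytest.approx(math.exp(-math.exp(5.0)), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=-30, max_value=10),
        st.floats(min_value=0.01, max_value=20),
    )
    def test_strictly_decreasing_in_binding_energy(self, dg, step):
        p = NoneqParams(dG_star=-12.0)
        kbt = 0.61633008
        s1 = survival_probability(dg, p, kbt)
        s2 = survival_probability(dg + step, p, kbt)
        assert 0.0 <= s2 <= s1 <= 1.0


class TestCharacteristicTime:
    def test_zero_threshold_gives_attempt_period(self):
        assert characteristic_time(NoneqParams(dG_star=0.0)) == pytest.approx(1e-7)

    def test_minus_twelve_is_about_half_a_minute(self, params):
        t = characteristic_time(NoneqParams(dG_star=-12.0), params.kBT)
        assert t == pytest.approx(math.exp(12.0 / params.kBT) / 1e7, rel=1e-12)
        assert 25 < t < 35

    def test_doubling_attempt_rate_halves_t_star(self, params):
        t1 = characteristic_time(NoneqParams(dG_star=-5.0, attempt_rate_k=1e7), params.kBT)
        t2 = characteristic_time(NoneqParams(dG_star=-5.0, attempt_rate_k=2e7), params.kBT)
        assert t1 == pytest.approx(2 * t2, rel=1e-12)


class TestNoneqBindingStrength:
    def test_pairless_pair_gives_sentinel(self, params):
        dg, contacts = noneq_binding_strength(
            "AAAAAAAA", "AAAAAAAA", NoneqParams(**EXACT), params
        )
        assert dg == math.inf
        assert contacts == []

    def test_weight_equals_contact_sum(self, params, rng):
        p = NoneqParams(dG_star=-6.0, **EXACT)
        for _ in range(5):
            s1, s2 = random_rna(rng, 30), random_rna(rng, 30)
            dg, contacts = noneq_binding_strength(s1, s2, p, params)
            w = sum(c.weight for c in contacts)
            if w == 0:
                assert dg == math.inf
            else:
                assert math.exp(-dg / params.kBT) == pytest.approx(w, rel=1e-12)

    def test_symmetry_in_arguments(self, params, rng):
        p = NoneqParams(dG_star=-6.0, **EXACT)
        s1, s2 = random_rna(rng, 25), random_rna(rng, 25)
        assert noneq_binding_strength(s1, s2, p, params)[0] == pytest.approx(
            noneq_binding_strength(s2, s1, p, params)[0], abs=1e-9
        )

    def test_single_contact_at_threshold_analytic(self, params):
        # AAAA vs UUUU: one contact, both molecules unstructured (pfree = 1);
        # choosing dG* equal to the contact energy makes the sum e^-1
        p0 = NoneqParams(dG_star=0.0, **EXACT)
        dg_ij = noneq_binding_strength("AAAA", "UUUU", p0, params)[1][0].region_pair.dG_ij
        p = NoneqParams(dG_star=dg_ij, **EXACT)
        dg, contacts = noneq_binding_strength("AAAA", "UUUU", p, params)
        assert len(contacts) == 1
        assert contacts[0].p_free_i == pytest.approx(1.0)
        assert dg == pytest.approx(params.kBT, abs=1e-9)

    def test_weight_monotone_in_dg_star_and_limits(self, params, rng):
        for _ in range(5):
            s1, s2 = random_rna(rng, 25), random_rna(rng, 25)
            weights = []
            contacts_ref = None
            for g_star in [-20.0, -10.0, 0.0, 10.0, 1e6]:
                dg, contacts = noneq_binding_strength(
                    s1, s2, NoneqParams(dG_star=g_star, **EXACT), params
                )
                contacts_ref = contacts
                weights.append(0.0 if dg == math.inf else math.exp(-dg / params.kBT))
            assert all(b >= a - 1e-15 for a, b in zip(weights, weights[1:]))
            # dG* -> +inf limit: all survivals -> 1
            limit = sum(c.p_free_i * c.p_free_j for c in contacts_ref)
            assert weights[-1] == pytest.approx(limit, rel=1e-9)


class TestPalindromicWeight:
    def test_palindrome_free_sequence_gives_zero(self, params):
        assert palindromic_noneq_weight("AAAAAAAA", NoneqParams(**EXACT), params) == 0.0

    def test_restricted_sum_bounded_by_full_self_sum(self, params, rng):
        p = NoneqParams(dG_star=-4.0, **EXACT)
        for _ in range(5):
            s = random_rna(rng, 30)
            wpal = palindromic_noneq_weight(s, p, params)
            dg11, _ = noneq_binding_strength(s, s, p, params)
            w11 = 0.0 if dg11 == math.inf else math.exp(-dg11 / params.kBT)
            assert wpal <= w11 + 1e-15

    def test_single_accessible_palindrome_at_threshold(self, params):
        # AUAU alone: its only palindrome is the whole molecule, fully free
        pal_dg = noneq_binding_strength(
            "AUAU", "AUAU", NoneqParams(dG_star=0.0, **EXACT), params
        )[1][0].region_pair.dG_ij
        w = palindromic_noneq_weight(
            "AUAU", NoneqParams(dG_star=pal_dg, **EXACT), params
        )
        assert w == pytest.approx(math.exp(-1), abs=1e-9)


class TestCensus:
    def test_palindrome_free_sequence(self, params):
        n, hits = accessible_strong_palindromes(
            "AAAAAAAA", dG_star=0.0, p=NoneqParams(**EXACT), params=params
        )
        assert n == 0 and hits == []

    def test_no_filter_returns_all_palindromes(self, params, rng):
        from rnapal.palindrome import find_palindromes

        s = random_rna(rng, 40)
        n, _ = accessible_strong_palindromes(
            s, dG_star=1e9, pfree_min=0.0, p=NoneqParams(**EXACT), params=params
        )
        assert n == len(find_palindromes(s, params=params))

    def test_buried_palindrome_fails_exposed_passes(self, params):
        # two GCGCGC arms zip into a strong stem (buried, pfree ~ 0) while
        # AUAU sits in an unstructured poly-A stretch (pfree >> 0.1)
        seq = "GCGCGC" + "AAAA" + "GCGCGC" + "AAAAA" + "AGCU" + "AAAAA"
        assert region_pfree(seq, (0, 6), params, mode="exact") < 0.1
        assert region_pfree(seq, (21, 4), params, mode="exact") >= 0.1
        n, hits = accessible_strong_palindromes(
            seq, dG_star=5.0, pfree_min=0.1, p=NoneqParams(**EXACT), params=params
        )
        assert n == 1
        assert hits[0][0].region == (21, 4)


class TestHomoVsHetero:
    def test_identical_sequences_exactly_zero(self, params, rng):
        s = random_rna(rng, 30)
        assert homo_vs_hetero_noneq(s, s, NoneqParams(**EXACT), params) == 0.0

    def test_compositional_recomputation(self, params, rng):
        p = NoneqParams(dG_star=-4.0, **EXACT)
        s1, s2 = random_rna(rng, 30), random_rna(rng, 30)
        g11 = noneq_binding_strength(s1, s1, p, params)[0]
        g22 = noneq_binding_strength(s2, s2, p, params)[0]
        g12 = noneq_binding_strength(s1, s2, p, params)[0]
        val = homo_vs_hetero_noneq(s1, s2, p, params)
        if all(map(math.isfinite, (g11, g22, g12))):
            assert val == pytest.approx(2 * g12 - g11 - g22, abs=1e-9)

    def test_inert_molecule_sentinel_rule(self, params):
        # poly-A is inert (no self or cross contacts with a GC-only partner):
        # the documented cancellation leaves minus the partner's self term
        p = NoneqParams(dG_star=0.0, **EXACT)
        partner = "GGGGCGCGCGCCCC"
        g22 = noneq_binding_strength(partner, partner, p, params)[0]
        assert math.isfinite(g22)
        val = homo_vs_hetero_noneq("AAAAAAAAAA", partner, p, params)
        assert val == pytest.approx(-g22, abs=1e-9)
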