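"""Unit and property tests of the per-cell estimators."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtnorm import (
    CountProfile,
    EmptyProfileError,
    FreqOfFreq,
    fit_loglog,
    freq_of_freq,
    gt_frequencies,
    missing_mass,
    ml_frequencies,
    sgt_fit,
    z_transform,
)
from gtnorm.errors import NeedsFallback
from gtnorm.sgt import UnreliableSlopeWarning

from conftest import make_profile, random_profile
from sgt_oracle import oracle_sgt, oracle_z_values


class TestFreqOfFreq:
    def test_direct_tally(self):
        fof = freq_of_freq(make_profile([2, 1, 1, 0]))
        assert list(fof.r) == [1, 2]
        assert list(fof.n_r) == [2, 1]
        assert fof.total == 4

    def test_single_count_value(self):
        fof = freq_of_freq(make_profile([5, 5, 5]))
        assert list(fof.r) == [5] and list(fof.n_r) == [3]
        assert fof.total == 15

    def test_empty_profile_rejected(self):
        with pytest.raises(EmptyProfileError):
            freq_of_freq(make_profile([0, 0]))

    def test_mass_identity_on_random_profiles(self, rng):
        for _ in range(50):
            p = random_profile(rng)
            fof = freq_of_freq(p)
            assert int(np.sum(fof.r * fof.n_r)) == p.total
            assert np.all(np.diff(fof.r) > 0)


class TestMlFrequencies:
    def test_simple_profile(self):
        f = ml_frequencies(make_profile([2, 1, 1, 0]))
        np.testing.assert_allclose(f.freqs, [0.5, 0.25, 0.25, 0.0])

    def test_single_gene(self):
        assert ml_frequencies(make_profile([7])).freqs[0] == 1.0

    def test_sums_to_one(self, rng):
        for _ in range(20):
            assert abs(ml_frequencies(random_profile(rng)).total_mass - 1) < 1e-12


class TestZTransform:
    @pytest.mark.parametrize(
        "r,n,expected",
        [
            ([1, 2, 4], [3, 2, 1], {1: 3.0, 2: 4 / 3, 4: 0.5}),
            ([1, 2], [2, 1], {1: 2.0, 2: 1.0}),
            ([5], [3], {5: 0.6}),
        ],
    )
    def test_hand_examples(self, r, n, expected):
        fof = FreqOfFreq(np.array(r), np.array(n), int(np.sum(np.array(r) * n)))
        assert dict(z_transform(fof)) == pytest.approx(expected)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(50):
            p = random_profile(rng)
            fof = freq_of_freq(p)
            ours = [z for _, z in z_transform(fof)]
            theirs = oracle_z_values([int(v) for v in fof.r], [int(v) for v in fof.n_r])
            np.testing.assert_allclose(ours, theirs, rtol=0, atol=1e-12)

    def test_adjacent_neighbors_recover_n_r(self):
        fof = FreqOfFreq(np.array([1, 2, 3]), np.array([4, 2, 1]), 11)
        z = dict(z_transform(fof))
        assert z[2] == 2.0  # both neighbors adjacent: Z == N_r


class TestFitLoglog:
    def test_two_point_exact_fit(self):
        a, b = fit_loglog([(1, 4.0), (2, 1.0)])
        assert b == pytest.approx(math.log(1 / 4) / math.log(2))
        assert a == pytest.approx(math.log(4))

    def test_flat_z_warns_unreliable(self):
        with pytest.warns(UnreliableSlopeWarning):
            a, b = fit_loglog([(1, 2.0), (2, 2.0), (3, 2.0)])
        assert b == pytest.approx(0.0)

    def test_single_point_needs_fallback(self):
        with pytest.raises(NeedsFallback):
            fit_loglog([(5, 0.6)])


class TestSgtFit:
    def test_rescaling_identity(self, rng):
        for _ in range(50):
            fof = freq_of_freq(random_profile(rng))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnreliableSlopeWarning)
                fit = sgt_fit(fof)
            observed = sum(
                int(n) * fit.per_count_prob[int(r)] for r, n in zip(fof.r, fof.n_r)
            )
            assert abs(observed + fit.missing_mass - 1.0) < 1e-10

    def test_single_distinct_count_falls_back_to_ml(self):
        fit = sgt_fit(freq_of_freq(make_profile([5, 5, 5])))
        assert fit.fallback_ml
        assert fit.per_count_prob[5] == pytest.approx(5 / 15)
        assert fit.missing_mass == 0.0

    def test_matches_oracle_on_reference_profile(self):
        # counts giving fof {(1,3),(2,2),(3,1)}, N = 10
        counts = [1, 1, 1, 2, 2, 3]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnreliableSlopeWarning)
            fit = sgt_fit(freq_of_freq(make_profile(counts)))
        probs, p0, a, b, switch, fallback = oracle_sgt(counts)
        assert not fallback and not fit.fallback_ml
        assert fit.missing_mass == pytest.approx(p0, abs=1e-15)
        assert fit.intercept == pytest.approx(a, abs=1e-12)
        assert fit.slope == pytest.approx(b, abs=1e-12)
        assert fit.switch_count == switch
        for r, p in probs.items():
            assert fit.per_count_prob[r] == pytest.approx(p, abs=1e-12)

    def test_oracle_equivalence_on_random_profiles(self, rng):
        """Implementation and independent scalar recipe agree to 1e-10."""
        checked = 0
        for _ in range(120):
            p = random_profile(rng, n_genes_max=50, total_max=500)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnreliableSlopeWarning)
                fit = sgt_fit(freq_of_freq(p))
            probs, p0, _, _, switch, fallback = oracle_sgt([int(c) for c in p.counts])
            assert fit.fallback_ml == fallback
            assert fit.missing_mass == pytest.approx(p0, abs=1e-10)
            if not fallback:
                assert fit.switch_count == switch
            assert set(fit.per_count_prob) == set(probs)
            for r, prob in probs.items():
                assert fit.per_count_prob[r] == pytest.approx(prob, abs=1e-10)
            checked += 1
        assert checked >= 100

    def test_monotone_probabilities_for_steep_slopes(self, rng):
        """p_r nondecreasing in r whenever the smoother slope b < -1."""
        seen = 0
        for _ in range(300):
            p = random_profile(rng, n_genes_max=60, total_max=300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnreliableSlopeWarning)
                fit = sgt_fit(freq_of_freq(p))
            if fit.fallback_ml or not fit.slope < -1:
                continue
            seen += 1
            rs = sorted(fit.per_count_prob)
            ps = [fit.per_count_prob[r] for r in rs]
            assert all(x > 0 for x in ps)
            assert all(b >= a - 1e-15 for a, b in zip(ps, ps[1:]))
        assert seen >= 10

    def test_lgt_variant_uses_pure_smoothed_ratios(self):
        counts = [1, 1, 1, 2, 2, 3]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnreliableSlopeWarning)
            fit = sgt_fit(freq_of_freq(make_profile(counts)), smoothing="lgt")
        b = fit.slope
        stars = {r: (r + 1) * ((r + 1) / r) ** b for r in (1, 2, 3)}
        denom = 3 * stars[1] + 2 * stars[2] + 1 * stars[3]
        for r in (1, 2, 3):
            expected = (1 - fit.missing_mass) * stars[r] / denom
            assert fit.per_count_prob[r] == pytest.approx(expected, abs=1e-12)


class TestGtFrequencies:
    def test_zero_counts_stay_exactly_zero(self, rng):
        for _ in range(20):
            p = random_profile(rng)
            f = gt_frequencies(p)
            assert np.all(f.freqs[p.counts == 0] == 0.0)
            assert np.all(f.freqs[p.counts > 0] > 0.0)

    def test_fallback_profile_equals_ml(self):
        p = make_profile([5, 5, 5])
        np.testing.assert_allclose(
            gt_frequencies(p).freqs, ml_frequencies(p).freqs, atol=1e-15
        )

    def test_per_gene_match_against_oracle(self):
        counts = [3, 2, 2, 1, 1, 1, 0, 0]
        p = make_profile(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnreliableSlopeWarning)
            f = gt_frequencies(p)
        probs, p0, *_ = oracle_sgt(counts)
        for c, est in zip(counts, f.freqs):
            assert est == pytest.approx(probs.get(c, 0.0), abs=1e-12)
        assert f.total_mass == pytest.approx(1 - p0, abs=1e-10)

    def test_gt_mass_below_ml_mass_with_singletons(self, rng):
        """GT shrinks singleton genes: total mass 1 - P0 <= 1."""
        found = 0
        for _ in range(100):
            p = random_profile(rng, total_max=60)
            p0 = missing_mass(p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UnreliableSlopeWarning)
                gt = gt_frequencies(p)
            if gt.freqs.sum() > 0 and not sgt_fit(freq_of_freq(p)).fallback_ml:
                assert gt.total_mass == pytest.approx(1 - p0, abs=1e-10)
            ml = ml_frequencies(p)
            if p0 >= 0.3 and not sgt_fit(freq_of_freq(p)).fallback_ml:
                singles = p.counts == 1
                if singles.any():
                    assert np.all(gt.freqs[singles] < ml.freqs[singles])
                    found += 1
        assert found >= 5

    def test_no_singletons_means_no_missing_mass(self):
        p = make_profile([2, 2, 3, 4, 4, 5])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnreliableSlopeWarning)
            gt = gt_frequencies(p)
        assert missing_mass(p) == 0.0
        assert gt.total_mass == pytest.approx(1.0, abs=1e-10)


class TestMissingMass:
    def test_singleton_fraction(self):
        assert missing_mass(make_profile([1, 1, 2])) == pytest.approx(0.5)

    def test_no_singletons(self):
        assert missing_mass(make_profile([2, 3, 2])) == 0.0

    def test_all_singletons_forces_fallback(self):
        p = make_profile([1, 1, 1, 1])
        assert missing_mass(p) == 1.0
        fit = sgt_fit(freq_of_freq(p))
        assert fit.fallback_ml and fit.missing_mass == 0.0
        assert gt_frequencies(p).total_mass == pytest.approx(1.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=40).filter(
        lambda c: sum(c) > 0
    )
)
def test_conservation_property(counts):
    """ML mass is exactly 1; GT observed mass plus P0 is exactly 1."""
    ids = np.array([f"g{i}" for i in range(len(counts))], dtype=object)
    p = CountProfile(gene_ids=ids, counts=np.array(counts, dtype=np.int64))
    assert abs(ml_frequencies(p).total_mass - 1.0) < 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnreliableSlopeWarning)
        fit = sgt_fit(freq_of_freq(p))
        gt = gt_frequencies(p)
    assert abs(gt.total_mass + fit.missing_mass - 1.0) < 1e-10
    assert np.all(gt.freqs[np.array(counts) == 0] == 0.0)
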