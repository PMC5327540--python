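import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from eyeshine.circular import (
    LayerMeasurement,
    SectionMean,
    SectionSample,
    TorsionFit,
    axial_transform,
    circular_sd,
    fit_torsion,
    section_mean,
    summarize_group,
    unwrap_means,
    weighted_circular_mean,
)


def brute_force_axial(angles):
    """Minimal spread achievable by per-angle +/-180 shifts (oracle)."""
    reduced = np.mod(np.asarray(angles, float), 180.0)
    best = math.inf
    for shifts in itertools.product([0.0, 180.0], repeat=len(reduced)):
        cand = reduced + np.array(shifts)
        best = min(best, cand.max() - cand.min())
    return best


def layers(*pairs):
    return [LayerMeasurement(a, l) for a, l in pairs]


class TestAxialTransform:
    def test_wrapped_pair(self):
        out = axial_transform([170.0, 10.0])
        np.testing.assert_allclose(sorted(out), [170.0, 190.0])
        assert out.max() - out.min() == pytest.approx(20.0)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(axial_transform([42.0, 42.0, 42.0]), 42.0)

    def test_tie_broken_to_smallest_nonneg_mean(self):
        # {0, 90}: both cuts give spread 90; tie -> mean 45 beats mean 135
        out = axial_transform([0.0, 90.0])
        np.testing.assert_allclose(sorted(out), [0.0, 90.0])

    def test_outputs_equivalent_mod_180(self, rng):
        angles = rng.uniform(0, 360, 10)
        out = axial_transform(angles)
        d = np.mod(out - angles, 180.0)
        np.testing.assert_allclose(np.minimum(d, 180.0 - d), 0.0, atol=1e-9)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 13))
            angles = rng.uniform(0, 360, n)
            out = axial_transform(angles)
            spread = out.max() - out.min()
            assert spread == pytest.approx(brute_force_axial(angles), abs=1e-9)

    def test_spread_not_larger_than_input(self, rng):
        for _ in range(50):
            angles = rng.uniform(0, 360, 6)
            out = axial_transform(angles)
            assert out.max() - out.min() <= angles.max() - angles.min() + 1e-9

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            axial_transform([])


class TestWeightedCircularMean:
    def test_single_layer(self):
        assert weighted_circular_mean(layers((37.0, 50.0))) == pytest.approx(37.0)

    def test_equal_weights_bisect(self):
        got = weighted_circular_mean(layers((30.0, 10.0), (90.0, 10.0)))
        assert got == pytest.approx(60.0)

    def test_vector_sum_oracle(self, rng):
        angs = rng.uniform(0, 360, 7)
        lens = rng.uniform(30, 60, 7)
        w = lens / lens.sum()
        s = np.sum(np.sin(np.radians(angs)) * w)
        c = np.sum(np.cos(np.radians(angs)) * w)
        expected = math.degrees(math.atan2(s, c)) % 360
        got = weighted_circular_mean(layers(*zip(angs, lens)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_weight_degeneracy_limit(self):
        got = weighted_circular_mean(layers((10.0, 5.0), (200.0, 1e-9)))
        assert got == pytest.approx(10.0, abs=1e-6)

    def test_antipodal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            weighted_circular_mean(layers((0.0, 1.0), (180.0, 1.0)))

    @given(shift=st.integers(-2, 2), scale=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_invariance_360_and_length_scaling(self, shift, scale):
        base = layers((20.0, 40.0), (70.0, 55.0), (110.0, 35.0))
        moved = layers(
            (20.0 + 360 * shift, 40.0 * scale),
            (70.0, 55.0 * scale),
            (110.0, 35.0 * scale),
        )
        assert weighted_circular_mean(base) == pytest.approx(
            weighted_circular_mean(moved), abs=1e-9
        )

    def test_equal_weights_match_unweighted_oracle(self, rng):
        angs = rng.uniform(0, 120, 9)
        got = weighted_circular_mean(layers(*((a, 42.0) for a in angs)))
        expected = math.degrees(ss.circmean(np.radians(angs)))
        assert got % 360 == pytest.approx(expected % 360, abs=1e-7)


class TestCircularSd:
    def test_identical_angles_zero(self):
        assert circular_sd(layers((50.0, 1.0), (50.0, 9.0))) == pytest.approx(0.0)

    def test_closed_form_pair(self):
        # equal-weight 30/90: R = cos(30 deg), v = sqrt(-2 ln R)
        v = circular_sd(layers((30.0, 1.0), (90.0, 1.0)))
        r = math.cos(math.radians(30))
        assert r == pytest.approx(0.8660, abs=1e-4)
        expected = math.degrees(math.sqrt(-2 * math.log(r)))
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(30.7, abs=0.05)

    def test_antipodal_flagged_nan(self):
        assert math.isnan(circular_sd(layers((0.0, 1.0), (180.0, 1.0))))

    def test_resultant_in_unit_interval(self, rng):
        from eyeshine.circular import resultant_length

        for _ in range(50):
            angs = rng.uniform(0, 360, 8)
            lens = rng.uniform(30, 60, 8)
            r = resultant_length(layers(*zip(angs, lens)))
            assert 0.0 <= r <= 1.0


class TestSectionMean:
    def test_single_layer(self):
        m = section_mean(SectionSample(0.1, layers((77.0, 40.0))))
        assert m.mean_angle == pytest.approx(77.0)
        assert m.circular_sd == pytest.approx(0.0)

    def test_axial_pair_means_to_180(self):
        m = section_mean(SectionSample(0.0, layers((170.0, 40.0), (10.0, 40.0))))
        assert m.mean_angle == pytest.approx(180.0)

    def test_synthetic_noise_recovery(self, rng):
        truth = 63.0
        angs = truth + rng.normal(0, 8, 400)
        m = section_mean(SectionSample(0.0, layers(*((a % 360, 40.0) for a in angs))))
        # allow the axial representative 63 or 243
        delta = min(abs(m.mean_angle - truth), abs(m.mean_angle - truth - 180))
        assert delta < 2.0

    def test_axial_off_uses_raw_angles(self):
        m = section_mean(
            SectionSample(0.0, layers((350.0, 40.0), (10.0, 40.0))), axial=False
        )
        assert m.mean_angle == pytest.approx(0.0, abs=1e-9)


class TestUnwrapMeans:
    @staticmethod
    def means(pairs):
        return [SectionMean(d, a, 0.0, 1.0) for d, a in pairs]

    def test_gentle_series_unchanged(self):
        ms = self.means([(0.0, 10.0), (0.1, 25.0), (0.2, 40.0)])
        out = unwrap_means(ms)
        assert [m.mean_angle for m in out] == [10.0, 25.0, 40.0]

    def test_hand_worked_example(self):
        ms = self.means([(0.0, 10.0), (0.1, 175.0), (0.2, 350.0)])
        out = unwrap_means(ms)
        assert [m.mean_angle for m in out] == pytest.approx([10.0, -5.0, -10.0])

    def test_constant_series_unchanged(self):
        ms = self.means([(0.0, 90.0), (0.1, 90.0)])
        assert [m.mean_angle for m in unwrap_means(ms)] == [90.0, 90.0]

    def test_tie_prefers_smaller_shift(self):
        ms = self.means([(0.0, 0.0), (0.1, 90.0)])
        assert [m.mean_angle for m in unwrap_means(ms)] == [0.0, 90.0]

    def test_successive_steps_bounded(self, rng):
        pairs = [(i * 0.05, float(a)) for i, a in enumerate(rng.uniform(0, 360, 15))]
        out = unwrap_means(self.means(pairs))
        diffs = np.diff([m.mean_angle for m in out])
        assert np.all(np.abs(diffs) <= 90.0 + 1e-9)

    def test_requires_increasing_distances(self):
        with pytest.raises(ValueError, match="increasing"):
            unwrap_means(self.means([(0.2, 0.0), (0.1, 10.0)]))


class TestFitTorsion:
    @staticmethod
    def line_means(intercept, slope, xs):
        return [SectionMean(x, intercept + slope * x, 0.0, 1.0) for x in xs]

    def test_noiseless_line_recovered(self):
        xs = np.linspace(0, 0.81, 15)
        fit = fit_torsion(self.line_means(19.3, 93.4, xs))
        assert fit.starting_angle == pytest.approx(19.3, abs=1e-9)
        assert fit.torsion_rate == pytest.approx(93.4, abs=1e-8)
        assert not fit.slope_zeroed and not fit.intercept_zeroed
        assert fit.total_torsion == pytest.approx(93.4 * 0.81, abs=1e-6)

    def test_matches_linregress_oracle(self, rng):
        xs = np.sort(rng.uniform(0, 1, 12))
        ys = 15 + 80 * xs + rng.normal(0, 5, 12)
        fit = fit_torsion(
            [SectionMean(x, y, 0.0, 1.0) for x, y in zip(xs, ys)], alpha=None
        )
        ref = ss.linregress(xs, ys)
        assert fit.torsion_rate == pytest.approx(ref.slope, rel=1e-9)
        assert fit.starting_angle == pytest.approx(ref.intercept, rel=1e-9)

    def test_slope_pvalue_matches_linregress(self, rng):
        xs = np.sort(rng.uniform(0, 1, 10))
        ys = 5 + rng.normal(0, 10, 10)
        fit = fit_torsion(
            [SectionMean(x, y, 0.0, 1.0) for x, y in zip(xs, ys)], alpha=1e-12
        )
        ref = ss.linregress(xs, ys)
        assert fit.slope_p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_flat_noisy_slope_zeroed(self, rng):
        xs = np.linspace(0, 1, 15)
        ys = 45.0 + rng.normal(0, 3, 15)
        fit = fit_torsion([SectionMean(x, y, 0.0, 1.0) for x, y in zip(xs, ys)])
        assert fit.slope_zeroed
        assert fit.torsion_rate == 0.0
        assert fit.total_torsion == 0.0

    def test_two_points_no_test(self):
        fit = fit_torsion(self.line_means(10.0, 50.0, [0.0, 0.5]))
        assert fit.torsion_rate == pytest.approx(50.0)
        assert not fit.slope_zeroed and not fit.intercept_zeroed
        assert math.isnan(fit.slope_p)

    def test_single_section_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_torsion(self.line_means(0, 0, [0.0]))

    def test_explicit_nerve_length(self):
        xs = np.linspace(0.1, 0.9, 10)
        fit = fit_torsion(self.line_means(0.0, 100.0, xs), nerve_length=0.96)
        assert fit.total_torsion == pytest.approx(96.0, abs=1e-6)


class TestSummarizeGroup:
    @staticmethod
    def fit(length, start, rate):
        return TorsionFit(start, rate, length, abs(rate) * length)

    def test_single_fit(self):
        s = summarize_group([self.fit(0.96, 12.5, 78.7)])
        assert s.n == 1
        assert s.torsion_rate[0] == pytest.approx(78.7)
        assert math.isnan(s.torsion_rate[1])

    def test_total_torsion_consistency_printed_row(self):
        # single-individual genus row: 78.7 deg/mm over 0.96 mm
        s = summarize_group([self.fit(0.96, 12.5, 78.7)])
        assert s.total_torsion[0] == pytest.approx(75.7, abs=0.2)

    def test_two_identical_fits(self):
        f = self.fit(0.8, 20.0, 90.0)
        s = summarize_group([f, f])
        assert s.torsion_rate == (pytest.approx(90.0), pytest.approx(0.0))

    def test_mean_sd_closed_form(self):
        s = summarize_group([self.fit(0.6, 0, 60.0), self.fit(0.8, 0, 80.0)])
        assert s.torsion_rate[0] == pytest.approx(70.0)
        assert s.torsion_rate[1] == pytest.approx(np.std([60, 80], ddof=1))

    def test_per_individual_averaging(self):
        fits = [self.fit(0.8, 0, 60.0), self.fit(0.8, 0, 80.0), self.fit(0.8, 0, 100.0)]
        s = summarize_group(fits, individuals=["a", "a", "b"])
        assert s.n == 2
        assert s.torsion_rate[0] == pytest.approx((70.0 + 100.0) / 2)
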