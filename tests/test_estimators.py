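import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from lifebias.estimators import (
    KMCurve,
    complete_mean,
    complete_median,
    km_fit,
    km_median,
    sample_median,
)
from lifebias.sampling import SurvivalSample, assign_weights


def make_sample(times, events, weights=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if weights is None:
        weights = np.ones_like(times)
    return SurvivalSample(times, events, np.asarray(weights, dtype=float))


def random_censored_sample(rng):
    n = int(rng.integers(5, 60))
    times = rng.weibull(1.3, n) * 25.0 + 1e-3
    censor = rng.uniform(0, 40, n)
    observed = np.minimum(times, censor)
    events = times <= censor
    if not events.any():  # ensure at least one event
        events[np.argmax(times)] = True
        observed[np.argmax(times)] = times[np.argmax(times)]
    return make_sample(observed, events)


class TestCompleteStatistics:
    def test_mean(self):
        assert complete_mean([10, 20, 30]) == pytest.approx(20.0)
        assert complete_mean([25.3]) == pytest.approx(25.3)
        assert complete_mean([]) is None

    def test_sample_median_order_statistic_convention(self):
        assert sample_median([10, 20, 30]) == 20
        assert sample_median([10, 20, 30, 40]) == 20  # no midpoint interpolation
        assert sample_median([]) is None

    def test_complete_median_midpoint_convention(self):
        assert complete_median([10, 20, 30]) == 20
        assert complete_median([10, 20, 30, 40]) == 25
        assert complete_median([]) is None

    def test_sample_mean_of_many_draws_matches_target(self, rng):
        draws = 27.4681 * rng.weibull(1.3181, 100_000)
        assert complete_mean(draws) == pytest.approx(25.3, abs=3 * 19.4 / np.sqrt(1e5))


class TestKMFit:
    def test_uncensored_hand_computation(self):
        c = km_fit(make_sample([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(c.times, [1, 2, 3])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_censored_hand_computation(self):
        c = km_fit(make_sample([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(c.times, [1, 3])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])

    def test_weighted_hand_computation(self):
        # censored record at 2 contributes only 0.1 to the risk set at t=1
        c = km_fit(make_sample([1, 2, 3], [1, 0, 1], [1, 0.1, 1]))
        np.testing.assert_allclose(c.times, [1, 3])
        np.testing.assert_allclose(c.survival, [1 - 1 / 2.1, 0.0])

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            km_fit(make_sample([1, 2], [0, 0]))

    def test_no_censoring_curve_is_one_minus_ecdf(self, rng):
        x = rng.exponential(10, 41)
        c = km_fit(make_sample(x, np.ones_like(x)))
        xs = np.sort(x)
        np.testing.assert_allclose(
            c.survival, 1.0 - np.arange(1, x.size + 1) / x.size, atol=1e-12
        )
        np.testing.assert_allclose(c.times, xs)

    def test_unit_weights_match_lifelines_reference(self, rng):
        """Independent oracle: 100 random censored samples vs lifelines."""
        for _ in range(100):
            s = random_censored_sample(rng)
            c = km_fit(s)
            kmf = KaplanMeierFitter().fit(s.times, s.events)
            ref = kmf.survival_function_at_times(c.times).to_numpy()
            np.testing.assert_allclose(c.survival, ref, atol=1e-10)
            ref_med = kmf.median_survival_time_
            ours = km_median(c)
            if np.isinf(ref_med):
                assert ours is None
            else:
                assert ours == pytest.approx(ref_med, abs=1e-10)

    def test_vanishing_censor_weight_approaches_events_only_curve(self, rng):
        s = random_censored_sample(rng)
        tiny = make_sample(s.times, s.events, np.where(s.events, 1.0, 1e-9))
        events_only = km_fit(
            make_sample(s.times[s.events], np.ones(s.n_events))
        )
        c = km_fit(tiny)
        np.testing.assert_allclose(c.survival, events_only.survival, atol=1e-6)


class TestKMMedian:
    def test_definition_cases(self):
        assert km_median(KMCurve([1, 5, 8], [0.9, 0.5, 0.2])) == 5
        assert km_median(KMCurve([1, 5], [0.9, 0.7])) is None
        assert km_median(km_fit(make_sample([1, 2, 3], [1, 1, 1]))) == 2

    def test_median_is_an_event_time(self, rng):
        for _ in range(20):
            s = random_censored_sample(rng)
            m = km_median(km_fit(s))
            if m is not None:
                assert m in s.times[s.events]

    def test_equals_sample_median_on_uncensored_data(self, rng):
        for n in (1, 2, 5, 10, 36, 37):
            x = rng.exponential(20, n)
            all_events = make_sample(x, np.ones(n))
            assert km_median(km_fit(all_events)) == pytest.approx(
                sample_median(x), abs=1e-12
            )

    def test_monotone_in_censor_weight(self, rng):
        """Larger censored weight slows the curve's descent: median grows."""
        grid = [0.02, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0]
        for _ in range(30):
            s = random_censored_sample(rng)
            meds = [
                km_median(km_fit(assign_weights(s, "fixed", w=w))) for w in grid
            ]
            defined = [m for m in meds if m is not None]
            assert all(b >= a - 1e-12 for a, b in zip(defined, defined[1:]))
            # once the median becomes unreachable it stays unreachable
            flags = [m is None for m in meds]
            assert flags == sorted(flags)


def test_curve_validation():
    with pytest.raises(ValueError):
        KMCurve([2, 1], [0.5, 0.4])  # times not increasing
    with pytest.raises(ValueError):
        KMCurve([1, 2], [0.4, 0.6])  # survival increasing
    with pytest.raises(ValueError):
        KMCurve([1], [1.5])  # out of range
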