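import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import phasor_mean_smooth, sample_power_law, scan_intervals

from plscan.errors import ArgumentError
from plscan.lockintervals import (
    IntervalSet,
    LockCriterion,
    extract_intervals,
    log_binned_distribution,
    phase_difference,
    pool_intervals,
    resolve_smoothing_window,
    smooth_circular,
)
from plscan.preprocess import BandSpec

FS = 600.0
NO_SMOOTH = LockCriterion(smoothing_window=0)


def crit(**kw):
    kw.setdefault("smoothing_window", 0)
    return LockCriterion(**kw)


class TestPhaseDifference:
    def test_plain_subtraction(self):
        assert phase_difference(np.array([0.1]), np.array([0.2]))[0] == pytest.approx(-0.1)

    def test_wrapping_convention(self):
        # 3.0 - (-3.0) = 6.0 -> 6.0 - 2*pi
        out = phase_difference(np.array([3.0]), np.array([-3.0]))
        assert out[0] == pytest.approx(6.0 - 2 * np.pi)  # ~ -0.28319

    def test_identity(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 100)
        assert np.allclose(phase_difference(phi, phi), 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            phase_difference(np.zeros(3), np.zeros(4))

    @given(st.lists(st.floats(-3.1, 3.1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_on_circle(self, vals):
        a = np.array(vals)
        b = a[::-1].copy()
        fwd = phase_difference(a, b)
        bwd = phase_difference(b, a)
        assert np.allclose(np.exp(1j * (fwd + bwd)), 1.0, atol=1e-9)


class TestSmoothCircular:
    def test_constant_preserved(self):
        out = smooth_circular(np.full(20, 1.3), 5)
        assert np.allclose(out, 1.3)

    def test_window_one_identity(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 50)
        assert np.allclose(smooth_circular(dphi, 1), dphi)

    def test_alternating_pattern_against_phasor_mean(self):
        # alternating +pi/2, -pi/2: the mean of (2 e^{+i pi/2} + e^{-i pi/2})/3
        # keeps the +-pi/2 pattern at reduced modulus
        dphi = np.tile([np.pi / 2, -np.pi / 2], 10)
        out = smooth_circular(dphi, 3)
        expected = phasor_mean_smooth(dphi, 3)
        assert np.allclose(out[1:-1], expected[1:-1], atol=1e-12)
        assert np.allclose(np.abs(out[1:-1]), np.pi / 2, atol=1e-12)

    def test_random_against_phasor_mean(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 101)
        for window in (3, 7, 15):
            assert np.allclose(smooth_circular(dphi, window),
                               phasor_mean_smooth(dphi, window), atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ArgumentError):
            smooth_circular(np.zeros(10), 4)


class TestExtractIntervals:
    def test_full_length_censored_run(self):
        dphi = np.zeros(600)
        out = extract_intervals(dphi, np.ones(600, bool), FS, NO_SMOOTH)
        assert len(out) == 1
        assert out.durations[0] == pytest.approx(1.0)
        assert out.censored[0]

    def test_alternating_unit_runs(self):
        dphi = np.tile([0.0, np.pi], 300)
        out = extract_intervals(dphi, np.ones(600, bool), FS, NO_SMOOTH)
        assert np.allclose(out.durations, 1.0 / FS)
        # interior runs are uncensored; the first touches the record edge
        assert out.censored[0]
        assert not out.censored[1:-1].any()

    def test_matches_oracle_on_seeded_random(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            dphi = rng.uniform(-np.pi, np.pi, n)
            valid = rng.uniform(size=n) < 0.8
            c = crit(threshold=float(rng.uniform(0.2, 3.0)),
                     min_duration=int(rng.integers(1, 4)),
                     include_censored=bool(rng.integers(0, 2)))
            got = extract_intervals(dphi, valid, FS, c)
            expected = scan_intervals(dphi, valid, FS, c.threshold,
                                      c.min_duration, c.include_censored)
            assert [(d, bool(f)) for d, f in zip(got.durations, got.censored)] \
                == [(d, c_) for d, c_ in expected]

    def test_all_invalid_gives_empty_set(self):
        out = extract_intervals(np.zeros(100), np.zeros(100, bool), FS, NO_SMOOTH)
        assert len(out) == 0
        assert out.n_samples_valid == 0

    def test_conservation_of_locked_samples(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 5000)
        valid = rng.uniform(size=5000) < 0.9
        out = extract_intervals(dphi, valid, FS, NO_SMOOTH)
        locked = (np.abs(dphi) < NO_SMOOTH.threshold) & valid
        assert int(round(out.durations.sum() * FS)) == locked.sum()
        assert out.n_locked_samples == locked.sum()

    def test_validity_gap_censors_abutting_runs(self):
        dphi = np.zeros(10)
        valid = np.ones(10, bool)
        valid[5] = False
        out = extract_intervals(dphi, valid, FS, NO_SMOOTH)
        assert len(out) == 2
        assert out.censored.all()  # both runs touch the gap and a record edge

    def test_interior_uncensored_run(self):
        dphi = np.array([np.pi, np.pi, 0.0, 0.0, 0.0, np.pi, np.pi])
        out = extract_intervals(dphi, np.ones(7, bool), FS, NO_SMOOTH)
        assert len(out) == 1
        assert not out.censored[0]
        assert out.durations[0] == pytest.approx(3 / FS)

    def test_min_duration_filter(self):
        dphi = np.array([np.pi, 0.0, np.pi, 0.0, 0.0, np.pi])
        out = extract_intervals(dphi, np.ones(6, bool), FS, crit(min_duration=2))
        assert len(out) == 1
        assert out.durations[0] == pytest.approx(2 / FS)

    def test_unresolved_auto_smoothing_rejected(self):
        with pytest.raises(ArgumentError):
            extract_intervals(np.zeros(10), np.ones(10, bool), FS, LockCriterion())

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        dphi = rng.uniform(-np.pi, np.pi, n)
        valid = rng.uniform(size=n) < 0.85
        totals = []
        for thr in (0.3, 0.8, 1.5, 2.5, 3.0):
            out = extract_intervals(dphi, valid, FS, crit(threshold=thr))
            totals.append(out.n_locked_samples)
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    @given(st.integers(0, 2**32 - 1), st.integers(5, 300))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, seed, n):
        rng = np.random.default_rng(seed)
        dphi = rng.uniform(-np.pi, np.pi, n)
        valid = rng.uniform(size=n) < 0.7
        got = extract_intervals(dphi, valid, FS, NO_SMOOTH)
        expected = scan_intervals(dphi, valid, FS, NO_SMOOTH.threshold)
        assert [(d, bool(f)) for d, f in zip(got.durations, got.censored)] == expected


class TestCriterionValidation:
    @pytest.mark.parametrize("kw", [
        {"threshold": 0.0}, {"threshold": np.pi}, {"threshold": 4.0},
        {"min_duration": 0}, {"smoothing_window": -1},
        {"smoothing_window": "sometimes"},
    ])
    def test_rejects(self, kw):
        with pytest.raises(ArgumentError):
            LockCriterion(**kw)

    def test_auto_resolution(self):
        band = BandSpec("gamma", 35.0, 70.0)
        c = LockCriterion()
        assert resolve_smoothing_window(c, "wavelet", 600.0, band) == 0
        w = resolve_smoothing_window(c, "hilbert", 600.0, band)
        assert w % 2 == 1
        assert w == pytest.approx(600.0 / band.center, abs=1.5)
        assert resolve_smoothing_window(crit(smoothing_window=7), "hilbert",
                                        600.0, band) == 7


def _iset(durs, cens=None, band=None, pair=None):
    durs = np.asarray(durs, float)
    cens = np.zeros(len(durs), bool) if cens is None else np.asarray(cens, bool)
    return IntervalSet(durations=durs, censored=cens, pair=pair, band=band,
                       n_samples_valid=1000, n_locked_samples=int(durs.sum() * FS))


class TestPooling:
    BAND = BandSpec("alpha", 8.0, 17.5)

    def test_single_set_identity(self):
        s = _iset([0.1, 0.2], band=self.BAND)
        pooled = pool_intervals([s], by="band")
        assert np.array_equal(pooled.durations, s.durations)

    def test_concatenation_size(self):
        a = _iset([0.1, 0.2, 0.3], band=self.BAND, pair=("x", "y"))
        b = _iset([0.4, 0.5, 0.6, 0.7], band=self.BAND, pair=("x", "z"))
        pooled = pool_intervals([a, b], by="band")
        assert len(pooled) == 7
        assert pooled.sources == [("x", "y"), ("x", "z")]

    def test_pooled_mean_is_weighted_mean(self):
        a = _iset([0.1, 0.2, 0.3], band=self.BAND)
        b = _iset([1.0, 2.0], band=self.BAND)
        pooled = pool_intervals([a, b], by="band")
        expected = (3 * a.durations.mean() + 2 * b.durations.mean()) / 5
        assert pooled.durations.mean() == pytest.approx(expected)

    def test_mixed_bands_rejected(self):
        a = _iset([0.1], band=self.BAND)
        b = _iset([0.2], band=BandSpec("beta", 17.5, 35.0))
        with pytest.raises(ArgumentError):
            pool_intervals([a, b], by="band")

    def test_pool_by_pair(self):
        a = _iset([0.1], band=self.BAND, pair=("x", "y"))
        b = _iset([0.2], band=BandSpec("beta", 17.5, 35.0), pair=("x", "y"))
        pooled = pool_intervals([a, b], by="pair")
        assert pooled.pair == ("x", "y")
        with pytest.raises(ArgumentError):
            pool_intervals([a, _iset([0.3], band=self.BAND, pair=("x", "z"))],
                           by="pair")


class TestLogBinnedDistribution:
    def test_equal_durations_single_bin(self):
        dist = log_binned_distribution(_iset([0.25] * 10))
        assert len(dist.density) == 1
        assert dist.counts[0] == 10
        assert np.sum(dist.density * np.diff(dist.edges)) == pytest.approx(1.0)

    def test_normalization(self, rng):
        durs = rng.lognormal(-2.0, 1.0, 5000)
        dist = log_binned_distribution(_iset(durs))
        assert np.sum(dist.density * np.diff(dist.edges)) == pytest.approx(1.0, abs=1e-9)
        assert dist.n == 5000
        assert dist.mean_duration == pytest.approx(durs.mean())

    def test_power_law_slope_recovered(self):
        # simulation against a known generator: slope of log density ~ -alpha
        rng = np.random.default_rng(99)
        alpha = 2.0
        durs = sample_power_law(rng, 10**4, alpha, xmin=0.01)
        dist = log_binned_distribution(_iset(durs), bins_per_decade=10)
        centers = dist.centers()
        mask = dist.counts >= 10
        slope = np.polyfit(np.log10(centers[mask]), np.log10(dist.density[mask]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.15)

    def test_empty_set_flagged(self):
        dist = log_binned_distribution(_iset([]))
        assert dist.empty
        assert dist.n == 0

    def test_bad_bins(self):
        with pytest.raises(ArgumentError):
            log_binned_distribution(_iset([0.1]), bins_per_decade=0)
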