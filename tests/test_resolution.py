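"""Power-law trend fit, noise floor, knee/resolution frequencies, Wiener filter."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xrfres import (
    ElementalMap,
    FitRange,
    InsufficientDataError,
    NoiseFloor,
    NoKneeError,
    PowerLawFit,
    azimuthal_average,
    estimate_noise_floor,
    fit_signal_trend,
    knee_frequency,
    map_psd,
    resolution_frequency,
    sensitivity_scan,
    wiener_filter,
)
from xrfres.psd import RadialPSD
from xrfres.synthetic import make_powerlaw_psd


def _psd(u, s, n=None):
    u = np.asarray(u, float)
    s = np.asarray(s, float)
    if n is None:
        n = np.ones_like(u, dtype=int)
    return RadialPSD(u_r=u, S=s, n=n)


class TestFitSignalTrend:
    def test_noiseless_power_law_exact(self):
        u = np.array([0.1, 0.2, 0.4])
        fit = fit_signal_trend(_psd(u, 3.0 * u**-2), FitRange(0.05, 0.5))
        assert fit.a == pytest.approx(-2.0, abs=1e-12)
        assert fit.P == pytest.approx(3.0, rel=1e-12)
        assert fit.valid and fit.n_points == 3

    def test_constant_psd_flagged_invalid(self):
        u = np.array([0.1, 0.2, 0.4])
        with pytest.warns(UserWarning, match="non-negative"):
            fit = fit_signal_trend(_psd(u, np.full(3, 2.5)), FitRange(0.05, 0.5))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.P == pytest.approx(2.5, rel=1e-12)
        assert not fit.valid

    def test_matches_normal_equations_oracle(self, rng):
        """OLS in log-log space agrees with an independent normal-equations
        solve on scattered power-law data."""
        u = np.geomspace(0.05, 1.0, 20)
        eps = rng.uniform(-0.05, 0.05, 20)
        s = 7.0 * u**-3.4 * 10.0**eps
        fit = fit_signal_trend(_psd(u, s), FitRange(0.01, 2.0))
        # normal equations for y = b0 + b1 x
        x, y = np.log10(u), np.log10(s)
        A = np.column_stack([np.ones_like(x), x])
        b0, b1 = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.a == pytest.approx(b1, abs=1e-10)
        assert np.log10(fit.P) == pytest.approx(b0, abs=1e-10)

    def test_nonpositive_bins_excluded_with_warning(self):
        u = np.array([0.1, 0.2, 0.3, 0.4])
        s = np.array([1.0, -0.5, 0.25, 0.0625])  # exact u^-2 except the bad bin
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_signal_trend(_psd(u * 10, s), FitRange(0.5, 5.0))
        assert fit.n_points == 3

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_signal_trend(_psd([0.1, 0.2], [1.0, 0.5]), FitRange(0.05, 0.15))


class TestNoiseFloor:
    def test_arithmetic_mean(self):
        floor = estimate_noise_floor(
            _psd([1.0, 1.1, 1.2], [1.0, 1.2, 0.8]), FitRange(0.5, 2.0)
        )
        assert floor.S_nf == pytest.approx(1.0)
        assert floor.n_points == 3

    def test_single_bin(self):
        floor = estimate_noise_floor(_psd([1.0], [0.37]), FitRange(0.5, 2.0))
        assert floor.S_nf == pytest.approx(0.37)

    def test_empty_range_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_noise_floor(_psd([1.0], [0.37]), FitRange(2.0, 3.0))

    def test_white_noise_floor_matches_full_grid_mean(self, rng):
        """On a pure white-noise image the binned floor agrees with the mean
        of the full 2-D PSD computed directly (the flat-spectrum level)."""
        emap = ElementalMap(rng.standard_normal((64, 64)), 1, 1)
        from xrfres import pad_to_even, psd2d, signed_amplitude

        s2 = psd2d(signed_amplitude(pad_to_even(emap)))
        psd = azimuthal_average(s2, n_bins=16)
        floor = estimate_noise_floor(psd, FitRange(0.2, 0.6))
        full_mean = s2.values[s2.radial_grid() > 0].mean()
        assert floor.S_nf == pytest.approx(full_mean, rel=0.15)


class TestKneeAndResolution:
    def test_knee_closed_form_examples(self):
        rng_fit = FitRange(0.01, 1.0)
        fit = PowerLawFit(P=1.0, a=-2.0, range=rng_fit, n_points=5)
        floor = NoiseFloor(S_nf=1e-4, range=rng_fit, n_points=5)
        assert knee_frequency(fit, floor) == pytest.approx(100.0)
        fit2 = PowerLawFit(P=5.0, a=-1.0, range=rng_fit, n_points=5)
        floor2 = NoiseFloor(S_nf=5.0, range=FitRange(1.0, 2.0), n_points=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # knee at the fit-range edge
            assert knee_frequency(fit2, floor2) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        logp=st.floats(-3, 6),
        a=st.floats(-8, -0.5),
        log_ratio=st.floats(-8, -1),
    )
    def test_knee_is_root_of_trend_minus_floor(self, logp, a, log_ratio):
        P = 10.0**logp
        S_nf = P * 10.0**log_ratio
        fit = PowerLawFit(P=P, a=a, range=FitRange(1e-6, 1.0), n_points=5)
        floor = NoiseFloor(S_nf=S_nf, range=FitRange(1.0, 2.0), n_points=5)
        u_knee = knee_frequency(fit, floor)
        assert abs(P * u_knee**a - S_nf) <= 1e-12 * S_nf

    def test_positive_slope_raises(self):
        fit = PowerLawFit(P=1.0, a=0.5, range=FitRange(0.1, 1.0), n_points=5)
        floor = NoiseFloor(S_nf=0.1, range=FitRange(1.0, 2.0), n_points=5)
        with pytest.raises(NoKneeError):
            knee_frequency(fit, floor)

    def test_resolution_closed_form(self):
        fit = PowerLawFit(P=1.0, a=-2.0, range=FitRange(0.01, 1.0), n_points=5)
        floor = NoiseFloor(S_nf=1e-4, range=FitRange(1.0, 2.0), n_points=5)
        res = resolution_frequency(fit, floor, snr_res=5.0)
        assert res.u_res == pytest.approx((5e-4) ** -0.5, rel=1e-12)
        assert res.u_res == pytest.approx(44.7214, rel=1e-5)
        assert res.delta_res == pytest.approx(0.011180, rel=1e-4)
        assert res.delta_knee == pytest.approx(1 / 200.0)

    def test_snr_one_gives_knee(self):
        fit = PowerLawFit(P=2.0, a=-3.0, range=FitRange(0.01, 1.0), n_points=5)
        floor = NoiseFloor(S_nf=1e-3, range=FitRange(1.0, 2.0), n_points=5)
        res = resolution_frequency(fit, floor, snr_res=1.0)
        assert res.u_res == res.u_knee
        assert res.delta_res == res.delta_knee

    @settings(derandomize=True, max_examples=30)
    @given(snr_pair=st.tuples(st.floats(1.01, 50), st.floats(1.01, 50)))
    def test_delta_res_monotone_in_snr(self, snr_pair):
        """Demanding a higher SNR must coarsen the reported resolution."""
        lo, hi = sorted(snr_pair)
        fit = PowerLawFit(P=10.0, a=-4.0, range=FitRange(0.01, 1.0), n_points=5)
        floor = NoiseFloor(S_nf=1e-5, range=FitRange(1.0, 2.0), n_points=5)
        d_lo = resolution_frequency(fit, floor, lo).delta_res
        d_hi = resolution_frequency(fit, floor, hi).delta_res
        if hi > lo:
            assert d_hi > d_lo

    def test_delta_res_monotone_in_noise_floor(self):
        fit = PowerLawFit(P=10.0, a=-4.0, range=FitRange(0.01, 1.0), n_points=5)
        deltas = [
            resolution_frequency(
                fit, NoiseFloor(S_nf=s, range=FitRange(1.0, 2.0), n_points=5), 5.0
            ).delta_res
            for s in [1e-6, 1e-5, 1e-4, 1e-3]
        ]
        assert np.all(np.diff(deltas) > 0)

    def test_scaling_psd_leaves_resolution_unchanged(self, rng):
        """Multiplying the whole PSD by k (equivalently changing the DFT
        normalization) leaves u_knee, u_res, delta_res unchanged."""
        u = np.geomspace(0.02, 2.0, 40)
        psd = make_powerlaw_psd(1e3, -4.0, 1e-2, u, scatter_df=50.0, seed=11)
        sig, noi = FitRange(0.02, 0.2), FitRange(0.9, 2.0)

        def solve(p):
            fit = fit_signal_trend(p, sig)
            floor = estimate_noise_floor(p, noi)
            return resolution_frequency(fit, floor, 5.0)

        base = solve(psd)
        for k in (1e-7, 3.7, 1e9):
            scaled = RadialPSD(u_r=psd.u_r, S=psd.S * k, n=psd.n)
            res = solve(scaled)
            assert res.u_res == pytest.approx(base.u_res, rel=1e-12)
            assert res.u_knee == pytest.approx(base.u_knee, rel=1e-12)
            assert res.delta_res == pytest.approx(base.delta_res, rel=1e-12)


class TestWienerFilter:
    FIT = PowerLawFit(P=1.0, a=-2.0, range=FitRange(0.01, 1.0), n_points=5)
    FLOOR = NoiseFloor(S_nf=1e-4, range=FitRange(1.0, 2.0), n_points=5)

    def test_half_at_knee(self):
        u_knee = knee_frequency(self.FIT, self.FLOOR)
        w = wiener_filter(self.FIT, self.FLOOR, np.array([u_knee]))
        assert w.W[0] == pytest.approx(0.5, abs=1e-14)

    def test_limits_and_monotonicity(self):
        u = np.geomspace(1e-4, 1e4, 200)
        w = wiener_filter(self.FIT, self.FLOOR, u)
        assert w.W[0] > 0.999999
        assert w.W[-1] < 1e-3  # S(1e4)/S_nf = 1e-4
        assert np.all(np.diff(w.W) < 0)
        assert np.all((w.W > 0) & (w.W < 1))

    def test_hand_arithmetic_value(self):
        # S(200) = 200^-2 = 2.5e-5; W = 2.5e-5 / (2.5e-5 + 1e-4) = 0.2
        w = wiener_filter(self.FIT, self.FLOOR, np.array([200.0]))
        assert w.W[0] == pytest.approx(0.2, rel=1e-12)


class TestSensitivityScan:
    def test_noiseless_power_law_zero_spread(self):
        u = np.geomspace(0.01, 10.0, 60)
        psd = make_powerlaw_psd(1.0, -3.0, 1e-6, u, scatter_df=None)
        ranges = [FitRange(0.01, 0.05), FitRange(0.02, 0.1), FitRange(0.05, 0.3)]
        results, spread = sensitivity_scan(psd, ranges, FitRange(3.0, 10.0))
        assert spread == pytest.approx(0.0, abs=1e-6)
        deltas = [r.delta_res for r in results]
        assert np.ptp(deltas) / deltas[0] < 1e-6

    def test_scattered_psd_small_spread(self):
        """Moderate multiplicative scatter: overlapping window selections
        should agree on delta_res to within 10%."""
        u = np.linspace(0.05, 4.0, 80)
        psd = make_powerlaw_psd(1e2, -4.0, 1e-2, u, scatter_df=80.0, seed=4)
        ranges = [FitRange(0.05, 0.4), FitRange(0.1, 0.6), FitRange(0.05, 0.8)]
        _, spread = sensitivity_scan(psd, ranges, FitRange(2.0, 4.0))
        assert spread <= 0.10

    def test_failed_range_reported_as_none(self):
        u = np.geomspace(0.01, 10.0, 60)
        psd = make_powerlaw_psd(1.0, -3.0, 1e-6, u, scatter_df=None)
        ranges = [FitRange(20.0, 30.0), FitRange(0.02, 0.1)]  # first has no bins
        with pytest.warns(UserWarning, match="failed"):
            results, spread = sensitivity_scan(psd, ranges, FitRange(3.0, 10.0))
        assert results[0] is None and results[1] is not None
        assert spread == 0.0

    def test_needs_two_ranges(self):
        u = np.geomspace(0.01, 10.0, 60)
        psd = make_powerlaw_psd(1.0, -3.0, 1e-6, u, scatter_df=None)
        with pytest.raises(ValueError):
            sensitivity_scan(psd, [FitRange(0.02, 0.1)], FitRange(3.0, 10.0))
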