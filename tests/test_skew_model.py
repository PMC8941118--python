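import numpy as np
import pytest

from repliskew.skew_model import (
    ChromosomeResult,
    DegenerateTrackError,
    FitParams,
    asymmetry_flags,
    bias_product,
    canonicalize,
    fit_constrained,
    fit_four_param,
    fit_profile,
    goodness,
    model_eval,
)
from repliskew.skew_scan import SkewTrack
from repliskew.synthetic import simulate_track

L = 1_048_576


def track_from(params, length=L, interval=4096):
    return simulate_track(params, length, noise_sd=0.0, interval=interval)


def shift_distance(a, b):
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


class TestModelEval:
    def test_flat_model(self):
        params = FitParams(0.0, 0.0, 0.5, 0.25)
        assert np.all(model_eval(params, 1000, [0, 100, 500, 1000]) == 0)

    def test_printed_rate_closed_form(self):
        # 46 excess per 1000 nucleotides -> 23000 at the half-way point
        params = FitParams(0.046, 0.046, 0.5, 0.0)
        value = model_eval(params, 1_000_000, [500_000])[0]
        assert value == pytest.approx(0.046 * 500_000)

    def test_anchored_at_zero(self):
        params = FitParams(0.03, 0.02, 0.6, 0.25)
        assert model_eval(params, 1_000_000, [0])[0] == 0.0

    def test_slope_on_each_arc(self):
        params = FitParams(0.04, 0.01, 0.5, 0.0)
        v = model_eval(params, 1000, [0, 250, 500, 750, 1000])
        assert np.allclose(np.diff(v), [0.04 * 250, 0.04 * 250, -0.01 * 250, -0.01 * 250])

    def test_wrapping_leading_arc(self):
        # leading arc wraps around the sequence end
        params = FitParams(0.04, 0.02, 0.5, 0.75)
        v = model_eval(params, 1000, [250, 750, 1000])
        assert v[0] == pytest.approx(0.04 * 250)  # [0,250) inside wrapped arc
        assert v[1] == pytest.approx(0.04 * 250 - 0.02 * 500)
        assert v[2] == pytest.approx(0.04 * 500 - 0.02 * 500)

    def test_invalid_div(self):
        with pytest.raises(ValueError):
            model_eval(FitParams(0.1, 0.1, 1.5, 0.0), 1000, [0])

    def test_invalid_shift(self):
        with pytest.raises(ValueError):
            model_eval(FitParams(0.1, 0.1, 0.5, 1.0), 1000, [0])


class TestGoodness:
    def test_perfect_fit(self):
        assert goodness([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert goodness([1, 2, 3], [3, 4, 5]) == pytest.approx(1.0)

    def test_zero_mean_sentinel(self):
        assert goodness([1, -1], [0, 0]) == float("inf")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            goodness([1, 2], [1, 2, 3])


class TestCanonicalize:
    def test_identity_when_canonical(self):
        params = FitParams(0.04, 0.03, 0.6, 0.2, rms=0.1)
        assert canonicalize(params) == params

    def test_mirrored_params_same_curve(self):
        raw = FitParams(-0.03, -0.04, 0.6, 0.2)
        canonical = canonicalize(raw)
        assert canonical.alpha1 == pytest.approx(0.04)
        assert canonical.alpha2 == pytest.approx(0.03)
        assert canonical.div == pytest.approx(0.4)
        assert canonical.shift == pytest.approx(0.8)
        positions = np.linspace(0, 1_000_000, 64)
        np.testing.assert_allclose(
            model_eval(canonical, 1_000_000, positions),
            model_eval(raw, 1_000_000, positions),
        )

    def test_shift_wrap(self):
        assert canonicalize(FitParams(0.1, 0.1, 0.5, 1.25 % 1.0)).shift == 0.25


class TestFitFourParam:
    def test_round_trip_recovery(self):
        truth = FitParams(0.046, 0.030, 0.557, 0.20)
        fit = fit_four_param(track_from(truth), L)
        assert fit.alpha1 == pytest.approx(truth.alpha1, abs=1e-3)
        assert fit.alpha2 == pytest.approx(truth.alpha2, abs=1e-3)
        assert fit.div == pytest.approx(truth.div, abs=1e-3)
        assert shift_distance(fit.shift, truth.shift) < 1e-3
        assert fit.rms < 1e-6

    def test_shift_equivariance(self):
        base = FitParams(0.046, 0.030, 0.557, 0.20)
        rotated = FitParams(0.046, 0.030, 0.557, (0.20 + 0.35) % 1.0)
        fit_base = fit_four_param(track_from(base), L)
        fit_rot = fit_four_param(track_from(rotated), L)
        assert shift_distance(fit_rot.shift - fit_base.shift, 0.35) < 1e-3
        assert fit_rot.alpha1 == pytest.approx(fit_base.alpha1, abs=1e-3)
        assert fit_rot.div == pytest.approx(fit_base.div, abs=1e-3)

    def test_symmetric_input(self):
        fit = fit_four_param(track_from(FitParams(0.04, 0.04, 0.5, 0.1)), L)
        assert fit.alpha1 == pytest.approx(fit.alpha2, abs=1e-3)

    def test_scale_covariance(self):
        truth = FitParams(0.02, 0.035, 0.45, 0.6)
        track = track_from(truth)
        scaled = SkewTrack(track.interval, track.positions, track.values * 3.0)
        fit = fit_four_param(track, L)
        fit_scaled = fit_four_param(scaled, L)
        assert fit_scaled.alpha1 == pytest.approx(3 * fit.alpha1, rel=1e-4)
        assert fit_scaled.alpha2 == pytest.approx(3 * fit.alpha2, rel=1e-4)
        assert fit_scaled.div == pytest.approx(fit.div, abs=1e-4)
        assert fit_scaled.shift == pytest.approx(fit.shift, abs=1e-4)
        assert fit_scaled.rms == pytest.approx(fit.rms, abs=1e-6)

    def test_all_zero_track_degenerate(self):
        track = SkewTrack(4096, np.arange(4096, 4096 * 20, 4096), np.zeros(19))
        with pytest.raises(DegenerateTrackError):
            fit_four_param(track, 4096 * 20)

    def test_too_few_checkpoints(self):
        track = SkewTrack(4096, [4096, 8192], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_four_param(track, 8192)

    def test_parameter_recovery_grid(self):
        # >= 50 noiseless parameter sets, max abs error < 1e-3 everywhere
        cases = []
        for a1, a2 in [(0.005, 0.08), (0.046, 0.03), (0.02, 0.02), (0.08, 0.046)]:
            for div in (0.3, 0.45, 0.557, 0.7):
                for shift in (0.0, 0.2, 0.55, 0.9):
                    cases.append(FitParams(a1, a2, div, shift))
        assert len(cases) >= 50
        for truth in cases:
            fit = fit_four_param(track_from(truth), L)
            assert fit.alpha1 == pytest.approx(truth.alpha1, abs=1e-3), truth
            assert fit.alpha2 == pytest.approx(truth.alpha2, abs=1e-3), truth
            assert fit.div == pytest.approx(truth.div, abs=1e-3), truth
            assert shift_distance(fit.shift, truth.shift) < 1e-3, truth

    def test_noisy_recovery_within_ten_percent(self):
        truth = FitParams(0.046, 0.046, 0.5, 0.0)
        track = simulate_track(truth, L, noise_sd=10.0, seed=1)
        fit = fit_four_param(track, L)
        assert fit.alpha1 == pytest.approx(truth.alpha1, rel=0.10)
        assert fit.alpha2 == pytest.approx(truth.alpha2, rel=0.10)

    def test_beats_grid_search_oracle(self):
        """Multi-start simplex RMSE <= exhaustive grid search on coarse tracks.

        The oracle evaluates every (div, shift) on a 1/64 grid, counts the
        leading-arc nucleotides per checkpoint by brute-force indicator sums,
        solves for the two slopes by normal equations, and keeps the best
        RMSE found.  Fully independent of the package's model evaluation.
        """
        length, interval = 4096, 64  # 64 checkpoints
        truth = FitParams(0.05, 0.02, 0.61, 0.37)
        track = track_from(truth, length=length, interval=interval)
        positions = track.positions
        values = track.values

        nt = np.arange(length)
        best = np.inf
        for div_i in range(1, 64):
            div = div_i / 64
            for shift_i in range(64):
                shift = shift_i / 64
                leading_nt = ((nt - shift * length) % length) < div * length
                lead_prefix = np.cumsum(leading_nt)[positions - 1].astype(float)
                lag_prefix = positions - lead_prefix
                A = np.column_stack([lead_prefix, -lag_prefix])
                coef = np.linalg.solve(A.T @ A, A.T @ values)
                rmse = np.sqrt(np.mean((values - A @ coef) ** 2))
                best = min(best, rmse)

        fit = fit_four_param(track, length)
        predicted = model_eval(fit, length, positions)
        fit_rmse = np.sqrt(np.mean((values - predicted) ** 2))
        assert fit_rmse <= best + 1e-9


class TestFitConstrained:
    def test_concordant_track(self):
        gc = FitParams(0.04, 0.03, 0.55, 0.2)
        ta = FitParams(0.025, 0.018, 0.55, 0.2)
        fit = fit_constrained(track_from(ta), L, gc.div, gc.shift)
        assert fit.alpha1 == pytest.approx(0.025, abs=1e-6)
        assert fit.alpha2 == pytest.approx(0.018, abs=1e-6)
        assert fit.rms < 1e-9

    def test_discordant_track_negative_alphas(self):
        # Firmicute-style: TA slopes opposite in sign to GC
        ta = FitParams(-0.02, -0.015, 0.55, 0.2)
        fit = fit_constrained(track_from(ta), L, 0.55, 0.2)
        assert fit.alpha1 == pytest.approx(-0.02, abs=1e-6)
        assert fit.alpha2 == pytest.approx(-0.015, abs=1e-6)

    def test_zero_track_degenerate_rms(self):
        positions = np.arange(4096, L + 1, 4096)
        track = SkewTrack(4096, positions, np.zeros(len(positions)))
        fit = fit_constrained(track, L, 0.55, 0.2)
        assert fit.alpha1 == pytest.approx(0.0, abs=1e-12)
        assert fit.alpha2 == pytest.approx(0.0, abs=1e-12)
        assert fit.rms == float("inf")


class TestAnalysisOps:
    def _result(self, alpha1, alpha2, div):
        return ChromosomeResult(
            accession="X",
            gc=FitParams(alpha1, alpha2, div, 0.0, rms=0.01),
            constrained={},
        )

    def test_skew_asymmetric_boundary_inclusive(self):
        assert asymmetry_flags(self._result(0.03, 0.01, 0.5))[0] is True
        assert asymmetry_flags(self._result(0.029, 0.01, 0.5))[0] is False

    def test_zero_slope_is_asymmetric(self):
        assert asymmetry_flags(self._result(0.03, 0.0, 0.5))[0] is True

    def test_strand_symmetric(self):
        assert asymmetry_flags(self._result(0.03, 0.03, 0.5))[1] is False

    def test_strand_asymmetric_boundary(self):
        assert asymmetry_flags(self._result(0.03, 0.03, 0.75))[1] is True

    @pytest.mark.parametrize(
        "ggcfrac,slope,expected",
        [(0.5, 0.7, 0.0), (0.6, 0.0, 0.0), (0.6, 0.5, 0.1)],
    )
    def test_bias_product(self, ggcfrac, slope, expected):
        assert bias_product(2 * ggcfrac - 1, slope) == pytest.approx(expected)


class TestFitProfile:
    def test_div_shift_shared(self, megabase_binomial):
        from repliskew.skew_scan import scan_chromosome

        spec, (record, genes, _) = megabase_binomial
        profile = scan_chromosome(record, genes)
        result = fit_profile(profile)
        assert set(result.constrained) == {
            "ta", "gc0", "gc1", "gc2", "ta0", "ta1", "ta2", "gcng", "tang", "sb",
        }
        assert result.div == result.gc.div
        assert result.gc.rms < 0.16
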