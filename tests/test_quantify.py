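"""Relative/absolute quantification and validation statistics."""

import numpy as np
import pytest

from cilquant.errors import QuantificationError, UsageError
from cilquant.peaks import PeakPair, integrate_transition
from cilquant.quantify import (
    CalibrationCurve,
    accuracy_re,
    fit_calibration,
    group_ratio_absolute,
    group_ratio_cil,
    precision_rsd,
    quantify_absolute,
    replicate_ratio_summary,
)
from cilquant.simulate import simulate_calibration_series

from conftest import make_peak


def make_pair(ratio, name="Test acid", status="ok"):
    light = make_peak(1000.0, name=name, channel="light",
                      detected=status not in ("light ND", "both ND"))
    heavy = make_peak(1000.0 * (ratio or 1.0), name=name, channel="heavy",
                      detected=status not in ("heavy ND", "both ND"))
    return PeakPair(name, light, heavy, 0.0,
                    ratio if status == "ok" else None, status)


class TestRatioSummary:
    def test_constant_ratios(self):
        s = replicate_ratio_summary([make_pair(1.0)] * 3)
        assert (s.n, s.mean, s.sd, s.nd) == (3, 1.0, 0.0, False)

    def test_triplicate_mean_sd(self):
        s = replicate_ratio_summary([make_pair(r) for r in (0.9, 1.0, 1.1)])
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(0.1)

    def test_all_nd(self):
        s = replicate_ratio_summary(
            [make_pair(None, status="heavy ND")] * 3
        )
        assert s.nd and s.mean is None and s.n == 0

    def test_errors(self):
        with pytest.raises(UsageError):
            replicate_ratio_summary([])
        with pytest.raises(UsageError):
            replicate_ratio_summary(
                [make_pair(1.0, name="A"), make_pair(1.0, name="B")]
            )


def _wls_oracle(x, y, w):
    """Independent weighted-LS solution via the normal equations."""
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    denominator = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denominator
    intercept = (swy * swxx - swx * swxy) / denominator
    return slope, intercept


class TestCalibration:
    def test_exact_line(self):
        levels = [(c, 0.5 * c) for c in (0.1, 0.5, 1.0, 5.0, 10.0)]
        curve = fit_calibration(levels, "1/x")
        assert curve.slope == pytest.approx(0.5, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r == pytest.approx(1.0, abs=1e-12)
        assert curve.reportable

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = np.sort(rng.uniform(0.1, 10.0, 7))
            y = 0.3 * x + 0.01 + rng.normal(0, 0.05 * x)
            curve = fit_calibration(list(zip(x, y)), "1/x")
            slope, intercept = _wls_oracle(x, y, 1.0 / x)
            assert curve.slope == pytest.approx(slope, abs=1e-9)
            assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    def test_weighting_helps_heteroscedastic_data(self):
        """With noise proportional to concentration, the 1/x-weighted
        slope is on average closer to truth than the unweighted one."""
        rng = np.random.default_rng(1)
        err_w, err_u, slopes = [], [], []
        x = np.array([0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        for _ in range(200):
            y = x * (1 + rng.normal(0, 0.1, x.size)) + \
                rng.normal(0, 0.002, x.size)
            slope_w = fit_calibration(list(zip(x, y)), "1/x").slope
            err_w.append(abs(slope_w - 1))
            err_u.append(abs(fit_calibration(list(zip(x, y)), "none").slope - 1))
            slopes.append(slope_w)
        assert np.mean(err_w) < np.mean(err_u)
        assert np.mean(slopes) == pytest.approx(1.0, rel=0.02)

    def test_errors(self):
        with pytest.raises(QuantificationError):
            fit_calibration([(1.0, 1.0)])
        with pytest.raises(QuantificationError):
            fit_calibration([(1.0, 1.0), (1.0, 2.0)])
        with pytest.raises(QuantificationError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)], "1/x2")


class TestAbsoluteQuantification:
    def test_inversion(self):
        curve = CalibrationCurve("x", ((1.0, 0.5), (2.0, 1.0)), 0.5, 0.0,
                                 1.0, "1/x")
        assert quantify_absolute(curve, 1.0).value == pytest.approx(2.0)
        assert quantify_absolute(curve, 0.0).value == pytest.approx(0.0)
        below = quantify_absolute(curve, -0.5)
        assert below.below_zero and below.value < 0

    def test_zero_slope_rejected(self):
        curve = CalibrationCurve("x", ((1.0, 1.0), (2.0, 1.0)), 0.0, 1.0,
                                 0.0, "none")
        with pytest.raises(QuantificationError):
            quantify_absolute(curve, 1.0)

    def test_simulation_round_trip(self, quiet_config, scfa_panel,
                                   internal_standards):
        """Simulate levels, fit, then re-quantify each level: recovered
        concentrations match the nominal ones."""
        analyte = scfa_panel[0]
        levels = [0.1, 0.3, 1.0, 3.0, 10.0]
        runs = simulate_calibration_series(
            analyte, levels, 10.0, quiet_config,
            internal_standards["Propanoic acid-d5"], area_cv=0.0,
        )
        points = []
        for run in runs:
            a = integrate_transition(run.analyte_trace)
            b = integrate_transition(run.is_trace)
            points.append((run.concentration, a.area / b.area))
        curve = fit_calibration(points, "1/x", analyte=analyte.name)
        for conc, ratio in points:
            found = quantify_absolute(curve, ratio).value
            assert found == pytest.approx(conc, rel=1e-6)


class TestValidationMetrics:
    @pytest.mark.parametrize(
        "found, endogenous, spiked, expected",
        [(15.0, 5.0, 10.0, 0.0), (16.0, 5.0, 10.0, 10.0),
         (14.0, 5.0, 10.0, -10.0)],
    )
    def test_accuracy_re(self, found, endogenous, spiked, expected):
        assert accuracy_re(found, endogenous, spiked) == \
            pytest.approx(expected)

    def test_accuracy_re_requires_spike(self):
        with pytest.raises(QuantificationError):
            accuracy_re(1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "values, expected", [([10, 10, 10], 0.0), ([9, 10, 11], 10.0)]
    )
    def test_precision_rsd(self, values, expected):
        assert precision_rsd(values) == pytest.approx(expected)

    def test_precision_rsd_errors(self):
        with pytest.raises(UsageError):
            precision_rsd([10.0])
        with pytest.raises(QuantificationError):
            precision_rsd([-1.0, 1.0])

    def test_scale_invariance(self):
        values = [9.0, 10.0, 11.0]
        assert precision_rsd([7.3 * v for v in values]) == \
            pytest.approx(precision_rsd(values))
        assert accuracy_re(16.0, 5.0, 10.0) == \
            pytest.approx(accuracy_re(32.0, 10.0, 20.0))


class TestGroupRatios:
    def test_absolute_ratio(self):
        assert group_ratio_absolute([2, 2, 2], [4, 4, 4]).ratio == \
            pytest.approx(2.0)
        assert group_ratio_absolute([3, 3], [3, 3]).ratio == \
            pytest.approx(1.0)
        with pytest.raises(QuantificationError):
            group_ratio_absolute([0, 0], [1, 1])

    def test_absolute_ratio_with_noise(self):
        rng = np.random.default_rng(4)
        spf = 2.0 * (1 + rng.normal(0, 0.05, 3))
        gf = 3.0 * (1 + rng.normal(0, 0.05, 3))
        result = group_ratio_absolute(spf, gf)
        assert result.ratio == pytest.approx(1.5, rel=0.15)
        assert result.sd is not None and result.sd > 0

    def test_cil_ratio(self):
        pairs = [make_pair(r) for r in (1.9, 2.0, 2.1)]
        result = group_ratio_cil(pairs)
        assert result.ratio == pytest.approx(2.0)
        assert result.status == "ok"

    def test_cil_ratio_nd(self):
        result = group_ratio_cil([make_pair(None, status="heavy ND")] * 3)
        assert np.isnan(result.ratio)
        assert "heavy ND" in result.status
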