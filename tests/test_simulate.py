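"""Properties of the synthetic SRM chromatogram generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cilquant.errors import ConfigurationError
from cilquant.simulate import (
    SimulationConfig,
    bundled_study_template,
    default_study_design,
    design_from_dict,
    design_to_dict,
    make_suppression_profile,
    simulate_calibration_series,
    simulate_differential_pair,
    simulate_group_study,
    simulate_trace,
)
from cilquant.transitions import LIGHT_2PA, HEAVY_2PA, make_transition


def test_suppression_identity_when_disabled():
    profile = make_suppression_profile(
        SimulationConfig(seed=1), 600.0, enabled=False
    )
    assert np.all(profile.factor == 1.0)


def test_suppression_deterministic():
    cfg = SimulationConfig(seed=42)
    a = make_suppression_profile(cfg, 1200.0, key="k")
    b = make_suppression_profile(cfg, 1200.0, key="k")
    assert np.array_equal(a.factor, b.factor)
    c = make_suppression_profile(cfg, 1200.0, key="other")
    assert not np.array_equal(a.factor, c.factor)


@given(st.integers(min_value=0, max_value=10_000))
def test_suppression_bounds(seed):
    profile = make_suppression_profile(
        SimulationConfig(seed=seed), 1800.0
    )
    assert np.all(profile.factor > 0.0)
    assert np.all(profile.factor <= 1.0)


def test_zero_amount_gives_flat_baseline(quiet_config, scfa_panel):
    t = make_transition(scfa_panel[0], LIGHT_2PA)
    trace = simulate_trace(t, 0.0, quiet_config)
    assert np.all(trace.intensity == quiet_config.baseline_level)


@pytest.mark.parametrize("shape", ["gaussian", "emg"])
def test_noiseless_area_matches_amount(quiet_config, scfa_panel, shape):
    """Numerically integrated noiseless peak area equals
    amount x response factor (unit-area peak shapes) within 1%."""
    import dataclasses

    cfg = dataclasses.replace(quiet_config, peak_shape=shape)
    t = make_transition(scfa_panel[0], LIGHT_2PA)
    trace = simulate_trace(t, 2.0, cfg)
    area = np.trapezoid(trace.intensity - cfg.baseline_level, trace.time)
    assert area == pytest.approx(2.0 * cfg.response_factor, rel=0.01)


def test_noiseless_area_linear_in_amount(quiet_config, scfa_panel):
    t = make_transition(scfa_panel[0], LIGHT_2PA)
    a1 = np.trapezoid(
        simulate_trace(t, 1.0, quiet_config).intensity
        - quiet_config.baseline_level,
        simulate_trace(t, 1.0, quiet_config).time,
    )
    a2 = np.trapezoid(
        simulate_trace(t, 2.0, quiet_config).intensity
        - quiet_config.baseline_level,
        simulate_trace(t, 2.0, quiet_config).time,
    )
    assert a2 / a1 == pytest.approx(2.0, rel=1e-6)


def test_trace_determinism(scfa_panel):
    cfg = SimulationConfig(seed=7)
    t = make_transition(scfa_panel[0], LIGHT_2PA)
    x = simulate_trace(t, 1.0, cfg, key="r")
    y = simulate_trace(t, 1.0, cfg, key="r")
    assert np.array_equal(x.intensity, y.intensity)


def test_pair_simulator_matches_single_trace(scfa_panel):
    """With no heavy RT shift and bias off, the differential pair is the
    channel-wise output of the single-trace simulator."""
    cfg = SimulationConfig(
        seed=9, heavy_rt_shift=0.0, isotope_effect_sd=0.0
    )
    amounts = {a.name: 1.5 for a in scfa_panel}
    run = simulate_differential_pair(
        amounts, amounts, scfa_panel, cfg, run_key="rep0"
    )
    analyte = scfa_panel[0]
    light, heavy = run.traces[analyte.name]
    direct = simulate_trace(
        make_transition(analyte, LIGHT_2PA), 1.5, cfg,
        run.suppression, key="rep0",
    )
    assert np.array_equal(light.intensity, direct.intensity)


def test_pair_true_ratio_independent_of_suppression(quiet_config, scfa_panel):
    amounts_l = {a.name: 1.0 for a in scfa_panel}
    amounts_h = {a.name: 2.0 for a in scfa_panel}
    run = simulate_differential_pair(
        amounts_l, amounts_h, scfa_panel, quiet_config
    )
    for name in amounts_l:
        assert run.true_ratio[name] == pytest.approx(2.0)
        light, heavy = run.traces[name]
        area_l = np.trapezoid(
            light.intensity - quiet_config.baseline_level, light.time
        )
        area_h = np.trapezoid(
            heavy.intensity - quiet_config.baseline_level, heavy.time
        )
        # shared suppression cancels exactly in the area ratio
        assert area_h / area_l == pytest.approx(2.0, rel=1e-9)


def test_pair_nd_analyte_gives_baseline_traces(quiet_config, scfa_panel):
    zero = {a.name: 0.0 for a in scfa_panel}
    run = simulate_differential_pair(zero, zero, scfa_panel, quiet_config)
    for light, heavy in run.traces.values():
        assert np.all(light.intensity == quiet_config.baseline_level)
        assert np.all(heavy.intensity == quiet_config.baseline_level)
    assert all(v is None for v in run.true_ratio.values())


def test_calibration_series(quiet_config, scfa_panel, internal_standards):
    levels = [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0]
    runs = simulate_calibration_series(
        scfa_panel[0], levels, 10.0, quiet_config,
        internal_standards["Propanoic acid-d5"], area_cv=0.0,
    )
    assert len(runs) == 7
    ratios = []
    for run in runs:
        a = np.trapezoid(
            run.analyte_trace.intensity - quiet_config.baseline_level,
            run.analyte_trace.time,
        )
        b = np.trapezoid(
            run.is_trace.intensity - quiet_config.baseline_level,
            run.is_trace.time,
        )
        ratios.append(a / b)
    # noise off: response ratios exactly proportional to concentration
    expected = np.asarray(levels) / 10.0
    assert np.allclose(ratios, expected, rtol=1e-9)


def test_calibration_series_errors(quiet_config, scfa_panel,
                                   internal_standards):
    std = internal_standards["Propanoic acid-d5"]
    with pytest.raises(ConfigurationError):
        simulate_calibration_series(
            scfa_panel[0], [1.0], 10.0, quiet_config, std
        )
    with pytest.raises(ConfigurationError):
        simulate_calibration_series(
            scfa_panel[0], [1.0, 0.5], 10.0, quiet_config, std
        )


def test_group_study_amount_logic(panel40):
    design = default_study_design(panel40)
    # configured fold changes and non-detects flow into cell amounts
    assert design.amount("SPF-RF", "plasma", "Cholic acid") == 5.0
    assert design.amount("GF", "plasma", "Cholic acid") == 0.0
    assert design.amount("GF", "feces", "Butyric acid") == 0.0
    assert design.amount("SPF", "plasma", "Cholic acid") == 1.0


def test_group_study_simulation(scfa_panel):
    design = default_study_design(scfa_panel)
    cfg = SimulationConfig(seed=5, noise_sd=0.0, isotope_effect_sd=0.0,
                           heavy_rt_shift=0.0)
    study = simulate_group_study(design, scfa_panel, cfg)
    assert set(study.runs) == {
        (g, m) for g in design.groups for m in design.matrices
    }
    assert all(len(runs) == 3 for runs in study.runs.values())
    # GF feces SCFAs are forced ND: heavy channel flat at baseline
    _, heavy = study.runs[("GF", "feces")][0].traces["Butyric acid"]
    assert np.all(heavy.intensity == cfg.baseline_level)


def test_group_study_determinism(scfa_panel):
    design = default_study_design(scfa_panel)
    cfg = SimulationConfig(seed=12)
    s1 = simulate_group_study(design, scfa_panel, cfg)
    s2 = simulate_group_study(design, scfa_panel, cfg)
    for cell in s1.runs:
        for r1, r2 in zip(s1.runs[cell], s2.runs[cell]):
            for name in r1.traces:
                assert np.array_equal(
                    r1.traces[name][1].intensity, r2.traces[name][1].intensity
                )


def test_design_round_trip_and_bundled_template(panel40):
    design = default_study_design(panel40)
    assert design_from_dict(design_to_dict(design)) == design
    template = bundled_study_template()
    assert template == design
    assert template.group_sizes == {"SPF": 4, "GF": 4, "SPF-RF": 3,
                                    "GF-RF": 5}


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(sampling_interval=0.0),
        dict(peak_sigma=-1.0),
        dict(peak_shape="lorentzian"),
        dict(noise_sd=-1.0),
        dict(suppression_depth=1.0),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)
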