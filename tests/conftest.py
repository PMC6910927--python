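"""Shared fixtures: small panels, simulation configs, and helpers for
fabricating traces and peaks without running the full simulator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cilquant import chem
from cilquant.panel import default_internal_standards, load_default_panel
from cilquant.peaks import Peak
from cilquant.simulate import ChromatogramTrace, SimulationConfig
from cilquant.transitions import Analyte, LIGHT_2PA, HEAVY_2PA, make_transition

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel40():
    return load_default_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel40):
    return {a.name: a for a in panel40}


@pytest.fixture(scope="session")
def internal_standards():
    return {a.name: a for a in default_internal_standards()}


@pytest.fixture
def scfa_panel(panel_by_name):
    return [panel_by_name["Propanoic acid"], panel_by_name["Butyric acid"]]


@pytest.fixture
def quiet_config():
    """Noise-free, bias-free, perfectly co-eluting configuration."""
    return SimulationConfig(
        seed=11, noise_sd=0.0, isotope_effect_sd=0.0, heavy_rt_shift=0.0
    )


def make_test_transition(
    name="Test acid", rt_min=5.0, rt_window_min=0.5, channel="light"
):
    analyte = Analyte(
        name=name,
        formula=chem.parse_formula("C4H8O2"),
        compound_class="SCFA",
        expected_rt=rt_min,
        rt_window=rt_window_min,
    )
    label = LIGHT_2PA if channel == "light" else HEAVY_2PA
    return make_transition(analyte, label)


def make_trace(intensity, rt_min=5.0, dt=0.5, channel="light", name="Test acid"):
    """Trace centered on rt_min with the given intensity array."""
    intensity = np.asarray(intensity, dtype=float)
    transition = make_test_transition(name, rt_min, channel=channel)
    n = intensity.size
    t = rt_min * 60.0 + (np.arange(n) - n // 2) * dt
    return ChromatogramTrace(transition, t, intensity)


def gaussian_trace(amplitude, sigma=3.0, baseline=0.0, rt_min=5.0, dt=0.5,
                   n=301, noise_sd=0.0, seed=0, channel="light"):
    rng = np.random.default_rng(seed)
    t_rel = (np.arange(n) - n // 2) * dt
    y = baseline + amplitude * np.exp(-0.5 * (t_rel / sigma) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, n)
    return make_trace(np.clip(y, 0, None), rt_min=rt_min, dt=dt,
                      channel=channel)


def make_peak(area, name="Test acid", channel="light", detected=True,
              apex_s=300.0, height=None):
    return Peak(
        transition_id=f"{name}|{channel}",
        apex_time=apex_s,
        left=apex_s - 10.0,
        right=apex_s + 10.0,
        height=height if height is not None else area / 7.5,
        area=area if detected else 0.0,
        snr=100.0 if detected else 1.0,
        detected=detected,
        baseline=10.0,
        noise_sd=2.0,
    )
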