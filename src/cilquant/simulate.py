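"""Synthetic SRM chromatogram generator.

This module emulates the data the chemical-isotope-labeling workflow
acquires on a triple quadrupole: co-eluting light/heavy derivative peaks
whose areas are proportional to injected amount, a slowly varying
multiplicative ion-suppression (matrix-effect) factor shared by all
channels at the same instant, additive detector noise on a flat
baseline, a small per-analyte heavy/light response bias near 1 (the
deuterium isotope effect), calibration series against a pre-deuterated
internal standard, and a 4-group x 3-matrix differential study with
configurable fold changes and forced non-detects.

Design notes
------------
* Ion suppression varies on the chromatographic timescale (tens of
  seconds to minutes, the width of co-eluting matrix bands), far slower
  than the ~3 s analyte peaks; this is what makes the light/heavy ratio
  insensitive to the matrix, since both channels are attenuated by
  essentially the same factor.
* Every random draw comes from a sub-stream derived from the single
  config seed plus a stable string key, so regenerating any one trace is
  independent of generation order.
* Time is seconds internally; retention times at the API boundary are
  minutes, matching printed method tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .transitions import (
    Analyte,
    HEAVY_2PA,
    LIGHT_2PA,
    SRMTransition,
    make_transition,
)

GROUPS = ("SPF", "SPF-RF", "GF", "GF-RF")
MATRICES = ("plasma", "feces", "cecal")


@dataclass(frozen=True)
class SimulationConfig:
    """Nuisance-parameter bundle for the simulator.

    Defaults describe a well-behaved targeted assay: Gaussian peaks of
    sigma 3 s sampled every 0.5 s, a flat baseline of 10 counts with
    2-count additive white noise, 10^4 counts of integrated signal per
    amount unit, a lognormal heavy-channel isotope-effect bias of
    sigma 0.05, and a 0.3 s heavy retention shift (derivative pairs
    co-elute almost exactly; the small shift exercises pairing
    tolerance).  ``area_cv`` adds per-trace multiplicative amplitude
    noise and is zero by default; calibration runs use 5% (see
    :func:`simulate_calibration_series`).
    """

    seed: int = 0
    sampling_interval: float = 0.5  # s
    peak_sigma: float = 3.0  # s
    peak_shape: str = "gaussian"  # "gaussian" | "emg"
    emg_tau: float = 2.0  # s, exponential tail of the EMG shape
    baseline_level: float = 10.0  # counts
    noise_sd: float = 2.0  # counts, additive white noise
    baseline_drift: float = 0.0  # counts, amplitude of slow sinusoidal drift
    response_factor: float = 1.0e4  # integrated counts per amount unit
    area_cv: float = 0.0  # per-trace multiplicative amplitude noise
    isotope_effect_sd: float = 0.05  # lognormal sigma of heavy/light bias
    heavy_rt_shift: float = 0.3  # s
    suppression_depth: float = 0.6  # max fractional signal loss
    trace_halfwidth_factor: float = 2.5  # trace span = factor x rt_window
    peak_sigma_overrides: Mapping[str, float] = field(default_factory=dict)
    response_factor_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be > 0")
        if self.peak_sigma <= 0:
            raise ConfigurationError("peak_sigma must be > 0")
        if self.peak_shape not in ("gaussian", "emg"):
            raise ConfigurationError(f"unknown peak_shape {self.peak_shape!r}")
        if self.noise_sd < 0 or self.area_cv < 0 or self.isotope_effect_sd < 0:
            raise ConfigurationError("noise magnitudes must be >= 0")
        if not 0 <= self.suppression_depth < 1:
            raise ConfigurationError("suppression_depth must be in [0, 1)")

    def sigma_for(self, analyte_name: str) -> float:
        return self.peak_sigma_overrides.get(analyte_name, self.peak_sigma)

    def response_for(self, analyte_name: str) -> float:
        return self.response_factor_overrides.get(
            analyte_name, self.response_factor
        )


@dataclass(frozen=True)
class SuppressionProfile:
    """Time-varying multiplicative ionization efficiency in (0, 1].

    The same factor applies to every channel at a given instant; this is
    the mechanism by which the 1:1 mixing design cancels matrix effects.
    """

    time: np.ndarray  # s
    factor: np.ndarray  # dimensionless, (0, 1]

    def __post_init__(self) -> None:
        if self.time.shape != self.factor.shape:
            raise ConfigurationError("time/factor arrays differ in length")
        if np.any(self.factor <= 0) or np.any(self.factor > 1):
            raise ConfigurationError("suppression factor must lie in (0, 1]")

    def at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.time, self.factor)


@dataclass(frozen=True)
class ChromatogramTrace:
    """Time/intensity series for one SRM transition (time in seconds)."""

    transition: SRMTransition
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.time.shape != self.intensity.shape:
            raise ConfigurationError("time/intensity arrays differ in length")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise ConfigurationError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ConfigurationError("intensity must be finite and non-negative")

    @property
    def transition_id(self) -> str:
        return self.transition.transition_id


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Deterministic sub-stream for (seed, key...) independent of call
    order.  String key parts are hashed with CRC32 for stability."""
    words = [seed & 0x7FFFFFFF]
    for part in key:
        if isinstance(part, str):
            words.append(zlib.crc32(part.encode("utf-8")))
        else:
            words.append(int(part) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def make_suppression_profile(
    config: SimulationConfig,
    run_duration: float,
    key: str = "suppression",
    enabled: bool = True,
) -> SuppressionProfile:
    """A smooth random ion-suppression curve over [0, run_duration] s.

    Built from 2-5 Gaussian matrix bands with 60-120 s widths; the
    normalized band envelope is scaled by a random depth bounded by
    ``config.suppression_depth``, keeping the factor within
    [1 - depth, 1].  ``enabled=False`` returns the identity profile.
    """
    if run_duration <= 0:
        raise ConfigurationError("run_duration must be > 0")
    grid = np.arange(0.0, run_duration + config.sampling_interval,
                     config.sampling_interval)
    if not enabled or config.suppression_depth == 0:
        return SuppressionProfile(grid, np.ones_like(grid))
    rng = _rng(config.seed, "suppression", key)
    n_bands = int(rng.integers(2, 6))
    centers = rng.uniform(0.0, run_duration, n_bands)
    widths = rng.uniform(60.0, 120.0, n_bands)
    amps = rng.uniform(0.3, 1.0, n_bands)
    envelope = np.zeros_like(grid)
    for c, w, a in zip(centers, widths, amps):
        envelope += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    peak = envelope.max()
    if peak > 0:
        envelope /= peak
    depth = rng.uniform(0.2, 1.0) * config.suppression_depth
    return SuppressionProfile(grid, 1.0 - depth * envelope)


def _unit_peak(
    t: np.ndarray, center: float, sigma: float, config: SimulationConfig
) -> np.ndarray:
    """Unit-area peak shape evaluated on the time grid."""
    if config.peak_shape == "emg":
        k = config.emg_tau / sigma
        return stats.exponnorm.pdf(t, k, loc=center, scale=sigma)
    return stats.norm.pdf(t, loc=center, scale=sigma)


def trace_time_grid(
    transition: SRMTransition, config: SimulationConfig
) -> np.ndarray:
    """Acquisition window for one transition: expected RT +/- a flank of
    ``trace_halfwidth_factor`` x the RT window (leaving baseline regions
    on both sides for noise estimation)."""
    center = transition.expected_rt * 60.0
    half = config.trace_halfwidth_factor * transition.analyte.rt_window * 60.0
    n = int(round(half / config.sampling_interval))
    offsets = np.arange(-n, n + 1) * config.sampling_interval
    return center + offsets


def simulate_trace(
    transition: SRMTransition,
    amount: float,
    config: SimulationConfig,
    suppression: SuppressionProfile | None = None,
    *,
    isotope_bias: float = 1.0,
    area_scale: float = 1.0,
    key: str = "trace",
) -> ChromatogramTrace:
    """One SRM chromatogram for ``amount`` of analyte in this channel.

    The noiseless peak area equals
    ``amount * response_factor * isotope_bias * area_scale * <s>``
    where ``<s>`` is the shape-weighted mean suppression under the peak;
    the baseline (detector background) is not suppressed.  ``amount = 0``
    yields a baseline-only trace.
    """
    if amount < 0:
        raise ConfigurationError("amount must be >= 0")
    t = trace_time_grid(transition, config)
    name = transition.analyte.name
    center = transition.expected_rt * 60.0
    if transition.channel == "heavy":
        center += config.heavy_rt_shift
    signal = np.zeros_like(t)
    if amount > 0:
        shape = _unit_peak(t, center, config.sigma_for(name), config)
        s = suppression.at(t) if suppression is not None else 1.0
        signal = (
            amount * config.response_for(name) * isotope_bias * area_scale
        ) * shape * s
    baseline = np.full_like(t, config.baseline_level)
    if config.baseline_drift > 0:
        baseline += config.baseline_drift * np.sin(2 * np.pi * t / 600.0)
    intensity = baseline + signal
    if config.noise_sd > 0:
        rng = _rng(config.seed, "noise", key, transition.transition_id)
        intensity = intensity + rng.normal(0.0, config.noise_sd, t.size)
    return ChromatogramTrace(transition, t, np.clip(intensity, 0.0, None))


def isotope_bias_for(analyte_name: str, config: SimulationConfig) -> float:
    """Per-analyte heavy-response bias, lognormal around 1 with sigma
    ``isotope_effect_sd``; fixed for a given seed (a property of the
    derivative, not of the injection)."""
    if config.isotope_effect_sd == 0:
        return 1.0
    rng = _rng(config.seed, "isotope-bias", analyte_name)
    return float(np.exp(config.isotope_effect_sd * rng.standard_normal()))


def _area_scale(config: SimulationConfig, key: str, trace_id: str) -> float:
    if config.area_cv == 0:
        return 1.0
    rng = _rng(config.seed, "area-noise", key, trace_id)
    return float(np.exp(config.area_cv * rng.standard_normal()))


@dataclass(frozen=True)
class DifferentialRun:
    """One 1:1-mixed light/heavy injection over a panel."""

    traces: dict[str, tuple[ChromatogramTrace, ChromatogramTrace]]
    true_ratio: dict[str, float | None]  # heavy/light amount ratio x bias
    suppression: SuppressionProfile
    run_key: str

    def all_traces(self) -> list[ChromatogramTrace]:
        out: list[ChromatogramTrace] = []
        for light, heavy in self.traces.values():
            out.extend((light, heavy))
        return out


def simulate_differential_pair(
    amounts_light: Mapping[str, float],
    amounts_heavy: Mapping[str, float],
    panel: Sequence[Analyte],
    config: SimulationConfig,
    *,
    run_key: str = "run",
    suppression: SuppressionProfile | None = None,
    apply_isotope_bias: bool = True,
) -> DifferentialRun:
    """Simulate one differential injection: each analyte gets a light and
    a heavy trace sharing a single suppression profile, so the true
    heavy/light area ratio equals the amount ratio times the isotope
    bias regardless of the matrix."""
    missing = [a.name for a in panel
               if a.name not in amounts_light or a.name not in amounts_heavy]
    if missing:
        raise ConfigurationError(f"amount maps missing analytes: {missing}")
    duration = (max(a.expected_rt for a in panel) + 3.0) * 60.0
    if suppression is None:
        suppression = make_suppression_profile(config, duration, key=run_key)
    traces: dict[str, tuple[ChromatogramTrace, ChromatogramTrace]] = {}
    truth: dict[str, float | None] = {}
    for analyte in panel:
        bias = (isotope_bias_for(analyte.name, config)
                if apply_isotope_bias else 1.0)
        light_t = make_transition(analyte, LIGHT_2PA)
        heavy_t = make_transition(analyte, HEAVY_2PA)
        a_l = amounts_light[analyte.name]
        a_h = amounts_heavy[analyte.name]
        light = simulate_trace(
            light_t, a_l, config, suppression,
            area_scale=_area_scale(config, run_key, light_t.transition_id),
            key=run_key,
        )
        heavy = simulate_trace(
            heavy_t, a_h, config, suppression, isotope_bias=bias,
            area_scale=_area_scale(config, run_key, heavy_t.transition_id),
            key=run_key,
        )
        traces[analyte.name] = (light, heavy)
        truth[analyte.name] = (a_h / a_l) * bias if a_l > 0 else None
    return DifferentialRun(traces, truth, suppression, run_key)


@dataclass(frozen=True)
class CalibrationRun:
    """One calibration level: analyte and internal-standard traces (both
    light-labeled; the IS is distinguished by its deuterated precursor)."""

    concentration: float
    is_concentration: float
    analyte_trace: ChromatogramTrace
    is_trace: ChromatogramTrace


def simulate_calibration_series(
    analyte: Analyte,
    levels: Sequence[float],
    is_concentration: float,
    config: SimulationConfig,
    internal_standard: Analyte,
    *,
    area_cv: float = 0.05,
    run_key: str = "cal",
) -> list[CalibrationRun]:
    """Calibration standards in neat solvent (no matrix suppression).

    Each level yields the analyte trace plus the pre-deuterated IS trace
    at its fixed spike concentration.  ``area_cv`` is the multiplicative
    level-to-level variability of the response (default 5%), applied to
    the analyte amplitude; additive baseline noise follows the config.
    """
    if len(levels) < 2:
        raise ConfigurationError("calibration needs at least 2 levels")
    arr = np.asarray(levels, dtype=float)
    if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
        raise ConfigurationError("levels must be strictly increasing and > 0")
    if is_concentration <= 0:
        raise ConfigurationError("is_concentration must be > 0")
    analyte_t = make_transition(analyte, LIGHT_2PA)
    is_t = make_transition(internal_standard, LIGHT_2PA)
    runs = []
    for i, conc in enumerate(arr):
        key = f"{run_key}|level{i}"
        if area_cv > 0:
            rng = _rng(config.seed, "cal-noise", key, analyte.name)
            scale = max(1.0 + area_cv * rng.standard_normal(), 0.05)
        else:
            scale = 1.0
        runs.append(
            CalibrationRun(
                concentration=float(conc),
                is_concentration=float(is_concentration),
                analyte_trace=simulate_trace(
                    analyte_t, conc, config, None, area_scale=scale, key=key
                ),
                is_trace=simulate_trace(
                    is_t, is_concentration, config, None, key=key
                ),
            )
        )
    return runs


@dataclass(frozen=True)
class GroupStudyDesign:
    """Pooled-sample study layout: 4 mouse groups x 3 sample matrices.

    ``baseline_amounts`` are per-analyte amounts in the reference
    condition; ``fold_change[(group, matrix, analyte)]`` multiplies them
    (default 1), and ``nd_set`` forces the amount to zero (a biological
    non-detect).  Each (group, matrix) cell is measured as
    ``replicates`` technical-replicate differential runs of the pooled
    group sample (heavy channel) against the pooled reference-group
    sample (light channel).  ``group_sizes`` records how many animals
    were pooled per group (metadata only; pooling removes biological
    variance by construction).
    """

    baseline_amounts: Mapping[str, float]
    fold_change: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )
    nd_set: frozenset[tuple[str, str, str]] = frozenset()
    groups: tuple[str, ...] = GROUPS
    matrices: tuple[str, ...] = MATRICES
    replicates: int = 3
    reference_group: str = "SPF"
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"SPF": 4, "GF": 4, "SPF-RF": 3, "GF-RF": 5}
    )

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        if self.reference_group not in self.groups:
            raise ConfigurationError(
                f"reference group {self.reference_group!r} not among groups"
            )
        if any(v < 0 for v in self.fold_change.values()):
            raise ConfigurationError("fold-change multipliers must be >= 0")
        if any(v < 0 for v in self.baseline_amounts.values()):
            raise ConfigurationError("baseline amounts must be >= 0")

    def amount(self, group: str, matrix: str, analyte: str) -> float:
        if (group, matrix, analyte) in self.nd_set:
            return 0.0
        base = self.baseline_amounts.get(analyte, 0.0)
        return base * self.fold_change.get((group, matrix, analyte), 1.0)


@dataclass(frozen=True)
class GroupStudy:
    """Simulated study dataset: per (group, matrix) cell a list of
    technical-replicate differential runs against the reference group."""

    design: GroupStudyDesign
    panel: tuple[Analyte, ...]
    runs: dict[tuple[str, str], list[DifferentialRun]]
    config: SimulationConfig


def simulate_group_study(
    design: GroupStudyDesign,
    panel: Sequence[Analyte],
    config: SimulationConfig,
    *,
    apply_isotope_bias: bool = True,
) -> GroupStudy:
    """Simulate the full 4-group x 3-matrix differential study."""
    runs: dict[tuple[str, str], list[DifferentialRun]] = {}
    for matrix in design.matrices:
        reference = {
            a.name: design.amount(design.reference_group, matrix, a.name)
            for a in panel
        }
        for group in design.groups:
            amounts = {
                a.name: design.amount(group, matrix, a.name) for a in panel
            }
            cell_runs = []
            for rep in range(design.replicates):
                cell_runs.append(
                    simulate_differential_pair(
                        reference,
                        amounts,
                        panel,
                        config,
                        run_key=f"{group}|{matrix}|rep{rep}",
                        apply_isotope_bias=apply_isotope_bias,
                    )
                )
            runs[(group, matrix)] = cell_runs
    return GroupStudy(design, tuple(panel), runs, config)


def default_study_design(panel: Sequence[Analyte]) -> GroupStudyDesign:
    """Bundled study template emulating the qualitative group patterns of
    a germ-free x renal-failure experiment.

    Encoded structure (all configured effects are >= 1.5-fold so they are
    resolvable at technical-triplicate precision):

    * plasma bile acids strongly elevated in SPF-RF, absent in both
      germ-free groups (microbiota-dependent species);
    * SCFAs and the secondary bile acids UDCA/LCA absent in germ-free
      feces and cecal contents;
    * fecal/cecal fatty acids reduced by renal failure and by the
      absence of microbiota, n-3 PUFAs lowest in GF-RF;
    * fecal glycine-conjugated bile acids elevated in germ-free groups
      (no bacterial deconjugation);
    * intestinal indole-3-acetic acid reduced in germ-free groups.
    """
    names = {a.name for a in panel}
    baseline = {a.name: 1.0 for a in panel}
    fold: dict[tuple[str, str, str], float] = {}
    nd: set[tuple[str, str, str]] = set()

    microbiota_bile = [
        "Cholic acid", "Chenodeoxycholic acid", "Deoxycholic acid",
        "b-Muricholic acid", "w-Muricholic acid", "Hyodeoxycholic acid",
    ]
    for name in microbiota_bile:
        fold[("SPF-RF", "plasma", name)] = 5.0
        for group in ("GF", "GF-RF"):
            nd.add((group, "plasma", name))
    for name in ("Ursodeoxycholic acid", "Lithocholic acid",
                 "Propanoic acid", "Butyric acid"):
        for group in ("GF", "GF-RF"):
            for matrix in ("feces", "cecal"):
                nd.add((group, matrix, name))
    for name in ("Glycochenodeoxycholic acid", "Glycodeoxycholic acid",
                 "Glycocholic acid"):
        for group in ("GF", "GF-RF"):
            for matrix in ("feces", "cecal"):
                fold[(group, matrix, name)] = 2.0
    fold[("SPF-RF", "plasma", "Indole-3-acetic acid")] = 3.0
    for group in ("GF", "GF-RF"):
        for matrix in ("feces", "cecal"):
            fold[(group, matrix, "Indole-3-acetic acid")] = 0.3
    for name in ("g-Linolenic acid", "Arachidic acid",
                 "Lignoceric acid", "Nervonic acid"):
        fold[("SPF-RF", "plasma", name)] = 0.5
    for name in ("Lauric acid", "Stearidonic acid", "Eicosapentaenoic acid"):
        fold[("GF", "plasma", name)] = 2.0
    for name in ("Myristic acid", "Oleic acid", "Adrenic acid"):
        fold[("GF", "plasma", name)] = 0.5
    fecal_fa = [
        "Myristic acid", "Oleic acid", "Linoleic acid", "g-Linolenic acid",
        "Arachidic acid", "Dihomo-g-linolenic acid", "Arachidonic acid",
        "Lignoceric acid", "Adrenic acid", "Palmitoleic acid",
    ]
    for name in fecal_fa:
        for matrix in ("feces", "cecal"):
            fold[("SPF-RF", matrix, name)] = 0.5
            fold[("GF", matrix, name)] = 0.4
            fold[("GF-RF", matrix, name)] = 0.25
    n3 = ["Stearidonic acid", "Eicosapentaenoic acid", "a-Linolenic acid",
          "Docosahexaenoic acid", "Docosapentaenoic acid"]
    for name in n3:
        for matrix in ("feces", "cecal"):
            fold[("SPF-RF", matrix, name)] = 0.5
            fold[("GF", matrix, name)] = 0.3
            fold[("GF-RF", matrix, name)] = 0.15
    fold = {k: v for k, v in fold.items() if k[2] in names}
    nd = {k for k in nd if k[2] in names}
    return GroupStudyDesign(
        baseline_amounts=baseline, fold_change=fold, nd_set=frozenset(nd)
    )


def bundled_study_template() -> GroupStudyDesign:
    """The study template shipped with the package (the YAML mirror of
    :func:`default_study_design` on the bundled panel)."""
    from importlib import resources
    import yaml

    text = (
        resources.files("cilquant.data")
        .joinpath("default_study.yaml")
        .read_text(encoding="utf-8")
    )
    return design_from_dict(yaml.safe_load(text))


def design_to_dict(design: GroupStudyDesign) -> dict:
    """JSON/YAML-serializable form of a study design."""
    return {
        "groups": list(design.groups),
        "matrices": list(design.matrices),
        "replicates": design.replicates,
        "reference_group": design.reference_group,
        "group_sizes": dict(design.group_sizes),
        "baseline_amounts": dict(design.baseline_amounts),
        "fold_change": [
            {"group": g, "matrix": m, "analyte": a, "fold": v}
            for (g, m, a), v in sorted(design.fold_change.items())
        ],
        "nd_set": [
            {"group": g, "matrix": m, "analyte": a}
            for (g, m, a) in sorted(design.nd_set)
        ],
    }


def design_from_dict(payload: Mapping) -> GroupStudyDesign:
    """Inverse of :func:`design_to_dict`."""
    try:
        fold = {
            (e["group"], e["matrix"], e["analyte"]): float(e["fold"])
            for e in payload.get("fold_change", [])
        }
        nd = frozenset(
            (e["group"], e["matrix"], e["analyte"])
            for e in payload.get("nd_set", [])
        )
        return GroupStudyDesign(
            baseline_amounts={
                k: float(v)
                for k, v in payload["baseline_amounts"].items()
            },
            fold_change=fold,
            nd_set=nd,
            groups=tuple(payload.get("groups", GROUPS)),
            matrices=tuple(payload.get("matrices", MATRICES)),
            replicates=int(payload.get("replicates", 3)),
            reference_group=payload.get("reference_group", "SPF"),
            group_sizes=payload.get(
                "group_sizes", {"SPF": 4, "GF": 4, "SPF-RF": 3, "GF-RF": 5}
            ),
        )
    except KeyError as exc:
        raise ConfigurationError(f"study design missing field {exc}") from exc
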