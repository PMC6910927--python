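"""Relative and absolute quantification with validation statistics.

Relative quantification summarizes replicate heavy/light peak-area
ratios (the 1:1 mixing design makes the expected ratio the true amount
ratio).  Absolute quantification fits a 1/x-weighted linear calibration
of analyte/internal-standard response ratio versus concentration and
back-calculates unknowns.  Validation metrics follow standard
bioanalytical definitions: precision as RSD of replicate measurements,
accuracy as relative error of spiked recovery
``((found - endogenous) / spiked - 1) x 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import QuantificationError, UsageError
from .peaks import PeakPair


@dataclass(frozen=True)
class RatioSummary:
    """Replicate statistics of the heavy/light area ratio for one
    analyte.  ``n`` counts detected replicates; ``sd`` uses the n-1
    denominator and is ``None`` for n < 2; ``nd`` is set when no
    replicate yielded a ratio."""

    analyte: str
    n: int
    mean: float | None
    sd: float | None
    nd: bool

    def __post_init__(self) -> None:
        if not self.nd:
            if self.n < 1 or self.mean is None or self.mean <= 0:
                raise UsageError("detected summary needs n >= 1 and mean > 0")
            if self.sd is not None and self.n < 2:
                raise UsageError("sd requires n >= 2")


def replicate_ratio_summary(pairs: Sequence[PeakPair]) -> RatioSummary:
    """Mean +/- sample SD over the detected replicate ratios; an
    all-absent set of pairs yields an ND summary."""
    if not pairs:
        raise UsageError("no replicate pairs given")
    analytes = {p.analyte for p in pairs}
    if len(analytes) != 1:
        raise UsageError(f"pairs mix analytes: {sorted(analytes)}")
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    name = analytes.pop()
    if not ratios:
        return RatioSummary(name, 0, None, None, True)
    arr = np.asarray(ratios, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return RatioSummary(name, arr.size, float(arr.mean()), sd, False)


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear fit of response ratio on concentration.

    ``r`` is the unweighted Pearson correlation of the level data.
    Curves fitted from fewer than 5 levels are flagged non-reportable
    but still usable for round-trip checks.
    """

    analyte: str
    levels: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r: float
    weighting: str  # "1/x" | "none"

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def reportable(self) -> bool:
        return self.n_levels >= 5


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    weighting: str = "1/x",
    analyte: str = "",
) -> CalibrationCurve:
    """Fit response ratio ~ concentration by weighted least squares.

    ``weighting="1/x"`` uses weights 1/concentration (down-weighting the
    high end, the standard choice when response variance grows with
    concentration); ``"none"`` is ordinary least squares.
    """
    if weighting not in ("1/x", "none"):
        raise QuantificationError(f"unknown weighting {weighting!r}")
    if len(levels) < 2:
        raise QuantificationError("calibration needs at least 2 levels")
    x = np.asarray([c for c, _ in levels], dtype=float)
    y = np.asarray([r for _, r in levels], dtype=float)
    if np.unique(x).size < 2:
        raise QuantificationError("all concentrations equal; fit is singular")
    if weighting == "1/x" and np.any(x <= 0):
        raise QuantificationError("1/x weighting requires concentrations > 0")
    weights = 1.0 / x if weighting == "1/x" else np.ones_like(x)
    fit = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    intercept, slope = fit.params
    r = float(np.corrcoef(x, y)[0, 1])
    return CalibrationCurve(
        analyte=analyte,
        levels=tuple((float(c), float(v)) for c, v in levels),
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        weighting=weighting,
    )


@dataclass(frozen=True)
class Concentration:
    """Back-calculated concentration; negative extrapolations are
    flagged, never silently clamped."""

    value: float
    below_zero: bool


def quantify_absolute(
    curve: CalibrationCurve, response_ratio: float
) -> Concentration:
    """Invert the calibration line: (ratio - intercept) / slope."""
    if curve.slope == 0:
        raise QuantificationError("calibration slope is zero")
    value = (response_ratio - curve.intercept) / curve.slope
    return Concentration(value=float(value), below_zero=value < 0)


def accuracy_re(found: float, endogenous: float, spiked: float) -> float:
    """Relative error (%) of a spiked-recovery measurement:
    ``((found - endogenous) / spiked - 1) x 100``."""
    if spiked <= 0:
        raise QuantificationError("spiked concentration must be > 0")
    return ((found - endogenous) / spiked - 1.0) * 100.0


def precision_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicate measurements:
    100 x sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UsageError("RSD needs at least 2 measurements")
    mean = arr.mean()
    if mean == 0:
        raise QuantificationError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class GroupRatio:
    """Between-group ratio with propagated uncertainty."""

    ratio: float
    sd: float | None
    status: str = "ok"


def group_ratio_absolute(
    concentrations_g1: Sequence[float], concentrations_g2: Sequence[float]
) -> GroupRatio:
    """Ratio of group means of absolute concentrations (g2 / g1), with
    the group SDs propagated in quadrature on the relative scale."""
    a = np.asarray(concentrations_g1, dtype=float)
    b = np.asarray(concentrations_g2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("both groups must be non-empty")
    if a.mean() == 0:
        raise QuantificationError("denominator group mean is zero")
    ratio = b.mean() / a.mean()
    if a.size >= 2 and b.size >= 2 and b.mean() != 0:
        rel = math.sqrt(
            (a.std(ddof=1) / a.mean()) ** 2 + (b.std(ddof=1) / b.mean()) ** 2
        )
        sd = abs(ratio) * rel
    else:
        sd = None
    return GroupRatio(float(ratio), sd)


def group_ratio_cil(pairs: Sequence[PeakPair]) -> GroupRatio:
    """Between-group ratio from a pooled differential run: the mean
    heavy/light area ratio over the technical replicates.  If no
    replicate yields a ratio the result is absent with the ND reason."""
    if not pairs:
        raise UsageError("no replicate pairs given")
    summary = replicate_ratio_summary(pairs)
    if summary.nd:
        reasons = sorted({p.status for p in pairs if p.status != "ok"})
        return GroupRatio(math.nan, None, status="; ".join(reasons) or "ND")
    return GroupRatio(summary.mean, summary.sd)
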