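"""Group-comparison layer: Student's t-tests, significance tiers, fold
changes with non-detect policy, and host/microbiota pathway
classification of the panel.

Tests are two-sided pooled-variance (equal-variance) Student's t-tests
on technical-replicate measurements of pooled group samples; no
multiple-testing correction is applied in the primary columns, but a
Benjamini-Hochberg q-value column is appended as supplementary output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ClassificationError, ReportError, UsageError
from .transitions import Analyte

DEFAULT_CONTRASTS = (("SPF", "SPF-RF"), ("SPF", "GF"), ("SPF-RF", "GF-RF"))

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

PATHWAY_ORDER = (
    "primary bile acid",
    "secondary bile acid",
    "glycine conjugate",
    "SCFA",
    "SFA",
    "MUFA",
    "n-3 PUFA",
    "n-6 PUFA",
    "indole",
)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool  # zero pooled variance


def students_t_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> TTestResult:
    """Two-sample two-sided pooled-variance Student's t-test.

    Zero pooled variance is degenerate: equal means give p = 1, unequal
    means p = 0 (flagged, with t = 0 or +/- infinity respectively).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UsageError("t-test needs >= 2 values per group")
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, df, True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * math.inf, 0.0, df, True)
    se = math.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), p, df, False)


def significance_stars(p: float) -> str:
    """Figure-caption star tiers: p<0.001 ***, p<0.01 **, p<0.05 *
    (strict inequalities)."""
    if not 0 <= p <= 1:
        raise UsageError(f"p-value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass(frozen=True)
class FoldChange:
    """mean_b / mean_a, or a non-detect status instead of a number:
    ``absent-in-b`` (detected only in a), ``emergent-in-b`` (detected
    only in b), ``absent-both``."""

    value: float | None
    status: str  # "ok" | "absent-in-b" | "emergent-in-b" | "absent-both"


def fold_change(
    mean_a: float | None, mean_b: float | None
) -> FoldChange:
    """Fold change between two group means with ND policy; pass ``None``
    for a non-detected group."""
    if mean_a is None and mean_b is None:
        return FoldChange(None, "absent-both")
    if mean_b is None:
        return FoldChange(None, "absent-in-b")
    if mean_a is None:
        return FoldChange(None, "emergent-in-b")
    if mean_a == 0:
        raise UsageError("detected group mean cannot be zero")
    return FoldChange(mean_b / mean_a, "ok")


@dataclass(frozen=True)
class PathwayClass:
    analyte: str
    origin: str  # "host" | "microbiota" | "mixed"
    pathway_group: str


_BILE_PRIMARY = {"Cholic acid", "Chenodeoxycholic acid"}
_FA_CLASS_MAP = {
    "saturated FA": "SFA",
    "monounsaturated FA": "MUFA",
    "n-3 PUFA": "n-3 PUFA",
    "n-6 PUFA": "n-6 PUFA",
}


def classify_metabolite(analyte: Analyte) -> PathwayClass:
    """Deterministic host/microbiota pathway assignment.

    Cholic and chenodeoxycholic acid are host-liver primary bile acids;
    every other unconjugated bile acid in the panel (deoxycholic,
    lithocholic, urso-/hyodeoxycholic, hyocholic, muricholic species) is
    a microbiota-transformed secondary species; glycine conjugates are
    host conjugation products.  SCFAs and indole-3-acetic acid are
    microbial fermentation products.  Long-chain fatty acids are
    classified by chain class with mixed origin (host synthesis
    modulated by microbial desaturation/elongation and saturation
    metabolism).
    """
    cls = analyte.compound_class
    if cls == "unconjugated bile acid":
        if analyte.name in _BILE_PRIMARY:
            return PathwayClass(analyte.name, "host", "primary bile acid")
        return PathwayClass(analyte.name, "microbiota", "secondary bile acid")
    if cls == "glycine-conjugated bile acid":
        return PathwayClass(analyte.name, "host", "glycine conjugate")
    if cls == "SCFA":
        return PathwayClass(analyte.name, "microbiota", "SCFA")
    if cls == "indole":
        return PathwayClass(analyte.name, "microbiota", "indole")
    if cls in _FA_CLASS_MAP:
        return PathwayClass(analyte.name, "mixed", _FA_CLASS_MAP[cls])
    raise ClassificationError(
        f"no pathway classification for {analyte.name!r} "
        f"(class {cls!r}); extend the registry"
    )


#: measurements: (group, matrix, analyte) -> list of replicate levels,
#: or None / empty list for a non-detected cell.
Measurements = Mapping[tuple[str, str, str], Sequence[float] | None]


def build_comparison_report(
    measurements: Measurements,
    panel: Sequence[Analyte],
    matrices: Sequence[str],
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """One row per analyte x matrix x contrast.

    Columns: pathway/origin, per-group mean and SD, pooled t and p,
    stars, fold change or ND status, and supplementary
    Benjamini-Hochberg q-values (computed across all tested rows; not
    part of the primary analysis).  Rows are ordered by pathway group,
    then analyte name.  A missing (group, matrix) cell for any analyte
    raises :class:`ReportError` naming the cell.
    """
    classes = {a.name: classify_metabolite(a) for a in panel}
    rows = []
    for analyte in panel:
        for matrix in matrices:
            for group_a, group_b in contrasts:
                cell_values = {}
                for group in (group_a, group_b):
                    key = (group, matrix, analyte.name)
                    if key not in measurements:
                        raise ReportError(
                            f"study is missing cell {key}"
                        )
                    vals = measurements[key]
                    cell_values[group] = (
                        None if vals is None or len(vals) == 0
                        else np.asarray(vals, dtype=float)
                    )
                va, vb = cell_values[group_a], cell_values[group_b]
                mean_a = None if va is None else float(va.mean())
                mean_b = None if vb is None else float(vb.mean())
                sd_a = (None if va is None or va.size < 2
                        else float(va.std(ddof=1)))
                sd_b = (None if vb is None or vb.size < 2
                        else float(vb.std(ddof=1)))
                if va is not None and vb is not None:
                    test = students_t_test(va, vb)
                    t_stat, p_val = test.t, test.p
                    stars = significance_stars(test.p)
                else:
                    t_stat, p_val, stars = None, None, ""
                fc = fold_change(mean_a, mean_b)
                cls = classes[analyte.name]
                rows.append(
                    {
                        "analyte": analyte.name,
                        "matrix": matrix,
                        "pathway_group": cls.pathway_group,
                        "origin": cls.origin,
                        "group_a": group_a,
                        "group_b": group_b,
                        "mean_a": mean_a,
                        "sd_a": sd_a,
                        "mean_b": mean_b,
                        "sd_b": sd_b,
                        "t_statistic": t_stat,
                        "p_value": p_val,
                        "stars": stars,
                        "fold_change": fc.value,
                        "nd_status": fc.status,
                    }
                )
    report = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(PATHWAY_ORDER)}
    report = report.sort_values(
        by=["pathway_group", "analyte", "matrix"],
        key=lambda col: (
            col.map(order) if col.name == "pathway_group" else col
        ),
        kind="stable",
    ).reset_index(drop=True)
    tested = report["p_value"].notna()
    qvals = pd.Series(np.nan, index=report.index)
    if tested.any():
        qvals[tested] = multipletests(
            report.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    report["q_value_bh"] = qvals  # supplementary; not part of the t-test layer
    return report
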