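"""SRM transition design for 2-picolylamine (2PA / 2PA-d6) derivatives.

2-picolylamine condenses with a carboxyl group to form an amide (loss of
one water), adding a proton-affinity pyridine moiety for positive ESI.
The heavy reagent 2PA-d6 carries six ring/methylene deuteriums, shifting
the precursor by 6 x (m(D) - m(H)) = 6.0377 Da.  Collision-induced
dissociation cleaves the amide bond, releasing the protonated
picolylamine fragment as the dominant product ion: m/z 109 (light),
m/z 115 (heavy), or m/z 110 when the light derivative of a
carbon-deuterated internal standard transfers a deuteron instead of a
proton during fragmentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import chem
from .chem import Composition
from .errors import ConfigurationError, FormulaError

COMPOUND_CLASSES = frozenset(
    {
        "SCFA",
        "saturated FA",
        "monounsaturated FA",
        "n-3 PUFA",
        "n-6 PUFA",
        "unconjugated bile acid",
        "glycine-conjugated bile acid",
        "indole",
    }
)

#: expected heavy-light precursor spacing (6 H->D substitutions), Da
HEAVY_LIGHT_SHIFT = 6 * chem.H_TO_D_SHIFT


@dataclass(frozen=True)
class Analyte:
    """One member of the carboxyl-metabolite panel.

    ``rt_window`` is the half-width (minutes) of the retention window
    searched for the peak.  ``deuterium_count`` > 0 marks pre-deuterated
    internal standards (e.g. propanoic acid-d5) whose deuteriums sit on
    the carbons alpha to the carboxyl, triggering the [2PA+D]+ product
    ion exception.
    """

    name: str
    formula: Composition
    compound_class: str
    expected_rt: float  # minutes
    rt_window: float = 0.5  # minutes, half-width
    deuterium_count: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("analyte name must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ConfigurationError(
                f"{self.name}: unknown compound class {self.compound_class!r}"
            )
        if self.formula.get("C", 0) < 1 or self.formula.get("O", 0) < 2:
            raise FormulaError(
                f"{self.name}: formula {chem.hill_formula(self.formula)} has no "
                "carboxyl group (needs >=1 C and >=2 O) and cannot be derivatized"
            )
        if self.expected_rt <= 0:
            raise ConfigurationError(f"{self.name}: expected_rt must be > 0")
        if self.rt_window <= 0:
            raise ConfigurationError(f"{self.name}: rt_window must be > 0")
        if self.deuterium_count is None:
            object.__setattr__(self, "deuterium_count", self.formula.get("D", 0))
        n_hd = self.formula.get("H", 0) + self.formula.get("D", 0)
        if not 0 <= self.deuterium_count <= n_hd:
            raise ConfigurationError(
                f"{self.name}: deuterium_count {self.deuterium_count} exceeds "
                f"total H+D count {n_hd}"
            )

    @property
    def monoisotopic_mass(self) -> float:
        return chem.monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class LabelReagent:
    """The amine tag in one of its two isotopic channels."""

    channel: str  # "light" | "heavy"
    formula: Composition
    deuterium_substitutions: int

    def __post_init__(self) -> None:
        if self.channel not in ("light", "heavy"):
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if self.formula.get("D", 0) != self.deuterium_substitutions:
            raise ConfigurationError(
                "deuterium_substitutions must match the D count of the formula"
            )

    @property
    def monoisotopic_mass(self) -> float:
        return chem.monoisotopic_mass(self.formula)


#: 2-picolylamine, C6H8N2
LIGHT_2PA = LabelReagent("light", chem.parse_formula("C6H8N2"), 0)
#: 2-picolylamine-d6 (four ring + two methylene deuteriums; the amine
#: hydrogens exchange back and stay light)
HEAVY_2PA = LabelReagent("heavy", chem.parse_formula("C6H2D6N2"), 6)


@dataclass(frozen=True)
class SRMTransition:
    """One monitored precursor -> product channel.

    ``precursor_mz`` keeps full precision; use :attr:`precursor_mz_reported`
    for the one-decimal table convention.  ``product_mz`` is unit
    resolution.  ``metadata`` carries pass-through instrument settings
    (collision energy, S-lens voltage) when supplied with the panel.
    """

    analyte: Analyte
    channel: str
    precursor_mz: float
    product_mz: int
    expected_rt: float  # minutes
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= self.product_mz:
            raise ConfigurationError(
                f"{self.transition_id}: precursor m/z must exceed product m/z"
            )

    @property
    def name(self) -> str:
        return self.analyte.name

    @property
    def transition_id(self) -> str:
        return f"{self.analyte.name}|{self.channel}"

    @property
    def precursor_mz_reported(self) -> float:
        return chem.round_half_up(self.precursor_mz, 1)


def derivative_composition(analyte: Analyte, label: LabelReagent) -> Composition:
    """Elemental composition of the amide derivative (analyte + tag - H2O)."""
    return chem.formula_subtract(
        chem.formula_add(analyte.formula, label.formula), chem.WATER
    )


def derivative_precursor_mz(analyte: Analyte, label: LabelReagent) -> float:
    """[M+H]+ m/z of the 2PA amide derivative, full precision.

    The condensation removes one water; protonation adds a proton.  For
    the one-decimal reported value apply :func:`chem.round_half_up`.
    """
    return (
        chem.monoisotopic_mass(derivative_composition(analyte, label))
        + chem.PROTON_MASS
    )


def product_ion_mz(label: LabelReagent, analyte: Analyte) -> int:
    """Unit-resolution m/z of the dominant picolylamine product ion.

    The protonated tag fragment gives m/z 109 (light) / 115 (heavy).
    Derivatives of analytes deuterated alpha to the carboxyl transfer a
    deuteron instead, raising the fragment by one mass unit (m/z 110 for
    the light channel of the d5/d7 internal standards).
    """
    charge_carrier = (
        chem.DEUTERON_MASS if analyte.deuterium_count > 0 else chem.PROTON_MASS
    )
    return int(chem.round_half_up(label.monoisotopic_mass + charge_carrier, 0))


def make_transition(analyte: Analyte, label: LabelReagent) -> SRMTransition:
    return SRMTransition(
        analyte=analyte,
        channel=label.channel,
        precursor_mz=derivative_precursor_mz(analyte, label),
        product_mz=product_ion_mz(label, analyte),
        expected_rt=analyte.expected_rt,
    )


def build_transition_table(
    panel: Sequence[Analyte],
    labels: Sequence[LabelReagent] = (LIGHT_2PA, HEAVY_2PA),
) -> list[SRMTransition]:
    """One transition per analyte per channel, ordered by retention time
    then name (light before heavy within an analyte)."""
    if not panel:
        raise ConfigurationError("panel is empty")
    names = [a.name for a in panel]
    duplicates = {n for n in names if names.count(n) > 1}
    if duplicates:
        raise ConfigurationError(f"duplicate analyte names: {sorted(duplicates)}")
    order = {"light": 0, "heavy": 1}
    transitions = [
        make_transition(analyte, label) for analyte in panel for label in labels
    ]
    transitions.sort(key=lambda t: (t.expected_rt, t.name, order[t.channel]))
    return transitions


def read_panel_csv(path: str | Path) -> list[Analyte]:
    """Read a panel definition CSV with header
    ``name,formula,class,rt_min,rt_window_min,deuterium_count``."""
    path = Path(path)
    required = {"name", "formula", "class", "rt_min", "rt_window_min"}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigurationError(
                f"{path}: panel CSV must have columns {sorted(required)}"
            )
        panel = []
        for row in reader:
            deut = row.get("deuterium_count") or None
            panel.append(
                Analyte(
                    name=row["name"].strip(),
                    formula=chem.parse_formula(row["formula"]),
                    compound_class=row["class"].strip(),
                    expected_rt=float(row["rt_min"]),
                    rt_window=float(row["rt_window_min"]),
                    deuterium_count=int(deut) if deut is not None else None,
                )
            )
    return panel


def write_transition_tsv(
    transitions: Iterable[SRMTransition], path: str | Path
) -> None:
    """Export the method table: ``name, channel, precursor_mz, product_mz,
    rt_min`` with one-decimal precursor reporting."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "channel", "precursor_mz", "product_mz", "rt_min"])
        for t in transitions:
            writer.writerow(
                [t.name, t.channel, f"{t.precursor_mz_reported:.1f}",
                 t.product_mz, f"{t.expected_rt:g}"]
            )
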