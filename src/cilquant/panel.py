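"""Bundled carboxyl-metabolite panel and internal standards.

The default registry covers the 40 analytes of the profiling method:
18 bile acids (free and glycine-conjugated), 19 longer-chain fatty acids,
the two short-chain fatty acids propanoic and butyric acid, and
indole-3-acetic acid.  Retention times correspond to the reversed-phase
gradients of the published method and are fixture data, not predictions.

The two pre-deuterated internal standards used for absolute
quantification of the SCFAs (propanoic acid-d5, butyric acid-d7) are
exposed separately: they are spiked at a fixed concentration and always
carry the light tag, so they are not part of the light/heavy panel.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import chem
from .transitions import Analyte, read_panel_csv

_PANEL_RESOURCE = "panel.csv"


def load_default_panel() -> list[Analyte]:
    """The bundled 40-analyte panel, ordered by retention time."""
    with resources.as_file(
        resources.files("cilquant.data").joinpath(_PANEL_RESOURCE)
    ) as path:
        return read_panel_csv(Path(path))


def default_internal_standards() -> list[Analyte]:
    """Carbon-deuterated SCFA internal standards (co-elute with their
    protiated analogues)."""
    return [
        Analyte(
            name="Propanoic acid-d5",
            formula=chem.parse_formula("C3HD5O2"),
            compound_class="SCFA",
            expected_rt=2.5,
            rt_window=0.5,
            deuterium_count=5,
        ),
        Analyte(
            name="Butyric acid-d7",
            formula=chem.parse_formula("C4HD7O2"),
            compound_class="SCFA",
            expected_rt=5.1,
            rt_window=0.5,
            deuterium_count=7,
        ),
    ]


def internal_standard_for(analyte_name: str) -> Analyte:
    """The matching internal standard for an absolute-quantification
    target (currently the two SCFAs)."""
    mapping = {
        "Propanoic acid": "Propanoic acid-d5",
        "Butyric acid": "Butyric acid-d7",
    }
    try:
        is_name = mapping[analyte_name]
    except KeyError:
        raise KeyError(
            f"no bundled internal standard for {analyte_name!r}; "
            f"available for {sorted(mapping)}"
        ) from None
    return next(
        s for s in default_internal_standards() if s.name == is_name
    )
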