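"""Chromatogram serialization: mzML chromatogram lists and a CSV dialect.

SRM data maps naturally onto the mzML ``chromatogramList``: one
chromatogram per transition with id ``"<analyte>|<channel>"``, time in
minutes (converted to seconds in memory) and 64-bit uncompressed binary
arrays.  The CSV dialect ``transition_id,time_s,intensity`` exists for
zero-dependency inspection and stores full-precision decimals so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import base64
import csv
import struct
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import zlib
from lxml import etree

from .errors import FormatError
from .simulate import ChromatogramTrace
from .transitions import SRMTransition

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _transition_index(
    transitions: Iterable[SRMTransition],
) -> dict[str, SRMTransition]:
    return {t.transition_id: t for t in transitions}


def write_chromatograms_csv(
    traces: Sequence[ChromatogramTrace], path: str | Path
) -> None:
    """Write ``transition_id,time_s,intensity`` rows at full precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["transition_id", "time_s", "intensity"])
        for trace in traces:
            for t, y in zip(trace.time, trace.intensity):
                writer.writerow([trace.transition_id, repr(float(t)),
                                 repr(float(y))])


def read_chromatograms_csv(
    path: str | Path, transitions: Iterable[SRMTransition]
) -> list[ChromatogramTrace]:
    """Read the CSV dialect back into traces.

    Unknown transition ids raise :class:`FormatError` listing the known
    candidates; non-monotone time axes are rejected (a truncated or
    shuffled file never loads silently)."""
    path = Path(path)
    index = _transition_index(transitions)
    series: dict[str, tuple[list[float], list[float]]] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != ["transition_id", "time_s", "intensity"]:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: malformed row {row!r}")
            tid, t, y = row
            if tid not in index:
                raise FormatError(
                    f"{path}:{lineno}: unknown transition id {tid!r}; "
                    f"known ids include {sorted(index)[:5]}..."
                )
            if tid not in series:
                series[tid] = ([], [])
                order.append(tid)
            series[tid][0].append(float(t))
            series[tid][1].append(float(y))
    return [_assemble(index[tid], *series[tid], source=path) for tid in order]


def _assemble(
    transition: SRMTransition,
    time: Sequence[float],
    intensity: Sequence[float],
    source: Path,
) -> ChromatogramTrace:
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise FormatError(
            f"{source}: non-monotone or truncated time axis for "
            f"{transition.transition_id!r}"
        )
    try:
        return ChromatogramTrace(transition, t, y)
    except Exception as exc:
        raise FormatError(
            f"{source}: invalid trace for {transition.transition_id!r}: {exc}"
        ) from exc


def _b64(values: np.ndarray) -> str:
    packed = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(packed).decode("ascii")


def _cv(parent, accession, name, **attrs):
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "UO" if accession.startswith("UO:") else "MS")
    el.set("accession", accession)
    el.set("name", name)
    for key, value in attrs.items():
        el.set(key, str(value))
    return el


def write_chromatograms_mzml(
    traces: Sequence[ChromatogramTrace], path: str | Path
) -> None:
    """Write traces as an mzML file with one SRM chromatogram per
    transition (time in minutes, 64-bit float arrays, no compression)."""
    path = Path(path)
    nsmap = {None: _MZML_NS}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="PSI-MS controlled vocabulary",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1001473", "selected reaction monitoring chromatogram")
    sw_list = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(sw_list, "software", id="cilquant", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="cilquant")
    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="cilquant")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = etree.SubElement(
        root, "run", id="cilquant_run", defaultInstrumentConfigurationRef="IC1"
    )
    chrom_list = etree.SubElement(
        run, "chromatogramList", count=str(len(traces)),
        defaultDataProcessingRef="DP1",
    )
    for i, trace in enumerate(traces):
        chrom = etree.SubElement(
            chrom_list, "chromatogram", index=str(i),
            id=trace.transition_id,
            defaultArrayLength=str(trace.time.size),
        )
        _cv(chrom, "MS:1001473", "selected reaction monitoring chromatogram")
        precursor = etree.SubElement(chrom, "precursor")
        iso = etree.SubElement(precursor, "isolationWindow")
        _cv(iso, "MS:1000827", "isolation window target m/z",
            value=f"{trace.transition.precursor_mz:.4f}",
            unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
        product = etree.SubElement(chrom, "product")
        iso_p = etree.SubElement(product, "isolationWindow")
        _cv(iso_p, "MS:1000827", "isolation window target m/z",
            value=f"{trace.transition.product_mz:.1f}",
            unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
        arrays = etree.SubElement(chrom, "binaryDataArrayList", count="2")
        time_minutes = trace.time / 60.0
        for kind, values in (("time", time_minutes),
                             ("intensity", trace.intensity)):
            encoded = _b64(values)
            array = etree.SubElement(
                arrays, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(array, "MS:1000523", "64-bit float")
            _cv(array, "MS:1000576", "no compression")
            if kind == "time":
                _cv(array, "MS:1000595", "time array",
                    unitCvRef="UO", unitAccession="UO:0000031",
                    unitName="minute")
            else:
                _cv(array, "MS:1000515", "intensity array",
                    unitCvRef="MS", unitAccession="MS:1000131",
                    unitName="number of detector counts")
            binary = etree.SubElement(array, "binary")
            binary.text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


def _decode_binary_array(array_el, path: Path) -> tuple[str, np.ndarray]:
    """Decode one ``binaryDataArray``: returns ("time"|"intensity"|"",
    values).  Time arrays are converted to seconds."""
    accessions = {
        cv.get("accession"): cv
        for cv in array_el.findall(f"{{{_MZML_NS}}}cvParam")
    }
    binary_el = array_el.find(f"{{{_MZML_NS}}}binary")
    payload = base64.b64decode((binary_el.text or "").encode("ascii"))
    if "MS:1000574" in accessions:  # zlib compression
        payload = zlib.decompress(payload)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    values = np.frombuffer(payload, dtype=dtype).astype(float)
    if "MS:1000595" in accessions:  # time array
        unit = accessions["MS:1000595"].get("unitName", "minute")
        scale = 60.0 if unit.startswith("minute") else 1.0
        return "time", values * scale
    if "MS:1000515" in accessions:  # intensity array
        return "intensity", values
    return "", values


def read_chromatograms_mzml(
    path: str | Path, transitions: Iterable[SRMTransition]
) -> list[ChromatogramTrace]:
    """Read an mzML chromatogram list written by this package (or any
    producer using the same id convention) back into traces.

    Understands 32/64-bit float arrays, optional zlib compression, and
    time units of minutes or seconds.
    """
    path = Path(path)
    index = _transition_index(transitions)
    traces = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not a parseable mzML file: {exc}") from exc
    for chrom in tree.iter(f"{{{_MZML_NS}}}chromatogram"):
        tid = chrom.get("id")
        if tid == "TIC":
            continue
        if tid not in index:
            raise FormatError(
                f"{path}: unknown transition id {tid!r}; known ids "
                f"include {sorted(index)[:5]}..."
            )
        arrays: dict[str, np.ndarray] = {}
        for array_el in chrom.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            kind, values = _decode_binary_array(array_el, path)
            if kind:
                arrays[kind] = values
        if set(arrays) != {"time", "intensity"}:
            raise FormatError(
                f"{path}: chromatogram {tid!r} lacks time/intensity arrays"
            )
        traces.append(
            _assemble(index[tid], arrays["time"], arrays["intensity"], path)
        )
    return traces


def read_chromatograms(
    path: str | Path,
    transitions: Iterable[SRMTransition],
    fmt: str | None = None,
) -> list[ChromatogramTrace]:
    """Dispatch on ``fmt`` ("mzml" | "csv") or the file extension."""
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    if fmt.lower() == "mzml":
        return read_chromatograms_mzml(path, transitions)
    if fmt.lower() == "csv":
        return read_chromatograms_csv(path, transitions)
    raise FormatError(f"unknown chromatogram format {fmt!r}")
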