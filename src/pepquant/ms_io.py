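"""Reading and writing mass-spectrometry runs and result tables.

Reads centroided mzML 1.1 and mzXML 3.x (optionally gzip-compressed) into
the internal :class:`Spectrum`/:class:`RunData` model via :mod:`pyteomics`,
and writes a minimal, schema-valid plain-mzML dialect sufficient for
round-tripping fixtures (64-bit, zlib-compressed arrays; fileDescription +
run/spectrumList only, not full CV coverage).

Retention times are normalized to seconds on read regardless of the unit
recorded in the source file.  Profile-mode spectra are rejected: all
downstream extracted-ion-chromatogram logic assumes centroids.
"""

from __future__ import annotations

import base64
import gzip
import os
import struct
import zlib
from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

import numpy as np
from lxml import etree
from pyteomics import mzxml as _pmzxml

from .errors import ContractError, FormatError, InputError


@dataclass
class Spectrum:
    """One centroided scan: peak arrays plus acquisition metadata."""

    scan_id: str
    ms_level: int
    rt_seconds: float
    mz_array: np.ndarray
    intensity_array: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    precursor_scan_id: str | None = None

    def validate(self) -> None:
        if self.ms_level not in (1, 2):
            raise ContractError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.rt_seconds < 0:
            raise ContractError("negative retention time")
        if len(self.mz_array) != len(self.intensity_array):
            raise ContractError("mz and intensity arrays differ in length")
        if len(self.mz_array) > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise ContractError(f"mz_array not strictly ascending in {self.scan_id}")
        if np.any(np.asarray(self.intensity_array) < 0):
            raise ContractError("negative intensities")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ContractError(f"MS2 spectrum {self.scan_id} lacks precursor m/z")


@dataclass
class RunData:
    """All spectra of one LC-MS run, ordered by retention time."""

    run_id: str
    spectra: list[Spectrum] = field(default_factory=list)

    def validate(self) -> None:
        rts = [s.rt_seconds for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ContractError("spectra not ordered by retention time")
        for s in self.spectra:
            s.validate()

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def spectrum_by_id(self, scan_id: str) -> Spectrum:
        for s in self.spectra:
            if s.scan_id == scan_id:
                return s
        raise InputError(f"scan {scan_id!r} not found in run {self.run_id!r}")


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _unit_to_seconds(value: float, unit: str | None) -> float:
    if unit in ("minute", "min"):
        return value * 60.0
    if unit in ("hour", "h"):
        return value * 3600.0
    # mzML default when no unit is recorded is seconds
    return value


def _localname(element) -> str:
    tag = element.tag
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _cv_params(element) -> list[dict]:
    return [
        dict(e.attrib)
        for e in element.iter()
        if _localname(e) == "cvParam"
    ]


def _decode_binary_array(bda_element, idx: int) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array name, float array)."""
    dtype = None
    compressed = None
    name = None
    payload = ""
    for child in bda_element.iter():
        ln = _localname(child)
        if ln == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = np.dtype("<f8")
            elif acc == "MS:1000521":
                dtype = np.dtype("<f4")
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000576":
                compressed = False
            elif acc == "MS:1000514":
                name = "mz"
            elif acc == "MS:1000515":
                name = "intensity"
        elif ln == "binary":
            payload = child.text or ""
    if dtype is None or compressed is None or name is None:
        raise FormatError(
            f"spectrum {idx}: binaryDataArray lacks type/compression/name terms"
        )
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return name, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path) -> RunData:
    """Read a (plain or indexed, optionally gzipped) mzML file.

    All MS1/MS2 spectra are loaded; RT is converted to seconds; binary
    arrays are decoded (zlib or uncompressed, 32/64-bit little-endian).
    Profile-mode spectra raise :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    run_id = _strip_ms_suffix(os.path.basename(str(path)))
    spectra: list[Spectrum] = []
    try:
        with _open_maybe_gzip(path) as fh:
            for _event, element in etree.iterparse(fh, events=("end",)):
                if _localname(element) != "spectrum":
                    continue
                spectra.append(_spectrum_from_mzml(element, len(spectra)))
                element.clear(keep_tail=True)
    except (FormatError, InputError):
        raise
    except Exception as exc:  # XML syntax errors, decoding failures ...
        raise FormatError(
            f"malformed mzML {path} (near spectrum {len(spectra)}): {exc}"
        ) from exc
    run = RunData(run_id=run_id, spectra=spectra)
    run.validate()
    return run


def _spectrum_from_mzml(element, idx: int) -> Spectrum:
    ms_level = None
    rt = None
    prec_mz = prec_z = prec_ref = None
    arrays: dict[str, np.ndarray] = {}

    for param in _cv_params(element):
        acc = param.get("accession", "")
        if acc == "MS:1000128":
            raise FormatError(
                f"spectrum {idx} is profile-mode; only centroided data are supported"
            )

    for child in element.iter():
        ln = _localname(child)
        if ln == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value"))
            elif acc == "MS:1000016":
                rt = _unit_to_seconds(
                    float(child.get("value")), child.get("unitName")
                )
            elif acc == "MS:1000744":
                prec_mz = float(child.get("value"))
            elif acc == "MS:1000041":
                prec_z = int(child.get("value"))
        elif ln == "precursor":
            prec_ref = child.get("spectrumRef") or prec_ref
        elif ln == "binaryDataArray":
            name, arr = _decode_binary_array(child, idx)
            arrays[name] = arr

    if rt is None:
        raise FormatError(f"spectrum {idx} lacks a scan start time")
    if ms_level is None:
        raise FormatError(f"spectrum {idx} lacks an ms level term")
    if "mz" not in arrays or "intensity" not in arrays:
        raise FormatError(f"spectrum {idx} lacks m/z or intensity arrays")
    return Spectrum(
        scan_id=element.get("id", f"index={idx}"),
        ms_level=ms_level,
        rt_seconds=rt,
        mz_array=arrays["mz"],
        intensity_array=arrays["intensity"],
        precursor_mz=prec_mz,
        precursor_charge=prec_z,
        precursor_scan_id=prec_ref,
    )


def read_mzxml(path) -> RunData:
    """Read an mzXML 3.x file; same contract as :func:`read_mzml`."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    run_id = _strip_ms_suffix(os.path.basename(str(path)))
    spectra: list[Spectrum] = []
    try:
        with _pmzxml.MzXML(_open_maybe_gzip(path)) as reader:
            for idx, entry in enumerate(reader):
                spectra.append(_spectrum_from_mzxml(entry, idx))
    except (FormatError, InputError):
        raise
    except Exception as exc:
        raise FormatError(
            f"malformed mzXML {path} (near spectrum {len(spectra)}): {exc}"
        ) from exc
    spectra.sort(key=lambda s: s.rt_seconds)
    run = RunData(run_id=run_id, spectra=spectra)
    run.validate()
    return run


def _spectrum_from_mzxml(entry: dict, idx: int) -> Spectrum:
    if int(entry.get("centroided", 1)) == 0:
        raise FormatError(
            f"scan {idx} is profile-mode; only centroided data are supported"
        )
    if "retentionTime" not in entry:
        raise FormatError(f"scan {idx} lacks a retention time")
    rt_value = entry["retentionTime"]
    rt = _unit_to_seconds(float(rt_value), getattr(rt_value, "unit_info", None))
    prec_mz = prec_z = None
    plist = entry.get("precursorMz")
    if plist:
        p = plist[0]
        prec_mz = float(p["precursorMz"])
        if "precursorCharge" in p:
            prec_z = int(p["precursorCharge"])
    return Spectrum(
        scan_id=str(entry["num"]),
        ms_level=int(entry["msLevel"]),
        rt_seconds=rt,
        mz_array=np.asarray(entry["m/z array"], dtype=np.float64),
        intensity_array=np.asarray(entry["intensity array"], dtype=np.float64),
        precursor_mz=prec_mz,
        precursor_charge=prec_z,
    )


def _strip_ms_suffix(name: str) -> str:
    for suffix in (".gz", ".mzML", ".mzml", ".mzXML", ".mzxml"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


# ---------------------------------------------------------------------------
# minimal mzML writer (fixture support)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str | None = None) -> str:
    parts = [
        f'<cvParam cvRef="MS" accession={quoteattr(accession)} '
        f"name={quoteattr(name)} value={quoteattr(value)}"
    ]
    if unit == "second":
        parts.append(
            ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'
        )
    parts.append("/>")
    return "".join(parts)


def write_mzml(run: RunData, path) -> None:
    """Write a RunData as minimal plain mzML 1.1.0.

    Arrays are 64-bit little-endian, zlib-compressed.  The output targets
    round-trip with common readers (fileDescription, run, spectrumList,
    binaryDataArrays), not archival CV completeness.
    """
    run.validate()
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "<cvList count=\"2\">"
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>",
        "<fileDescription><fileContent>"
        + _cv("MS:1000579", "MS1 spectrum")
        + _cv("MS:1000127", "centroid spectrum")
        + "</fileContent></fileDescription>",
        f"<run id={quoteattr(run.run_id)}>",
        f'<spectrumList count="{len(run.spectra)}">',
    ]
    for i, s in enumerate(run.spectra):
        n = len(s.mz_array)
        lines.append(
            f"<spectrum index=\"{i}\" id={quoteattr(s.scan_id)} defaultArrayLength=\"{n}\">"
        )
        lines.append(_cv("MS:1000511", "ms level", str(s.ms_level)))
        lines.append(_cv("MS:1000579" if s.ms_level == 1 else "MS:1000580",
                         "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum"))
        lines.append(_cv("MS:1000127", "centroid spectrum"))
        lines.append(
            "<scanList count=\"1\"><scan>"
            + _cv("MS:1000016", "scan start time", repr(float(s.rt_seconds)), unit="second")
            + "</scan></scanList>"
        )
        if s.ms_level == 2:
            ref = (
                f" spectrumRef={quoteattr(s.precursor_scan_id)}"
                if s.precursor_scan_id
                else ""
            )
            ion = _cv("MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)))
            if s.precursor_charge is not None:
                ion += _cv("MS:1000041", "charge state", str(s.precursor_charge))
            lines.append(
                f'<precursorList count="1"><precursor{ref}>'
                '<selectedIonList count="1"><selectedIon>'
                + ion
                + "</selectedIon></selectedIonList></precursor></precursorList>"
            )
        lines.append('<binaryDataArrayList count="2">')
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz_array),
            ("MS:1000515", "intensity array", s.intensity_array),
        ):
            b64 = _encode_array(arr)
            lines.append(
                f'<binaryDataArray encodedLength="{len(b64)}">'
                + _cv("MS:1000523", "64-bit float")
                + _cv("MS:1000574", "zlib compression")
                + _cv(accession, name)
                + f"<binary>{b64}</binary></binaryDataArray>"
            )
        lines.append("</binaryDataArrayList></spectrum>")
    lines.append("</spectrumList></run></mzML>")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def write_quant_table(table, path) -> None:
    """Write a peptide- or protein-level quantification table as TSV.

    ``table`` is a pandas DataFrame (one row per entity); missing values are
    encoded as "NA".  Numeric cells survive a re-parse to 6 significant
    digits or better.
    """
    try:
        table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
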