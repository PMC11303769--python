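"""Run and spectrum containers plus readers/writers for mzML and an internal
JSON-lines format.

The run model is deliberately small: centroided spectra only, retention times
normalized to seconds on read, MS2 spectra carrying their precursor selection
(m/z, charge, isolation half-width). The mzML reader and writer cover the
PSI-mzML subset this pipeline needs: centroided spectrum lists with 64-bit
m/z and 32-bit intensity arrays, base64-encoded, zlib-compressed or not, scan
start times in seconds or minutes, and precursor isolation windows — no
chromatogram elements, vendor extensions or ion mobility. The internal format
is one JSON object per line — a header record with sample metadata followed
by one record per spectrum — and exists so that test fixtures and simulator
output stay plain text.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from lxml import etree


class RunFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Precursor:
    mz: float
    charge: int | None = None
    isolation_half_width: float = 0.85


@dataclass
class Spectrum:
    scan_id: str
    ms_level: int
    rt: float  # seconds
    mz_array: np.ndarray
    intensity_array: np.ndarray
    precursor: Precursor | None = None

    def __post_init__(self):
        self.mz_array = np.asarray(self.mz_array, dtype=np.float64)
        self.intensity_array = np.asarray(self.intensity_array, dtype=np.float64)
        if self.mz_array.shape != self.intensity_array.shape:
            raise RunFormatError(
                f"scan {self.scan_id}: m/z and intensity arrays differ in length"
            )
        if self.mz_array.size > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise RunFormatError(f"scan {self.scan_id}: m/z array not strictly ascending")
        if np.any(self.intensity_array < 0):
            raise RunFormatError(f"scan {self.scan_id}: negative intensity")
        if self.rt < 0:
            raise RunFormatError(f"scan {self.scan_id}: negative retention time")
        if self.ms_level not in (1, 2):
            raise RunFormatError(f"scan {self.scan_id}: ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor is None:
            raise RunFormatError(f"scan {self.scan_id}: MS2 spectrum lacks precursor")


@dataclass
class Run:
    sample_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise RunFormatError("spectra not ordered by non-decreasing retention time")

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self):
        return len(self.spectra)


# ---------------------------------------------------------------------------
# internal JSON-lines format

def _write_internal(run: Run, path: Path) -> None:
    with open(path, "w") as fh:
        header = {"record": "run", "sample_id": run.sample_id, "metadata": run.metadata}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for s in run.spectra:
            rec = {
                "record": "spectrum",
                "scan_id": s.scan_id,
                "ms_level": s.ms_level,
                "rt": s.rt,
                "mz": [round(x, 6) for x in s.mz_array.tolist()],
                "intensity": [round(float(x), 4) for x in s.intensity_array.tolist()],
            }
            if s.precursor is not None:
                rec["precursor"] = {
                    "mz": s.precursor.mz,
                    "charge": s.precursor.charge,
                    "isolation_half_width": s.precursor.isolation_half_width,
                }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _read_internal(path: Path) -> Run:
    spectra: list[Spectrum] = []
    sample_id = Path(path).stem
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if rec.get("record") == "run":
                sample_id = rec.get("sample_id", sample_id)
                metadata = rec.get("metadata", {})
                continue
            prec = None
            if "precursor" in rec:
                p = rec["precursor"]
                prec = Precursor(p["mz"], p.get("charge"),
                                 p.get("isolation_half_width", 0.85))
            spectra.append(Spectrum(
                scan_id=rec["scan_id"], ms_level=rec["ms_level"], rt=rec["rt"],
                mz_array=np.array(rec["mz"], dtype=np.float64),
                intensity_array=np.array(rec["intensity"], dtype=np.float64),
                precursor=prec,
            ))
    return Run(sample_id=sample_id, spectra=spectra, metadata=metadata)


# ---------------------------------------------------------------------------
# mzML subset

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray, dtype: str) -> str:
    data = np.asarray(values, dtype=dtype).tobytes()
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession, name, value="", unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrs.update({"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]})
    etree.SubElement(parent, "cvParam", attrs)


def _write_mzml(run: Run, path: Path) -> None:
    root = etree.Element("mzML", nsmap={None: _NS},
                         attrib={"version": "1.1.0", "id": run.sample_id})
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(cv_list, "cv", id="MS", fullName="PSI-MS controlled vocabulary",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cv_list, "cv", id="UO", fullName="Unit Ontology",
                     URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")

    slist = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(slist, "software", id="enamelsex", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="enamelsex")

    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="0", softwareRef="enamelsex")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mzml_run = etree.SubElement(root, "run", id=run.sample_id,
                                defaultInstrumentConfigurationRef="IC1")
    spec_list = etree.SubElement(mzml_run, "spectrumList",
                                 count=str(len(run.spectra)),
                                 defaultDataProcessingRef="DP1")
    for idx, s in enumerate(run.spectra):
        spec = etree.SubElement(
            spec_list, "spectrum", index=str(idx),
            id=f"scan={s.scan_id}", defaultArrayLength=str(s.mz_array.size))
        _cv(spec, "MS:1000511", "ms level", value=s.ms_level)
        _cv(spec, "MS:1000579" if s.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(scan, "MS:1000016", "scan start time", value=repr(s.rt),
            unit=("UO:0000010", "second"))
        if s.precursor is not None:
            plist = etree.SubElement(spec, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                value=repr(s.precursor.mz), unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset",
                value=repr(s.precursor.isolation_half_width), unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset",
                value=repr(s.precursor.isolation_half_width), unit=("MS:1000040", "m/z"))
            silist = etree.SubElement(prec, "selectedIonList", count="1")
            si = etree.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", value=repr(s.precursor.mz),
                unit=("MS:1000040", "m/z"))
            if s.precursor.charge is not None:
                _cv(si, "MS:1000041", "charge state", value=s.precursor.charge)
            act = etree.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arrays = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for values, dtype, acc, name in (
            (s.mz_array, "<f8", "MS:1000514", "m/z array"),
            (s.intensity_array, "<f4", "MS:1000515", "intensity array"),
        ):
            encoded = _encode_array(values, dtype)
            arr = etree.SubElement(arrays, "binaryDataArray",
                                   encodedLength=str(len(encoded)))
            _cv(arr, "MS:1000523" if dtype == "<f8" else "MS:1000521",
                "64-bit float" if dtype == "<f8" else "32-bit float")
            _cv(arr, "MS:1000576", "no compression")
            _cv(arr, acc, name,
                unit=("MS:1000040", "m/z") if acc == "MS:1000514"
                else ("MS:1000131", "number of detector counts"))
            binary = etree.SubElement(arr, "binary")
            binary.text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {name, value, unit} for the element's direct cvParam
    children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "name": child.get("name"),
                "value": child.get("value"),
                "unit": child.get("unitName"),
            }
    return out


def _find(elem, *tags):
    """First descendant along a tag path, namespace-agnostic."""
    current = [elem]
    for tag in tags:
        nxt = []
        for e in current:
            nxt.extend(c for c in e if _local(c.tag) == tag)
        current = nxt
        if not current:
            return None
    return current[0]


def _decode_binary_array(array_elem) -> np.ndarray:
    params = _cv_params(array_elem)
    binary = _find(array_elem, "binary")
    data = base64.b64decode((binary.text or "").encode("ascii"))
    if "MS:1000574" in params:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f8" if "MS:1000523" in params else "<f4"
    return np.frombuffer(data, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path) -> Run:
    spectra: list[Spectrum] = []
    for _, spec_elem in etree.iterparse(str(path), tag=f"{{{_NS}}}spectrum"):
        params = _cv_params(spec_elem)
        ms_level = int(params.get("MS:1000511", {}).get("value", 1))
        scan = _find(spec_elem, "scanList", "scan")
        rt_seconds = 0.0
        if scan is not None:
            rt_param = _cv_params(scan).get("MS:1000016")
            if rt_param is not None:
                rt_seconds = float(rt_param["value"])
                if rt_param["unit"] and "min" in rt_param["unit"].lower():
                    rt_seconds *= 60.0
        spec_id = spec_elem.get("id", "")
        scan_id = spec_id.split("scan=")[-1] if "scan=" in spec_id else spec_id

        prec = None
        if ms_level == 2:
            prec_elem = _find(spec_elem, "precursorList", "precursor")
            if prec_elem is None:
                raise RunFormatError(f"scan {scan_id}: MS2 spectrum lacks precursor")
            ion = _find(prec_elem, "selectedIonList", "selectedIon")
            ion_params = _cv_params(ion) if ion is not None else {}
            mz_val = float(ion_params["MS:1000744"]["value"])
            charge_param = ion_params.get("MS:1000041")
            charge = int(charge_param["value"]) if charge_param else None
            iso = _find(prec_elem, "isolationWindow")
            half = 0.85
            if iso is not None:
                lower = _cv_params(iso).get("MS:1000828")
                if lower is not None:
                    half = float(lower["value"])
            prec = Precursor(mz_val, charge, half)

        mz_array = intensity_array = None
        arr_list = _find(spec_elem, "binaryDataArrayList")
        if arr_list is not None:
            for arr in arr_list:
                if _local(arr.tag) != "binaryDataArray":
                    continue
                arr_params = _cv_params(arr)
                values = _decode_binary_array(arr)
                if "MS:1000514" in arr_params:
                    mz_array = values
                elif "MS:1000515" in arr_params:
                    intensity_array = values
        if mz_array is None or intensity_array is None:
            raise RunFormatError(f"scan {scan_id}: missing m/z or intensity array")
        spectra.append(Spectrum(
            scan_id=scan_id, ms_level=ms_level, rt=rt_seconds,
            mz_array=mz_array, intensity_array=intensity_array, precursor=prec))
        spec_elem.clear(keep_tail=True)
    spectra.sort(key=lambda s: s.rt)
    return Run(sample_id=Path(path).stem.replace(".mzML", ""), spectra=spectra)


# ---------------------------------------------------------------------------

RunFormat = Literal["mzml", "internal"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = "".join(Path(path).suffixes).lower()
    return "mzml" if "mzml" in suffix else "internal"


def read_run(path: str | Path, fmt: RunFormat | None = None) -> Run:
    """Read a centroided LC-MS run from mzML or the internal JSON-lines format."""
    path = Path(path)
    if not path.exists():
        raise RunFormatError(f"no such run file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "mzml":
        return _read_mzml(path)
    if fmt == "internal":
        return _read_internal(path)
    raise RunFormatError(f"unknown run format {fmt!r}")


def write_run(run: Run, path: str | Path, fmt: RunFormat | None = None) -> Path:
    """Write a run; read_run(write_run(r)) reproduces r within float tolerance."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mzml":
        _write_mzml(run, path)
    elif fmt == "internal":
        _write_internal(run, path)
    else:
        raise RunFormatError(f"unknown run format {fmt!r}")
    return path
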