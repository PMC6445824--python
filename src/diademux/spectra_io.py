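"""Reading and writing runs of MS/MS spectra with isolation metadata.

Two on-disk formats are supported:

* **mzML 1.1** — the interchange format.  Both directions go through lxml:
  writing emits a minimal standards-conforming document (standard CV terms,
  uncompressed 64-bit binary arrays); reading handles the common subset of
  mzML 1.1 (zlib or uncompressed binary arrays, 32/64-bit floats, isolation
  windows via the standard CV accessions).
* **TSV fixture dialect** — a hermetic plain-text format for tests: one row
  per peak with columns ``scan_index  rt  ms_level  iso_low  iso_high  mz
  intensity`` (tab-separated, header line included).  A spectrum with no
  peaks is one row with empty ``mz``/``intensity`` fields; MS1 spectra have
  empty ``iso_low``/``iso_high``.

Isolation windows are reconstructed from mzML metadata as
``[target - lower_offset, target + upper_offset)``.
"""

from __future__ import annotations

import base64
import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from lxml import etree

from .scheme import IsolationScheme, IsolationWindow

__all__ = ["Spectrum", "Run", "RunFormatError", "read_run", "write_run",
           "assign_cycle_variant"]


class RunFormatError(ValueError):
    """Malformed run file or inconsistent spectrum metadata."""


@dataclass
class Spectrum:
    """One scan: 0-based acquisition index, RT in minutes, centroided peaks."""

    scan_index: int
    rt: float
    ms_level: int
    isolation: Optional[IsolationWindow]
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError(
                f"scan {self.scan_index}: m/z and intensity lengths differ"
            )
        if self.ms_level == 2 and self.isolation is None:
            raise RunFormatError(
                f"MS2 scan {self.scan_index} lacks isolation metadata"
            )
        if np.any(self.intensity < 0):
            raise RunFormatError(f"scan {self.scan_index}: negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            warnings.warn(
                f"scan {self.scan_index}: peaks not sorted by m/z; sorting",
                stacklevel=2,
            )
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def intensity_near(self, mz: float, tol: float) -> float:
        """Summed intensity of peaks within ``mz +/- tol``."""
        lo = np.searchsorted(self.mz, mz - tol, side="left")
        hi = np.searchsorted(self.mz, mz + tol, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    """Time-ordered spectra, optionally tied to the scheme that acquired them."""

    spectra: list[Spectrum]
    scheme: Optional[IsolationScheme] = None

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise RunFormatError("retention time decreases with scan index")

    def __len__(self) -> int:
        return len(self.spectra)

    def ms2_indices(self) -> list[int]:
        return [s.scan_index for s in self.spectra if s.ms_level == 2]

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def by_index(self, scan_index: int) -> Spectrum:
        s = self.spectra[scan_index]
        if s.scan_index != scan_index:  # sparse indices: fall back to search
            for s in self.spectra:
                if s.scan_index == scan_index:
                    return s
            raise KeyError(scan_index)
        return s


def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    return {"": "tsv", ".tsv": "tsv", ".txt": "tsv", ".mzml": "mzml"}.get(
        suffix, "mzml"
    )


def read_run(path: str | Path, format: Optional[str] = None,
             scheme: Optional[IsolationScheme] = None) -> Run:
    """Read a run from mzML or the TSV fixture dialect (inferred from suffix)."""
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path, scheme)
    if fmt == "mzml":
        return _read_mzml(path, scheme)
    raise RunFormatError(f"unknown run format {fmt!r}")


def write_run(run: Run, path: str | Path, format: Optional[str] = None) -> None:
    """Write a run so that :func:`read_run` reproduces it (1e-6 relative)."""
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        _write_tsv(run, path)
    elif fmt == "mzml":
        _write_mzml(run, path)
    else:
        raise RunFormatError(f"unknown run format {fmt!r}")


# ---------------------------------------------------------------- TSV dialect

_TSV_COLUMNS = ["scan_index", "rt", "ms_level", "iso_low", "iso_high", "mz",
                "intensity"]


def _read_tsv(path: str | Path, scheme: Optional[IsolationScheme]) -> Run:
    rows_by_scan: dict[int, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise RunFormatError(f"TSV run missing columns: {sorted(missing)}")
        for row in reader:
            idx = int(row["scan_index"])
            rec = rows_by_scan.setdefault(
                idx,
                {
                    "rt": float(row["rt"]),
                    "ms_level": int(row["ms_level"]),
                    "iso_low": row["iso_low"],
                    "iso_high": row["iso_high"],
                    "mz": [],
                    "intensity": [],
                },
            )
            if row["mz"] not in ("", None):
                rec["mz"].append(float(row["mz"]))
                rec["intensity"].append(float(row["intensity"]))
    spectra = []
    for idx in sorted(rows_by_scan):
        rec = rows_by_scan[idx]
        iso = None
        if rec["iso_low"] not in ("", None):
            iso = IsolationWindow(float(rec["iso_low"]), float(rec["iso_high"]))
        if rec["ms_level"] == 2 and iso is None:
            raise RunFormatError(f"MS2 scan {idx} lacks isolation metadata")
        spectra.append(
            Spectrum(idx, rec["rt"], rec["ms_level"], iso,
                     np.array(rec["mz"]), np.array(rec["intensity"]))
        )
    return Run(spectra, scheme)


def _write_tsv(run: Run, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for s in run.spectra:
            iso_low = f"{s.isolation.low:.6f}" if s.isolation else ""
            iso_high = f"{s.isolation.high:.6f}" if s.isolation else ""
            base = [s.scan_index, f"{s.rt:.8f}", s.ms_level, iso_low, iso_high]
            if s.mz.size == 0:
                writer.writerow(base + ["", ""])
            else:
                for mz, inten in zip(s.mz, s.intensity):
                    writer.writerow(base + [f"{mz:.6f}", f"{inten:.8g}"])


# --------------------------------------------------------------------- mzML

_NS = "http://psi.hupo.org/ms/mzml"


_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_map(elem) -> dict[str, dict]:
    return {
        cv.get("accession"): dict(cv.attrib)
        for cv in elem.iterfind(f"{{{_NS}}}cvParam")
    }


def _decode_binary(array_elem) -> np.ndarray:
    accs = _cv_map(array_elem)
    binary = array_elem.findtext(f"{{{_NS}}}binary") or ""
    raw = base64.b64decode(binary)
    if _ACC_ZLIB in accs:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str | Path, scheme: Optional[IsolationScheme]) -> Run:
    spectra = []
    for i, (_, spec) in enumerate(
        etree.iterparse(str(path), events=("end",), tag=f"{{{_NS}}}spectrum")
    ):
        accs = _cv_map(spec)
        if _ACC_MS_LEVEL not in accs:
            raise RunFormatError(f"spectrum at index {i} lacks an ms level")
        ms_level = int(accs[_ACC_MS_LEVEL]["value"])

        rt = 0.0
        for scan in spec.iterfind(
            f"{{{_NS}}}scanList/{{{_NS}}}scan"
        ):
            scan_accs = _cv_map(scan)
            if _ACC_SCAN_START in scan_accs:
                p = scan_accs[_ACC_SCAN_START]
                rt = float(p["value"])
                if "second" in p.get("unitName", "minute"):
                    rt /= 60.0

        iso = None
        if ms_level >= 2:
            iso_elem = spec.find(
                f"{{{_NS}}}precursorList/{{{_NS}}}precursor/"
                f"{{{_NS}}}isolationWindow"
            )
            iso_accs = _cv_map(iso_elem) if iso_elem is not None else {}
            if not {_ACC_ISO_TARGET, _ACC_ISO_LOWER,
                    _ACC_ISO_UPPER} <= set(iso_accs):
                raise RunFormatError(
                    f"MS2 spectrum at index {i} lacks isolation metadata"
                )
            target = float(iso_accs[_ACC_ISO_TARGET]["value"])
            lower = float(iso_accs[_ACC_ISO_LOWER]["value"])
            upper = float(iso_accs[_ACC_ISO_UPPER]["value"])
            iso = IsolationWindow(target - lower, target + upper)

        mz = intensity = np.empty(0)
        for arr in spec.iterfind(
            f"{{{_NS}}}binaryDataArrayList/{{{_NS}}}binaryDataArray"
        ):
            arr_accs = _cv_map(arr)
            if _ACC_MZ_ARRAY in arr_accs:
                mz = _decode_binary(arr)
            elif _ACC_INT_ARRAY in arr_accs:
                intensity = _decode_binary(arr)
        spectra.append(Spectrum(i, rt, ms_level, iso, mz, intensity))
        spec.clear(keep_tail=True)
    return Run(spectra, scheme)


def _cv(parent, accession, name, value=None, unit=None):
    attrib = {"cvRef": "MS", "accession": accession, "name": name}
    if value is not None:
        attrib["value"] = str(value)
    if unit is not None:
        attrib.update(
            unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
        )
    return etree.SubElement(parent, f"{{{_NS}}}cvParam", attrib)


def _binary_array(parent, data: np.ndarray, accession: str, name: str,
                  unit=None) -> None:
    payload = base64.b64encode(np.ascontiguousarray(data, dtype="<f8")
                               .tobytes()).decode("ascii")
    arr = etree.SubElement(parent, f"{{{_NS}}}binaryDataArray",
                           {"encodedLength": str(len(payload))})
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name, value="", unit=unit)
    etree.SubElement(arr, f"{{{_NS}}}binary").text = payload


def _write_mzml(run: Run, path: str | Path) -> None:
    E = lambda tag, parent, **attrib: etree.SubElement(  # noqa: E731
        parent, f"{{{_NS}}}{tag}", {k: str(v) for k, v in attrib.items()}
    )
    root = etree.Element(f"{{{_NS}}}mzML", {"version": "1.1.0"},
                         nsmap={None: _NS})
    cv_list = E("cvList", root, count=2)
    E("cv", cv_list, id="MS", fullName="Proteomics Standards Initiative Mass "
      "Spectrometry Ontology",
      URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    E("cv", cv_list, id="UO", fullName="Unit Ontology",
      URI="https://raw.githubusercontent.com/bio-ontology-research-group/"
          "unit-ontology/master/unit.obo")
    fdesc = E("fileDescription", root)
    fcontent = E("fileContent", fdesc)
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    slist = E("softwareList", root, count=1)
    sw = E("software", slist, id="diademux", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="diademux")
    icl = E("instrumentConfigurationList", root, count=1)
    ic = E("instrumentConfiguration", icl, id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = E("dataProcessingList", root, count=1)
    dp = E("dataProcessing", dpl, id="dp1")
    pm = E("processingMethod", dp, order=0, softwareRef="diademux")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run_el = E("run", root, id="run", defaultInstrumentConfigurationRef="IC1")
    spec_list = E("spectrumList", run_el, count=len(run.spectra),
                  defaultDataProcessingRef="dp1")
    for i, s in enumerate(run.spectra):
        spec = E("spectrum", spec_list, index=i, id=f"scan={s.scan_index}",
                 defaultArrayLength=s.mz.size)
        _cv(spec, "MS:1000511", "ms level", value=s.ms_level)
        if s.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = E("scanList", spec, count=1)
        _cv(scan_list, "MS:1000795", "no combination")
        scan = E("scan", scan_list)
        _cv(scan, "MS:1000016", "scan start time", value=f"{s.rt:.10g}",
            unit=("UO:0000031", "minute"))
        if s.isolation is not None:
            plist = E("precursorList", spec, count=1)
            prec = E("precursor", plist)
            iso = E("isolationWindow", prec)
            target = s.isolation.center
            _cv(iso, "MS:1000827", "isolation window target m/z",
                value=f"{target:.10g}", unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset",
                value=f"{target - s.isolation.low:.10g}",
                unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset",
                value=f"{s.isolation.high - target:.10g}",
                unit=("MS:1000040", "m/z"))
            ions = E("selectedIonList", prec, count=1)
            ion = E("selectedIon", ions)
            _cv(ion, "MS:1000744", "selected ion m/z", value=f"{target:.10g}",
                unit=("MS:1000040", "m/z"))
            act = E("activation", prec)
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        arrays = E("binaryDataArrayList", spec, count=2)
        _binary_array(arrays, s.mz, "MS:1000514", "m/z array",
                      unit=("MS:1000040", "m/z"))
        _binary_array(arrays, s.intensity, "MS:1000515", "intensity array",
                      unit=("MS:1000131", "number of detector counts"))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


# ---------------------------------------------------------- variant labeling

def assign_cycle_variant(
    run: Run, scheme: IsolationScheme, tol: float = 0.01
) -> dict[int, int]:
    """Map each MS2 scan index to the scheme cycle variant that acquired it.

    Purely a function of the recorded isolation window (never scan parity,
    so dropped scans cannot shift the labeling).  A window matching no
    variant, or more than one, is a labeling error.
    """
    labels: dict[int, int] = {}
    for s in run.spectra:
        if s.ms_level != 2:
            continue
        hits = scheme.find_window(s.isolation, tol)
        variant_ids = {v for v, _ in hits}
        if len(variant_ids) != 1:
            raise RunFormatError(
                f"scan {s.scan_index}: isolation window "
                f"[{s.isolation.low},{s.isolation.high}) matches "
                f"{len(variant_ids)} scheme variants (expected exactly 1)"
            )
        labels[s.scan_index] = variant_ids.pop()
    return labels
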