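"""Reading and writing centroided MS/MS spectra: MGF, mzML (read), MSP.

Only positive-mode, singly protonated precursors are assumed throughout
(missing CHARGE in MGF is read as 1+).  Intensities are stored exactly as
given; nothing is normalized at I/O time.  All paths transparently accept
gzip-compressed files.
"""

from __future__ import annotations

import base64
import gzip
import struct
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence
from xml.etree import ElementTree

import numpy as np
from pyteomics import mgf as _pt_mgf

__all__ = ["Spectrum", "LibraryRecord", "read_spectra", "write_mgf", "write_msp"]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum with its selected precursor.

    Peaks are kept as parallel numpy arrays sorted ascending by m/z; the
    constructor enforces the sort and rejects negative intensities.
    """

    precursor_mz: float
    mz: np.ndarray
    intensities: np.ndarray
    charge: int = 1
    identifier: str = ""
    source_file: str = ""
    scan: int | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensities must be matching 1-D arrays")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", inten[order])

    def __len__(self) -> int:
        return self.mz.size

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensities.max()) if len(self) else 0.0

    def with_identifier(self, identifier: str) -> "Spectrum":
        return replace(self, identifier=identifier)


@dataclass(frozen=True)
class LibraryRecord:
    """An annotated (consensus) spectrum destined for the spectral library."""

    spectrum: Spectrum
    annotation: str
    adduct: str = "[M+H]+"
    provenance: tuple[str, ...] = ()
    n_observations: int = 1


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_mgf(path: str | Path) -> Iterator[Spectrum]:
    source = str(path)
    with _open_maybe_gzip(path) as fh:
        reader = _pt_mgf.MGF(fh, convert_arrays=1)
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            try:
                pepmass = params["pepmass"]
                prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"malformed MGF entry {i} in {source}: missing/invalid PEPMASS"
                ) from exc
            charge_param = params.get("charge")
            charge = int(charge_param[0]) if charge_param else 1
            title = str(params.get("title", "")) or f"{source}::index{i}"
            scans = params.get("scans")
            yield Spectrum(
                precursor_mz=prec,
                mz=entry.get("m/z array", np.empty(0)),
                intensities=entry.get("intensity array", np.empty(0)),
                charge=charge,
                identifier=title,
                source_file=source,
                scan=int(scans) if scans is not None else None,
            )


# Minimal streaming mzML reader (MS2 scans only).  CV accessions handled:
# ms level (MS:1000511), selected ion m/z (MS:1000744), charge state
# (MS:1000041), m/z / intensity arrays (MS:1000514/5), 64-/32-bit float
# (MS:1000523/1000521), zlib / no compression (MS:1000574/1000576).

def _decode_binary_array(node: ElementTree.Element, ns: str) -> np.ndarray:
    accessions = {
        cv.get("accession") for cv in node.iter(f"{ns}cvParam")
    }
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    width, code = (4, "f") if "MS:1000521" in accessions else (8, "d")
    count = len(raw) // width
    return np.asarray(struct.unpack(f"<{count}{code}", raw[: count * width]))


def _iter_mzml(path: str | Path) -> Iterator[Spectrum]:
    source = str(path)
    n_ms2 = 0
    with _open_maybe_gzip(path, "rb") as fh:
        for _, elem in ElementTree.iterparse(fh, events=("end",)):
            tag = elem.tag
            ns = tag[: tag.rfind("}") + 1] if tag.startswith("{") else ""
            if tag != f"{ns}spectrum":
                continue
            params = {
                cv.get("accession"): cv.get("value")
                for cv in elem.findall(f"{ns}cvParam")
            }
            if params.get("MS:1000511") != "2":
                elem.clear()
                continue
            n_ms2 += 1
            ident = str(elem.get("id", ""))
            prec = charge = None
            for ion in elem.iter(f"{ns}selectedIon"):
                for cv in ion.iter(f"{ns}cvParam"):
                    if cv.get("accession") == "MS:1000744":
                        prec = float(cv.get("value"))
                    elif cv.get("accession") == "MS:1000041":
                        charge = int(cv.get("value"))
            if prec is None:
                raise ValueError(f"malformed mzML MS2 scan {ident!r} in {source}")
            mz = inten = np.empty(0)
            for arr in elem.iter(f"{ns}binaryDataArray"):
                accs = {cv.get("accession") for cv in arr.iter(f"{ns}cvParam")}
                if "MS:1000514" in accs:
                    mz = _decode_binary_array(arr, ns)
                elif "MS:1000515" in accs:
                    inten = _decode_binary_array(arr, ns)
            scan = None
            for tok in ident.split():
                if tok.startswith("scan="):
                    scan = int(tok[5:])
            yield Spectrum(
                precursor_mz=prec,
                mz=mz,
                intensities=inten,
                charge=charge if charge is not None else 1,
                identifier=f"{source}::{ident}" if ident else f"{source}::index",
                source_file=source,
                scan=scan,
            )
            elem.clear()
    if n_ms2 == 0:
        warnings.warn(f"no MS2 scans in {source}", stacklevel=2)


def read_spectra(path: str | Path, format: str | None = None) -> Iterator[Spectrum]:
    """Stream spectra from an MGF or mzML file (MS level 2 only for mzML).

    ``format`` is inferred from the file extension when not given.
    """
    path = Path(path)
    if format is None:
        suffixes = [s.lower() for s in path.suffixes]
        if ".mgf" in suffixes:
            format = "MGF"
        elif ".mzml" in suffixes:
            format = "mzML"
        else:
            raise ValueError(f"cannot infer spectrum format from {path.name!r}")
    fmt = format.lower()
    if fmt == "mgf":
        return _iter_mgf(path)
    if fmt == "mzml":
        return _iter_mzml(path)
    raise ValueError(f"unsupported spectrum format {format!r}")


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as Mascot generic format blocks (PEPMASS/CHARGE/TITLE)."""
    with _open_maybe_gzip(path, "wt") as fh:
        for i, s in enumerate(spectra):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier or f'index{i}'}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            if s.scan is not None:
                fh.write(f"SCANS={s.scan}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz:.6f} {inten:.6g}\n")
            fh.write("END IONS\n")


def write_msp(records: Iterable[LibraryRecord], path: str | Path) -> None:
    """Write library records as NIST MSP text blocks.

    ``Name`` is the candidate display name (``head-Cn:d``), so annotations
    round-trip through the library file.
    """
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            if not rec.annotation:
                raise ValueError("library record lacks an annotation")
            s = rec.spectrum
            fh.write(f"Name: {rec.annotation}\n")
            fh.write(f"PrecursorMZ: {s.precursor_mz:.6f}\n")
            fh.write(f"Precursor_type: {rec.adduct}\n")
            if rec.provenance:
                fh.write(f"Comments: provenance={','.join(rec.provenance)}\n")
            fh.write(f"Num Peaks: {len(s)}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz:.6f} {inten:.6g}\n")
            fh.write("\n")
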