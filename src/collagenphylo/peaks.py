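"""Centroided MALDI-ToF peak lists: container and file I/O.

Supported formats: two-column text (m/z, intensity; TSV or whitespace),
mzML and mzXML (centroided spectra only, via pyteomics).  A minimal mzML
writer is provided so synthetic spectra can be round-tripped through the
standard format in tests and demonstrations.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class PeakList:
    """A centroided spectrum: (m/z, intensity) pairs sorted by m/z."""

    sample_id: str
    peaks: list[tuple[float, float]]
    site: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mz, inten in self.peaks:
            if inten < 0:
                raise ValueError(f"{self.sample_id}: negative intensity at m/z {mz}")
        self.peaks = sorted(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def base_peak_intensity(self) -> float:
        return max((p[1] for p in self.peaks), default=0.0)

    def __len__(self) -> int:
        return len(self.peaks)


def _read_tsv(path: Path, sample_id: str) -> PeakList:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'mz intensity', got {line!r}")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric peak {line!r}") from None
            peaks.append((mz, inten))
    if not peaks:
        raise ValueError(f"{path}: no peaks found (empty file?)")
    return PeakList(sample_id=sample_id, peaks=peaks)


def _spectrum_to_peaklist(spec: dict, sample_id: str, path: Path) -> PeakList:
    if int(spec.get("ms level", spec.get("msLevel", 1))) != 1:
        raise ValueError(f"{path}: not an MS1 spectrum")
    # Reject profile-mode data: we do not implement peak picking.
    if "profile spectrum" in spec:
        raise ValueError(
            f"{path}: profile-mode spectrum; centroid the data before loading"
        )
    mz = np.asarray(spec["m/z array"], dtype=float)
    inten = np.asarray(spec["intensity array"], dtype=float)
    return PeakList(sample_id=sample_id, peaks=list(zip(mz.tolist(), inten.tolist())))


def read_peaklist(path: str | Path, format: str | None = None, sample_id: str | None = None) -> PeakList:
    """Read a centroided peak list from TSV, mzML or mzXML.

    The format is inferred from the extension when not given.  Only the first
    spectrum of an mzML/mzXML file is read (ZooMS stores one fingerprint per
    file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "tsv", "mzml": "mzml", "mzxml": "mzxml"}.get(
            suffix, "tsv"
        )
    sid = sample_id or path.stem
    if format == "tsv":
        return _read_tsv(path, sid)
    if format == "mzml":
        return _read_mzml(path, sid)
    if format == "mzxml":
        from pyteomics import mzxml

        with mzxml.read(str(path)) as reader:
            for spec in reader:
                return _spectrum_to_peaklist(spec, sid, path)
        raise ValueError(f"{path}: mzXML file contains no spectra")
    raise ValueError(f"unknown peak-list format {format!r}")


def write_peaklist_tsv(pl: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in pl.peaks:
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def _decode_binary(binary_el, n: int) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or none)."""
    accessions = {
        cv.get("accession") for cv in binary_el.findall("{*}cvParam")
    }
    data = base64.b64decode((binary_el.findtext("{*}binary") or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(data, dtype=dtype)
    if n and len(arr) != n:
        raise ValueError(f"binary array length {len(arr)} != defaultArrayLength {n}")
    return arr.astype(float)


def _read_mzml(path: Path, sample_id: str) -> PeakList:
    """Minimal mzML reader for centroided MS1 peak lists.

    Understands the controlled-vocabulary terms needed for ZooMS exports:
    ms level, centroid/profile flag, 32/64-bit float arrays, zlib or no
    compression.  Profile-mode spectra are rejected (no peak picking here).
    """
    from lxml import etree

    tree = etree.parse(str(path))
    spectra = tree.findall(".//{*}spectrum")
    if not spectra:
        raise ValueError(f"{path}: mzML file contains no spectra")
    spec = spectra[0]
    accessions = {cv.get("accession"): cv.get("value") for cv in spec.findall("{*}cvParam")}
    if "MS:1000128" in accessions:
        raise ValueError(f"{path}: profile-mode spectrum; centroid the data before loading")
    if accessions.get("MS:1000511") not in (None, "1"):
        raise ValueError(f"{path}: first spectrum is not MS1")
    n = int(spec.get("defaultArrayLength", 0))
    mz = inten = None
    for bda in spec.findall(".//{*}binaryDataArray"):
        accs = {cv.get("accession") for cv in bda.findall("{*}cvParam")}
        if "MS:1000514" in accs:
            mz = _decode_binary(bda, n)
        elif "MS:1000515" in accs:
            inten = _decode_binary(bda, n)
    if mz is None or inten is None:
        raise ValueError(f"{path}: spectrum lacks m/z or intensity arrays")
    return PeakList(sample_id=sample_id, peaks=list(zip(mz.tolist(), inten.tolist())))


_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def _encode_doubles(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_peaklist_mzml(pl: PeakList, path: str | Path) -> None:
    """Write a single-spectrum centroided mzML file (uncompressed 64-bit)."""
    mz_b64 = _encode_doubles([p[0] for p in pl.peaks])
    int_b64 = _encode_doubles([p[1] for p in pl.peaks])
    Path(path).write_text(
        _MZML_TEMPLATE.format(
            run_id=pl.sample_id,
            n=len(pl.peaks),
            mz_len=len(mz_b64),
            mz_b64=mz_b64,
            int_len=len(int_b64),
            int_b64=int_b64,
        )
    )
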