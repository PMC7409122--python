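"""Acquisition serialization: JSON-lines format and an mzML reader.

The native on-disk format is one JSON object per scan::

    {"drift_bin": 12, "mz": [185.1025, ...], "intensity": [41.2, ...]}

with a sidecar ``<stem>.meta.json`` carrying the sample record, the
instrument snapshot, the drift-time axis and the seed.  The round trip
is lossless.

The optional mzML reader ingests centroided spectra whose scans carry an
ion-mobility drift-time attribute ("ion mobility drift time", ms) and
maps them onto the same Acquisition contract; spectra without the
attribute are skipped with a log message, and a file where *no* spectrum
has it is a format error.  The reader is a lightweight lxml-based
implementation covering the subset of mzML this pipeline consumes
(centroided m/z + intensity arrays, 32/64-bit floats, no or zlib
compression).
"""

from __future__ import annotations

import base64
import json
import logging
import zlib as _zlib
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import Acquisition, Scan

__all__ = [
    "write_acquisition",
    "read_acquisition",
    "write_acquisitions",
    "read_acquisitions",
    "read_acquisition_mzml",
    "AcquisitionFormatError",
]

logger = logging.getLogger(__name__)

DRIFT_TIME_KEY = "ion mobility drift time"


class AcquisitionFormatError(ValueError):
    """Raised for malformed acquisition files."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_acquisition(acq: Acquisition, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for scan in acq.scans:
            fh.write(
                json.dumps(
                    {
                        "drift_bin": int(scan.drift_bin),
                        "mz": [float(v) for v in scan.mz],
                        "intensity": [float(v) for v in scan.intensity],
                    }
                )
            )
            fh.write("\n")
    meta = dict(acq.metadata)
    meta["dt_centers"] = [float(v) for v in acq.dt_centers]
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_acquisition(path: str | Path) -> Acquisition:
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise AcquisitionFormatError(f"missing sidecar metadata file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    dt_centers = np.asarray(meta.pop("dt_centers"), dtype=float)
    scans = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                scans.append(
                    Scan(
                        drift_bin=int(obj["drift_bin"]),
                        mz=np.asarray(obj["mz"], dtype=float),
                        intensity=np.asarray(obj["intensity"], dtype=float),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise AcquisitionFormatError(
                    f"{path}: malformed scan on line {lineno}: {exc}"
                ) from exc
    return Acquisition.from_scans(scans, dt_centers=dt_centers, metadata=meta)


def write_acquisitions(acqs: Sequence[Acquisition], directory: str | Path) -> list[Path]:
    """One ``<sample_id>.jsonl`` (+ sidecar) per acquisition."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for acq in acqs:
        sample_id = acq.metadata.get("sample", {}).get("sample_id", f"acq{len(paths)}")
        p = directory / f"{sample_id}.jsonl"
        write_acquisition(acq, p)
        paths.append(p)
    return paths


def read_acquisitions(directory: str | Path) -> list[Acquisition]:
    directory = Path(directory)
    return [read_acquisition(p) for p in sorted(directory.glob("*.jsonl"))]


_ACCESSION_DRIFT_TIME = "MS:1002476"
_ACCESSION_F64 = "MS:1000523"
_ACCESSION_F32 = "MS:1000521"
_ACCESSION_ZLIB = "MS:1000574"
_ACCESSION_MZ_ARRAY = "MS:1000514"
_ACCESSION_INTENSITY_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, str]:
    """accession -> value for all cvParam descendants (name used as fallback key)."""
    params = {}
    for cv in element.iter():
        if _local(cv.tag) == "cvParam":
            key = cv.get("accession") or cv.get("name")
            params[key] = cv.get("value", "")
            if cv.get("name"):
                params.setdefault(cv.get("name"), cv.get("value", ""))
    return params


def _decode_binary_array(bda) -> np.ndarray | None:
    params = _cv_params(bda)
    text = None
    for child in bda:
        if _local(child.tag) == "binary":
            text = child.text or ""
    if text is None:
        return None
    data = base64.b64decode(text)
    if _ACCESSION_ZLIB in params:
        data = _zlib.decompress(data)
    dtype = np.float64 if _ACCESSION_F64 in params else np.float32
    return np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum(spectrum):
    """(drift_time | None, mz array, intensity array) for one <spectrum>."""
    drift_time = None
    mz = inten = None
    for el in spectrum.iter():
        tag = _local(el.tag)
        if tag == "scan":
            params = _cv_params(el)
            value = params.get(_ACCESSION_DRIFT_TIME, params.get(DRIFT_TIME_KEY))
            if value not in (None, ""):
                drift_time = float(value)
        elif tag == "binaryDataArray":
            params = _cv_params(el)
            arr = _decode_binary_array(el)
            if arr is None:
                continue
            if _ACCESSION_MZ_ARRAY in params or "m/z array" in params:
                mz = arr
            elif _ACCESSION_INTENSITY_ARRAY in params or "intensity array" in params:
                inten = arr
    if mz is None:
        mz = np.empty(0)
    if inten is None:
        inten = np.zeros_like(mz)
    return drift_time, mz, inten


def read_acquisition_mzml(path: str | Path, metadata: dict | None = None) -> Acquisition:
    """Read one spot acquisition from an mzML file with ion-mobility scans.

    Each spectrum carrying a drift-time attribute becomes one scan; the
    drift-time axis is the sorted set of observed drift times.
    """
    from lxml import etree

    path = Path(path)
    raw: list[tuple[float, np.ndarray, np.ndarray]] = []
    n_spectra = 0
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        n_spectra += 1
        dt, mz, inten = _parse_spectrum(spectrum)
        if dt is None:
            logger.info("%s: spectrum %s lacks %r; skipped",
                        path.name, spectrum.get("id"), DRIFT_TIME_KEY)
        else:
            raw.append((dt, mz, inten))
        spectrum.clear(keep_tail=True)
    if not raw:
        raise AcquisitionFormatError(
            f"{path}: no spectrum carries the {DRIFT_TIME_KEY!r} attribute "
            f"({n_spectra} spectra read)"
        )
    dt_values = np.array(sorted({dt for dt, _, _ in raw}))
    bin_of = {dt: i for i, dt in enumerate(dt_values)}
    scans = [Scan(drift_bin=bin_of[dt], mz=mz, intensity=inten) for dt, mz, inten in raw]
    meta = dict(metadata or {})
    meta.setdefault("source", str(path))
    return Acquisition.from_scans(scans, dt_centers=dt_values, metadata=meta)
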