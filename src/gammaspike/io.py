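"""Readers and writers for recordings, annotations and detections.

Recordings: EDF (read-only, via mne) or CSV.  Annotations and detections:
CSV with ``#``-prefixed header lines carrying metadata (``# key=value``),
comma-separated data rows.  Detections round-trip through
:func:`read_annotations` losslessly for center and amplitude.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .records import (
    AnnotationEvent,
    AnnotationSet,
    DetectionEvent,
    DetectionResult,
    ECoGRecord,
    seconds_to_sample,
)

logger = logging.getLogger(__name__)

#: Tolerance on CSV time-column uniformity, seconds.
TIME_UNIFORMITY_TOL_S = 1e-6


def _parse_header(path: Path) -> tuple[dict[str, str], list[str]]:
    """Split a CSV file into ``# key=value`` metadata and data lines."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    return meta, rows


def read_record(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
) -> ECoGRecord:
    """Read a single-channel recording from EDF or CSV.

    CSV files carry either two columns (time s, amplitude μV) or one
    amplitude column with the sampling rate in a ``# fs=...`` header line
    (or the ``fs`` argument).  EDF files use the declared channel rate; the
    first channel is taken.

    Raises
    ------
    OSError
        Unreadable or missing file.
    ValueError
        Malformed content, e.g. a non-uniform time column.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path, subject_id)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    meta, rows = _parse_header(path)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.array(
        [[float(v) for v in r.split(",")] for r in rows], dtype=float
    )
    if data.shape[1] >= 2:
        t, x = data[:, 0], data[:, 1]
        dts = np.diff(t)
        if len(dts) == 0:
            raise ValueError(f"{path}: need at least two samples")
        dt = np.median(dts)
        if dt <= 0 or np.any(np.abs(dts - dt) > TIME_UNIFORMITY_TOL_S):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        fs_file = 1.0 / dt
    else:
        x = data[:, 0]
        if fs is None and "fs" in meta:
            fs = float(meta["fs"])
        if fs is None:
            raise ValueError(
                f"{path}: single-column CSV needs fs in header or argument"
            )
        fs_file = float(fs)
    if fs is not None and abs(fs_file - fs) > 1e-6 * fs:
        logger.warning(
            "%s: file sampling rate %.6g overrides requested %.6g", path, fs_file, fs
        )
    return ECoGRecord(
        samples=x,
        fs=float(meta.get("fs", fs_file)),
        subject_id=subject_id or meta.get("subject_id", path.stem),
        t0_offset_min=float(meta.get("t0_offset_min", 0.0)),
    )


def _read_edf(path: Path, subject_id: str | None) -> ECoGRecord:
    import mne  # EDF reader lives in mne-base; imported lazily

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0]
    # mne rescales EEG-typed channels to volts; recordings here are μV
    if np.max(np.abs(data)) < 1e-2:
        data = data * 1e6
    return ECoGRecord(
        samples=data,
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id or path.stem,
    )


def read_annotations(
    path: str | Path,
    fs: float | None = None,
    n_record_samples: int | None = None,
) -> AnnotationSet:
    """Read expert annotations (or previously written detections).

    Expected columns: center, amplitude, label (label optional, defaults to
    ``spike``); extra columns are ignored.  The ``# units=`` header declares
    whether centers are ``samples`` (default) or ``seconds``; seconds are
    converted by rounding to the nearest sample using ``# fs=`` or the
    ``fs`` argument.
    """
    path = Path(path)
    meta, rows = _parse_header(path)
    units = meta.get("units", "samples")
    fs_eff = float(meta.get("fs", fs if fs is not None else 1024.0))
    events = []
    for row in rows:
        parts = [p.strip() for p in row.split(",")]
        if parts and parts[0].lower() in ("center", "center_sample", "center_s"):
            continue  # optional column-name line
        center_raw = float(parts[0])
        amplitude = float(parts[1]) if len(parts) > 1 else float("nan")
        label = parts[2] if len(parts) > 2 and parts[2] else "spike"
        if units == "seconds":
            center = int(seconds_to_sample(center_raw, fs_eff))
        else:
            center = int(round(center_raw))
        events.append(AnnotationEvent(center, amplitude, label))
    return AnnotationSet.from_events(
        events,
        record_id=meta.get("record_id", path.stem),
        n_record_samples=n_record_samples,
    )


def write_annotations(annotations: AnnotationSet, path: str | Path, fs: float = 1024.0) -> None:
    """Write an annotation set as a detections-compatible CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units=samples\n")
        fh.write(f"# fs={fs:g}\n")
        fh.write(f"# record_id={annotations.record_id}\n")
        fh.write("# columns=center_sample,peak_amplitude_uV,label\n")
        for e in annotations:
            fh.write(f"{e.center_sample},{float(e.peak_amplitude)!r},{e.label}\n")


def write_detections(result: DetectionResult, path: str | Path) -> None:
    """Write detector output as CSV.

    The header records the sampling rate, both thresholds and the band so a
    detection file is self-describing; data rows are
    ``center_sample,peak_amplitude_uV,label,duration_ms``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units=samples\n")
        fh.write(f"# fs={result.fs:g}\n")
        fh.write(f"# lambda1={float(result.lambda1)!r}\n")
        fh.write(f"# lambda2={float(result.lambda2)!r}\n")
        fh.write(f"# band={result.band[0]:g}:{result.band[1]:g}\n")
        fh.write("# columns=center_sample,peak_amplitude_uV,label,duration_ms\n")
        for e in result.events:
            fh.write(f"{e.center_sample},{float(e.peak_amplitude)!r},spike,{float(e.duration_ms)!r}\n")


def read_detections(path: str | Path) -> DetectionResult:
    """Read a detections CSV written by :func:`write_detections`."""
    path = Path(path)
    meta, rows = _parse_header(path)
    events = []
    for row in rows:
        parts = [p.strip() for p in row.split(",")]
        if parts and parts[0].lower().startswith("center"):
            continue
        duration = float(parts[3]) if len(parts) > 3 else 0.0
        events.append(DetectionEvent(int(round(float(parts[0]))), float(parts[1]), duration))
    low, _, high = meta.get("band", "80:120").partition(":")
    return DetectionResult(
        events=tuple(sorted(events, key=lambda e: e.center_sample)),
        lambda1=float(meta.get("lambda1", 14.0)),
        lambda2=float(meta.get("lambda2", 0.1)),
        band=(float(low), float(high)),
        fs=float(meta.get("fs", 1024.0)),
    )


def write_record_csv(record: ECoGRecord, path: str | Path, two_column: bool = False) -> None:
    """Write a recording as CSV (single amplitude column by default)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write("# units=uV\n")
        fh.write(f"# subject_id={record.subject_id}\n")
        fh.write(f"# t0_offset_min={record.t0_offset_min:g}\n")
        if two_column:
            for i, v in enumerate(record.samples):
                fh.write(f"{i / record.fs!r},{float(v)!r}\n")
        else:
            for v in record.samples:
                fh.write(f"{float(v)!r}\n")
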