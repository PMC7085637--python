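"""The Type-1 fuzzy-logic decision stage.

The published rule is a crisp two-condition if-then: a sample is labeled a
spike transient iff the raw amplitude satisfies |x| >= λ1 (14 μV) AND the
unit-normalized band signal satisfies |y| >= λ2 (alpha).  Both memberships
are step functions combined with a min t-norm, which reduces exactly to the
boolean AND; a product t-norm and graded (ramped) memberships are available
for experimentation.  Labeled points are then merged into events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fourier import BandPassSpec, fft_bandpass, normalized_band_signal, unit_normalize
from .preprocess import FIRSpec, fir_filter, zero_mean
from .records import AnnotationSet, DetectionEvent, DetectionResult, ECoGRecord


@dataclass(frozen=True)
class FLCParams:
    """Classifier parameters.

    lambda1
        Fixed raw-amplitude threshold in μV (annotation protocol floor, 14).
    lambda2
        Moving threshold on the normalized band signal, in (0, 1).
    tnorm
        Fuzzy conjunction: ``min`` (default) or ``product``.
    merge_gap_ms
        Labeled runs closer than this merge into one event; spikes are
        < 20 ms, so sub-10 ms fragmentation within one spike is merged.
    max_event_ms
        Events longer than this (the conventional spike duration ceiling,
        70 ms) are split at their largest internal gap or truncated.
    transition_uv, transition_band
        Optional half-widths of linear membership ramps around λ1 (μV) and
        λ2 (normalized units); 0 keeps the published crisp rule.
    """

    lambda1: float = 14.0
    lambda2: float = 0.10
    tnorm: str = "min"
    merge_gap_ms: float = 10.0
    max_event_ms: float = 70.0
    transition_uv: float = 0.0
    transition_band: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be > 0")
        if not 0 < self.lambda2 < 1:
            raise ValueError("lambda2 must be in (0, 1)")
        if self.merge_gap_ms < 0 or self.max_event_ms <= 0:
            raise ValueError("merge_gap_ms >= 0 and max_event_ms > 0 required")
        if self.tnorm not in ("min", "product"):
            raise ValueError(f"unknown tnorm {self.tnorm!r}")


@dataclass(frozen=True)
class SweepSpec:
    """Grid of λ2 values, default 0.10 to 0.95 in steps of 0.05."""

    lambda2_values: tuple[float, ...] = tuple(
        np.round(np.arange(0.10, 0.951, 0.05), 2)
    )

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.lambda2_values)
        object.__setattr__(self, "lambda2_values", vals)
        arr = np.asarray(vals)
        if arr.size == 0 or np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError("lambda2 values must lie in (0, 1)")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("lambda2 values must be strictly increasing")


def _ramp(mag: np.ndarray, threshold: float, width: float) -> np.ndarray:
    """Step membership at ``threshold`` (width 0) or a linear ramp of the
    given half-width; inclusive at the threshold."""
    if width <= 0:
        return (mag >= threshold).astype(float)
    return np.clip((mag - (threshold - width)) / (2 * width), 0.0, 1.0)


def membership_raw(x, lambda1: float = 14.0, transition_uv: float = 0.0):
    """Degree to which the raw amplitude satisfies |x| >= λ1."""
    return _ramp(np.abs(np.asarray(x, dtype=float)), lambda1, transition_uv)


def membership_band(y, lambda2: float, transition_band: float = 0.0):
    """Degree to which the normalized band signal satisfies |y| >= λ2."""
    return _ramp(np.abs(np.asarray(y, dtype=float)), lambda2, transition_band)


def classify_points(
    raw: ECoGRecord, band_norm: ECoGRecord, params: FLCParams
) -> np.ndarray:
    """Per-sample spike mask: t-norm of the two memberships, cut at 0.5.

    With crisp memberships and the min t-norm this is exactly
    (|raw| >= λ1) AND (|band| >= λ2).
    """
    if raw.n_samples != band_norm.n_samples:
        raise ValueError("raw and band-normalized signals must have equal length")
    mu1 = membership_raw(raw.samples, params.lambda1, params.transition_uv)
    mu2 = membership_band(band_norm.samples, params.lambda2, params.transition_band)
    if params.tnorm == "min":
        degree = np.minimum(mu1, mu2)
    else:
        degree = mu1 * mu2
    return degree >= 0.5


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[brk + 1]]
    ends = np.r_[idx[brk], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def _split_group(
    group: list[tuple[int, int]], raw: np.ndarray, fs: float, max_len: int
) -> list[list[tuple[int, int]]]:
    """Split a merged group exceeding max_len at its largest internal gap."""
    span = group[-1][1] - group[0][0] + 1
    if span <= max_len or len(group) == 1:
        return [group]
    gaps = [group[i + 1][0] - group[i][1] for i in range(len(group) - 1)]
    cut = int(np.argmax(gaps)) + 1
    return _split_group(group[:cut], raw, fs, max_len) + _split_group(
        group[cut:], raw, fs, max_len
    )


def extract_events(
    mask: np.ndarray, raw: ECoGRecord, params: FLCParams
) -> DetectionResult:
    """Merge labeled samples into events.

    Runs separated by gaps shorter than ``merge_gap_ms`` merge; the event
    center is the sample of maximum |raw| within the run, the duration the
    run span.  Merged groups longer than ``max_event_ms`` are split at
    their largest internal gap, or truncated around the peak if gapless.
    """
    if len(mask) != raw.n_samples:
        raise ValueError("mask must align with the record")
    fs = raw.fs
    gap_samples = int(round(params.merge_gap_ms * fs / 1000.0))
    # floor, so a truncated event's duration never exceeds max_event_ms
    max_len = max(1, int(params.max_event_ms * fs / 1000.0))
    runs = _runs_from_mask(np.asarray(mask, dtype=bool))

    # merge runs separated by < merge_gap_ms
    groups: list[list[tuple[int, int]]] = []
    for run in runs:
        if groups and run[0] - groups[-1][-1][1] < gap_samples:
            groups[-1].append(run)
        else:
            groups.append([run])

    x = raw.samples
    events = []
    for group in groups:
        for part in _split_group(group, x, fs, max_len):
            start, end = part[0][0], part[-1][1]
            if end - start + 1 > max_len:  # single gapless over-long run
                peak = start + int(np.argmax(np.abs(x[start : end + 1])))
                start = max(start, peak - max_len // 2)
                end = min(end, start + max_len - 1)
            peak = start + int(np.argmax(np.abs(x[start : end + 1])))
            events.append(
                DetectionEvent(
                    center_sample=peak,
                    peak_amplitude=float(np.abs(x[peak])),
                    duration_ms=(end - start + 1) * 1000.0 / fs,
                )
            )
    events.sort(key=lambda e: e.center_sample)
    return DetectionResult(
        events=tuple(events),
        lambda1=params.lambda1,
        lambda2=params.lambda2,
        band=(0.0, 0.0),  # filled by detect()
        fs=fs,
    )


def detect(
    record: ECoGRecord,
    band: BandPassSpec | None = None,
    params: FLCParams | None = None,
    fir: FIRSpec | None = None,
    epoch_s: float | None = None,
) -> DetectionResult:
    """Full detector: zero-mean -> (optional FIR) -> FFT band isolation ->
    unit normalization -> fuzzy point labeling -> event extraction.

    ``fir`` enables the optional 25.6-66.56 Hz band-stop conditioning stage;
    it is off by default.  Deterministic for fixed inputs.
    """
    band = band or BandPassSpec()
    params = params or FLCParams()
    raw = zero_mean(record)
    if fir is not None:
        raw = fir_filter(raw, fir)
    banded = fft_bandpass(raw, band)
    # a band peak at the numerical noise floor of the transform means no
    # in-band energy: nothing can satisfy the band condition
    if np.max(np.abs(banded.samples)) <= 1e-9 * np.max(np.abs(raw.samples)):
        return DetectionResult(
            events=(),
            lambda1=params.lambda1,
            lambda2=params.lambda2,
            band=(band.f_low, band.f_high),
            fs=record.fs,
        )
    band_norm = unit_normalize(banded, epoch_s=epoch_s)
    mask = classify_points(raw, band_norm, params)
    result = extract_events(mask, raw, params)
    return replace(result, band=(band.f_low, band.f_high))


@dataclass(frozen=True)
class SweepResult:
    """Performance at each λ2 plus the best-performing threshold."""

    records: tuple  # of evaluation.PerformanceRecord
    best_lambda2: float

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def sweep(
    record: ECoGRecord,
    annotations: AnnotationSet,
    band: BandPassSpec | None = None,
    sweep_spec: SweepSpec | None = None,
    match_config=None,
    params: FLCParams | None = None,
    fir: FIRSpec | None = None,
) -> SweepResult:
    """Evaluate the detector over a grid of λ2 values.

    The band signal is computed once; each λ2 re-labels points, extracts
    events and scores them against the spike annotations.  The best
    threshold maximizes overall performance, ties resolved toward the
    smallest λ2.
    """
    from .evaluation import MatchConfig, match_events, performance

    band = band or BandPassSpec()
    sweep_spec = sweep_spec or SweepSpec()
    match_config = match_config or MatchConfig()
    base = params or FLCParams()

    raw = zero_mean(record)
    if fir is not None:
        raw = fir_filter(raw, fir)
    band_norm = normalized_band_signal(raw, band)
    truth = annotations.spikes()

    records = []
    for lam2 in sweep_spec.lambda2_values:
        p = replace(base, lambda2=lam2)
        mask = classify_points(raw, band_norm, p)
        detections = extract_events(mask, raw, p)
        m = match_events(detections, truth, match_config, fs=record.fs)
        records.append(performance(m.tp, m.fp, m.fn, lambda2=lam2))
    best = max(records, key=lambda r: (r.overall, -r.lambda2))
    return SweepResult(records=tuple(records), best_lambda2=best.lambda2)
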