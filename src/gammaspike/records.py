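"""Core containers for recordings, expert annotations and detector output.

All sample indices are 0-based integers; times are seconds; amplitudes are
microvolts (μV) throughout the package.  Annotation centers are stored as
the nearest integer sample so that events keep their identity across file
formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Labels accepted for annotated transients.
TRANSIENT_LABELS = ("spike", "sharp", "slow", "other")

#: Annotation protocol floor for spike amplitude (μV).
SPIKE_AMPLITUDE_FLOOR_UV = 14.0


@dataclass(frozen=True)
class ECoGRecord:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Voltage values in μV.
    fs
        Sampling rate in Hz (1024 for the recordings this package targets).
    subject_id
        Free-text subject identifier.
    t0_offset_min
        Minutes from the end of the hypoxic-ischemic insult to the first
        sample; used when binning detections over the 6 h latent phase.
    """

    samples: np.ndarray
    fs: float = 1024.0
    subject_id: str = ""
    t0_offset_min: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        """Sampling period in seconds (Δt = 1/fs)."""
        return 1.0 / self.fs

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECoGRecord":
        """Copy of this record carrying new sample values."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def sample_to_minutes(self, sample: int | np.ndarray) -> float | np.ndarray:
        """Convert a sample index to minutes post-insult."""
        return self.t0_offset_min + np.asarray(sample) / self.fs / 60.0


@dataclass(frozen=True)
class AnnotationEvent:
    """One expert-labeled transient."""

    center_sample: int
    peak_amplitude: float
    label: str = "spike"

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_sample", int(self.center_sample))
        if self.label not in TRANSIENT_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {TRANSIENT_LABELS}"
            )


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth events for one record, sorted by center sample."""

    events: tuple[AnnotationEvent, ...]
    record_id: str = ""
    n_record_samples: int | None = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        centers = [e.center_sample for e in events]
        if centers != sorted(centers):
            raise ValueError("annotation events must be sorted by center_sample")
        if self.n_record_samples is not None:
            bad = [c for c in centers if not 0 <= c < self.n_record_samples]
            if bad:
                raise ValueError(
                    f"annotation centers out of record bounds: {bad[:5]}"
                )
        dup = len(centers) - len(set(centers))
        if dup:
            logger.warning("annotation set contains %d duplicate centers", dup)
        low = [
            e.center_sample
            for e in events
            if e.label == "spike" and e.peak_amplitude < SPIKE_AMPLITUDE_FLOOR_UV
        ]
        if low:
            logger.warning(
                "%d spike annotations below the %g μV protocol floor",
                len(low),
                SPIKE_AMPLITUDE_FLOOR_UV,
            )

    @classmethod
    def from_events(
        cls,
        events: Iterable[AnnotationEvent],
        record_id: str = "",
        n_record_samples: int | None = None,
    ) -> "AnnotationSet":
        """Build a set from events in any order (sorts them)."""
        ev = sorted(events, key=lambda e: e.center_sample)
        return cls(tuple(ev), record_id, n_record_samples)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def centers(self) -> np.ndarray:
        return np.array([e.center_sample for e in self.events], dtype=int)

    def with_label(self, label: str) -> "AnnotationSet":
        """Subset carrying only events with the given label."""
        return AnnotationSet(
            tuple(e for e in self.events if e.label == label),
            self.record_id,
            self.n_record_samples,
        )

    def spikes(self) -> "AnnotationSet":
        """The spike ground truth (distractor labels removed)."""
        return self.with_label("spike")


@dataclass(frozen=True)
class DetectionEvent:
    """One detected event: peak location, peak raw amplitude, duration."""

    center_sample: int
    peak_amplitude: float
    duration_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_sample", int(self.center_sample))
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be >= 0")


@dataclass(frozen=True)
class DetectionResult:
    """Detector output together with the thresholds that produced it."""

    events: tuple[DetectionEvent, ...]
    lambda1: float
    lambda2: float
    band: tuple[float, float]
    fs: float = 1024.0

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "band", (float(self.band[0]), float(self.band[1])))
        if not 0 < self.lambda2 < 1:
            raise ValueError(f"lambda2 must be in (0, 1), got {self.lambda2}")
        centers = [e.center_sample for e in events]
        if centers != sorted(centers):
            raise ValueError("detection events must be sorted by center_sample")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def centers(self) -> np.ndarray:
        return np.array([e.center_sample for e in self.events], dtype=int)


def seconds_to_sample(t_s: float | np.ndarray, fs: float) -> int | np.ndarray:
    """Nearest-sample conversion from seconds; inverse of ``sample/fs`` up to
    half-sample rounding."""
    return np.rint(np.asarray(t_s) * fs).astype(int)
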