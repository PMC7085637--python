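"""Seeded generator of latent-phase-like ECoG with ground-truth transients.

The scene model is: a stochastic power-law background (suppressed
post-insult cortical activity), an optional mains tone, and planted
transient atoms — gamma-band spike transients (< 20 ms, >= 14 μV, carrier
80-120 Hz), plus sharp-wave and slow-wave distractors at sub-gamma
frequencies.  All transients are Gabor atoms (Gaussian-enveloped cosines):
the detector assumes nothing about spike shape beyond raw amplitude and
in-band energy, which the atom realizes minimally.

Background colors: ``white`` (flat PSD), ``pink`` (1/f PSD), ``ecog``
(1/f³ PSD, the default — intracranial background falls off far more
steeply than pink above ~75 Hz, and post-insult suppression steepens it
further), or ``mixture`` (pink + white at equal power).  All randomness
flows from a single integer seed through one generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import AnnotationEvent, AnnotationSet, ECoGRecord

BACKGROUND_EXPONENTS = {"white": 0.0, "pink": 1.0, "ecog": 3.0}

#: Hardware-like high-pass corner: no background power below this, Hz.
BACKGROUND_HIGHPASS_HZ = 1.6


def gabor_spike(
    fs: float,
    f0: float,
    duration_ms: float,
    amplitude: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Gaussian-enveloped cosine transient.

    The envelope's full width at 5% of peak equals ``duration_ms``; the
    waveform is rescaled so its peak absolute amplitude is exactly
    ``amplitude``.  The dominant periodogram frequency lies within a few Hz
    of ``f0`` for the durations used here.
    """
    if not 0 < f0 < fs / 2:
        raise ValueError(f"carrier f0={f0} must lie in (0, fs/2)")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    half_s = duration_ms / 2000.0
    # envelope exp(-t²/2σ²) hits 0.05 at t = ±duration/2
    sigma = half_s / np.sqrt(2.0 * np.log(20.0))
    t = np.arange(-half_s, half_s + 0.5 / fs, 1.0 / fs)
    w = np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(2.0 * np.pi * f0 * t + phase)
    return amplitude * w / np.max(np.abs(w))


def power_law_noise(
    n: int,
    fs: float,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
    f_min: float = BACKGROUND_HIGHPASS_HZ,
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ f^-exponent above
    ``f_min`` (zero below), scaled to the requested RMS."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    passband = freqs >= f_min
    shaping[passband] = freqs[passband] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("degenerate noise spectrum")
    return x * (rms / sd)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults define the reference study scene: 10 min at 1024 Hz, 5 μV-RMS
    suppressed-ECoG background, 50 spikes of 25 μV peak (broadband SNR
    ≈ 14 dB) with carriers uniform over 80-120 Hz and durations 6-18 ms,
    plus 10 sharp-wave and 5 slow-wave distractors.
    """

    fs: float = 1024.0
    duration_min: float = 10.0
    background: str = "ecog"
    background_rms_uv: float = 5.0
    background_exponent: float | None = None  # overrides the color preset
    mains_hz: float = 50.0
    mains_amplitude_uv: float = 0.0
    n_spikes: int = 50
    rate_profile: tuple[int, ...] | None = None  # spikes per 30-min bin
    spike_amp_uv: tuple[float, float] = (25.0, 25.0)
    spike_freq_hz: tuple[float, float] = (80.0, 120.0)
    spike_duration_ms: tuple[float, float] = (6.0, 18.0)
    n_sharp: int = 10
    sharp_freq_hz: tuple[float, float] = (20.0, 45.0)
    sharp_duration_ms: tuple[float, float] = (70.0, 120.0)
    sharp_amp_uv: tuple[float, float] = (20.0, 40.0)
    n_slow: int = 5
    slow_freq_hz: tuple[float, float] = (1.0, 3.0)
    slow_duration_ms: tuple[float, float] = (250.0, 500.0)
    slow_amp_uv: tuple[float, float] = (30.0, 60.0)
    min_separation_ms: float = 100.0
    t0_offset_min: float = 0.0
    seed: int = 0
    allow_sub_threshold: bool = False

    def __post_init__(self) -> None:
        if self.background not in (*BACKGROUND_EXPONENTS, "mixture"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.spike_duration_ms[1] >= 20.0:
            raise ValueError("spike durations must stay below 20 ms")
        if not self.allow_sub_threshold and self.spike_amp_uv[0] < 14.0:
            raise ValueError(
                "spike amplitudes below the 14 μV annotation floor require "
                "allow_sub_threshold=True"
            )
        record_ms = self.duration_min * 60_000.0
        longest = max(
            self.spike_duration_ms[1],
            self.sharp_duration_ms[1] if self.n_sharp else 0.0,
            self.slow_duration_ms[1] if self.n_slow else 0.0,
        )
        if longest >= record_ms:
            raise ValueError("transient durations must be shorter than the record")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 * self.fs))

    def exponent(self) -> float:
        if self.background_exponent is not None:
            return float(self.background_exponent)
        return BACKGROUND_EXPONENTS.get(self.background, 1.0)


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    lo, hi = lohi
    return float(lo if lo == hi else rng.uniform(lo, hi))


def _place_centers(
    rng: np.random.Generator,
    count: int,
    lo: int,
    hi: int,
    taken: list[int],
    sep: int,
    max_tries: int = 10_000,
) -> list[int]:
    """Draw ``count`` centers in [lo, hi) keeping >= sep samples between all
    placed transients; raises if the packing is infeasible."""
    if hi <= lo:
        raise ValueError("placement window is empty")
    placed: list[int] = []
    tries = 0
    while len(placed) < count:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {count} transients with separation {sep} samples"
            )
        tries += 1
        c = int(rng.integers(lo, hi))
        if all(abs(c - o) >= sep for o in taken) and all(
            abs(c - o) >= sep for o in placed
        ):
            placed.append(c)
    return placed


def generate_scene(spec: SceneSpec) -> tuple[ECoGRecord, AnnotationSet]:
    """Build the scene; identical seeds give bit-identical output.

    The annotation set contains exactly the planted transients: spikes with
    their planted peak amplitude (the spike ground truth), distractors under
    their own labels.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    fs = spec.fs

    if spec.background == "mixture":
        amp = spec.background_rms_uv / np.sqrt(2.0)
        x = power_law_noise(n, fs, 1.0, amp, rng) + power_law_noise(
            n, fs, 0.0, amp, rng
        )
    else:
        x = power_law_noise(n, fs, spec.exponent(), spec.background_rms_uv, rng)
    if spec.mains_amplitude_uv > 0:
        t = np.arange(n) / fs
        x = x + spec.mains_amplitude_uv * np.sin(
            2 * np.pi * spec.mains_hz * t + rng.uniform(0, 2 * np.pi)
        )

    sep = int(round(spec.min_separation_ms * fs / 1000.0))
    margin = int(round(0.6 * fs))  # keep transients clear of record edges
    taken: list[int] = []

    # spike centers: flat count, or a per-30-min-bin rate profile
    if spec.rate_profile is not None:
        spike_centers = []
        for k, count in enumerate(spec.rate_profile):
            lo_min = 30.0 * k - spec.t0_offset_min
            hi_min = 30.0 * (k + 1) - spec.t0_offset_min
            lo = max(int(lo_min * 60 * fs), margin)
            hi = min(int(hi_min * 60 * fs), n - margin)
            if count and hi <= lo:
                raise ValueError(
                    f"rate profile bin {k} lies outside the record"
                )
            got = _place_centers(rng, count, lo, hi, taken, sep)
            spike_centers.extend(got)
            taken.extend(got)
    else:
        spike_centers = _place_centers(
            rng, spec.n_spikes, margin, n - margin, taken, sep
        )
        taken.extend(spike_centers)
    sharp_centers = _place_centers(rng, spec.n_sharp, margin, n - margin, taken, sep)
    taken.extend(sharp_centers)
    slow_centers = _place_centers(rng, spec.n_slow, margin, n - margin, taken, sep)

    events: list[AnnotationEvent] = []

    def plant(center: int, freq, dur, amp, label: str) -> None:
        w = gabor_spike(
            fs,
            _uniform(rng, freq),
            _uniform(rng, dur),
            _uniform(rng, amp),
            phase=float(rng.uniform(0, 2 * np.pi)),
        )
        start = center - len(w) // 2
        x[start : start + len(w)] += w
        peak = start + int(np.argmax(np.abs(w)))
        events.append(AnnotationEvent(peak, float(np.max(np.abs(w))), label))

    for c in spike_centers:
        plant(c, spec.spike_freq_hz, spec.spike_duration_ms, spec.spike_amp_uv, "spike")
    for c in sharp_centers:
        plant(c, spec.sharp_freq_hz, spec.sharp_duration_ms, spec.sharp_amp_uv, "sharp")
    for c in slow_centers:
        plant(c, spec.slow_freq_hz, spec.slow_duration_ms, spec.slow_amp_uv, "slow")

    record = ECoGRecord(
        samples=x,
        fs=fs,
        subject_id=f"synthetic-seed{spec.seed}",
        t0_offset_min=spec.t0_offset_min,
    )
    annotations = AnnotationSet.from_events(
        events, record_id=record.subject_id, n_record_samples=n
    )
    return record, annotations


def snr_report(
    record: ECoGRecord,
    annotations: AnnotationSet,
    guard_ms: float = 250.0,
) -> np.ndarray:
    """Per-event SNR in dB: 20 log10(peak / background RMS).

    Background RMS is estimated from samples more than ``guard_ms`` away
    from every annotated event.
    """
    mask = np.ones(record.n_samples, dtype=bool)
    guard = int(round(guard_ms * record.fs / 1000.0))
    for e in annotations:
        lo = max(0, e.center_sample - guard)
        hi = min(record.n_samples, e.center_sample + guard + 1)
        mask[lo:hi] = False
    if not mask.any():
        raise ValueError("no annotation-free segment to estimate background")
    bg_rms = float(np.sqrt(np.mean(record.samples[mask] ** 2)))
    peaks = np.array([e.peak_amplitude for e in annotations], dtype=float)
    return 20.0 * np.log10(peaks / bg_rms)
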