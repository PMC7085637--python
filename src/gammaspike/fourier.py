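"""Gamma-band isolation by forward FFT, frequency masking and inverse FFT.

The whole record is transformed at once; bins whose frequency k*fs/N lies
inside [f_low, f_high] are kept (inclusive at both edges), everything else
— including DC and Nyquist — is zeroed, and the spectrum is inverted back
to a real time series.  No window, no taper: edge ringing is tolerated and
absorbed by the moving threshold downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ECoGRecord


@dataclass(frozen=True)
class BandPassSpec:
    """Pass band in Hz; default is the 80-120 Hz gamma band in which the
    hypoxic-ischemic spike transients live."""

    f_low: float = 80.0
    f_high: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError("need 0 < f_low < f_high")

    def validate_for(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"f_high {self.f_high} must be below the Nyquist rate {fs / 2}"
            )


def fft_bandpass(record: ECoGRecord, band: BandPassSpec | None = None) -> ECoGRecord:
    """Keep only spectral content inside the band; invert to the time domain.

    Energy of the output equals the in-band spectral energy of the input
    (Parseval).  Applying the operation twice gives the same result as once.
    """
    band = band or BandPassSpec()
    band.validate_for(record.fs)
    n = record.n_samples
    if n < 2:
        raise ValueError("record must have at least 2 samples")
    spectrum = np.fft.rfft(record.samples)
    freqs = np.fft.rfftfreq(n, d=record.dt)
    keep = (freqs >= band.f_low) & (freqs <= band.f_high)
    keep[0] = False  # DC always removed (zero-mean contract)
    if n % 2 == 0:
        keep[-1] = False  # Nyquist bin always removed
    spectrum[~keep] = 0.0
    return record.with_samples(np.fft.irfft(spectrum, n=n))


def unit_normalize(banded: ECoGRecord, epoch_s: float | None = None) -> ECoGRecord:
    """Scale a band signal to peak at ±1, per record or per epoch."""
    x = banded.samples
    if epoch_s is None or epoch_s >= banded.duration_s:
        peak = np.max(np.abs(x))
        if peak == 0.0:
            raise ValueError("band signal is identically zero")
        return banded.with_samples(x / peak)
    step = int(round(epoch_s * banded.fs))
    if step <= 0:
        raise ValueError("epoch_s too small for the sampling rate")
    out = np.empty_like(x)
    for start in range(0, x.size, step):
        seg = x[start : start + step]
        peak = np.max(np.abs(seg))
        if peak == 0.0:
            raise ValueError("band signal is identically zero within an epoch")
        out[start : start + step] = seg / peak
    return banded.with_samples(out)


def normalized_band_signal(
    record: ECoGRecord,
    band: BandPassSpec | None = None,
    epoch_s: float | None = None,
) -> ECoGRecord:
    """Band-passed signal scaled to peak at ±1.

    The comparand of the moving threshold λ2.  Normalization is by the
    maximum absolute value over the whole record (``epoch_s=None``, the
    default) or per consecutive epoch of ``epoch_s`` seconds.
    """
    return unit_normalize(fft_bandpass(record, band), epoch_s=epoch_s)
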