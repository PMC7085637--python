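"""Band-justification mathematics: wavelet center frequency, the
pseudo-frequency approximation f_p = f_c / (a Δt), and frequency-dependent
wavelet energy spectra

    E_w(f) = 1 / (f_c C_φ) ∫ |T(f, b)|² db

computed with the reverse biorthogonal rbio2.8 mother wavelet by default.
Scales 5-7 of rbio2.8 at 1024 Hz map to ≈120.5-86.1 Hz, which is how the
80-120 Hz pass band of the spike detector is justified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .fourier import BandPassSpec
from .records import ECoGRecord

#: Dyadic refinement level for sampling wavelet functions (2^10+ points).
DEFAULT_PRECISION = 8


def _wavelet_function(wavelet_name: str, precision: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampled wavelet function ψ and its grid x.

    For biorthogonal pairs the decomposition wavelet is used, matching the
    convention of the standard center-frequency estimator.
    """
    try:
        wavelet = pywt.DiscreteContinuousWavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    approx = wavelet.wavefun(precision)
    if len(approx) == 2:
        psi, x = approx
    else:
        # (phi, psi, x) or (phi_d, psi_d, phi_r, psi_r, x)
        psi, x = approx[1], approx[-1]
    return np.asarray(psi, dtype=float), np.asarray(x, dtype=float)


def dominant_frequency(psi: np.ndarray, domain: float) -> float:
    """Frequency of the dominant magnitude-spectrum peak of a sampled
    function whose support spans ``domain`` time units (cycles per unit)."""
    if domain <= 0:
        raise ValueError("domain must be positive")
    index = int(np.argmax(np.abs(np.fft.fft(psi)[1:]))) + 2
    if index > len(psi) / 2:
        index = len(psi) - index + 2
    return (index - 1) / domain


def center_frequency(wavelet_name: str, precision: int = DEFAULT_PRECISION) -> float:
    """Center frequency f_c of a mother wavelet in cycles per sample.

    Estimated as the dominant peak of the magnitude spectrum of the wavelet
    function sampled at dyadic precision (≥ 2^10 points at the default
    level).  rbio2.8 gives ≈ 0.5884.
    """
    psi, x = _wavelet_function(wavelet_name, precision)
    return dominant_frequency(psi, float(x[-1] - x[0]))


def pseudo_frequency(a: float, fc: float, dt: float) -> float:
    """Pseudo-frequency f_p = f_c / (a Δt) in Hz for scale ``a``."""
    if a < 1 or fc <= 0 or dt <= 0:
        raise ValueError("need a >= 1, fc > 0, dt > 0")
    return fc / (a * dt)


@dataclass(frozen=True)
class PseudoFrequencyTable:
    """(scale, pseudo-frequency, wavelength) triples for one mother wavelet.

    ``wavelength`` is fs / f_p, i.e. the wavelet period expressed in samples
    at fs.  (Tabulations of this quantity sometimes label it "ms"; at
    1024 Hz one sample is 0.977 ms so the numbers are close, but the unit
    here is samples.)
    """

    wavelet_name: str
    fc: float
    fs: float
    scales: tuple[int, ...]
    f_p: tuple[float, ...]
    wavelength: tuple[float, ...]

    def __post_init__(self) -> None:
        fp = np.asarray(self.f_p)
        if np.any(np.diff(fp) >= 0):
            raise ValueError("f_p must be strictly decreasing in scale")
        prod = np.asarray(self.scales) * fp
        if np.ptp(prod) > 1e-9 * prod[0]:
            raise ValueError("a * f_p must be constant across rows")

    def row(self, scale: int) -> tuple[float, float]:
        """(f_p, wavelength) for one scale."""
        i = self.scales.index(scale)
        return self.f_p[i], self.wavelength[i]

    def to_frame(self, decimals: int = 3):
        """Rounded report table (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "scale": self.scales,
                "pseudo_freq_hz": np.round(self.f_p, decimals),
                "wavelength_samples": np.round(self.wavelength, decimals),
            }
        )


def pseudo_frequency_table(
    wavelet_name: str = "rbio2.8",
    fs: float = 1024.0,
    scales: Sequence[int] = tuple(range(1, 13)),
    precision: int = DEFAULT_PRECISION,
) -> PseudoFrequencyTable:
    """Tabulate f_p and wavelength over integer scales."""
    scales = tuple(int(a) for a in scales)
    if not scales or min(scales) < 1:
        raise ValueError("scales must be non-empty positive integers")
    fc = center_frequency(wavelet_name, precision)
    dt = 1.0 / fs
    fp = tuple(pseudo_frequency(a, fc, dt) for a in scales)
    wavelength = tuple(fs / f for f in fp)
    return PseudoFrequencyTable(wavelet_name, fc, fs, scales, fp, wavelength)


def band_from_scales(
    table: PseudoFrequencyTable,
    scales: Sequence[int],
    clamp_high: float | None = None,
) -> BandPassSpec:
    """Pass band suggested by a set of scales.

    The smallest pseudo-frequency is rounded down and the largest rounded up
    to the nearest 10 Hz; ``clamp_high`` optionally caps the upper edge
    (rbio2.8 scales 5-7 at 1024 Hz give (80, 130), conventionally clamped to
    the published 80-120 Hz band).
    """
    scales = tuple(int(a) for a in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    fps = [table.row(a)[0] for a in scales]
    low = math.floor(min(fps) / 10.0) * 10.0
    high = math.ceil(max(fps) / 10.0) * 10.0
    if clamp_high is not None:
        high = min(high, clamp_high)
    return BandPassSpec(low, high)


@dataclass(frozen=True)
class WaveletEnergySpectrum:
    """Frequency-dependent wavelet energy spectrum E_w(f).

    ``c_phi`` is the numerically evaluated admissibility constant of the
    mother wavelet; it scales the spectrum uniformly, so peak locations and
    energy ratios do not depend on it.  ``tau`` is the analyzed duration in
    seconds.
    """

    freqs: np.ndarray
    energy: np.ndarray
    c_phi: float
    tau: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.energy) < 0):
            raise ValueError("energy must be non-negative")

    @property
    def peak_frequency(self) -> float:
        """Frequency of the spectrum maximum, Hz."""
        return float(self.freqs[int(np.argmax(self.energy))])


def admissibility_constant(
    wavelet_name: str, precision: int = DEFAULT_PRECISION
) -> float:
    """Numerical admissibility integral C_φ = ∫₀^∞ |Ψ(ω)|² / ω dω."""
    psi, x = _wavelet_function(wavelet_name, precision)
    dx = float(x[1] - x[0])
    spectrum = np.fft.rfft(psi) * dx
    omega = 2 * np.pi * np.fft.rfftfreq(len(psi), d=dx)
    mag2 = np.abs(spectrum[1:]) ** 2
    return float(np.trapezoid(mag2 / omega[1:], omega[1:]))


def _cwt_row(
    samples: np.ndarray, psi: np.ndarray, x: np.ndarray, scale: float
) -> np.ndarray:
    """Continuous wavelet coefficients T(a, b) at one (fractional) scale.

    The wavelet function is resampled onto the signal's integer sample grid
    at dilation ``a`` (scale 1 = mother wavelet at the sampling rate) and
    correlated with the signal.  The kernel carries 1/a (amplitude-
    preserving) normalization so that a narrowband oscillation produces
    coefficients of scale-independent magnitude and the energy spectrum
    peaks at the oscillation's pseudo-frequency.
    """
    half_span = scale * max(abs(x[0]), abs(x[-1]))
    j = np.arange(-math.ceil(half_span), math.ceil(half_span) + 1, dtype=float)
    kernel = np.interp(j / scale, x, psi, left=0.0, right=0.0) / scale
    # correlation: flip the (real) kernel for convolution
    return fftconvolve(samples, kernel[::-1], mode="same")


def wavelet_energy_spectrum(
    record: ECoGRecord,
    wavelet_name: str = "rbio2.8",
    scales: Sequence[float] = (5, 6, 7),
    n_freqs: int = 64,
    precision: int = DEFAULT_PRECISION,
) -> WaveletEnergySpectrum:
    """E_w(f) over a fine fractional-scale sweep spanning ``scales``.

    The requested scales fix the span; ``n_freqs`` log-spaced fractional
    scales inside it turn the spectrum into a curve.  |T|² is integrated
    over the record duration (trapezoidal rule) and scaled by 1/(f_c C_φ).
    """
    scales = [float(a) for a in scales]
    if not scales or min(scales) < 1:
        raise ValueError("scales must be >= 1")
    psi, x = _wavelet_function(wavelet_name, precision)
    fc = center_frequency(wavelet_name, precision)
    c_phi = admissibility_constant(wavelet_name, precision)
    lo, hi = min(scales), max(scales)
    if lo == hi:
        sweep = np.array([lo])
    else:
        sweep = np.geomspace(lo, hi, n_freqs)
    dt = record.dt
    freqs = np.array([pseudo_frequency(a, fc, dt) for a in sweep])
    energy = np.empty_like(freqs)
    for i, a in enumerate(sweep):
        t_ab = _cwt_row(record.samples, psi, x, a)
        energy[i] = np.trapezoid(np.abs(t_ab) ** 2, dx=dt)
    energy /= fc * c_phi
    order = np.argsort(freqs)
    return WaveletEnergySpectrum(
        freqs=freqs[order],
        energy=energy[order],
        c_phi=c_phi,
        tau=record.duration_s,
    )
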