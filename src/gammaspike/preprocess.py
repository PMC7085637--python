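"""Signal conditioning: zero-meaning, max-abs normalization and the optional
100th-order FIR band filter over the normalized 0.05-0.13 stop band
(25.60-66.56 Hz at fs = 1024 Hz).

The FIR stage is optional ("if needed"): the detector's own performance
contract is defined with it disabled.  It defaults to band-stop: although
the conditioning chain is sometimes described as band-pass, rejecting
25.6-66.56 Hz (which covers the 50 Hz mains region) is the only reading
consistent with a detector whose target band is 80-120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .records import ECoGRecord


@dataclass(frozen=True)
class FIRSpec:
    """Design of the linear-phase FIR stage.

    Frequencies are normalized to Nyquist = 1 (so 0.05 is 25.6 Hz at
    fs = 1024 Hz).  ``order`` must be even so the group delay is an integer
    number of samples and can be removed exactly.
    """

    order: int = 100
    omega_low: float = 0.05
    omega_high: float = 0.13
    mode: str = "band_stop"

    def __post_init__(self) -> None:
        if not (0 < self.omega_low < self.omega_high < 1):
            raise ValueError("need 0 < omega_low < omega_high < 1")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be even and > 0")
        if self.mode not in ("band_stop", "band_pass"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def taps(self) -> np.ndarray:
        """FIR coefficients (order + 1 taps, Hamming window design)."""
        return signal.firwin(
            self.order + 1,
            [self.omega_low, self.omega_high],
            pass_zero=(self.mode == "band_stop"),
        )

    def response_db(self, freq_hz: float, fs: float) -> float:
        """Magnitude response at one frequency, in dB."""
        w, h = signal.freqz(self.taps(), worN=[freq_hz], fs=fs)
        return float(20 * np.log10(np.abs(h[0])))


def zero_mean(record: ECoGRecord) -> ECoGRecord:
    """Remove the mean of the trace."""
    return record.with_samples(record.samples - record.samples.mean())


def fir_filter(record: ECoGRecord, spec: FIRSpec | None = None) -> ECoGRecord:
    """Apply the FIR stage with the group delay removed.

    Single forward pass of the linear-phase filter; because the filter is
    symmetric with even order, convolving in ``same`` mode centers the
    response, so event timing is preserved (timing is the evaluation
    currency).  Output length equals input length.
    """
    spec = spec or FIRSpec()
    if record.n_samples <= spec.order:
        raise ValueError(
            f"record length {record.n_samples} must exceed filter order {spec.order}"
        )
    out = np.convolve(record.samples, spec.taps(), mode="same")
    return record.with_samples(out)


def normalize(record: ECoGRecord, mode: str = "maxabs") -> tuple[ECoGRecord, float]:
    """Scale the trace; returns (scaled record, scale in μV).

    ``maxabs`` divides by the maximum absolute value so the output peaks at
    ±1; multiplying by the returned scale restores μV.  Amplitude thresholds
    stated in μV must always be applied to the unscaled trace.
    """
    if mode == "none":
        return record, 1.0
    if mode != "maxabs":
        raise ValueError(f"unknown mode {mode!r}")
    scale = float(np.max(np.abs(record.samples)))
    if scale == 0.0:
        raise ValueError("cannot maxabs-normalize an all-zero trace")
    return record.with_samples(record.samples / scale), scale
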