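import struct

import numpy as np
import pytest
from hypothesis import settings

from gammaspike import ECoGRecord, SceneSpec, generate_scene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """2-min scene with 12 spikes: fast enough for unit tests."""
    spec = SceneSpec(duration_min=2.0, n_spikes=12, n_sharp=3, n_slow=2, seed=7)
    record, annotations = generate_scene(spec)
    return spec, record, annotations


@pytest.fixture(scope="session")
def default_scene():
    """The reference study scene: 10 min, 50 spikes at ~14 dB SNR."""
    spec = SceneSpec(seed=11)
    record, annotations = generate_scene(spec)
    return spec, record, annotations


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_minimal_edf(path, samples, fs, phys_dim="uV"):
    """Write a single-channel EDF file (generated at test time; EDF is a
    binary format so no fixture file is shipped)."""
    samples = np.asarray(samples, dtype=float)
    n_per_record = int(fs)
    n_records = int(np.ceil(samples.size / n_per_record))
    padded = np.zeros(n_records * n_per_record)
    padded[: samples.size] = samples
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((padded - phys_min) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad("1", 4),
        ]
    )
    per_signal = b"".join(
        [
            pad("ECoG1", 16),
            pad("AgAgCl electrode", 80),
            pad(phys_dim, 8),
            pad(f"{phys_min:g}", 8),
            pad(f"{phys_max:g}", 8),
            pad(str(dig_min), 8),
            pad(str(dig_max), 8),
            pad("", 80),
            pad(str(n_per_record), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        fh.write(digital.tobytes())


@pytest.fixture
def edf_writer():
    return write_minimal_edf
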