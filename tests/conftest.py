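import struct

import numpy as np
import pytest

from eegmodes import GeneratorConfig


@pytest.fixture
def small_config():
    """A desk-scale generator configuration: 2 subjects, 6-second epochs
    (long enough for the nonlinear estimators on level-3 subbands)."""
    return GeneratorConfig(n_subjects=2, duration=6.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_minimal_edf(path, data, fs, channel_names):
    """Write a minimal single-record EDF file (int16, one data record).

    Synthetic stand-in for a clinical EDF export, built byte-by-byte so
    tests do not depend on an EDF-writing library.
    """
    data = np.asarray(data, dtype=float)
    n_sig, n_samp = data.shape
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header_bytes = 256 * (1 + n_sig)
    head = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(header_bytes), 8),
            pad("", 44),
            pad("1", 8),
            pad(str(n_samp / fs), 8),
            pad(str(n_sig), 4),
        ]
    )
    fields = [
        (16, channel_names),
        (80, [""] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [str(phys_min)] * n_sig),
        (8, [str(phys_max)] * n_sig),
        (8, [str(dig_min)] * n_sig),
        (8, [str(dig_max)] * n_sig),
        (80, [""] * n_sig),
        (8, [str(n_samp)] * n_sig),
        (32, [""] * n_sig),
    ]
    sig_head = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        for row in digital:
            fh.write(row.tobytes())
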