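import numpy as np
import pytest

import ssxpipe as s


@pytest.fixture(scope="session")
def tables():
    """Jittered 8x1024 calibration (two datagrams per frame)."""
    return s.make_calibration((8, 1024), seed=11)


@pytest.fixture(scope="session")
def flat_tables():
    """Jitter-free 4x6 calibration with the documented level scalars."""
    return s.make_calibration(
        (4, 6),
        gain_levels=(40.0, 2.0, 0.5),
        pedestal_levels=(1000.0, 800.0, 700.0),
        jitter_fraction=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def scene(tables):
    energy, peaks = s.generate_peaks_image(
        tables.shape, n_peaks=10, amplitude=100.0, peak_sigma=1.2,
        background_sigma=1.0, seed=5,
    )
    return energy, peaks


@pytest.fixture()
def sequence_datagrams(tables):
    """A 4-pair chopper sequence packetized into one lossless stream."""
    seq = s.make_sequence(4, tables, seed=21)
    dgs, n = [], 0
    for f in seq.frames:
        p = s.packetize(f.raw, f.frame_id, seq_start=n)
        n += len(p)
        dgs.extend(p)
    return seq, dgs
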