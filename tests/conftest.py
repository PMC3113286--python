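import numpy as np
import pytest

from ephyskit import SimComponent, SimSpec, epoch, simulate
from ephyskit.synthetic import fibonacci_montage


@pytest.fixture(scope="session")
def cap64():
    """64-channel cap-like montage (upper sphere plus a rim band)."""
    return fibonacci_montage(64)


@pytest.fixture(scope="session")
def sphere64():
    """64-channel full-sphere montage (whole-head coverage)."""
    return fibonacci_montage(64, z_min=-1.0)


MIXED = {
    "fs": 256.0,
    "evoked_freq": 10.0,
    "induced_freq": 25.0,
    "amplitude": 5.0,
    "noise_sd": 1.0,
    "n_trials": 200,
    "latency": 0.2,
    "comp_duration": 0.3,
}


@pytest.fixture(scope="session")
def mixed_epochs():
    """200 trials mixing a phase-locked 10 Hz wave and a random-phase 25 Hz
    burst on the same channel, plus white noise: the evoked/induced
    dissociation testbed."""
    spec = SimSpec(
        fs=MIXED["fs"], n_channels=2, noise_sd=MIXED["noise_sd"],
        events=[(1, MIXED["n_trials"], 1.2, 0.0)],
        components=[
            SimComponent("evoked_wave", [0], MIXED["latency"],
                         MIXED["comp_duration"], MIXED["amplitude"],
                         frequency=MIXED["evoked_freq"]),
            SimComponent("induced_burst", [0], MIXED["latency"],
                         MIXED["comp_duration"], MIXED["amplitude"],
                         frequency=MIXED["induced_freq"]),
        ],
        seed=42,
    )
    rec = simulate(spec)
    return epoch(rec, 1, (-0.2, 0.8))


def write_edf(path, digital, fs, labels, units, pmin, pmax,
              dmin=-32768, dmax=32767):
    """Minimal single-record EDF writer used as import ground truth.

    ``digital`` is int16, channels x samples; physical value of digital d
    is pmin + (d - dmin) * (pmax - pmin) / (dmax - dmin).
    """
    rows = [np.asarray(row, dtype=np.int16) for row in digital]
    nch = len(rows)
    spr = [row.size for row in rows]  # per-signal samples per record
    nsamp = spr[0]
    hdr = b""
    hdr += b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2020 X X X".ljust(80)
    hdr += b"01.01.20".ljust(8)
    hdr += b"00.00.00".ljust(8)
    hdr += str(256 + nch * 256).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += b"1".ljust(8)  # one data record
    hdr += f"{nsamp / fs:g}".encode()[:8].ljust(8)
    hdr += str(nch).encode().ljust(4)
    for lab in labels:
        hdr += lab.encode().ljust(16)
    hdr += b"".ljust(80) * nch  # transducer
    for unit in units:
        hdr += unit.encode().ljust(8)
    for _ in range(nch):
        hdr += f"{pmin:g}".encode()[:8].ljust(8)
    for _ in range(nch):
        hdr += f"{pmax:g}".encode()[:8].ljust(8)
    for _ in range(nch):
        hdr += str(dmin).encode().ljust(8)
    for _ in range(nch):
        hdr += str(dmax).encode().ljust(8)
    hdr += b"".ljust(80) * nch  # prefiltering
    for n in spr:
        hdr += str(n).encode().ljust(8)
    hdr += b"".ljust(32) * nch
    with open(path, "wb") as fh:
        fh.write(hdr)
        for row in rows:
            fh.write(row.astype("<i2").tobytes())


@pytest.fixture()
def edf_writer():
    return write_edf
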