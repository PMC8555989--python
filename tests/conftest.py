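"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

from optopace.synth import EcgSimSpec, VesselSimSpec, synth_ecg, synth_vessel_video


@pytest.fixture(scope="session")
def paced_ventricular():
    """Ventricular-mode paced ECG: 30 autonomous beats then 60 paced beats,
    R peaks 20 ms after pulse rising edges."""
    spec = EcgSimSpec(
        sampling_rate=1000.0,
        duration=18.2,
        heart_rate=5.0,
        stim_onset_time=6.1,
        stim_latency=20.0,
        mode="ventricular",
        seed=42,
    )
    ecg, ttl, gt = synth_ecg(spec)
    return spec, ecg, ttl, gt


@pytest.fixture(scope="session")
def paced_nodal():
    """Nodal-mode paced ECG: P peaks 45 ms after pulse falling edges."""
    spec = EcgSimSpec(
        sampling_rate=1000.0,
        duration=18.2,
        heart_rate=5.0,
        stim_onset_time=6.1,
        stim_latency=45.0,
        mode="nodal",
        seed=43,
    )
    ecg, ttl, gt = synth_ecg(spec)
    return spec, ecg, ttl, gt


@pytest.fixture(scope="session")
def quiet_vessel():
    """Constant-width noise-free vessel video (analytic wall positions)."""
    spec = VesselSimSpec(
        n_frames=10, noise_sd=0.0, jitter_max=0, texture_amplitude=0.0, seed=7
    )
    frames, gt = synth_vessel_video(spec)
    return spec, frames, gt


def brute_force_shift_search(ref, frame, mask=None, radius=10):
    """Independent exhaustive integer-shift search oracle (Pearson over mask)."""
    h, w = ref.shape
    if mask is None:
        mask = np.ones_like(ref, dtype=bool)
    ys, xs = np.nonzero(mask)
    rv = ref[ys, xs]
    rv = rv - rv.mean()
    rn = np.linalg.norm(rv)
    best, best_c = (0, 0), -np.inf
    cands = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
    ]
    cands.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]))
    for dy, dx in cands:
        fv = frame[(ys - dy) % h, (xs - dx) % w]
        fv = fv - fv.mean()
        fn = np.linalg.norm(fv)
        if fn == 0:
            continue
        c = float(rv @ fv) / (rn * fn)
        if c > best_c + 1e-12:
            best, best_c = (dy, dx), c
    return best
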