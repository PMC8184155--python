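"""Synthetic spike rasters and miniature network configurations.

Used by the test suite (decoder oracles, small fast rings) and by the
`make-fixtures` CLI command.  Rasters are inhomogeneous-Poisson samples from
known rate profiles, so decoding results can be checked against the
generating truth.
"""

from __future__ import annotations

import numpy as np

from .lif_core import SpikeRecord
from .ring_network import RingConfig, ring_directions

__all__ = [
    "bump_rate_profile",
    "sample_poisson_raster",
    "sample_bump_raster",
    "mini_ring_config",
]


def bump_rate_profile(n: int, theta_center: float, peak_hz: float,
                      sigma: float = 0.4, baseline_hz: float = 0.0) -> np.ndarray:
    """Per-neuron rates (Hz) of a bump-shaped profile.

    Uses the same circular Gaussian-like shape as the afferent drive,
    exp(2 pi (cos(theta - center) - 1) / sigma), scaled to `peak_hz` plus a
    uniform baseline.
    """
    theta = ring_directions(n)
    prof = np.exp(2.0 * np.pi * (np.cos(theta - theta_center) - 1.0) / sigma)
    return baseline_hz + peak_hz * prof


def sample_poisson_raster(rates_hz: np.ndarray, duration_ms: float,
                          seed) -> SpikeRecord:
    """Independent-Poisson raster with constant per-neuron rates."""
    rng = np.random.default_rng(seed)
    n = rates_hz.size
    lam = np.asarray(rates_hz, float) * duration_ms / 1000.0
    counts = rng.poisson(lam)
    neurons = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, duration_ms, neurons.size)
    return SpikeRecord(neurons, times, n)


def sample_bump_raster(n: int, theta_center: float, duration_ms: float, seed,
                       peak_hz: float = 40.0, sigma: float = 0.4,
                       baseline_hz: float = 0.5) -> SpikeRecord:
    """Poisson raster whose rates form a bump at `theta_center`."""
    rates = bump_rate_profile(n, theta_center, peak_hz, sigma, baseline_hz)
    return sample_poisson_raster(rates, duration_ms, seed)


def mini_ring_config(n_pyr: int = 64, n_int: int = 16, **overrides) -> RingConfig:
    """A miniature ring for fast tests.

    Keeps all cellular and synaptic parameters at their defaults; only the
    population sizes shrink (weight normalization keeps the total recurrent
    drive comparable).
    """
    return RingConfig(n_pyr=n_pyr, n_int=n_int, **overrides)
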