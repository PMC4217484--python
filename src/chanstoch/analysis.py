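"""Comparison statistics: spike detection, firing efficiency and timing,
spontaneous rates, voltage-clamp open-channel moments, and the accuracy /
cost heuristics for choosing between exact and diffusion simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .membrane import Trace

__all__ = [
    "SpikeTrain",
    "EnsembleStats",
    "detect_spikes",
    "firing_stats",
    "spontaneous_stats",
    "openstate_moments",
    "heuristics",
]

#: spike detection threshold (mV); the only value the protocols use
DEFAULT_THRESHOLD = 0.0


@dataclass
class SpikeTrain:
    """Spike times per sweep (ms), with the common sweep duration."""

    sweeps: list  # list of np.ndarray of spike times
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean = []
        for s in self.sweeps:
            s = np.asarray(s, dtype=float)
            if s.size and (np.any(np.diff(s) <= 0) or s[0] < 0 or s[-1] > self.duration):
                raise ValueError("spike times must be increasing within [0, T]")
            clean.append(s)
        self.sweeps = clean

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def total_spikes(self) -> int:
        return int(sum(s.size for s in self.sweeps))


@dataclass
class EnsembleStats:
    """Per-timepoint open-state moments and their analytic expectations.

    Open fractions throughout; the expected variance of the open fraction
    of N independent channels is ``E (1 - E) / N``.
    """

    t: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    expected_mean: Optional[np.ndarray] = None
    expected_var: Optional[np.ndarray] = None
    n_channels: Optional[int] = None
    n_reps: int = 0


def detect_spikes(trace, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Upward threshold-crossing times of a voltage trace.

    A spike is a below-to-above crossing of ``threshold``; the time is
    linearly interpolated between the bracketing samples, and a new spike
    requires the voltage to have returned below threshold first (which the
    crossing definition enforces).  Accepts a :class:`Trace` or a pair of
    arrays via ``trace=(t, v)``.
    """
    if isinstance(trace, Trace):
        t, v = trace.t, trace.v
    else:
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if t.size < 2:
        return np.empty(0)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def firing_stats(trains: SpikeTrain) -> tuple[float, Optional[float], Optional[float]]:
    """Firing efficiency and first-spike-time moments.

    Efficiency is the fraction of sweeps with at least one spike.  The mean
    and variance (population convention, over firing sweeps only) of the
    first-spike time are ``None`` when no sweep fires.
    """
    if trains.n_sweeps < 1:
        raise ValueError("need at least one sweep")
    firsts = np.array([s[0] for s in trains.sweeps if s.size])
    eff = firsts.size / trains.n_sweeps
    if firsts.size == 0:
        return 0.0, None, None
    return eff, float(firsts.mean()), float(firsts.var())


def spontaneous_stats(trains: SpikeTrain) -> tuple[float, np.ndarray]:
    """Mean spontaneous rate (Hz) and the pooled per-sweep ISIs (ms)."""
    total_s = trains.n_sweeps * trains.duration / 1000.0
    rate = trains.total_spikes / total_s
    isis = [np.diff(s) for s in trains.sweeps if s.size >= 2]
    return rate, np.concatenate(isis) if isis else np.empty(0)


def openstate_moments(
    t: np.ndarray,
    ensemble: np.ndarray,
    n_channels: Optional[int] = None,
    expected_mean: Optional[np.ndarray] = None,
) -> EnsembleStats:
    """Per-timepoint sample mean/variance of an open-fraction ensemble.

    ``ensemble`` is (n_reps, n_times).  When ``expected_mean`` (e.g. the
    deterministic master-equation run) and ``n_channels`` are given, the
    expected variance ``E (1-E) / N`` is filled in as well; it vanishes at
    E = 0 and E = 1 and peaks at E = 1/2.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 2 or ensemble.shape[0] < 2:
        raise ValueError("need a 2-D ensemble with at least 2 replicates")
    t = np.asarray(t, dtype=float)
    if t.size != ensemble.shape[1]:
        raise ValueError("time grid does not match the ensemble")
    exp_var = None
    if expected_mean is not None:
        expected_mean = np.asarray(expected_mean, dtype=float)
        if expected_mean.size != t.size:
            raise ValueError("expected_mean grid does not match the ensemble")
        if n_channels is not None:
            exp_var = expected_mean * (1.0 - expected_mean) / n_channels
    return EnsembleStats(
        t=t,
        mean=ensemble.mean(axis=0),
        var=ensemble.var(axis=0, ddof=1),
        expected_mean=expected_mean,
        expected_var=exp_var,
        n_channels=n_channels,
        n_reps=ensemble.shape[0],
    )


def heuristics(alpha: float, dt: float, N: Optional[int] = None) -> tuple[float, Optional[float]]:
    """Accuracy / cost rules of thumb for choosing MC vs DA.

    The Gaussian approximation behind the DA is accurate, and the DA
    becomes cheaper than event-driven MC, when ``N * alpha * dt >> 1``
    (alpha the typical transition rate in ms^-1, dt the timestep in ms).
    Returns ``(N*, updates)`` where ``N* = 1 / (alpha * dt)`` is the
    channel-number threshold of that condition and ``updates = N*alpha*dt``
    is the expected number of MC state updates per timestep (None when N is
    not given).
    """
    if alpha <= 0 or dt <= 0:
        raise ValueError("alpha and dt must be positive")
    n_star = 1.0 / (alpha * dt)
    updates = None if N is None else N * alpha * dt
    return n_star, updates
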