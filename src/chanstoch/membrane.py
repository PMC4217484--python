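"""Single-compartment membrane equation coupled to stochastic channel
populations, plus the stimulus generators and clamp protocols.

The membrane potential obeys

    Cm dV/dt = -gNa x_o^Na (V - ENa) - gK x_o^K (V - EK) - gl (V - El) + I(t)

with ``x_o`` the fraction of channels in the conducting state (m3h1, n4).
Integration is forward Euler with operator splitting: within each timestep
the voltage advances first using the current open fractions, and the
channel populations then advance using the new voltage.

Units: voltages mV, time ms, currents uA/cm^2, conductance densities
mS/cm^2, capacitance uF/cm^2, membrane area um^2, unitary conductance pS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import _kernels
from ._kernels import ALG_CODES
from .engine import SimulationOverflowError, largest_remainder_counts
from .kinetics import KineticScheme, build_scheme, steady_state

__all__ = [
    "MembraneModel",
    "StimulusProtocol",
    "Trace",
    "VClampResult",
    "advance_voltage",
    "channel_count",
    "ou_stimulus",
    "run_current_clamp",
    "run_voltage_clamp",
    "get_scheme",
]


@lru_cache(maxsize=32)
def get_scheme(name: str, sc: float = 1.0) -> KineticScheme:
    """Shared instance of a built-in scheme (compiled arrays are cached
    per instance, so reuse matters)."""
    return build_scheme(name, sc=sc)


def channel_count(area_um2: float, density_ms_cm2: float, gamma_ps: float) -> int:
    """Number of channels on a membrane patch.

    ``round(area * density / gamma)`` with unit conversion: an area in um^2
    carrying a conductance density in mS/cm^2 holds
    ``area * density * 10`` pS of conductance.
    """
    if area_um2 <= 0 or density_ms_cm2 <= 0 or gamma_ps <= 0:
        raise ValueError("area, density and unitary conductance must be positive")
    return int(round(area_um2 * density_ms_cm2 * 10.0 / gamma_ps))


@dataclass
class MembraneModel:
    """Membrane parameters plus the two channel populations.

    ``n_na`` / ``n_k`` are the population sizes used by the stochastic
    algorithms; the conductance densities gNa/gK stay the deterministic
    maxima (the stochastic conductance is gNa * open fraction).
    """

    cm: float = 1.0
    gna: float = 120.0
    gk: float = 36.0
    gl: float = 0.1
    ena: float = 50.0
    ek: float = -77.0
    el: float = -54.3
    v_init: float = -65.0
    n_na: int = 5000
    n_k: int = 1500
    na_scheme: KineticScheme = field(default_factory=lambda: get_scheme("hh_na"))
    k_scheme: KineticScheme = field(default_factory=lambda: get_scheme("hh_k"))
    area_um2: Optional[float] = None
    gamma_ps: float = 20.0

    def __post_init__(self) -> None:
        for g in (self.gna, self.gk, self.gl):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.cm <= 0:
            raise ValueError("Cm must be positive")
        if self.n_na <= 0 or self.n_k <= 0:
            raise ValueError("channel counts must be positive")

    @classmethod
    def hh(cls, n_na: int = 5000, n_k: Optional[int] = None) -> "MembraneModel":
        """Original Hodgkin-Huxley squid model, resting at -65 mV.

        ``n_k`` defaults to ``0.3 * n_na`` (the ratio of the spontaneous-
        firing sweeps).
        """
        if n_k is None:
            n_k = max(1, int(round(0.3 * n_na)))
        return cls(n_na=n_na, n_k=n_k)

    @classmethod
    def sb_single(
        cls, area_um2: float = 314.2, sc: float = 1.0, which: str = "somatic"
    ) -> "MembraneModel":
        """Schmidt-Hieber & Bischofberger single-compartment model.

        Channel numbers follow from the membrane area, the conductance
        densities (20 and 4 mS/cm^2) and a unitary conductance of 20 pS.
        """
        gamma = 20.0
        return cls(
            gna=20.0,
            gk=4.0,
            gl=0.1,
            ena=75.0,
            ek=-95.0,
            el=-70.0,
            v_init=-70.0,
            n_na=channel_count(area_um2, 20.0, gamma),
            n_k=channel_count(area_um2, 4.0, gamma),
            na_scheme=get_scheme(f"sb_na_{which}"),
            k_scheme=get_scheme("sb_k", sc=sc),
            area_um2=area_um2,
            gamma_ps=gamma,
        )


@dataclass
class Trace:
    """Uniformly sampled simulation record."""

    t: np.ndarray
    v: np.ndarray
    stim: Optional[np.ndarray] = None
    states: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("time and voltage must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        cols = {"time": self.t, "V": self.v}
        if self.stim is not None:
            cols["stim"] = self.stim
        cols.update(self.states)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        if "time" in df.columns:
            tcol, vcol = "time", "V"
        else:  # bare two-column replay table
            tcol, vcol = df.columns[:2]
        extra = [c for c in df.columns if c not in (tcol, vcol, "stim")]
        return cls(
            t=df[tcol].to_numpy(),
            v=df[vcol].to_numpy(),
            stim=df["stim"].to_numpy() if "stim" in df.columns else None,
            states={c: df[c].to_numpy() for c in extra},
        )


@dataclass
class StimulusProtocol:
    """Stimulus specification: pulse, constant, Ornstein-Uhlenbeck or a
    replay voltage trace.

    Current amplitudes are uA/cm^2 unless ``area_um2`` is set, in which
    case ``amplitude`` / ``mean`` / ``sd`` are read as nA and divided by
    the membrane area.
    """

    kind: str = "pulse"
    delay: float = 1.0       # ms
    duration: float = 2.0    # ms
    amplitude: float = 0.0   # uA/cm^2 (or nA with area_um2)
    tau: float = 5.0         # ms, OU correlation time
    mean: float = 0.0
    sd: float = 0.0
    seed: Optional[int] = None
    vtrace: Optional[Trace] = None
    area_um2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("pulse", "constant", "ou", "vtrace"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.delay < 0 or self.duration < 0:
            raise ValueError("delay and duration must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def _density(self, value: float) -> float:
        if self.area_um2 is None:
            return value
        # nA over um^2: 1e-3 uA / (area * 1e-8 cm^2)
        return value * 1e5 / self.area_um2

    def samples(self, dt: float, T: float, seed: Optional[int] = None) -> np.ndarray:
        """Per-step current samples on the grid t_k = k*dt, k < round(T/dt)."""
        nsteps = int(round(T / dt))
        t = np.arange(nsteps) * dt
        if self.kind == "constant":
            return np.full(nsteps, self._density(self.amplitude))
        if self.kind == "pulse":
            out = np.zeros(nsteps)
            on = (t >= self.delay) & (t < self.delay + self.duration)
            out[on] = self._density(self.amplitude)
            return out
        if self.kind == "ou":
            s = seed if seed is not None else (self.seed or 0)
            return ou_stimulus(
                self.tau,
                self._density(self.mean),
                self._density(self.sd),
                dt,
                T,
                s,
            )
        raise ValueError("a vtrace stimulus replays voltage; use run_voltage_clamp")


def ou_stimulus(
    tau: float, mean: float, sd: float, dt: float, T: float, seed: int
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck current with correlation time tau.

    Exact discretization (mean reversion factor ``exp(-dt/tau)``, stationary
    standard deviation ``sd`` independent of dt); the first sample is drawn
    from the stationary law.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    nsteps = int(round(T / dt))
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        return np.full(nsteps, mean)
    rho = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    # zero-mean AR(1): x_k = rho x_{k-1} + innov_sd * xi_k, stationary start
    noise = innov_sd * rng.standard_normal(nsteps)
    noise[0] = sd * rng.standard_normal()
    x = lfilter([1.0], [1.0, -rho], noise)
    return mean + x


def advance_voltage(
    V: float,
    open_fractions: tuple[float, float],
    model: MembraneModel,
    I: float,
    dt: float,
) -> float:
    """One forward-Euler step of the membrane equation.

    ``open_fractions`` is (sodium, potassium) conducting-state fractions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    po_na, po_k = open_fractions
    dv = (dt / model.cm) * (
        -model.gna * po_na * (V - model.ena)
        - model.gk * po_k * (V - model.ek)
        - model.gl * (V - model.el)
        + I
    )
    vn = V + dv
    if not math.isfinite(vn):
        raise FloatingPointError(
            f"membrane potential diverged (V={V:g}, open={open_fractions}, I={I:g})"
        )
    return vn


def _kernel_seed(seed: int, *keys: int) -> int:
    """Derive a sub-2^31 kernel seed from a root seed and context keys."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def _initial_state(scheme: KineticScheme, N: int, V: float, algorithm: str) -> np.ndarray:
    x = steady_state(scheme, V)
    if algorithm in ("mc", "ssmc"):
        return largest_remainder_counts(N, x).astype(float)
    return x


def run_current_clamp(
    model: MembraneModel,
    stimulus: StimulusProtocol,
    algorithm: str,
    T: float,
    dt: float = 0.005,
    seed: int = 0,
    v0: Optional[float] = None,
) -> Trace:
    """Coupled current-clamp simulation for ``T`` ms.

    Channels start at the steady state of the initial voltage (default
    ``model.v_init``).  Records V(t), the stimulus and the open fractions
    of both populations; ``trace.meta["updates"]`` counts state updates
    (SSA transitions for mc/ssmc, one per population step otherwise) for
    the N*alpha*dt cost model.

    Raises :class:`SimulationOverflowError` when the unbounded DA state or
    the voltage diverges, reporting the failing step and seed.
    """
    if algorithm not in ALG_CODES:
        raise ValueError(f"unknown algorithm {algorithm!r}; known: {sorted(ALG_CODES)}")
    if stimulus.kind == "vtrace":
        raise ValueError("use run_voltage_clamp for replay-trace protocols")
    v_start = model.v_init if v0 is None else v0
    stim = stimulus.samples(dt, T, seed=None if stimulus.seed is not None else seed)
    alg = ALG_CODES[algorithm]
    cna = model.na_scheme.compiled()
    ck = model.k_scheme.compiled()
    xna0 = _initial_state(model.na_scheme, model.n_na, v_start, algorithm)
    xk0 = _initial_state(model.k_scheme, model.n_k, v_start, algorithm)
    kseed = _kernel_seed(seed, alg)
    status, step, V, open_na, open_k, updates = _kernels.run_current_clamp_kernel(
        alg,
        cna.esrc, cna.edst, cna.fwd_form, cna.fwd_par, cna.fwd_mult,
        cna.bwd_form, cna.bwd_par, cna.bwd_mult, cna.open_edge, cna.conducting,
        ck.esrc, ck.edst, ck.fwd_form, ck.fwd_par, ck.fwd_mult,
        ck.bwd_form, ck.bwd_par, ck.bwd_mult, ck.open_edge, ck.conducting,
        xna0, xk0, model.n_na, model.n_k,
        model.cm, model.gna, model.gk, model.gl, model.ena, model.ek, model.el,
        v_start, stim, dt, kseed,
    )
    if status != _kernels.OK:
        raise SimulationOverflowError(
            f"{algorithm} simulation failed (status {status}) at step {step} "
            f"(t={step * dt:g} ms), N_Na={model.n_na}, N_K={model.n_k}, seed={seed}"
        )
    scale_na = model.n_na if algorithm in ("mc", "ssmc") else 1.0
    scale_k = model.n_k if algorithm in ("mc", "ssmc") else 1.0
    t = np.arange(stim.size + 1) * dt
    return Trace(
        t=t,
        v=V,
        stim=np.append(stim, stim[-1] if stim.size else 0.0),
        states={"na_open": open_na / scale_na, "k_open": open_k / scale_k},
        meta={"algorithm": algorithm, "seed": seed, "dt": dt, "updates": int(updates)},
    )


@dataclass
class VClampResult:
    """Voltage-clamp ensemble: per-replicate open-fraction trajectories."""

    t: np.ndarray
    open: dict  # name -> (n_reps, nsteps+1) open fractions
    counts: dict  # name -> channel number N
    updates: dict  # name -> state-update count (cost model)


def run_voltage_clamp(
    populations: Sequence[tuple[str, KineticScheme, int]],
    vtrace: Trace,
    n_reps: int,
    algorithm: str,
    dt: Optional[float] = None,
    seed: int = 0,
) -> VClampResult:
    """Replay a voltage trace through channel populations only.

    The imposed voltage is linearly interpolated onto the simulation grid
    (replay dt need not equal simulation dt); populations start at the
    steady state of the first voltage sample.  ``algorithm="det"`` yields
    the master-equation expectation E[open](t) with a single replicate.
    """
    if algorithm not in ALG_CODES:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dt is None:
        dt = vtrace.dt
    alg = ALG_CODES[algorithm]
    if alg == _kernels.ALG_DET:
        n_reps = 1
    T = vtrace.duration
    nsteps = int(round(T / dt))
    # voltage governing the advance over [t_k, t_k+dt): V(t_{k+1}), matching
    # the voltage-first splitting of the coupled integration
    t_grid = (np.arange(nsteps) + 1) * dt + vtrace.t[0]
    v_steps = np.interp(t_grid, vtrace.t, vtrace.v)
    out_open: dict[str, np.ndarray] = {}
    out_counts: dict[str, int] = {}
    out_updates: dict[str, int] = {}
    for pidx, (name, scheme, N) in enumerate(populations):
        cs = scheme.compiled()
        x0 = _initial_state(scheme, N, float(vtrace.v[0]), algorithm)
        status, open_arr, updates = _kernels.run_clamped_ensemble_kernel(
            alg,
            cs.esrc, cs.edst, cs.fwd_form, cs.fwd_par, cs.fwd_mult,
            cs.bwd_form, cs.bwd_par, cs.bwd_mult, cs.open_edge, cs.conducting,
            x0, N, v_steps, dt, n_reps, _kernel_seed(seed, alg, pidx),
        )
        if status != _kernels.OK:
            raise SimulationOverflowError(
                f"{algorithm} voltage clamp failed (status {status}) for "
                f"population {name!r}, N={N}, seed={seed}"
            )
        scale = N if algorithm in ("mc", "ssmc") else 1.0
        out_open[name] = open_arr / scale
        out_counts[name] = N
        out_updates[name] = int(updates)
    t = np.arange(nsteps + 1) * dt + vtrace.t[0]
    return VClampResult(t=t, open=out_open, counts=out_counts, updates=out_updates)
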