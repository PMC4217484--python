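"""Stepping algorithms for channel populations.

Six algorithms advance a population one voltage-timestep at a time under a
single contract ``stepper(pop, ctx) -> pop``:

``mc``
    Exact Markov-chain simulation (Gillespie SSA) on integer state counts.
``ua``
    Unbounded diffusion approximation: Euler-Maruyama on state fractions,
    normalization by a dependent state, absolute values inside the noise
    square roots, no bounding.
``ref``
    Reflected SDE: the same proposal followed by Euclidean projection onto
    the probability simplex.
``tr``
    Truncated-and-restored DA: truncation to [0,1] with the remainders
    carried as a residual into the next step, renormalization on violation.
``ssmc``
    Stochastic shielding on real-valued counts: shielded transitions as
    deterministic ODE fluxes, open-adjacent transitions as discrete SSA
    events.
``ssda``
    Stochastic shielding in the DA: identical to ``ua`` but with noise only
    on the open-adjacent edges (2 Brownian terms for the sodium schemes, 1
    for potassium).

A seventh entry ``det`` exposes the deterministic master-equation forward
Euler step that the DA variants reduce to when their noise is suppressed;
it doubles as the expectation oracle for the voltage-clamp tests.

All DA variants share one proposal routine (free states advanced, state 0
recomputed as ``1 - sum(others)``; per-edge noise columns sum to zero so
this equals the full-vector update up to rounding) and differ only in their
constraint repair, which is the identity whenever no constraint is
violated.  With noise suppressed they are therefore bitwise identical to
each other and to ``det``.

These pure-numpy steppers are the reference implementation; the drivers in
:mod:`chanstoch.membrane` run the same algorithms through compiled kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .kinetics import KineticScheme, steady_state

__all__ = [
    "ChannelPopulation",
    "StepContext",
    "SimulationOverflowError",
    "project_simplex",
    "largest_remainder_counts",
    "euler_master_step",
    "ssa_advance",
    "ua_step",
    "ref_step",
    "tr_step",
    "ssmc_step",
    "ssda_step",
    "det_step",
    "STEPPERS",
]

#: |sum(x) - 1| above which a normalization repair is considered violated
_NORM_TOL = 1e-12
#: DA state magnitude treated as numerical blow-up
_OVERFLOW_LIMIT = 1e6


class SimulationOverflowError(RuntimeError):
    """A DA state vector became non-finite or unphysically large.

    The unbounded algorithms (ua, ssda) are known to blow up at very small
    channel numbers (tens of channels); the simulation aborts loudly rather
    than flatlining.
    """


@dataclass
class StepContext:
    """Per-step context: voltage (mV), timestep (ms), time (ms), RNG."""

    V: float
    dt: float
    rng: np.random.Generator
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def largest_remainder_counts(N: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic integer counts summing to N from a fraction vector."""
    target = N * np.asarray(fractions, dtype=float)
    counts = np.floor(target).astype(np.int64)
    short = N - int(counts.sum())
    if short > 0:
        order = np.argsort(-(target - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


@dataclass
class ChannelPopulation:
    """A population of N identical channels of one kinetic scheme.

    ``X`` holds integer state counts (as float64) for the discrete
    algorithms (mc, ssmc) or state fractions for the DA variants.  The MC
    waiting-time bookkeeping (pending uniform draw ``xi1``, previous
    transition time ``t_p``) and the TR residual vector live here so that
    steppers are stateless.
    """

    scheme: KineticScheme
    N: int
    X: np.ndarray
    representation: str = "fractions"  # or "counts"
    xi1: float = -1.0  # negative: no pending draw yet
    t_p: float = 0.0
    residual: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be a positive integer")
        if self.representation not in ("counts", "fractions"):
            raise ValueError("representation must be 'counts' or 'fractions'")
        self.X = np.asarray(self.X, dtype=float).copy()
        if self.X.shape != (self.scheme.n_states,):
            raise ValueError("state vector length must match the scheme")
        if self.residual is None:
            self.residual = np.zeros(self.scheme.n_states)

    @classmethod
    def from_steady_state(
        cls,
        scheme: KineticScheme,
        N: int,
        V: float,
        representation: str = "fractions",
        rng: Optional[np.random.Generator] = None,
    ) -> "ChannelPopulation":
        """Population initialized at the stationary law of ``scheme`` at V.

        Counts are derived from the stationary fractions by deterministic
        largest-remainder rounding; pass ``rng`` to draw them from the
        multinomial instead.
        """
        x = steady_state(scheme, V)
        if representation == "counts":
            if rng is not None:
                counts = rng.multinomial(N, x / x.sum())
            else:
                counts = largest_remainder_counts(N, x)
            return cls(scheme, N, counts.astype(float), "counts")
        return cls(scheme, N, x, "fractions")

    @property
    def open_fraction(self) -> float:
        s = sum(self.X[c] for c in self.scheme.conducting)
        return s / self.N if self.representation == "counts" else s


def project_simplex(x: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``x`` onto the probability simplex.

    Sort-based exact algorithm (O(S log S)); idempotent, and the identity
    on inputs already feasible to within 1e-12 on the normalization so that
    reflection fires only on genuine constraint violations.
    """
    x = np.asarray(x, dtype=float)
    if np.all(x >= 0.0) and abs(x.sum() - 1.0) <= _NORM_TOL:
        return x.copy()
    u = np.sort(x)[::-1]
    css = np.cumsum(u)
    ks = np.arange(1, x.size + 1)
    cond = u - (css - 1.0) / ks > 0.0
    rho = int(np.nonzero(cond)[0][-1])
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(x - theta, 0.0)


def _em_proposal(
    pop: ChannelPopulation,
    ctx: StepContext,
    noise: str,
) -> np.ndarray:
    """Shared Euler-Maruyama proposal (see module docstring).

    noise: "off" | "all_abs" | "all_clamp" | "open_abs".
    """
    scheme = pop.scheme
    X = pop.X
    fr, br = scheme.edge_rates(ctx.V)
    out = X.copy()
    for k, e in enumerate(scheme.edges):
        phi = (fr[k] * X[e.source] - br[k] * X[e.target]) * ctx.dt
        out[e.source] -= phi
        out[e.target] += phi
    if noise != "off":
        open_mask = scheme.open_edge_mask()
        sq_dt_n = math.sqrt(ctx.dt / pop.N)
        for k, e in enumerate(scheme.edges):
            if noise == "open_abs" and not open_mask[k]:
                continue
            if noise == "all_clamp":
                arg = max(fr[k] * X[e.source] + br[k] * X[e.target], 0.0)
            else:
                arg = fr[k] * abs(X[e.source]) + br[k] * abs(X[e.target])
            g = math.sqrt(arg) * sq_dt_n * ctx.rng.standard_normal()
            out[e.source] += g
            out[e.target] -= g
    out[0] = 1.0 - out[1:].sum()
    return out


def _check_finite(pop: ChannelPopulation, ctx: StepContext, X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)) or np.any(np.abs(X) > _OVERFLOW_LIMIT):
        raise SimulationOverflowError(
            f"state overflow at t={ctx.t:g} ms (scheme {pop.scheme.name!r}, "
            f"N={pop.N}); the unbounded DA is unstable at low channel numbers"
        )


def euler_master_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Deterministic forward-Euler step of ``dX/dt = A(V) X``."""
    pop.X = _em_proposal(pop, ctx, "off")
    return pop


det_step = euler_master_step


def ua_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Unbounded DA step: no bounding, ``|x|`` inside the noise roots."""
    X = _em_proposal(pop, ctx, "all_abs")
    _check_finite(pop, ctx, X)
    pop.X = X
    return pop


def ssda_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """UA step with noise restricted to the open-adjacent edges."""
    X = _em_proposal(pop, ctx, "open_abs")
    _check_finite(pop, ctx, X)
    pop.X = X
    return pop


def ref_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Reflected SDE step: proposal, then projection onto the simplex."""
    X = _em_proposal(pop, ctx, "all_clamp")
    _check_finite(pop, ctx, X)
    pop.X = project_simplex(X)
    return pop


def tr_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Truncated-and-restored DA step.

    The proposal is incremented with the residual carried from the previous
    step; entries are truncated to [0,1]; the truncation remainders become
    the new residual; the truncated vector is renormalized to sum 1 when a
    constraint was violated.
    """
    Xstar = _em_proposal(pop, ctx, "all_clamp") + pop.residual
    _check_finite(pop, ctx, Xstar)
    Xtr = np.clip(Xstar, 0.0, 1.0)
    pop.residual = Xstar - Xtr
    if np.any(Xtr != Xstar) or abs(Xtr.sum() - 1.0) > _NORM_TOL:
        s = Xtr.sum()
        if s <= 0.0:
            raise SimulationOverflowError(
                f"TR renormalization by non-positive sum {s:g} at t={ctx.t:g} ms"
            )
        Xtr = Xtr / s
    pop.X = Xtr
    return pop


def _directed_propensities(pop, fr, br, open_only, open_mask):
    """(2E,) propensity vector: forward transitions then backward."""
    E = len(pop.scheme.edges)
    a = np.zeros(2 * E)
    for k, e in enumerate(pop.scheme.edges):
        if open_only and not open_mask[k]:
            continue
        a[k] = fr[k] * pop.X[e.source]
        a[E + k] = br[k] * pop.X[e.target]
    return a


def _ssa_events(pop, ctx, fr, br, open_only, open_mask, t_end) -> int:
    """SSA event loop shared by mc and ssmc; mutates pop.X/xi1/t_p."""
    edges = pop.scheme.edges
    E = len(edges)
    if pop.xi1 <= 0.0:
        pop.xi1 = float(ctx.rng.random())
    a = _directed_propensities(pop, fr, br, open_only, open_mask)
    events = 0
    while True:
        lam = a.sum()
        if lam <= 0.0:
            break  # t_n = +inf: no transition this step
        t_n = pop.t_p - math.log(pop.xi1) / lam
        if t_n > t_end:
            break
        u = float(ctx.rng.random()) * lam
        sel = int(np.searchsorted(np.cumsum(a), u, side="right"))
        sel = min(sel, 2 * E - 1)
        if sel < E:
            i, j = edges[sel].source, edges[sel].target
        else:
            i, j = edges[sel - E].target, edges[sel - E].source
        pop.X[i] -= 1.0
        pop.X[j] += 1.0
        if pop.X[i] < -0.5:
            raise RuntimeError("negative channel count: SSA bookkeeping bug")
        events += 1
        pop.t_p = t_n
        pop.xi1 = float(ctx.rng.random())
        for k, e in enumerate(edges):
            if open_only and not open_mask[k]:
                continue
            if e.source in (i, j):
                a[k] = fr[k] * pop.X[e.source]
            if e.target in (i, j):
                a[E + k] = br[k] * pop.X[e.target]
    return events


def ssa_advance(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Exact SSA advance of integer counts across one voltage timestep.

    Rates are frozen at ctx.V for the step.  The candidate transition time
    ``t_n = t_p - log(xi1)/lambda`` is recomputed each call from the stored
    uniform draw and the current total propensity; transitions execute while
    ``t_n <= t + dt``, redrawing xi1 after each.
    """
    if pop.representation != "counts":
        raise ValueError("ssa_advance requires the counts representation")
    fr, br = pop.scheme.edge_rates(ctx.V)
    mask = pop.scheme.open_edge_mask()
    _ssa_events(pop, ctx, fr, br, False, mask, ctx.t + ctx.dt)
    return pop


def ssmc_step(pop: ChannelPopulation, ctx: StepContext) -> ChannelPopulation:
    """Stochastic-shielding hybrid step on real-valued counts.

    Shielded (non-open-adjacent) transitions advance as deterministic Euler
    fluxes; open-adjacent transitions fire as discrete unit jumps.  Values
    are clipped to [0, N] and the reference state 0 recomputed as
    N - sum(others).
    """
    if pop.representation != "counts":
        raise ValueError("ssmc_step requires the counts representation")
    scheme = pop.scheme
    fr, br = scheme.edge_rates(ctx.V)
    mask = scheme.open_edge_mask()
    delta = np.zeros(scheme.n_states)
    for k, e in enumerate(scheme.edges):
        if mask[k]:
            continue
        phi = (fr[k] * pop.X[e.source] - br[k] * pop.X[e.target]) * ctx.dt
        delta[e.source] -= phi
        delta[e.target] += phi
    pop.X += delta
    _ssa_events(pop, ctx, fr, br, True, mask, ctx.t + ctx.dt)
    np.clip(pop.X[1:], 0.0, pop.N, out=pop.X[1:])
    pop.X[0] = pop.N - pop.X[1:].sum()
    return pop


STEPPERS: dict[str, Callable[[ChannelPopulation, StepContext], ChannelPopulation]] = {
    "mc": ssa_advance,
    "ua": ua_step,
    "ref": ref_step,
    "tr": tr_step,
    "ssmc": ssmc_step,
    "ssda": ssda_step,
    "det": det_step,
}
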