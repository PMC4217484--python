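"""Channel kinetic schemes: states, voltage-dependent rates, and the matrices
derived from them.

A kinetic scheme is a connected graph of channel states with bidirectional
edges; each edge carries a forward and a backward voltage-dependent rate
(ms^-1).  From one scheme description this module derives everything the
simulation algorithms need:

* per-edge transition rates at a voltage ``V`` (Gillespie propensities),
* the drift matrix ``A(V)`` of the population master equation
  ``dX/dt = A X``,
* the noise matrix ``S(X, V)`` of the chemical Langevin equation, with one
  column of entries ``+/- sqrt(alpha_e * x_i + beta_e * x_j)`` per edge,
* the steady-state occupancy at a clamped voltage.

Rates are restricted to four parametric forms (constant, linoid,
exponential, sigmoid) which cover the Hodgkin-Huxley squid model and the
Schmidt-Hieber & Bischofberger (SB) granule-cell sodium model; the forms are
also what the YAML scheme loader accepts.

State ordering is fixed and shared by every matrix, file and test in the
package: sodium ``[m0h0, m1h0, m2h0, m3h0, m0h1, m1h1, m2h1, m3h1]``
(conducting state ``m3h1``), potassium ``[n0, n1, n2, n3, n4]``
(conducting state ``n4``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import yaml
from scipy.linalg import null_space

__all__ = [
    "RateForm",
    "Edge",
    "KineticScheme",
    "CompiledScheme",
    "eval_hh_rates",
    "eval_sb_rates",
    "eval_rates",
    "build_scheme",
    "scheme_from_yaml",
    "drift_matrix",
    "noise_matrix",
    "steady_state",
    "SCHEME_NAMES",
]

# Numeric codes shared with the numba kernels in ``_kernels``.
FORM_CONSTANT = 0
FORM_LINOID = 1
FORM_EXPONENTIAL = 2
FORM_SIGMOID = 3

#: half-width of the series-expansion window around a linoid singularity (mV)
LINOID_EPS = 1e-6


@dataclass(frozen=True)
class RateForm:
    """One voltage-dependent rate in a parametric functional form.

    form = "constant":     a
    form = "linoid":       a * (V - th) / (1 - exp(-(V - th) / q))
    form = "exponential":  a * exp(b * (V - th))
    form = "sigmoid":      a / (1 + c * exp(b * (V - th)))

    The linoid form has a removable singularity at ``V == th``; it is
    evaluated by a second-order series expansion for ``|V - th| < 1e-6`` mV
    so near-singular voltages stay accurate (limit value ``a * q``).
    """

    form: str
    a: float
    b: float = 0.0
    th: float = 0.0
    c: float = 0.0

    def __call__(self, v: float) -> float:
        if self.form == "constant":
            return self.a
        if self.form == "linoid":
            x = v - self.th
            q = self.c
            if abs(x) < LINOID_EPS:
                # x / (1 - e^(-x/q)) = q + x/2 + x^2/(12 q) + O(x^3)
                return self.a * (q + 0.5 * x + x * x / (12.0 * q))
            return self.a * x / (1.0 - math.exp(-x / q))
        if self.form == "exponential":
            return self.a * math.exp(self.b * (v - self.th))
        if self.form == "sigmoid":
            return self.a / (1.0 + self.c * math.exp(self.b * (v - self.th)))
        raise ValueError(f"unknown rate form {self.form!r}")

    @property
    def code(self) -> int:
        return {
            "constant": FORM_CONSTANT,
            "linoid": FORM_LINOID,
            "exponential": FORM_EXPONENTIAL,
            "sigmoid": FORM_SIGMOID,
        }[self.form]

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.th, self.c)


def _linoid(a: float, th: float, q: float) -> RateForm:
    return RateForm("linoid", a=a, th=th, c=q)


def _expo(a: float, b: float, th: float = 0.0) -> RateForm:
    return RateForm("exponential", a=a, b=b, th=th)


def _sigmoid(a: float, c: float, b: float, th: float = 0.0) -> RateForm:
    return RateForm("sigmoid", a=a, b=b, th=th, c=c)


# ---------------------------------------------------------------------------
# Rate sets
# ---------------------------------------------------------------------------

# Original Hodgkin-Huxley rates (squid axon, 6.3 C), shifted so that the
# resting potential sits at -65 mV.  All rates in ms^-1, V in mV.
HH_RATES: Mapping[str, RateForm] = {
    "alpha_m": _linoid(0.1, -40.0, 10.0),
    "beta_m": _expo(4.0, -1.0 / 18.0, -65.0),
    "alpha_h": _expo(0.07, -1.0 / 20.0, -65.0),
    "beta_h": _sigmoid(1.0, 1.0, -1.0 / 10.0, -35.0),
    "alpha_n": _linoid(0.01, -55.0, 10.0),
    "beta_n": _expo(0.125, -1.0 / 80.0, -65.0),
}

# SB sodium-channel activation/inactivation constants (somatic and axonal
# fits).  alpha_i = a0*exp(a1*V); beta_i = b0*exp(-b1*V);
# alpha_h = ah0 / (1 + ah1*exp(ah2*V)); beta_h = bh0 / (1 + bh1*exp(-bh2*V)).
# The published table contains three typographical slips which are read as
# 162.84, 0.1933 and 0.07496.
_SB_TABLE = {
    "somatic": dict(
        a1_0=45.850, a1_1=0.00239, b1_0=0.0144, b1_1=0.0885,
        a2_0=19.808, a2_1=0.02218, b2_0=0.5650, b2_1=0.06108,
        a3_0=71.812, a3_1=0.0659, b3_0=0.7531, b3_1=0.0365,
        ah_0=0.5757, ah_1=162.84, ah_2=0.0268,
        bh_0=2.8301, bh_1=0.289, bh_2=0.0696,
    ),
    "axonal": dict(
        a1_0=62.648, a1_1=0.0116, b1_0=0.00194, b1_1=0.1377,
        a2_0=34.783, a2_1=0.0299, b2_0=0.0957, b2_1=0.0928,
        a3_0=76.698, a3_1=0.0537, b3_0=1.2488, b3_1=0.0311,
        ah_0=6.882, ah_1=4654.0, ah_2=0.0296,
        bh_0=3.573, bh_1=0.1933, bh_2=0.07496,
    ),
}


def _sb_rate_forms(which: str) -> dict[str, RateForm]:
    if which not in _SB_TABLE:
        raise ValueError(
            f"unknown SB parameter set {which!r}; expected 'somatic' or 'axonal'"
        )
    p = _SB_TABLE[which]
    return {
        "alpha_1": _expo(p["a1_0"], p["a1_1"]),
        "beta_1": _expo(p["b1_0"], -p["b1_1"]),
        "alpha_2": _expo(p["a2_0"], p["a2_1"]),
        "beta_2": _expo(p["b2_0"], -p["b2_1"]),
        "alpha_3": _expo(p["a3_0"], p["a3_1"]),
        "beta_3": _expo(p["b3_0"], -p["b3_1"]),
        "alpha_h": _sigmoid(p["ah_0"], p["ah_1"], p["ah_2"]),
        "beta_h": _sigmoid(p["bh_0"], p["bh_1"], -p["bh_2"]),
    }


def _sb_k_rate_forms(sc: float) -> dict[str, RateForm]:
    # HH potassium functional forms with the rate constants scaled by sc,
    # the per-compartment kinetic scale factor of the SB model.
    return {
        "alpha_n": _linoid(sc * 0.01, -55.0, 10.0),
        "beta_n": _expo(sc * 0.125, -1.0 / 80.0, -65.0),
    }


def eval_hh_rates(v: float) -> dict[str, float]:
    """Evaluate the six HH rates (ms^-1) at membrane voltage ``v`` (mV).

    Total on finite ``v``; the removable singularities of alpha_m (at
    -40 mV) and alpha_n (at -55 mV) evaluate to their analytic limits.
    """
    return {name: f(v) for name, f in HH_RATES.items()}


def eval_sb_rates(v: float, which: str = "somatic", sc: float = 1.0) -> dict[str, float]:
    """Evaluate the SB sodium rates plus the sc-scaled potassium rates at ``v``.

    Parameters
    ----------
    which : {"somatic", "axonal"}
        Which fitted sodium parameter set to use.
    sc : float
        Scale factor applied to the potassium alpha_n / beta_n constants
        (dimensionless, > 0).
    """
    if sc <= 0:
        raise ValueError("sc must be positive")
    forms = _sb_rate_forms(which)
    forms.update(_sb_k_rate_forms(sc))
    return {name: f(v) for name, f in forms.items()}


# ---------------------------------------------------------------------------
# Schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    """A bidirectional edge: ``source -> target`` at ``fwd_mult * rates[fwd]``
    and ``target -> source`` at ``bwd_mult * rates[bwd]``."""

    source: int
    target: int
    fwd: str
    bwd: str
    fwd_mult: float = 1.0
    bwd_mult: float = 1.0


class CompiledScheme(NamedTuple):
    """Flat-array view of a scheme consumed by the numba kernels."""

    n_states: int
    esrc: np.ndarray        # (E,) int64, edge source state
    edst: np.ndarray        # (E,) int64, edge target state
    fwd_form: np.ndarray    # (E,) int64 functional-form code
    fwd_par: np.ndarray     # (E, 4) float64 [a, b, th, c]
    fwd_mult: np.ndarray    # (E,) float64
    bwd_form: np.ndarray
    bwd_par: np.ndarray
    bwd_mult: np.ndarray
    open_edge: np.ndarray   # (E,) bool, edge incident to a conducting state
    conducting: np.ndarray  # (n_open,) int64


@dataclass(frozen=True, eq=False)
class KineticScheme:
    """A channel state graph with voltage-dependent edge rates.

    ``rates`` maps rate names to :class:`RateForm`; edges reference rates by
    name with an integer multiplicity (e.g. the ``3 alpha_m`` aggregate rate
    of the first activation step).
    """

    name: str
    states: tuple[str, ...]
    edges: tuple[Edge, ...]
    conducting: tuple[int, ...]
    rates: Mapping[str, RateForm] = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        seen_pairs = set()
        touched = set()
        for e in self.edges:
            if not (0 <= e.source < n and 0 <= e.target < n):
                raise ValueError(f"edge {e} references a missing state")
            if e.source == e.target:
                raise ValueError(f"edge {e} connects a state to itself")
            seen_pairs.add(frozenset((e.source, e.target)))
            touched.update((e.source, e.target))
            for rname in (e.fwd, e.bwd):
                if rname not in self.rates:
                    raise ValueError(f"edge rate {rname!r} is not defined")
        if n > 1:
            # connectivity via union-find over the edge list
            parent = list(range(n))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for e in self.edges:
                parent[find(e.source)] = find(e.target)
            if len({find(i) for i in range(n)}) != 1:
                raise ValueError(f"scheme {self.name!r} is not connected")
        for c in self.conducting:
            if not 0 <= c < n:
                raise ValueError("conducting state index out of range")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_rates(self, v: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (forward, backward) aggregate rates at voltage ``v``."""
        rs = eval_rates(self, v)
        fr = np.array([e.fwd_mult * rs[e.fwd] for e in self.edges])
        br = np.array([e.bwd_mult * rs[e.bwd] for e in self.edges])
        return fr, br

    def open_edge_mask(self) -> np.ndarray:
        cond = set(self.conducting)
        return np.array(
            [e.source in cond or e.target in cond for e in self.edges], dtype=bool
        )

    def compiled(self) -> CompiledScheme:
        """Flat arrays for the numba kernels (cached per scheme instance)."""
        cached = _COMPILED_CACHE.get(id(self))
        if cached is not None:
            return cached
        E = self.n_edges
        fwd_par = np.zeros((E, 4))
        bwd_par = np.zeros((E, 4))
        fwd_form = np.zeros(E, dtype=np.int64)
        bwd_form = np.zeros(E, dtype=np.int64)
        for k, e in enumerate(self.edges):
            fwd_form[k] = self.rates[e.fwd].code
            fwd_par[k] = self.rates[e.fwd].params
            bwd_form[k] = self.rates[e.bwd].code
            bwd_par[k] = self.rates[e.bwd].params
        out = CompiledScheme(
            n_states=self.n_states,
            esrc=np.array([e.source for e in self.edges], dtype=np.int64),
            edst=np.array([e.target for e in self.edges], dtype=np.int64),
            fwd_form=fwd_form,
            fwd_par=fwd_par,
            fwd_mult=np.array([e.fwd_mult for e in self.edges]),
            bwd_form=bwd_form,
            bwd_par=bwd_par,
            bwd_mult=np.array([e.bwd_mult for e in self.edges]),
            open_edge=self.open_edge_mask(),
            conducting=np.array(self.conducting, dtype=np.int64),
        )
        _COMPILED_CACHE[id(self)] = out
        return out


_COMPILED_CACHE: dict[int, CompiledScheme] = {}


@lru_cache(maxsize=512)
def _eval_rates_cached(scheme_id: int, v: float) -> Mapping[str, float]:
    scheme = _SCHEMES_BY_ID[scheme_id]
    return {name: f(v) for name, f in scheme.rates.items()}


_SCHEMES_BY_ID: dict[int, KineticScheme] = {}


def eval_rates(scheme: KineticScheme, v: float) -> Mapping[str, float]:
    """Evaluate all named rates of ``scheme`` at ``v``, cached per (scheme, V).

    All stepping algorithms need the full rate set exactly once per
    voltage-timestep, so a small LRU cache keyed on the scheme instance and
    the voltage avoids recomputation within a step.
    """
    if id(scheme) not in _SCHEMES_BY_ID:
        _SCHEMES_BY_ID[id(scheme)] = scheme
    return _eval_rates_cached(id(scheme), float(v))


def _sodium_topology(rate_names: Sequence[tuple[str, str, float, float]]) -> tuple[Edge, ...]:
    """4x2 activation/inactivation grid: two rows of m-steps plus 4 h-edges.

    ``rate_names`` lists the three horizontal steps as
    (fwd, bwd, fwd_mult, bwd_mult).
    """
    edges = []
    for row0 in (0, 4):  # h0 row then h1 row
        for step, (fwd, bwd, fm, bm) in enumerate(rate_names):
            edges.append(Edge(row0 + step, row0 + step + 1, fwd, bwd, fm, bm))
    for col in range(4):  # vertical h-gate edges (h0 -> h1 at alpha_h)
        edges.append(Edge(col, col + 4, "alpha_h", "beta_h"))
    return tuple(edges)


_NA_STATES = ("m0h0", "m1h0", "m2h0", "m3h0", "m0h1", "m1h1", "m2h1", "m3h1")
_K_STATES = ("n0", "n1", "n2", "n3", "n4")


def _potassium_edges() -> tuple[Edge, ...]:
    return tuple(
        Edge(k, k + 1, "alpha_n", "beta_n", float(4 - k), float(k + 1))
        for k in range(4)
    )


SCHEME_NAMES = ("hh_na", "hh_k", "sb_na_somatic", "sb_na_axonal", "sb_k")


def build_scheme(name: str, sc: float = 1.0) -> KineticScheme:
    """Build one of the built-in schemes.

    ``hh_na`` / ``sb_na_somatic`` / ``sb_na_axonal``: 8 states, 10 edges,
    conducting state m3h1.  ``hh_k`` / ``sb_k``: 5 states, 4 edges,
    conducting state n4.  ``sc`` only affects ``sb_k`` (default 1.0, the
    value used for single-compartment runs).
    """
    if name == "hh_na":
        hh_steps = [
            ("alpha_m", "beta_m", 3.0, 1.0),
            ("alpha_m", "beta_m", 2.0, 2.0),
            ("alpha_m", "beta_m", 1.0, 3.0),
        ]
        return KineticScheme(
            name, _NA_STATES, _sodium_topology(hh_steps), (7,), dict(HH_RATES)
        )
    if name == "hh_k":
        return KineticScheme(name, _K_STATES, _potassium_edges(), (4,), dict(HH_RATES))
    if name in ("sb_na_somatic", "sb_na_axonal"):
        which = name.rsplit("_", 1)[1]
        sb_steps = [
            ("alpha_1", "beta_1", 1.0, 1.0),
            ("alpha_2", "beta_2", 1.0, 1.0),
            ("alpha_3", "beta_3", 1.0, 1.0),
        ]
        return KineticScheme(
            name, _NA_STATES, _sodium_topology(sb_steps), (7,), _sb_rate_forms(which)
        )
    if name == "sb_k":
        if sc <= 0:
            raise ValueError("sc must be positive")
        return KineticScheme(name, _K_STATES, _potassium_edges(), (4,), _sb_k_rate_forms(sc))
    raise ValueError(f"unknown scheme {name!r}; known: {SCHEME_NAMES}")


_YAML_FORMS: dict[str, Callable[..., RateForm]] = {
    "constant": lambda a: RateForm("constant", a=a),
    "linoid": _linoid,
    "exponential": _expo,
    "sigmoid": _sigmoid,
}


def scheme_from_yaml(source) -> KineticScheme:
    """Load a user-defined scheme from a YAML file, string or mapping.

    Expected layout::

        name: my_channel
        states: [closed, open]
        conducting: [open]
        rates:
          alpha: {form: exponential, a: 1.0, b: 0.05}
          beta:  {form: constant, a: 0.5}
        edges:
          - {source: closed, target: open, fwd: alpha, bwd: beta}

    Rate expressions are limited to the built-in functional forms
    (constant, linoid, exponential, sigmoid); edge endpoints may be given
    by state name or index, with optional ``fwd_mult`` / ``bwd_mult``.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = source.read_text() if hasattr(source, "read_text") else str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    states = tuple(str(s) for s in doc["states"])
    index = {s: i for i, s in enumerate(states)}

    def state_idx(v) -> int:
        return index[v] if isinstance(v, str) else int(v)

    rates = {}
    for rname, spec in doc["rates"].items():
        spec = dict(spec)
        form = spec.pop("form")
        if form not in _YAML_FORMS:
            raise ValueError(f"unknown rate form {form!r} for rate {rname!r}")
        rates[rname] = _YAML_FORMS[form](**spec)
    edges = tuple(
        Edge(
            state_idx(e["source"]),
            state_idx(e["target"]),
            e["fwd"],
            e["bwd"],
            float(e.get("fwd_mult", 1.0)),
            float(e.get("bwd_mult", 1.0)),
        )
        for e in doc["edges"]
    )
    conducting = tuple(state_idx(c) for c in doc["conducting"])
    return KineticScheme(str(doc.get("name", "user")), states, edges, conducting, rates)


# ---------------------------------------------------------------------------
# Derived matrices
# ---------------------------------------------------------------------------


def drift_matrix(scheme: KineticScheme, v: float) -> np.ndarray:
    """Drift matrix ``A(v)`` of the master-equation mean dynamics.

    ``dX/dt = A X`` for the state-fraction vector X.  Off-diagonal entries
    are non-negative and every column sums to zero (probability
    conservation).
    """
    S = scheme.n_states
    A = np.zeros((S, S))
    fr, br = scheme.edge_rates(v)
    for k, e in enumerate(scheme.edges):
        A[e.source, e.source] -= fr[k]
        A[e.target, e.source] += fr[k]
        A[e.target, e.target] -= br[k]
        A[e.source, e.target] += br[k]
    return A


def noise_matrix(
    scheme: KineticScheme,
    X: np.ndarray,
    v: float,
    edges: str = "all",
    use_abs: bool = False,
) -> np.ndarray:
    """Langevin noise matrix ``S(X, v)`` with one column per included edge.

    Column ``e`` for edge (i, j) has ``+g`` on state i and ``-g`` on state j
    with ``g = sqrt(fwd_e * x_i + bwd_e * x_j)``.  With ``use_abs`` the
    absolute values ``|x|`` are used inside the square roots (and only
    there), keeping the entries real when X has left [0, 1].

    ``edges="open_adjacent"`` keeps only columns for edges incident to a
    conducting state (the stochastic-shielding reduction: 2 columns for the
    sodium schemes, 1 for potassium).

    Raises ``ValueError`` if a square-root argument is negative while
    ``use_abs`` is off: that signals a boundary-constraint violation to the
    caller.
    """
    if edges not in ("all", "open_adjacent"):
        raise ValueError("edges must be 'all' or 'open_adjacent'")
    X = np.asarray(X, dtype=float)
    if X.shape != (scheme.n_states,):
        raise ValueError("X length must equal the number of states")
    fr, br = scheme.edge_rates(v)
    mask = (
        scheme.open_edge_mask()
        if edges == "open_adjacent"
        else np.ones(scheme.n_edges, dtype=bool)
    )
    cols = np.nonzero(mask)[0]
    S = np.zeros((scheme.n_states, len(cols)))
    Xeff = np.abs(X) if use_abs else X
    for out_k, k in enumerate(cols):
        e = scheme.edges[k]
        arg = fr[k] * Xeff[e.source] + br[k] * Xeff[e.target]
        if arg < 0:
            raise ValueError(
                f"negative square-root argument on edge {e.source}-{e.target}: "
                "state fractions violate the boundary constraint "
                "(enable use_abs for the unbounded algorithms)"
            )
        g = math.sqrt(arg)
        S[e.source, out_k] = g
        S[e.target, out_k] = -g
    return S


def steady_state(scheme: KineticScheme, v: float) -> np.ndarray:
    """Stationary state-fraction vector at clamped voltage ``v``.

    Solves ``A(v) x = 0`` with ``sum(x) = 1`` via the null space of the
    drift matrix.  Raises for schemes whose stationary distribution is not
    unique (disconnected or degenerate graphs).
    """
    A = drift_matrix(scheme, v)
    ns = null_space(A)
    if ns.shape[1] != 1:
        raise ValueError(
            f"scheme {scheme.name!r} has a {ns.shape[1]}-dimensional stationary "
            "space at V={v}; expected a unique stationary distribution"
        )
    x = ns[:, 0]
    x = x / x.sum()
    # null-space rounding can leave tiny negative entries
    x = np.clip(x, 0.0, None)
    return x / x.sum()
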