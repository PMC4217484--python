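"""Compiled (numba) inner loops shared by the stepping engine and the
membrane drivers.

Everything here operates on the flat-array view of a scheme
(:meth:`chanstoch.kinetics.KineticScheme.compiled`) and on plain float64
state vectors:

* state fractions for the diffusion-approximation (DA) algorithms,
* real-valued channel counts for MC (exact integers) and SSmc.

Algorithm codes (shared with :mod:`chanstoch.engine`):

====  =====================================================
0     deterministic master-equation forward Euler ("det")
1     Markov chain / Gillespie SSA ("mc")
2     unbounded DA with absolute values ("ua")
3     reflected DA, simplex projection ("ref")
4     truncated-and-restored DA ("tr")
5     stochastic shielding, discrete open transitions ("ssmc")
6     stochastic shielding with DA noise terms ("ssda")
====  =====================================================

Randomness comes from numba's internal np.random state, seeded once per
kernel call; a given (seed, arguments) pair is fully reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ALG_DET = 0
ALG_MC = 1
ALG_UA = 2
ALG_REF = 3
ALG_TR = 4
ALG_SSMC = 5
ALG_SSDA = 6

ALG_CODES = {
    "det": ALG_DET,
    "mc": ALG_MC,
    "ua": ALG_UA,
    "ref": ALG_REF,
    "tr": ALG_TR,
    "ssmc": ALG_SSMC,
    "ssda": ALG_SSDA,
}

# status codes returned by the drivers
OK = 0
ERR_VOLTAGE = 1      # non-finite membrane potential
ERR_OVERFLOW = 2     # DA state overflow / non-finite
ERR_NEG_COUNT = 3    # negative channel count (internal bug guard)
ERR_BAD_RENORM = 4   # TR renormalization with non-positive sum

_LINOID_EPS = 1e-6


@njit(cache=True)
def _rate_value(form, a, b, th, c, v):
    if form == 0:  # constant
        return a
    if form == 1:  # linoid, c holds the slope scale q
        x = v - th
        if abs(x) < _LINOID_EPS:
            return a * (c + 0.5 * x + x * x / (12.0 * c))
        return a * x / (1.0 - np.exp(-x / c))
    if form == 2:  # exponential
        return a * np.exp(b * (v - th))
    # sigmoid
    return a / (1.0 + c * np.exp(b * (v - th)))


@njit(cache=True)
def _edge_rates(v, fwd_form, fwd_par, fwd_mult, bwd_form, bwd_par, bwd_mult, fr, br):
    for k in range(fr.size):
        fr[k] = fwd_mult[k] * _rate_value(
            fwd_form[k], fwd_par[k, 0], fwd_par[k, 1], fwd_par[k, 2], fwd_par[k, 3], v
        )
        br[k] = bwd_mult[k] * _rate_value(
            bwd_form[k], bwd_par[k, 0], bwd_par[k, 1], bwd_par[k, 2], bwd_par[k, 3], v
        )


# noise modes for the Euler-Maruyama proposal
NOISE_OFF = 0
NOISE_ALL_ABS = 1     # all edges, |x| inside the square roots (UA)
NOISE_ALL_CLAMP = 2   # all edges, sqrt arguments clamped at 0 (Ref, TR)
NOISE_OPEN_ABS = 3    # open-adjacent edges only, |x| (SSda)


@njit(cache=True)
def _em_proposal(X, out, fr, br, esrc, edst, dt, sq_dt_n, noise_mode, open_edge):
    """One Euler-Maruyama proposal with the dependent-state normalization.

    Free states (indices 1..S-1) get drift + per-edge noise; state 0 is then
    recomputed as 1 - sum(others).  Because each noise column sums to zero
    across states this is equivalent, up to rounding, to advancing the full
    vector; it is the single code path every DA variant shares.
    """
    S = X.size
    for i in range(S):
        out[i] = X[i]
    for k in range(esrc.size):
        i = esrc[k]
        j = edst[k]
        phi = (fr[k] * X[i] - br[k] * X[j]) * dt
        out[i] -= phi
        out[j] += phi
    if noise_mode != NOISE_OFF:
        for k in range(esrc.size):
            if noise_mode == NOISE_OPEN_ABS and not open_edge[k]:
                continue
            i = esrc[k]
            j = edst[k]
            if noise_mode == NOISE_ALL_CLAMP:
                arg = fr[k] * X[i] + br[k] * X[j]
                if arg < 0.0:
                    arg = 0.0
            else:
                arg = fr[k] * abs(X[i]) + br[k] * abs(X[j])
            g = np.sqrt(arg) * sq_dt_n * np.random.normal(0.0, 1.0)
            out[i] += g
            out[j] -= g
    s = 0.0
    for i in range(1, S):
        s += out[i]
    out[0] = 1.0 - s


@njit(cache=True)
def _project_simplex(x):
    """Euclidean projection onto {y >= 0, sum y = 1}, in place.

    Identity (bit-preserving) when x is already feasible to within 1e-12 on
    the normalization, so the projection fires only on actual violations.
    Sort-based exact algorithm; S <= 8 in practice.
    """
    S = x.size
    s = 0.0
    neg = False
    for i in range(S):
        s += x[i]
        if x[i] < 0.0:
            neg = True
    if not neg and abs(s - 1.0) <= 1e-12:
        return
    u = np.sort(x)[::-1]
    css = 0.0
    theta = 0.0
    for i in range(S):
        css += u[i]
        t = (css - 1.0) / (i + 1)
        if u[i] - t > 0.0:
            theta = t
    for i in range(S):
        v = x[i] - theta
        x[i] = v if v > 0.0 else 0.0


@njit(cache=True)
def _tr_repair(xstar, r):
    """Truncate xstar to [0,1], store the remainders in r, renormalize.

    Renormalization (division by the post-truncation sum) runs only when a
    constraint was actually violated.  Returns OK or ERR_BAD_RENORM.
    """
    S = xstar.size
    violated = False
    s = 0.0
    for i in range(S):
        xi = xstar[i]
        xt = xi
        if xt < 0.0:
            xt = 0.0
        elif xt > 1.0:
            xt = 1.0
        r[i] = xi - xt
        if xt != xi:
            violated = True
        xstar[i] = xt
        s += xt
    if violated or abs(s - 1.0) > 1e-12:
        if s <= 0.0:
            return ERR_BAD_RENORM
        for i in range(S):
            xstar[i] /= s
    return OK


@njit(cache=True)
def _ssa_advance(X, fr, br, esrc, edst, open_edge, open_only, ssa_state, t_end):
    """Gillespie SSA over one voltage timestep at frozen rates.

    X holds per-state channel counts (float64 integers).  ssa_state is
    [xi1, t_p]: the pending uniform draw (negative = draw a fresh one) and
    the time of the previous transition.  The candidate transition time
    t_n = t_p - log(xi1) / lambda is recomputed from the stored xi1 and the
    current total propensity each call, following the per-timestep coupling
    of the membrane equation.  With open_only, only transitions on edges
    incident to a conducting state are simulated (the SSmc hybrid).

    Returns the number of executed transitions, or -1 on a negative count.
    """
    E = esrc.size
    a = np.empty(2 * E)
    lam = 0.0
    for k in range(E):
        if open_only and not open_edge[k]:
            a[k] = 0.0
            a[E + k] = 0.0
        else:
            a[k] = fr[k] * X[esrc[k]]
            a[E + k] = br[k] * X[edst[k]]
            lam += a[k] + a[E + k]
    xi1 = ssa_state[0]
    tp = ssa_state[1]
    if xi1 <= 0.0:
        xi1 = np.random.random()
    events = 0
    refresh = 0
    while True:
        if lam <= 1e-300:
            break
        tn = tp - np.log(xi1) / lam
        if tn > t_end:
            break
        u = np.random.random() * lam
        acc = 0.0
        sel = 2 * E - 1
        for k in range(2 * E):
            acc += a[k]
            if acc > u:
                sel = k
                break
        if sel < E:
            i = esrc[sel]
            j = edst[sel]
        else:
            i = edst[sel - E]
            j = esrc[sel - E]
        X[i] -= 1.0
        X[j] += 1.0
        if X[i] < -0.5:
            return -1
        events += 1
        tp = tn
        xi1 = np.random.random()
        # incremental propensity update for the two touched states
        for k in range(E):
            if open_only and not open_edge[k]:
                continue
            sk = esrc[k]
            dk = edst[k]
            if sk == i or sk == j:
                nv = fr[k] * X[sk]
                lam += nv - a[k]
                a[k] = nv
            if dk == i or dk == j:
                nv = br[k] * X[dk]
                lam += nv - a[E + k]
                a[E + k] = nv
        refresh += 1
        if refresh >= 1024:
            # periodic full recompute to stop float drift of lambda
            refresh = 0
            lam = 0.0
            for k in range(2 * E):
                lam += a[k]
    ssa_state[0] = xi1
    ssa_state[1] = tp
    return events


@njit(cache=True)
def _ssmc_step(X, fr, br, esrc, edst, open_edge, ssa_state, N, dt, t_end):
    """Stochastic-shielding hybrid step on real-valued counts in [0, N].

    Shielded edges advance by a deterministic Euler flux; open-adjacent
    edges fire as discrete unit jumps via the SSA.  Out-of-range values are
    clipped to [0, N] and the reference state 0 is recomputed as
    N - sum(others).
    """
    S = X.size
    delta = np.zeros(S)
    for k in range(esrc.size):
        if open_edge[k]:
            continue
        i = esrc[k]
        j = edst[k]
        phi = (fr[k] * X[i] - br[k] * X[j]) * dt
        delta[i] -= phi
        delta[j] += phi
    for i in range(S):
        X[i] += delta[i]
    events = _ssa_advance(X, fr, br, esrc, edst, open_edge, True, ssa_state, t_end)
    if events < 0:
        return events
    s = 0.0
    for i in range(1, S):
        if X[i] < 0.0:
            X[i] = 0.0
        elif X[i] > N:
            X[i] = N
        s += X[i]
    X[0] = N - s
    return events


@njit(cache=True)
def _advance_population(
    alg, X, resid, ssa_state, tmp, fr, br,
    esrc, edst, fwd_form, fwd_par, fwd_mult, bwd_form, bwd_par, bwd_mult,
    open_edge, N, v, dt, t_end,
):
    """Advance one channel population across [t_end - dt, t_end] at voltage v.

    Returns (status, updates): updates is the SSA transition count for
    MC/SSmc and 1 for the per-step DA/deterministic update (the unit of the
    N*alpha*dt cost model).
    """
    _edge_rates(v, fwd_form, fwd_par, fwd_mult, bwd_form, bwd_par, bwd_mult, fr, br)
    if alg == ALG_MC:
        ev = _ssa_advance(X, fr, br, esrc, edst, open_edge, False, ssa_state, t_end)
        if ev < 0:
            return ERR_NEG_COUNT, 0
        return OK, ev
    if alg == ALG_SSMC:
        ev = _ssmc_step(X, fr, br, esrc, edst, open_edge, ssa_state, N, dt, t_end)
        if ev < 0:
            return ERR_NEG_COUNT, 0
        return OK, ev
    sq_dt_n = np.sqrt(dt / N)
    if alg == ALG_DET:
        mode = NOISE_OFF
    elif alg == ALG_UA:
        mode = NOISE_ALL_ABS
    elif alg == ALG_SSDA:
        mode = NOISE_OPEN_ABS
    else:  # Ref, TR
        mode = NOISE_ALL_CLAMP
    _em_proposal(X, tmp, fr, br, esrc, edst, dt, sq_dt_n, mode, open_edge)
    if alg == ALG_REF:
        _project_simplex(tmp)
    elif alg == ALG_TR:
        for i in range(X.size):
            tmp[i] += resid[i]
        st = _tr_repair(tmp, resid)
        if st != OK:
            return st, 0
    ok = True
    for i in range(X.size):
        X[i] = tmp[i]
        if not np.isfinite(tmp[i]) or abs(tmp[i]) > 1e6:
            ok = False
    if not ok:
        return ERR_OVERFLOW, 0
    return OK, 1


@njit(cache=True)
def _open_total(X, conducting):
    s = 0.0
    for c in conducting:
        s += X[c]
    return s


@njit(cache=True)
def run_current_clamp_kernel(
    alg,
    # sodium scheme
    na_esrc, na_edst, na_ff, na_fp, na_fm, na_bf, na_bp, na_bm, na_open, na_cond,
    # potassium scheme
    k_esrc, k_edst, k_ff, k_fp, k_fm, k_bf, k_bp, k_bm, k_open, k_cond,
    xna0, xk0, n_na, n_k,
    cm, gna, gk, gl, ena, ek, el,
    v0, stim, dt, seed,
):
    """Coupled current-clamp run: membrane Euler step, then channel advance.

    Within each dt the voltage is advanced first using the current open
    fractions, and the populations then advance using the new voltage.
    xna0/xk0 are the initial state vectors in the representation the
    algorithm uses (fractions for DA, counts for MC/SSmc).

    Returns (status, err_step, V, open_na, open_k, updates) where the open
    arrays are in the native units of the representation.
    """
    np.random.seed(seed)
    nsteps = stim.size
    V = np.empty(nsteps + 1)
    open_na = np.empty(nsteps + 1)
    open_k = np.empty(nsteps + 1)
    V[0] = v0
    Xna = xna0.copy()
    Xk = xk0.copy()
    rna = np.zeros(Xna.size)
    rk = np.zeros(Xk.size)
    ssa_na = np.array([-1.0, 0.0])
    ssa_k = np.array([-1.0, 0.0])
    fr_na = np.empty(na_esrc.size)
    br_na = np.empty(na_esrc.size)
    fr_k = np.empty(k_esrc.size)
    br_k = np.empty(k_esrc.size)
    tna = np.empty(Xna.size)
    tk = np.empty(Xk.size)
    counts_repr = alg == ALG_MC or alg == ALG_SSMC
    na_scale = n_na if counts_repr else 1.0
    k_scale = n_k if counts_repr else 1.0
    updates = 0
    for step in range(nsteps):
        po_na = _open_total(Xna, na_cond)
        po_k = _open_total(Xk, k_cond)
        open_na[step] = po_na
        open_k[step] = po_k
        v = V[step]
        dv = (dt / cm) * (
            -gna * (po_na / na_scale) * (v - ena)
            - gk * (po_k / k_scale) * (v - ek)
            - gl * (v - el)
            + stim[step]
        )
        vn = v + dv
        if not np.isfinite(vn):
            return ERR_VOLTAGE, step, V, open_na, open_k, updates
        V[step + 1] = vn
        t_end = (step + 1) * dt
        st, up = _advance_population(
            alg, Xna, rna, ssa_na, tna, fr_na, br_na,
            na_esrc, na_edst, na_ff, na_fp, na_fm, na_bf, na_bp, na_bm,
            na_open, float(n_na), vn, dt, t_end,
        )
        if st != OK:
            return st, step, V, open_na, open_k, updates
        updates += up
        st, up = _advance_population(
            alg, Xk, rk, ssa_k, tk, fr_k, br_k,
            k_esrc, k_edst, k_ff, k_fp, k_fm, k_bf, k_bp, k_bm,
            k_open, float(n_k), vn, dt, t_end,
        )
        if st != OK:
            return st, step, V, open_na, open_k, updates
        updates += up
    open_na[nsteps] = _open_total(Xna, na_cond)
    open_k[nsteps] = _open_total(Xk, k_cond)
    return OK, nsteps, V, open_na, open_k, updates


@njit(cache=True)
def run_clamped_ensemble_kernel(
    alg,
    esrc, edst, ff, fp, fm, bf, bp, bm, open_edge, cond,
    x0, N, v_steps, dt, n_reps, seed,
):
    """Voltage-clamp ensemble for a single channel population.

    v_steps[k] is the (imposed) voltage used for the advance over step k.
    x0 is the shared initial state in the algorithm's representation.
    Returns (status, open[n_reps, nsteps+1] in native units, updates).
    """
    np.random.seed(seed)
    nsteps = v_steps.size
    S = x0.size
    out = np.empty((n_reps, nsteps + 1))
    fr = np.empty(esrc.size)
    br = np.empty(esrc.size)
    tmp = np.empty(S)
    resid = np.zeros(S)
    ssa = np.array([-1.0, 0.0])
    updates = 0
    for rep in range(n_reps):
        X = x0.copy()
        for i in range(S):
            resid[i] = 0.0
        ssa[0] = -1.0
        ssa[1] = 0.0
        out[rep, 0] = _open_total(X, cond)
        for step in range(nsteps):
            st, up = _advance_population(
                alg, X, resid, ssa, tmp, fr, br,
                esrc, edst, ff, fp, fm, bf, bp, bm,
                open_edge, float(N), v_steps[step], dt, (step + 1) * dt,
            )
            if st != OK:
                return st, out, updates
            updates += up
            out[rep, step + 1] = _open_total(X, cond)
    return OK, out, updates
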