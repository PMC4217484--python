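# Methods

## Model

A membrane patch carries `N_Na` sodium and `N_K` potassium channels, each an
independent continuous-time Markov chain on a small state graph: sodium as an
8-state activation/inactivation grid (states `m_i h_j`, conducting state
`m3h1`), potassium as a 5-state chain (`n0..n4`, conducting `n4`).  Edge rates
are voltage dependent, in one of four parametric forms (constant, linoid,
exponential, sigmoid); two built-in parameter sets are provided — the original
Hodgkin–Huxley squid kinetics shifted to rest at −65 mV, and the
Schmidt-Hieber & Bischofberger (SB) granule-cell sodium model with somatic and
axonal fits plus an `sc`-scaled potassium chain.  The membrane potential obeys

    Cm dV/dt = −gNa x_o^Na (V−ENa) − gK x_o^K (V−EK) − gl (V−El) + I(t)

with `x_o` the conducting-state fraction.  Default parameters (HH): Cm = 1
µF/cm², gNa = 120, gK = 36, gl = 0.1 mS/cm², ENa = 50, EK = −77, El = −54.3 mV;
SB: gNa = 20, gK = 4, gl = 0.1 mS/cm², ENa = 75, EK = −95, El = −70 mV, with
channel counts derived from membrane area at 20 pS unitary conductance
(`N = round(area·density·10/γ)` for area in µm², density in mS/cm², γ in pS).

One detail of the SB inactivation rates deserves mention: the closing rate is
implemented as `βh = βh0 / (1 + βh1·exp(−βh2·V))`.  With a positive exponent
the fitted constants would leave the channel ≥97 % inactivated at every
voltage between −120 and +30 mV — a channel that can never conduct — whereas
the negative exponent gives a sigmoidal availability curve with
half-inactivation near −77 mV, matching the granule-cell characterization the
parameter set comes from.  The opening rate keeps its published form
(`αh → αh0` as V → −∞).

## Algorithms

All six steppers share one contract (advance a population across one voltage
timestep `dt` at frozen rates) and one operator splitting: the voltage is
advanced first by forward Euler using the current open fractions, then the
channels advance using the new voltage.

* **mc** — exact Gillespie SSA on integer counts.  The total propensity is
  `λ = Σ_i N_i ζ_i` (ζ_i the summed escape rates of state i); the candidate
  transition time `t_n = t_p − log(ξ1)/λ` is recomputed every timestep from
  the stored uniform draw `ξ1` and the current λ, transitions execute while
  `t_n ≤ t+dt` with cumulative-sum selection, and ξ1 is redrawn after each.
  This per-timestep coupling (not exact time rescaling) matches the frozen-
  rate treatment of the voltage.
* **ua** — Euler–Maruyama on state fractions:
  `X ← X + A X dt + (dt/N)^{1/2} S(|X|) ξ`, one standard normal per edge, with
  absolute values inside (and only inside) the noise square roots and no
  bounding; normalization is enforced by computing state 0 as 1 − Σ(others).
* **ref** — the same proposal followed by Euclidean projection onto the
  probability simplex (sort-based exact algorithm).
* **tr** — the proposal plus the residual carried from the previous step;
  entries are truncated to [0,1], the truncation remainders become the new
  residual, and the vector is renormalized when a constraint was violated.
  The residual carries the truncation remainder only, not renormalization
  losses.
* **ssmc** — stochastic shielding on real-valued counts: transitions not
  touching a conducting state advance as deterministic Euler fluxes;
  open-adjacent transitions fire as discrete SSA events; values are clipped
  to [0, N] and state 0 recomputed as N − Σ(others).
* **ssda** — ua with noise restricted to open-adjacent edges (2 Brownian
  terms for the sodium schemes, 1 for potassium).

A seventh mode, **det**, is the forward-Euler master-equation integration
`dX/dt = A(V) X`; it serves as the expectation oracle for voltage-clamp
ensembles.

### One proposal, per-variant repair

Every DA variant uses the same proposal routine: free states advanced by
Euler–Maruyama, state 0 computed as 1 − Σ(others).  Because each per-edge
noise column sums to zero across states, this equals the full-vector update
up to floating-point rounding, and it makes the variants differ *only* in
their constraint repair.  The repairs short-circuit to the identity when
nothing is violated (all entries in range and |Σ−1| ≤ 1e−12), so with noise
suppressed ua, ref, tr and ssda produce bitwise-identical trajectories equal
to det — the discretized methods genuinely coincide in their deterministic
limit, and the test suite asserts that equality exactly.

## Numerical choices

* Linoid rates have a removable singularity; within |V−V₀| < 1e−6 mV they are
  evaluated by the series `a(q + x/2 + x²/12q)` rather than an
  equality test, so near-singular voltages stay accurate.
* Rates are evaluated once per (scheme, V) and cached for the step.
* Default dt = 5 µs, with 0.5 µs for stability-sensitive comparisons; these
  are the two steps at which the deterministic trajectories were checked to
  agree (spike-time shift < 0.1 ms on halving).
* Initial conditions: V₀ = −65 mV (HH) or −70 mV (SB), channels at the
  stationary law of V₀.  Note the HH fixed point with gl = 0.1 mS/cm² is
  near −67.8 mV, so a stimulus-free deterministic run drifts ~3 mV before
  settling; V₀ = −65 is retained as configuration, not asserted as a fixed
  point.  Integer counts come from the stationary fractions by deterministic
  largest-remainder rounding (an optional multinomial draw is available).
* MC counts are stored as float64 integers (exact below 2^53); a negative
  count aborts the run as an internal error.
* The unbounded algorithms (ua, ssda) abort with `SimulationOverflowError`
  when a state magnitude exceeds 1e6 or turns non-finite — the documented
  failure mode at very low channel numbers (tens of channels) — rather than
  flatlining silently.
* The Ornstein–Uhlenbeck stimulus uses the exact AR(1) discretization
  (mean-reversion factor `exp(−dt/τ)`), so its stationary moments are
  dt-independent; a stimulus given in nA is converted to µA/cm² by the
  configured membrane area.
* Replay voltage traces are linearly interpolated onto the simulation grid;
  the advance over `[t_k, t_k+dt)` uses `V(t_{k+1})`, mirroring the
  voltage-first splitting of the coupled integration.
* Simplex projection is the exact sort-based algorithm; with S ≤ 8 its cost
  is negligible.
* One global seed expands into per-sweep and per-kernel sub-seeds through a
  counter-based `SeedSequence` scheme, keeping sweeps independent and every
  run exactly reproducible.

## What the generated data emulates — and what it does not

All validation inputs are produced by the package itself: clamp protocols at
analytically known stationary laws, pulse/constant/OU current stimuli, and a
noisy 100-ms voltage trace containing one action potential (a UA run of the
N_Na = 5000 HH model, regenerated deterministically from its seed).  These
reproduce the statistical structure the methods are meant to capture —
binomial occupancy fluctuations, channel-noise-driven threshold crossings,
voltage-locked ensemble moments — but not properties of experimental
recordings (electrode noise, temperature drift, channel subtypes and
modal gating, spatial coupling).  Passing tests therefore demonstrate
fidelity of the simulation algorithms to the underlying Markov model, not
fidelity of that model to any particular neuron.

## Validation design and problem sizes

The statistical suites run at desk scale, chosen so the full set completes in
minutes on one core while keeping every check's standard error well below the
effects of interest: stationary-law checks with N = 1000 channels and 300
independent replicates (3-SE bands); voltage-clamp ensembles with N_Na = 500,
N_K = 160 and 500 replicates; firing-efficiency comparisons with
N_Na = 5000 and 500 sweeps per amplitude (two-proportion tests,
familywise 5 %); spontaneous-firing runs of 50 s at N_Na ∈ {1600, 8000,
50 000}.  Figure-level quantitative reproduction of full-scale sweeps
(10 000 trials, 500-s runs) is intentionally out of scope; direction-of-bias
characterizations stand in for it.

Two domain restrictions are applied deliberately.  First, ensemble-mean and
variance agreement for the diffusion approximations is asserted only where
the Gaussian condition N·E ≳ 1 holds: the resting HH sodium open state at
N_Na = 500 carries ~0.045 expected channels, and there the unbounded scheme
intrinsically overdisperses (a two-state probe gives var/binomial ≈ 2.9 at
N·p = 0.05, falling to 1.0 by N·p ≈ 5) while MC remains exact.  This is the
N·α·dt ≫ 1 accuracy rule at work, not an implementation artifact.  Second,
the reflected method's small positive mean bias and the shielding methods'
variance deficit during the action-potential upstroke are asserted as
directions, not magnitudes.

## Known limitations

* Forward Euler / Euler–Maruyama only; no implicit or higher-order SDE
  integrators, no adaptive dt (the truncate-and-restore bookkeeping is
  defined relative to the plain Euler step).
* Single compartment only; no cable equation or axial coupling.
* Rate expressions are limited to the four built-in functional forms; no
  temperature (Q10) scaling.
* The SSmc boundary repair clips to [0, N] (one of several defensible
  readings of "manual correction"); the reflected method uses the Euclidean
  projection, not a weighted one.
* The SB potassium scale factor `sc` defaults to 1.0 for single-compartment
  runs and is configurable per scheme instance.
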