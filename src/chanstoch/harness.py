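"""Run configuration, protocol drivers, fixture generation and output
writers: every test protocol runs from one config + seed.

A :class:`RunConfig` resolves to one of four protocols:

``clamp``
    a single current-clamp sweep, written as a full trace;
``sweep``
    firing-efficiency / spike-timing statistics over ``n_sweeps``
    repetitions per stimulus amplitude;
``spontaneous``
    long unstimulated runs, reporting the spontaneous rate and ISIs;
``vclamp``
    an ensemble replay of a voltage trace through the channel populations,
    with the deterministic expectation and the binomial variance reference.

One global seed expands into per-sweep sub-seeds through a counter-based
``SeedSequence`` scheme, so sweeps are independent and reproducible
regardless of execution order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    SpikeTrain,
    detect_spikes,
    firing_stats,
    openstate_moments,
    spontaneous_stats,
)
from .membrane import (
    MembraneModel,
    StimulusProtocol,
    Trace,
    run_current_clamp,
    run_voltage_clamp,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "sweep_seed",
    "run_protocol",
    "run_firing_sweeps",
    "run_spontaneous",
    "generate_ap_fixture",
]

ALGORITHMS = ("mc", "ua", "ref", "tr", "ssmc", "ssda")
PROTOCOLS = ("clamp", "sweep", "spontaneous", "vclamp")
MODELS = ("hh", "sb_single")


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def sweep_seed(seed: int, *counters: int) -> int:
    """Counter-based per-sweep sub-seed (< 2^31)."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(c) for c in counters]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Complete description of one simulation run."""

    protocol: str = "clamp"
    model: str = "hh"
    algorithm: str = "mc"
    n_na: Optional[int] = 5000
    n_k: Optional[int] = None     # defaults to 0.3 * n_na
    area_um2: Optional[float] = None  # SB: channel counts from area
    sc: float = 1.0
    dt: float = 0.005             # ms
    t_total: float = 15.0         # ms
    n_sweeps: int = 100
    n_reps: int = 500             # vclamp replicates
    seed: int = 0
    stimulus: dict = field(default_factory=lambda: {"kind": "pulse", "delay": 1.0, "duration": 2.0, "amplitude": 7.0})
    amplitudes: Optional[list] = None  # sweep protocol
    vtrace: Optional[str] = None       # vclamp replay CSV
    threshold: float = 0.0             # spike detection, mV
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError([f"unknown config keys: {sorted(unknown)}"])
        return cls(**doc)

    def validate(self) -> None:
        errors = []
        if self.protocol not in PROTOCOLS:
            errors.append(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if self.model not in MODELS:
            errors.append(f"model must be one of {MODELS}, got {self.model!r}")
        if self.algorithm not in ALGORITHMS + ("det",):
            errors.append(f"algorithm must be one of {ALGORITHMS + ('det',)}, got {self.algorithm!r}")
        if self.dt <= 0:
            errors.append("dt must be positive")
        if self.t_total <= 0:
            errors.append("t_total must be positive")
        if self.n_sweeps < 1:
            errors.append("n_sweeps must be >= 1")
        if self.model == "hh" and (self.n_na is None or self.n_na < 1):
            errors.append("hh model requires a positive n_na")
        if self.model == "sb_single" and self.area_um2 is None and self.n_na is None:
            errors.append("sb_single model requires area_um2 or explicit channel counts")
        if self.protocol == "sweep" and not self.amplitudes:
            errors.append("sweep protocol requires an amplitudes list")
        if self.protocol == "vclamp" and not self.vtrace:
            errors.append("vclamp protocol requires a vtrace file")
        if self.stimulus.get("kind", "pulse") == "vtrace" and self.protocol != "vclamp":
            errors.append("a vtrace stimulus is only valid with the vclamp protocol")
        if errors:
            raise ConfigError(errors)

    def build_model(self) -> MembraneModel:
        if self.model == "hh":
            m = MembraneModel.hh(self.n_na, self.n_k)
        else:
            if self.area_um2 is not None:
                m = MembraneModel.sb_single(self.area_um2, sc=self.sc)
            else:
                m = MembraneModel.sb_single(sc=self.sc)
            if self.n_na:
                m.n_na = self.n_na
            if self.n_k:
                m.n_k = self.n_k
        return m

    def build_stimulus(self) -> StimulusProtocol:
        return StimulusProtocol(**self.stimulus)


def run_firing_sweeps(
    model: MembraneModel,
    stimulus: StimulusProtocol,
    algorithm: str,
    n_sweeps: int,
    T: float,
    dt: float,
    seed: int,
    threshold: float = 0.0,
    amp_index: int = 0,
) -> SpikeTrain:
    """Repeat a current-clamp stimulus ``n_sweeps`` times, collecting spike
    times per sweep with counter-derived sub-seeds."""
    sweeps = []
    for i in range(n_sweeps):
        tr = run_current_clamp(
            model, stimulus, algorithm, T, dt, seed=sweep_seed(seed, amp_index, i)
        )
        sweeps.append(detect_spikes(tr, threshold))
    return SpikeTrain(sweeps, duration=T)


def run_spontaneous(
    model: MembraneModel,
    algorithm: str,
    T: float,
    dt: float,
    seed: int,
    n_sweeps: int = 1,
    threshold: float = 0.0,
) -> SpikeTrain:
    """Unstimulated runs for the spontaneous-firing statistics."""
    stim = StimulusProtocol(kind="constant", amplitude=0.0)
    return run_firing_sweeps(model, stim, algorithm, n_sweeps, T, dt, seed, threshold)


def generate_ap_fixture(
    seed: int = 0,
    path=None,
    T: float = 100.0,
    dt: float = 0.005,
    n_na: int = 5000,
    n_k: int = 1500,
) -> Trace:
    """Noisy 100-ms voltage trajectory containing an action potential.

    Produced by simulating the stochastic HH model with the UA algorithm
    (a 2-ms pulse at 30 ms elicits the spike); verified to contain at least
    one threshold crossing, regenerating with a sub-seed if a draw happens
    not to spike.  Written as a replay CSV when ``path`` is given.
    """
    model = MembraneModel.hh(n_na, n_k)
    stim = StimulusProtocol(kind="pulse", delay=30.0, duration=2.0, amplitude=7.0)
    trace = None
    for attempt in range(10):
        tr = run_current_clamp(model, stim, "ua", T, dt, seed=sweep_seed(seed, attempt))
        if detect_spikes(tr).size >= 1:
            trace = tr
            break
    if trace is None:
        raise RuntimeError("no action potential in 10 fixture attempts")
    if path is not None:
        pd_path = Path(path)
        pd_path.parent.mkdir(parents=True, exist_ok=True)
        trace.to_csv(pd_path)
    return trace


def _manifest(config: RunConfig) -> dict:
    return {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {"chanstoch": __version__, "numpy": np.__version__},
    }


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_protocol(config: RunConfig) -> dict:
    """Execute a configured protocol; write outputs when outdir is set.

    Returns the stats record; writes ``manifest.json``, ``stats.json`` and
    any trace CSVs into ``config.outdir``.
    """
    config.validate()
    model = config.build_model()
    outdir = Path(config.outdir) if config.outdir else None
    record: dict = {
        "protocol": config.protocol,
        "algorithm": config.algorithm,
        "model": config.model,
        "n_na": model.n_na,
        "n_k": model.n_k,
        "dt": config.dt,
        "seed": config.seed,
    }

    if config.protocol == "clamp":
        trace = run_current_clamp(
            model, config.build_stimulus(), config.algorithm,
            config.t_total, config.dt, seed=config.seed,
        )
        spikes = detect_spikes(trace, config.threshold)
        record["spike_times_ms"] = spikes.tolist()
        record["n_spikes"] = int(spikes.size)
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            trace.to_csv(outdir / "trace.csv")

    elif config.protocol == "sweep":
        records = []
        for a_idx, amp in enumerate(config.amplitudes):
            stim_spec = dict(config.stimulus)
            stim_spec["amplitude"] = float(amp)
            trains = run_firing_sweeps(
                model, StimulusProtocol(**stim_spec), config.algorithm,
                config.n_sweeps, config.t_total, config.dt, config.seed,
                config.threshold, amp_index=a_idx,
            )
            eff, mean_t, var_t = firing_stats(trains)
            records.append(
                {
                    "amplitude": float(amp),
                    "efficiency": eff,
                    "mean_first_spike_ms": mean_t,
                    "var_first_spike_ms2": var_t,
                    "n_sweeps": trains.n_sweeps,
                }
            )
        record["amplitude_records"] = records

    elif config.protocol == "spontaneous":
        trains = run_spontaneous(
            model, config.algorithm, config.t_total, config.dt,
            config.seed, config.n_sweeps, config.threshold,
        )
        rate, isis = spontaneous_stats(trains)
        record["rate_hz"] = rate
        record["n_spikes"] = trains.total_spikes
        record["isis_ms"] = isis.tolist()

    else:  # vclamp
        vtrace = Trace.from_csv(config.vtrace)
        pops = [
            ("na", model.na_scheme, model.n_na),
            ("k", model.k_scheme, model.n_k),
        ]
        res = run_voltage_clamp(
            pops, vtrace, config.n_reps, config.algorithm, dt=config.dt, seed=config.seed
        )
        det = run_voltage_clamp(pops, vtrace, 1, "det", dt=config.dt, seed=config.seed)
        summary = {}
        for name, _, N in pops:
            stats = openstate_moments(
                res.t, res.open[name], n_channels=N, expected_mean=det.open[name][0]
            )
            summary[name] = {
                "mean_abs_mean_err": float(np.mean(np.abs(stats.mean - stats.expected_mean))),
                "mean_var": float(stats.var.mean()),
                "mean_expected_var": float(stats.expected_var.mean()),
                "n_reps": stats.n_reps,
            }
            if outdir:
                outdir.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(
                    {
                        "time": stats.t,
                        "mean": stats.mean,
                        "var": stats.var,
                        "expected_mean": stats.expected_mean,
                        "expected_var": stats.expected_var,
                    }
                ).to_csv(outdir / f"vclamp_{name}.csv", index=False)
        record["vclamp"] = summary

    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_json(outdir / "manifest.json", _manifest(config))
        _write_json(outdir / "stats.json", record)
    return record
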