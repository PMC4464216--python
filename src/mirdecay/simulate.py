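"""Synthetic single-molecule trajectories and experiment-like decay data.

Every stage of the pipeline is testable without external data: exact
(Gillespie) stochastic simulation of the degradation chain produces
single-molecule absorption times, empirical survival curves on a time grid,
and — with multiplicative lognormal measurement noise and replicates — a
bundle of decay datasets mimicking the five-condition knockdown experiment
(negative control, PAN3&NOT1 KD, NOT1 KD, PAN3 KD, positive control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DecayDataset
from .fitting import CONDITION_NETWORK
from .network import SINK, DegradationNetwork, condition_network, survival_closed_form, survival
from .rates import RateSet

#: Default experiment design: grid spanning 0-480 min in 30-min steps (covers
#: all rate scales down to ~0.003 min^-1), three replicates, lognormal
#: measurement scatter of 0.05 decades.
DEFAULT_TIME_GRID = np.arange(0.0, 481.0, 30.0)
DEFAULT_SIGMA_LOG = 0.05
DEFAULT_N_REPLICATES = 3

EXPERIMENT_CONDITIONS = tuple(CONDITION_NETWORK)


class SimulationError(RuntimeError):
    """A trajectory reached a state with no positive exit rate."""


@dataclass(frozen=True)
class TrajectorySample:
    """One molecule's path from synthesis state to degradation."""

    absorption_time: float
    path: tuple[str, ...]  # visited transient states, ending at the sink
    exit_branch: str  # direct | alternative | mirisc | via_<state>

    def __post_init__(self):
        if self.absorption_time <= 0:
            raise ValueError("absorption time must be > 0")
        if self.path[-1] != SINK:
            raise ValueError("path must end at the sink")


@dataclass(frozen=True)
class ExperimentBundle:
    """Per-condition decay datasets plus the metadata to regenerate them."""

    datasets: dict[str, DecayDataset]
    metadata: dict = field(repr=False)

    def __getitem__(self, condition: str) -> DecayDataset:
        return self.datasets[condition]


def _exit_table(network: DegradationNetwork):
    """Per-state outgoing (destinations, rates, total) with zero-rate edges dropped."""
    table = {}
    for s in network.states:
        dests, rates = [], []
        for e in network.edges:
            if e.frm == s and network.rates[e.rate] > 0:
                dests.append(e.to)
                rates.append(network.rates[e.rate])
        table[s] = (dests, np.array(rates), float(sum(rates)))
    return table


def _branch_label(network: DegradationNetwork, last_state: str) -> str:
    if last_state == network.initial:
        return "direct"
    return {"1": "alternative", "2": "mirisc"}.get(last_state, f"via_{last_state}")


def gillespie_trajectory(
    network: DegradationNetwork, seed: int | np.random.Generator | None = None
) -> TrajectorySample:
    """Simulate one molecule exactly: exponential waits, rate-proportional jumps."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = _exit_table(network)
    state, t, path = network.initial, 0.0, [network.initial]
    while state != SINK:
        dests, rates, total = table[state]
        if total <= 0:
            raise SimulationError(f"state {state!r} has no positive exit rate; molecule trapped")
        t += rng.exponential(1.0 / total)
        prev = state
        state = dests[rng.choice(len(dests), p=rates / total)]
        path.append(state)
    return TrajectorySample(t, tuple(path), _branch_label(network, prev))


def sample_absorption(
    network: DegradationNetwork, n: int, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Gillespie: absorption times and exit-branch labels for n molecules."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = _exit_table(network)
    labels = np.array(network.states + (SINK,))
    sidx = {s: i for i, s in enumerate(labels)}
    sink_i = sidx[SINK]
    state = np.full(n, sidx[network.initial])
    times = np.zeros(n)
    last = np.full(n, sidx[network.initial])
    while True:
        active = state != sink_i
        if not active.any():
            break
        for s in network.states:
            here = np.flatnonzero(active & (state == sidx[s]))
            if here.size == 0:
                continue
            dests, rates, total = table[s]
            if total <= 0:
                raise SimulationError(f"state {s!r} has no positive exit rate; molecules trapped")
            times[here] += rng.exponential(1.0 / total, here.size)
            last[here] = sidx[s]
            if len(dests) == 1:
                state[here] = sidx[dests[0]]
            else:
                nxt = rng.choice(len(dests), size=here.size, p=rates / total)
                state[here] = np.array([sidx[d] for d in dests])[nxt]
    branch = np.array([_branch_label(network, labels[i]) for i in last])
    return times, branch


def simulate_decay_curve(
    network: DegradationNetwork,
    n_molecules: int,
    time_grid,
    seed: int | np.random.Generator | None = None,
) -> DecayDataset:
    """Empirical survival of ``n_molecules`` on the grid (value = fraction alive)."""
    grid = np.asarray(time_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid is empty")
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    times, _ = sample_absorption(network, n_molecules, seed)
    frac = (times[None, :] > grid[:, None]).mean(axis=1)
    # keep abundances strictly positive for the log fit scale
    frac = np.maximum(frac, 0.5 / n_molecules)
    return DecayDataset.from_arrays(network.name, grid, frac, replicate="sim", normalized=True)


def analytic_decay_curve(network: DegradationNetwork, time_grid) -> DecayDataset:
    """Noiseless decay pattern: the exact survival function on the grid."""
    grid = np.asarray(time_grid, dtype=float)
    try:
        curve = survival_closed_form(network, grid)
    except Exception:
        curve = survival(network, grid)
    vals = np.maximum(curve.values, 1e-12)
    return DecayDataset.from_arrays(network.name, grid, vals, replicate="exact", normalized=True)


def add_measurement_noise(
    curve: DecayDataset,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | np.random.Generator | None = None,
) -> DecayDataset:
    """Emulate replicate measurements with multiplicative lognormal noise.

    Each replicate value is the input value times 10^eps with
    eps ~ Normal(0, sigma_log), then re-normalized to 1 at the earliest time.
    """
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    base = curve.observations.sort_values("time_min")
    for r in range(1, n_replicates + 1):
        eps = rng.normal(0.0, sigma_log, len(base))
        vals = base["value"].to_numpy() * np.power(10.0, eps)
        vals = vals / vals[0]  # re-normalize at the reference time
        frames.append(
            pd.DataFrame(
                {"time_min": base["time_min"].to_numpy(), "value": vals, "replicate": f"r{r}"}
            )
        )
    return DecayDataset(curve.condition, pd.concat(frames, ignore_index=True), normalized=True)


def generate_experiment(
    rates: RateSet,
    time_grid=DEFAULT_TIME_GRID,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = 1,
    conditions: tuple[str, ...] = EXPERIMENT_CONDITIONS,
    n_molecules: int | None = None,
) -> ExperimentBundle:
    """Five-condition synthetic knockdown experiment.

    Curves come from the exact survival function (or, with ``n_molecules``,
    from empirical Gillespie survival) of each condition's network, with
    lognormal replicate noise.  With ``sigma_log=0`` and the default exact
    curves the bundle is noiseless.  Identical arguments regenerate the
    bundle bit-identically.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.size == 0 or grid[0] != 0:
        raise ValueError("time grid must start at 0")
    missing = []
    for cond in conditions:
        net_name = CONDITION_NETWORK.get(cond, cond)
        from .fitting import FREE_RATES

        for s in FREE_RATES[net_name] + (("lambda", "mu", "nu") if net_name != "single_exponential" else ()):
            if s not in rates:
                missing.append((cond, s))
    if missing:
        raise ValueError(f"missing rates for conditions: {missing}")

    rng = np.random.default_rng(seed)
    datasets: dict[str, DecayDataset] = {}
    truth: dict[str, dict[str, float]] = {}
    for cond in conditions:
        net = condition_network(CONDITION_NETWORK.get(cond, cond), rates)
        truth[cond] = net.rates.to_dict()
        if n_molecules is None:
            base = analytic_decay_curve(net, grid)
        else:
            base = simulate_decay_curve(net, n_molecules, grid, rng)
        noisy = add_measurement_noise(base, sigma_log, n_replicates, rng)
        datasets[cond] = DecayDataset(cond, noisy.observations, normalized=True)
    metadata = {
        "true_rates": truth,
        "time_grid": grid.tolist(),
        "sigma_log": sigma_log,
        "n_replicates": n_replicates,
        "seed": seed,
        "n_molecules": n_molecules,
        "conditions": list(conditions),
    }
    return ExperimentBundle(datasets, metadata)
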