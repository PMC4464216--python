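"""Derived quantities: branching fractions and steady-state occupancy.

The branching fraction sigma of a competing exit route is the probability
that a single molecule is eventually absorbed through that route.  For the
star networks used here the miRISC-branch entry reduces to

    sigma_X = lambda_X / (lambda_X + lambda + mu),

the fraction of target mRNA degraded via the miRISC-containing complex X.
The steady-state occupancy assumes constant zeroth-order production into the
central state with first-order losses, the simplest model consistent with a
steady expression level; the resulting per-state fractions are independent
of the production rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DegradationNetwork

#: Canonical route labels by exiting transient state.
_ROUTE_BY_STATE = {"1": "alternative", "2": "mirisc"}


class UndefinedFractionError(ValueError):
    """All exit rates are zero: absorption probabilities are undefined."""


class DivergentOccupancyError(ValueError):
    """A reachable state has zero exit rate: steady-state mass diverges."""


@dataclass(frozen=True)
class BranchingFractions:
    """Absorption probability per exit route (direct / alternative / mirisc)."""

    fractions: dict[str, float]

    @property
    def direct(self) -> float:
        return self.fractions.get("direct", 0.0)

    @property
    def alternative(self) -> float:
        return self.fractions.get("alternative", 0.0)

    @property
    def mirisc(self) -> float:
        return self.fractions.get("mirisc", 0.0)

    def as_percent(self, route: str) -> int:
        """Rounded integer percent, the headline presentation (0.074 -> 7%)."""
        return round(100 * self.fractions.get(route, 0.0))

    def __str__(self) -> str:
        return ", ".join(
            f"{route}: {p:.3f} (~{self.as_percent(route)}%)" for route, p in self.fractions.items()
        )


@dataclass(frozen=True)
class SteadyStateOccupancy:
    """Fraction of steady-state mRNA in each transient state."""

    fractions: dict[str, float]
    production_rate: float

    def __getitem__(self, state: str) -> float:
        return self.fractions[state]


def _route_label(network: DegradationNetwork, state: str) -> str:
    if state == network.initial:
        return "direct"
    return _ROUTE_BY_STATE.get(state, f"via_{state}")


def branching_fraction(network: DegradationNetwork) -> BranchingFractions:
    """Probability of absorption through each exit route.

    Computed from the fundamental matrix: the expected time spent in state i
    is tau_i = [p0^T (-Q)^{-1}]_i, and the probability of degrading from
    state i is tau_i times its sink rate.  Routes are labeled by the state
    the molecule degrades from: "direct" (the initial state), "alternative"
    (state 1) and "mirisc" (state 2).
    """
    Q = network.generator()
    if np.allclose(Q, 0):
        raise UndefinedFractionError("all exit rates are zero; no absorption occurs")
    try:
        tau = np.linalg.solve(-Q.T, network.initial_vector())
    except np.linalg.LinAlgError:
        raise UndefinedFractionError("absorption probabilities undefined (singular generator)")
    sink = network.sink_rates()
    fracs: dict[str, float] = {}
    for i, state in enumerate(network.states):
        label = _route_label(network, state)
        fracs[label] = fracs.get(label, 0.0) + float(tau[i] * sink[i])
    return BranchingFractions(fracs)


def steady_state_occupancy(
    network: DegradationNetwork, production_rate: float = 1.0
) -> SteadyStateOccupancy:
    """Per-state fraction of mRNA at steady state under constant production.

    Molecules are produced into the initial state at rate P and removed by
    the network's first-order transitions; flux balance gives the occupancy
    vector N = P (-Q^T)^{-1} e0 (for the star topology: N0 = P/R,
    N1 = lambda N0 / nu, N2 = lambda_X N0 / mu_X).  Fractions N_i / sum N_j
    do not depend on P.
    """
    if production_rate <= 0:
        raise ValueError("production_rate must be > 0")
    Q = network.generator()
    try:
        N = production_rate * np.linalg.solve(-Q.T, network.initial_vector())
    except np.linalg.LinAlgError:
        raise DivergentOccupancyError("a reachable state has zero exit rate; occupancy diverges")
    if not np.all(np.isfinite(N)) or np.any(N < -1e-12):
        raise DivergentOccupancyError("occupancy diverges or is negative")
    fracs = {s: float(n / N.sum()) for s, n in zip(network.states, N)}
    return SteadyStateOccupancy(fracs, production_rate)


def compare_occupancy(a: SteadyStateOccupancy, b: SteadyStateOccupancy) -> dict[str, float]:
    """Signed per-state difference b - a, in total-percentage points."""
    if set(a.fractions) != set(b.fractions):
        raise ValueError(
            f"state labels differ: {sorted(a.fractions)} vs {sorted(b.fractions)}"
        )
    return {s: 100.0 * (b.fractions[s] - a.fractions[s]) for s in a.fractions}
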