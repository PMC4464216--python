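"""Degradation networks as absorbing continuous-time Markov chains.

A single mRNA molecule wanders among a small set of biochemical states
(unbound, bound to competing complexes, bound to miRISC assemblies) until it
is absorbed by the "degraded" sink.  The population-average decay pattern
measured after transcription shut-off equals the first-passage survival
function S(t) of this chain, computed here from the transient-state generator
via its matrix exponential, with a closed form available for the star
topologies used throughout (a central initial state with independent one-hop
branches to absorption).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .rates import RateSet

SINK = "sink"

#: Degenerate-branch switch: the closed form divides by (R - nu_i); below this
#: relative gap the limit form lambda_i * t * exp(-R t) is used instead to
#: avoid catastrophic cancellation.
_DEGENERATE_RTOL = 1e-9


class ConfigurationError(ValueError):
    """A network definition is inconsistent or references a missing rate."""


class UnsupportedTopologyError(ValueError):
    """Raised when a closed form only valid for star topologies is requested."""


class InfiniteLifetimeError(ValueError):
    """The sink is unreachable with positive probability."""


@dataclass(frozen=True)
class Edge:
    """Directed transition carrying a named first-order rate."""

    frm: str
    to: str  # transient state label or SINK
    rate: str  # rate symbol resolved against the bound RateSet


@dataclass(frozen=True)
class DegradationNetwork:
    """Absorbing CTMC: transient states, one degraded sink, bound rates.

    All probability mass starts in ``initial``.  Every transient state must
    have at least one outgoing edge and (when its rates are positive) a path
    to the sink.
    """

    states: tuple[str, ...]
    initial: str
    edges: tuple[Edge, ...]
    rates: RateSet
    name: str = "custom"

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("duplicate state labels")
        if self.initial not in self.states:
            raise ConfigurationError(f"initial state {self.initial!r} not among states")
        if SINK in self.states:
            raise ConfigurationError("the sink is implicit and must not be listed as a state")
        out: dict[str, list[Edge]] = {s: [] for s in self.states}
        for e in self.edges:
            if e.frm == SINK:
                raise ConfigurationError("no edges may leave the sink")
            if e.frm not in self.states:
                raise ConfigurationError(f"edge from unknown state {e.frm!r}")
            if e.to != SINK and e.to not in self.states:
                raise ConfigurationError(f"edge to unknown state {e.to!r}")
            if e.rate not in self.rates:
                raise ConfigurationError(f"missing rate symbol {e.rate!r} for edge {e.frm}->{e.to}")
            out[e.frm].append(e)
        for s, es in out.items():
            if not es:
                raise ConfigurationError(f"state {s!r} has no outgoing edge")
        # reachability of the sink from every state, counting only positive rates
        adj = {s: [e.to for e in es if self.rates[e.rate] > 0] for s, es in out.items()}
        if all(any(self.rates[e.rate] > 0 for e in es) for es in out.values()):
            for s in self.states:
                if not self._reaches_sink(s, adj):
                    raise ConfigurationError(f"state {s!r} cannot reach the sink")

    @staticmethod
    def _reaches_sink(start: str, adj: dict[str, list[str]]) -> bool:
        seen, stack = set(), [start]
        while stack:
            s = stack.pop()
            if s == SINK:
                return True
            if s in seen:
                continue
            seen.add(s)
            stack.extend(adj.get(s, []))
        return False

    # ---- generator matrices -------------------------------------------------

    def generator(self) -> np.ndarray:
        """Transient-block generator Q: Q[i,j] = rate i->j, Q[i,i] = -total exit."""
        idx = {s: i for i, s in enumerate(self.states)}
        n = len(self.states)
        Q = np.zeros((n, n))
        for e in self.edges:
            r = self.rates[e.rate]
            Q[idx[e.frm], idx[e.frm]] -= r
            if e.to != SINK:
                Q[idx[e.frm], idx[e.to]] += r
        return Q

    def sink_rates(self) -> np.ndarray:
        """Per-state total degradation rate (sum of sink-edge rates)."""
        idx = {s: i for i, s in enumerate(self.states)}
        a = np.zeros(len(self.states))
        for e in self.edges:
            if e.to == SINK:
                a[idx[e.frm]] += self.rates[e.rate]
        return a

    def initial_vector(self) -> np.ndarray:
        p0 = np.zeros(len(self.states))
        p0[self.states.index(self.initial)] = 1.0
        return p0

    # ---- star-topology introspection ---------------------------------------

    def star_decomposition(self) -> tuple[float, list[tuple[str, float, float]]]:
        """Return (direct sink rate mu, [(branch state, entry rate, exit rate)]).

        Raises UnsupportedTopologyError unless the network is a star: every
        edge either leaves the initial state (to the sink or to a one-hop
        branch state) or takes a branch state straight to the sink.
        """
        mu = 0.0
        entry: dict[str, float] = {}
        exit_: dict[str, float] = {}
        for e in self.edges:
            r = self.rates[e.rate]
            if e.frm == self.initial:
                if e.to == SINK:
                    mu += r
                else:
                    entry[e.to] = entry.get(e.to, 0.0) + r
            elif e.to == SINK:
                exit_[e.frm] = exit_.get(e.frm, 0.0) + r
            else:
                raise UnsupportedTopologyError(
                    f"edge {e.frm}->{e.to} is neither radial nor absorbing; "
                    "use survival() for general topologies"
                )
        if set(entry) != set(exit_):
            raise UnsupportedTopologyError("branch states must have exactly entry and sink edges")
        branches = [(s, entry[s], exit_[s]) for s in self.states if s in entry]
        return mu, branches

    # ---- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "states": list(self.states),
            "initial": self.initial,
            "edges": [{"from": e.frm, "to": e.to, "rate": e.rate} for e in self.edges],
            "rates": self.rates.to_dict(),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DegradationNetwork":
        doc = json.loads(text)
        return cls(
            states=tuple(doc["states"]),
            initial=doc["initial"],
            edges=tuple(Edge(e["from"], e["to"], e["rate"]) for e in doc["edges"]),
            rates=RateSet(doc["rates"], allow_custom=True),
            name=doc.get("name", "custom"),
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "DegradationNetwork":
        return cls.from_json(Path(path).read_text())


def load_network(name: str) -> "DegradationNetwork":
    """Load one of the packaged network configs (see CONDITIONS) with its
    reference rates bound."""
    from importlib.resources import files

    res = files("mirdecay").joinpath(f"data/networks/{name}.json")
    if not res.is_file():
        raise ConfigurationError(f"no packaged network named {name!r}")
    return DegradationNetwork.from_json(res.read_text())


@dataclass(frozen=True)
class SurvivalCurve:
    """First-passage survival S(t): fraction of molecules not yet degraded."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")


# ---------------------------------------------------------------------------
# Condition networks
# ---------------------------------------------------------------------------

#: miRISC-branch rate suffix for each experimental network.
_BRANCH_SUFFIX = {
    "mirisc_only": "R",  # NOT1 & PAN3 knocked down: miRISC binds alone
    "pan3_kd": "RN",  # PAN3 knocked down: preformed miRISC+NOT1
    "control_positive": "RNP",  # all factors: preformed miRISC+NOT1+PAN3
}

CONDITIONS = ("control_negative", "mirisc_only", "pan3_kd", "control_positive", "single_exponential")


def condition_network(condition: str, rates: RateSet) -> DegradationNetwork:
    """Build the star network for one experimental condition.

    State labels follow the convention: 0 the central unbound state, 1 the
    alternative-pathway state on the left, 2 the miRISC-bound state on the
    right.  ``single_exponential`` is the one-state null model, and
    ``control_negative`` the two-state parsimonious model (rates lambda, mu,
    nu); the three miRISC conditions add the right branch with rates
    lambda_X, mu_X for X in {R, RN, RNP}.
    """
    if condition == "single_exponential":
        edges = (Edge("0", SINK, "mu"),)
        states: tuple[str, ...] = ("0",)
    elif condition == "control_negative":
        states = ("0", "1")
        edges = (Edge("0", SINK, "mu"), Edge("0", "1", "lambda"), Edge("1", SINK, "nu"))
    elif condition in _BRANCH_SUFFIX:
        x = _BRANCH_SUFFIX[condition]
        states = ("0", "1", "2")
        edges = (
            Edge("0", SINK, "mu"),
            Edge("0", "1", "lambda"),
            Edge("1", SINK, "nu"),
            Edge("0", "2", f"lambda_{x}"),
            Edge("2", SINK, f"mu_{x}"),
        )
    else:
        raise ConfigurationError(f"unrecognized condition {condition!r}; expected one of {CONDITIONS}")
    needed = {e.rate for e in edges}
    missing = sorted(needed - set(rates))
    if missing:
        raise ConfigurationError(f"RateSet is missing required symbols: {missing}")
    return DegradationNetwork(
        states=states,
        initial="0",
        edges=edges,
        rates=RateSet({s: rates[s] for s in needed}, allow_custom=True),
        name=condition,
    )


# ---------------------------------------------------------------------------
# Survival, hazard, lifetime
# ---------------------------------------------------------------------------


def survival(network: DegradationNetwork, times: Sequence[float]) -> SurvivalCurve:
    """Exact survival S(t) = total transient mass, via the matrix exponential.

    ``times`` must be sorted and nonnegative; S(0) = 1 and S is non-increasing,
    decaying to zero whenever the sink is reachable from every occupied state.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    Q = network.generator()
    p0 = network.initial_vector()
    vals = np.empty(t.shape)
    for i, ti in np.ndenumerate(t):
        vals[i] = float(p0 @ expm(Q * ti) @ np.ones(len(p0)))
    return SurvivalCurve(t, np.clip(vals, 0.0, 1.0))


def survival_closed_form(network: DegradationNetwork, times: Sequence[float]) -> SurvivalCurve:
    """Closed-form survival for star topologies.

    With total initial exit rate R = mu + sum_i lambda_i over branches with
    exit rates nu_i:

        S(t) = exp(-R t) + sum_i lambda_i/(R - nu_i) * (exp(-nu_i t) - exp(-R t))

    and the degenerate branch R == nu_i contributes lambda_i * t * exp(-R t).
    Agrees with :func:`survival` to ~1e-15; kept as an independent route and
    as a fast path for fitting.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    mu, branches = network.star_decomposition()
    R = mu + sum(lam for _, lam, _ in branches)
    eRt = np.exp(-R * t)
    S = eRt.copy()
    for _, lam, nu in branches:
        if abs(R - nu) < _DEGENERATE_RTOL * max(R, nu):
            S += lam * t * eRt
        else:
            S += lam / (R - nu) * (np.exp(-nu * t) - eRt)
    return SurvivalCurve(t, np.clip(S, 0.0, 1.0))


def _decay_eigenvalues(network: DegradationNetwork) -> np.ndarray:
    """Decay rates of the modes actually excited from the initial state."""
    Q = network.generator()
    p0 = network.initial_vector()
    ones = np.ones(len(p0))
    lam, V = np.linalg.eig(Q)
    # S(t) = sum_k c_k exp(lam_k t) with c_k = (p0^T V)_k (V^{-1} 1)_k
    coeff = (p0 @ V) * np.linalg.solve(V, ones)
    rates = -lam.real
    keep = np.abs(coeff) > 1e-12
    return np.sort(rates[keep])


def asymptotic_hazard(network: DegradationNetwork) -> float:
    """Long-time limit of the hazard: the smallest excited decay eigenvalue."""
    return float(_decay_eigenvalues(network)[0])


def hazard(network: DegradationNetwork, t: float) -> float:
    """Age-dependent degradation rate h(t) = -d ln S / dt in min^-1.

    Equals the degradation flux divided by the surviving mass,
    h(t) = sum_i a_i p_i(t) / S(t) with a_i the per-state sink rates.  When
    S(t) underflows to zero the long-time limit is returned with a warning.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    Q = network.generator()
    p = network.initial_vector() @ expm(Q * float(t))
    S = float(p.sum())
    if S <= 0.0:
        warnings.warn(
            "survival underflowed to 0; reporting the asymptotic hazard limit",
            RuntimeWarning,
            stacklevel=2,
        )
        return asymptotic_hazard(network)
    return float(p @ network.sink_rates()) / S


def mean_lifetime(network: DegradationNetwork) -> float:
    """Mean first-passage time to degradation, in minutes.

    Equals the integral of S(t) and, in matrix form, p0^T (-Q)^{-1} 1.  For
    a star topology this reduces to 1/R + sum_i (lambda_i/R)(1/nu_i).
    """
    Q = network.generator()
    p0 = network.initial_vector()
    try:
        tau = np.linalg.solve(-Q, np.ones(len(p0)))
    except np.linalg.LinAlgError:
        raise InfiniteLifetimeError("the degraded state is unreachable with positive probability")
    if not np.all(np.isfinite(tau)) or np.any(tau < 0):
        raise InfiniteLifetimeError("the degraded state is unreachable with positive probability")
    return float(p0 @ tau)
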