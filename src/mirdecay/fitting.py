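"""Least-squares fitting of survival models to decay data.

The observed decay pattern is the population-average fraction of mRNA
remaining, so the model prediction is the first-passage survival function of
the degradation network.  Fits minimize equally weighted residuals of
log10(model S) against log10(observed abundance) — decay patterns are read
in linear-log scale, where exponential phases are straight lines — with all
rates bounded below by zero.  The hierarchical strategy first estimates the
baseline rates (lambda, mu, nu) on the negative control and then freezes
them while fitting the two miRISC-branch rates of each knockdown condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

from .dataset import DecayDataset
from .network import (
    SINK,
    DegradationNetwork,
    UnsupportedTopologyError,
    condition_network,
)
from .rates import RateSet

#: Maps experiment condition labels to the network fitted to them.  The
#: NOT1-knockdown condition reuses the miRISC-only topology: PAN3 without
#: NOT1 adds no identifiable destabilization, so no separate network exists.
CONDITION_NETWORK: dict[str, str] = {
    "control_negative": "control_negative",
    "pan3_not1_kd": "mirisc_only",
    "not1_kd": "mirisc_only",
    "pan3_kd": "pan3_kd",
    "control_positive": "control_positive",
}

#: Free parameters per network in the hierarchical scheme.
FREE_RATES: dict[str, tuple[str, ...]] = {
    "single_exponential": ("mu",),
    "control_negative": ("lambda", "mu", "nu"),
    "mirisc_only": ("lambda_R", "mu_R"),
    "pan3_kd": ("lambda_RN", "mu_RN"),
    "control_positive": ("lambda_RNP", "mu_RNP"),
}

_LOG_FLOOR = 1e-300


class UnderdeterminedFitError(ValueError):
    """Fewer distinct time points than free parameters + 1."""


@dataclass
class FitResult:
    """Estimates and diagnostics from one decay-curve fit.

    ``fixed`` carries the frozen (inherited) rates so stage-2 results record
    the baseline they were conditioned on.  ``at_boundary`` lists free rates
    estimated at the zero bound, ``unidentifiable`` those whose Jacobian
    column vanishes at the optimum (the data carry no information on them).
    """

    condition: str
    network: DegradationNetwork
    free: tuple[str, ...]
    estimates: dict[str, float]
    fixed: dict[str, float]
    rss: float
    n: int
    k: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    jac: np.ndarray = field(repr=False)
    fitted_log10: np.ndarray = field(repr=False)
    at_boundary: list[str] = field(default_factory=list)
    unidentifiable: list[str] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] | None = None
    ci_method: str | None = None
    data_hash: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return aic(self)

    def rates(self) -> RateSet:
        """Full rate set: estimates merged over the fixed values."""
        return RateSet({**self.fixed, **self.estimates}, allow_custom=True)

    def fitted_network(self) -> DegradationNetwork:
        """The network with its rates replaced by the fitted values."""
        vals = {**self.fixed, **self.estimates}
        return DegradationNetwork(
            states=self.network.states,
            initial=self.network.initial,
            edges=self.network.edges,
            rates=RateSet({s: vals[s] for s in self.network.rates}, allow_custom=True),
            name=self.network.name,
        )

    def summary(self) -> str:
        lines = [f"fit[{self.condition}] network={self.network.name} n={self.n} k={self.k}"]
        for s in self.free:
            ci = f"  95% CI [{self.ci[s][0]:.4g}, {self.ci[s][1]:.4g}]" if self.ci else ""
            flags = " (boundary)" if s in self.at_boundary else ""
            flags += " (unidentifiable)" if s in self.unidentifiable else ""
            lines.append(f"  {s} = {self.estimates[s]:.4g} min^-1{ci}{flags}")
        for s, v in self.fixed.items():
            lines.append(f"  {s} = {v:.4g} min^-1 (fixed)")
        lines.append(f"  RSS = {self.rss:.4g}, AIC = {self.aic:.2f}")
        return "\n".join(lines)


def _dataset_hash(dataset: DecayDataset) -> int:
    h = pd.util.hash_pandas_object(dataset.observations.round(12), index=False).sum()
    return int(np.uint64(h))


def _model_factory(network: DegradationNetwork):
    """Return f(rate_values, times) -> S(times), with a star fast path."""
    try:
        # symbolic star decomposition: direct-sink symbols and branch symbol pairs
        direct: list[str] = []
        entry: dict[str, list[str]] = {}
        exit_: dict[str, list[str]] = {}
        for e in network.edges:
            if e.frm == network.initial:
                (direct if e.to == SINK else entry.setdefault(e.to, [])).append(e.rate)
            elif e.to == SINK:
                exit_.setdefault(e.frm, []).append(e.rate)
            else:
                raise UnsupportedTopologyError(e.frm)
        if set(entry) != set(exit_):
            raise UnsupportedTopologyError("non-star")

        branches = [(entry[s], exit_[s]) for s in network.states if s in entry]

        def model(vals: dict[str, float], t: np.ndarray) -> np.ndarray:
            R = sum(vals[s] for s in direct) + sum(
                vals[s] for ent, _ in branches for s in ent
            )
            eRt = np.exp(-R * t)
            S = eRt.copy()
            for ent, ext in branches:
                lam = sum(vals[s] for s in ent)
                nu = sum(vals[s] for s in ext)
                if abs(R - nu) < 1e-9 * max(R, nu, 1e-300):
                    S += lam * t * eRt
                else:
                    S += lam / (R - nu) * (np.exp(-nu * t) - eRt)
            return S

        return model
    except UnsupportedTopologyError:
        idx = {s: i for i, s in enumerate(network.states)}
        n = len(network.states)
        terms = [(idx[e.frm], None if e.to == SINK else idx[e.to], e.rate) for e in network.edges]
        p0 = network.initial_vector()

        def model(vals: dict[str, float], t: np.ndarray) -> np.ndarray:
            Q = np.zeros((n, n))
            for i, j, sym in terms:
                r = vals[sym]
                Q[i, i] -= r
                if j is not None:
                    Q[i, j] += r
            return np.array([float(p0 @ expm(Q * ti) @ np.ones(n)) for ti in t])

        return model


def fit_decay(
    dataset: DecayDataset,
    network: DegradationNetwork,
    free_rates: tuple[str, ...] | list[str],
    fixed_rates: dict[str, float] | None = None,
    *,
    average_replicates: bool = False,
    x0: dict[str, float] | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Bounded least squares of log10 survival against log10 abundance.

    Replicates enter as independent observations (set ``average_replicates``
    to fit the mean pattern instead).  The optimizer is a trust-region
    reflective method with rates bounded at zero, multi-started from
    ``n_starts`` log-spaced initial guesses spanning 1e-4 to 1e-1 min^-1;
    the start with the lowest residual sum of squares wins, ties going to
    the smaller parameter vector.
    """
    free = tuple(free_rates)
    data = dataset.normalize()
    if average_replicates:
        data = data.averaged()
    # canonical observation order: estimates must not depend on row order
    data = DecayDataset(
        data.condition,
        data.observations.sort_values(["time_min", "replicate"], kind="stable"),
        normalized=True,
    )
    needed = set(network.rates)
    fixed = dict(fixed_rates) if fixed_rates is not None else {}
    for s in needed - set(free) - set(fixed):
        fixed[s] = network.rates[s]
    uncovered = needed - set(free) - set(fixed)
    if uncovered:
        raise ValueError(f"rates neither free nor fixed: {sorted(uncovered)}")

    t_obs = data.times
    y_log = np.log10(data.values)
    n, k = len(t_obs), len(free)
    if len(np.unique(t_obs)) < k + 1:
        raise UnderdeterminedFitError(
            f"{len(np.unique(t_obs))} distinct time points cannot identify {k} rates"
        )

    model = _model_factory(network)

    def residual(theta: np.ndarray) -> np.ndarray:
        vals = dict(fixed)
        vals.update(zip(free, theta))
        S = np.clip(model(vals, t_obs), _LOG_FLOOR, None)
        return np.log10(S) - y_log

    starts = [np.full(k, g) for g in np.logspace(-4, -1, n_starts)]
    if x0 is not None:
        starts.insert(0, np.array([max(x0[s], 1e-12) for s in free]))

    best = None
    for theta0 in starts:
        sol = least_squares(
            residual, theta0, bounds=(0.0, np.inf), method="trf",
            x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss = float(sol.cost * 2)
        if (
            best is None
            or rss < best[0] - 1e-12 * max(best[0], 1.0)
            or (abs(rss - best[0]) <= 1e-12 * max(best[0], 1.0)
                and np.linalg.norm(sol.x) < np.linalg.norm(best[1].x))
        ):
            best = (rss, sol)
    rss, sol = best

    # estimates this far below any resolvable rate sit on the zero bound
    estimates = dict(zip(free, (0.0 if v < 1e-12 else float(v) for v in sol.x)))
    col_norm = np.linalg.norm(sol.jac, axis=0)
    scale = max(col_norm.max(), 1e-30)
    return FitResult(
        condition=dataset.condition,
        network=network,
        free=free,
        estimates=estimates,
        fixed=fixed,
        rss=rss,
        n=n,
        k=k,
        converged=bool(sol.status > 0),
        residuals=sol.fun.copy(),
        jac=sol.jac.copy(),
        fitted_log10=y_log + sol.fun,
        at_boundary=[s for s, v in estimates.items() if v < 1e-9],
        unidentifiable=[s for s, cn in zip(free, col_norm) if cn < 1e-8 * scale],
        data_hash=_dataset_hash(data),
        message=sol.message,
    )


def hierarchical_fit(
    datasets: dict[str, DecayDataset],
    *,
    ci_method: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    average_replicates: bool = False,
) -> dict[str, FitResult]:
    """Two-stage fit across knockdown conditions.

    Stage 1 estimates (lambda, mu, nu) on the negative control; stage 2 fits
    each remaining condition on its own network topology with the baseline
    rates frozen and exactly the two miRISC-branch rates free.  Results
    record the inherited rates in ``fixed``.
    """
    if "control_negative" not in datasets:
        raise ValueError("hierarchical fit requires a 'control_negative' dataset to anchor stage 1")
    unknown = [c for c in datasets if c not in CONDITION_NETWORK and c not in FREE_RATES]
    if unknown:
        raise ValueError(f"unknown condition labels: {unknown}")

    placeholder = RateSet(dict.fromkeys(
        ("lambda", "mu", "nu", "lambda_R", "mu_R", "lambda_RN", "mu_RN",
         "lambda_RNP", "mu_RNP"), 0.01))
    results: dict[str, FitResult] = {}

    base_net = condition_network("control_negative", placeholder)
    stage1 = fit_decay(
        datasets["control_negative"], base_net, FREE_RATES["control_negative"],
        average_replicates=average_replicates,
    )
    results["control_negative"] = stage1
    baseline = {s: stage1.estimates[s] for s in ("lambda", "mu", "nu")}

    for cond, ds in datasets.items():
        if cond == "control_negative":
            continue
        net_name = CONDITION_NETWORK.get(cond, cond)
        net = condition_network(net_name, placeholder)
        free = FREE_RATES[net_name]
        results[cond] = fit_decay(
            ds, net, free, fixed_rates=dict(baseline), average_replicates=average_replicates,
        )

    if ci_method is not None:
        rng_seed = seed
        for cond, fit in results.items():
            confidence_intervals(
                fit, datasets[cond], method=ci_method, n_boot=n_boot, seed=rng_seed
            )
            rng_seed = None if rng_seed is None else rng_seed + 1
    return results


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def confidence_intervals(
    fit: FitResult,
    dataset: DecayDataset,
    method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """95% intervals per free rate, stored on the fit and returned.

    ``asymptotic`` linearizes at the optimum (Jacobian-based Wald intervals,
    truncated at zero); ``bootstrap`` parametrically resamples residuals on
    the log10 fit scale, refits, and takes percentile intervals.  A singular
    Jacobian makes the asymptotic route fall back to the bootstrap with a
    warning.  Intervals always contain the point estimate.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if method == "asymptotic":
        ci = _asymptotic_ci(fit)
        if ci is None:
            warnings.warn(
                "singular Jacobian; falling back to bootstrap intervals",
                RuntimeWarning,
                stacklevel=2,
            )
            method, ci = "bootstrap", _bootstrap_ci(fit, dataset, n_boot, seed)
    elif method == "bootstrap":
        ci = _bootstrap_ci(fit, dataset, n_boot, seed)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    ci = {
        s: (min(lo, fit.estimates[s]), max(hi, fit.estimates[s]))
        for s, (lo, hi) in ci.items()
    }
    ci = {s: (0.0 if lo < 1e-12 else lo, hi) for s, (lo, hi) in ci.items()}
    fit.ci, fit.ci_method = ci, method
    return ci


def _asymptotic_ci(fit: FitResult) -> dict[str, tuple[float, float]] | None:
    dof = max(fit.n - fit.k, 1)
    s2 = fit.rss / dof
    JTJ = fit.jac.T @ fit.jac
    if np.linalg.cond(JTJ) > 1e12:
        return None
    cov = s2 * np.linalg.inv(JTJ)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return {
        s: (max(0.0, fit.estimates[s] - 1.96 * e), fit.estimates[s] + 1.96 * e)
        for s, e in zip(fit.free, se)
    }


def _bootstrap_ci(
    fit: FitResult, dataset: DecayDataset, n_boot: int, seed: int | None
) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed)
    data = dataset.normalize()
    data = DecayDataset(
        data.condition,
        data.observations.sort_values(["time_min", "replicate"], kind="stable"),
        normalized=True,
    )
    sigma = np.sqrt(fit.rss / max(fit.n - fit.k, 1))
    t_obs = data.times
    model = _model_factory(fit.network)
    fixed, free = fit.fixed, fit.free
    theta_hat = np.array([max(fit.estimates[s], 1e-12) for s in free])
    # resampled replicates must satisfy the dataset invariant (value = 1 at the
    # reference time), so renormalize each bootstrap replicate the same way the
    # measurements are normalized; without this the within-replicate error
    # correlation is lost and the intervals undercover
    reps = data.observations["replicate"].to_numpy()
    ref_of = {}
    for r in np.unique(reps):
        mask = reps == r
        ref_of[r] = np.flatnonzero(mask)[np.argmin(t_obs[mask])]
    draws = np.empty((n_boot, fit.k))
    for b in range(n_boot):
        y = fit.fitted_log10 + rng.normal(0.0, sigma, fit.n)
        for r, i_ref in ref_of.items():
            y[reps == r] -= y[i_ref] - fit.fitted_log10[i_ref]

        def residual(theta: np.ndarray) -> np.ndarray:
            vals = dict(fixed)
            vals.update(zip(free, theta))
            return np.log10(np.clip(model(vals, t_obs), _LOG_FLOOR, None)) - y

        sol = least_squares(
            residual, theta_hat, bounds=(0.0, np.inf), method="trf",
            x_scale="jac", xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        draws[b] = sol.x
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return {s: (float(lo[i]), float(hi[i])) for i, s in enumerate(fit.free)}


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def aic(fit: FitResult, *, corrected: bool = False) -> float:
    """Least-squares AIC, n*ln(RSS/n) + 2k; AICc adds the small-sample term."""
    if fit.rss <= 0:
        return -np.inf
    value = fit.n * np.log(fit.rss / fit.n) + 2 * fit.k
    if corrected:
        dof = fit.n - fit.k - 1
        value += (2 * fit.k * (fit.k + 1) / dof) if dof > 0 else np.inf
    return float(value)


def aic_compare(fits: list[FitResult], *, corrected: bool = False) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (ascending), with delta-AIC."""
    if not fits:
        raise ValueError("no fits to compare")
    h0 = fits[0].data_hash
    if any(f.data_hash != h0 for f in fits):
        raise ValueError("fits compare different datasets; AIC ranking is meaningless")
    rows = [
        {
            "model": f.network.name,
            "k": f.k,
            "rss": f.rss,
            "aic": aic(f, corrected=corrected),
        }
        for f in fits
    ]
    tab = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    return tab
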