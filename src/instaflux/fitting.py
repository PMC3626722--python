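"""Weighted least-squares estimation of free fluxes and unmeasured pools.

Measurement errors follow the constant-relative-error model sigma =
rel * value (default 2%) with an absolute floor so that fractions near
zero do not receive infinite weight.  The sum of squared weighted
residuals (SSR) is compared against the chi-square distribution with
dof = n_measurements - n_parameters at the 95% level; a fit is accepted
when SSR falls below that threshold.  Confidence intervals come from
linearised error propagation, cov = (J^T W J)^-1, with rank-deficient
directions flagged as structurally unidentifiable rather than silently
pseudo-inverted away.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist

from .emu import FeedLabeling, LabelingSystem, MIDTimeSeries, simulate_inst
from .network import ConstraintSet, FluxBasis, MetabolicNetwork, free_flux_basis


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# measurement model and residuals
# ---------------------------------------------------------------------------

@dataclass
class MeasurementModel:
    """Measured MID time series plus the error model applied to them."""
    series: dict[str, MIDTimeSeries]
    rel_sigma: float = 0.02
    abs_floor: float = 0.002

    def __post_init__(self):
        if self.rel_sigma < 0 or self.abs_floor <= 0:
            raise FitError("sigma policy must be positive")
        for ts in self.series.values():
            if ts.sigma is None:
                ts.sigma = self.sigma_for(ts.mids)
            elif np.any(ts.sigma <= 0):
                raise FitError(f"{ts.fragment_id}: non-positive sigma")

    def sigma_for(self, values: np.ndarray) -> np.ndarray:
        return np.maximum(self.rel_sigma * np.abs(values), self.abs_floor)

    @property
    def n_measurements(self) -> int:
        return sum(ts.mids.size for ts in self.series.values())

    @property
    def times(self) -> np.ndarray:
        return np.unique(np.concatenate([ts.times for ts in self.series.values()]))


def residual_vector(simulated: dict[str, MIDTimeSeries],
                    measured: MeasurementModel) -> np.ndarray:
    """Stacked (sim - meas)/sigma over every fraction and time point."""
    chunks = []
    for fid, meas in measured.series.items():
        if fid not in simulated:
            raise FitError(f"no simulation for measured fragment {fid}")
        sim = simulated[fid]
        if sim.mids.shape != meas.mids.shape or not np.allclose(sim.times, meas.times):
            raise FitError(f"{fid}: simulated and measured indexing differ")
        chunks.append(((sim.mids - meas.mids) / meas.sigma).ravel())
    return np.concatenate(chunks)


def weighted_residual(simulated: dict[str, MIDTimeSeries],
                      measured: MeasurementModel) -> float:
    """SSR = sum of ((sim - meas)/sigma)^2."""
    return float(np.sum(residual_vector(simulated, measured) ** 2))


@dataclass
class Chi2Result:
    dof: int
    threshold: float
    accepted: bool


def chi2_acceptance(ssr: float, n_measurements: int, n_parameters: int,
                    alpha: float = 0.05) -> Chi2Result:
    """Goodness-of-fit verdict: SSR below the (1-alpha) chi-square quantile."""
    dof = n_measurements - n_parameters
    if dof <= 0:
        raise FitError(f"non-positive degrees of freedom ({dof})")
    threshold = float(chi2_dist.ppf(1.0 - alpha, dof))
    return Chi2Result(dof, threshold, bool(ssr <= threshold))


# ---------------------------------------------------------------------------
# parameterisation
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    n_starts: int = 10
    seed: int = 0
    net_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_net_bounds: tuple[float, float] = (-5.0, 5.0)
    beta_max: float = 0.95           # exchange = beta/(1-beta), cap ~19
    pool_bounds: tuple[float, float] = (1e-3, 50.0)  # umol/gCDW
    init: dict[str, float] | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    xtol: float = 1e-10


class _Parameterisation:
    """Maps the optimiser vector to (fluxes, pools).

    Free net fluxes are used directly (bounded), exchange fluxes through
    the bounded transform exchange = beta/(1-beta) with beta in [0, beta_max],
    unmeasured pools through log10.
    """

    def __init__(self, basis: FluxBasis, system: LabelingSystem,
                 measured_pools: dict[str, float], config: FitConfig):
        self.basis = basis
        self.system = system
        self.measured_pools = dict(measured_pools)
        self.config = config
        hosts = sorted({met for met, _ in system.emus})
        self.unmeasured = [m for m in hosts if m not in measured_pools]
        self.names = ([f"net:{r}" for r in basis.free_net_ids]
                      + [f"exch:{r}" for r in basis.exchange_ids]
                      + [f"pool:{m}" for m in self.unmeasured])
        nb = [config.net_bounds.get(r, config.default_net_bounds)
              for r in basis.free_net_ids]
        lo = [b[0] for b in nb] + [0.0] * len(basis.exchange_ids) \
            + [np.log10(config.pool_bounds[0])] * len(self.unmeasured)
        hi = [b[1] for b in nb] + [config.beta_max] * len(basis.exchange_ids) \
            + [np.log10(config.pool_bounds[1])] * len(self.unmeasured)
        self.lower, self.upper = np.array(lo), np.array(hi)

    @property
    def n(self) -> int:
        return len(self.names)

    def split(self, x: np.ndarray):
        nf = len(self.basis.free_net_ids)
        ne = len(self.basis.exchange_ids)
        free_net = dict(zip(self.basis.free_net_ids, x[:nf]))
        beta = x[nf:nf + ne]
        exchange = {r: float(b / (1.0 - b)) for r, b in
                    zip(self.basis.exchange_ids, beta)}
        pools = dict(self.measured_pools)
        pools.update({m: float(10.0 ** v) for m, v in
                      zip(self.unmeasured, x[nf + ne:])})
        return free_net, exchange, pools

    def pack(self, fluxes, pools) -> np.ndarray:
        """Vector for a known (flux, pool) state - used for starts at truth."""
        vals = [fluxes.net[r] for r in self.basis.free_net_ids]
        for r in self.basis.exchange_ids:
            ex = fluxes.exchange.get(r, 0.0)
            vals.append(ex / (1.0 + ex))
        for m in self.unmeasured:
            vals.append(np.log10(pools[m]))
        return np.clip(np.array(vals), self.lower, self.upper)


# ---------------------------------------------------------------------------
# the fit itself
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    parameters: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    identifiable: dict[str, bool]
    ssr: float
    n_measurements: int
    n_parameters: int
    dof: int
    chi2_threshold: float
    accepted: bool
    seed: int
    n_starts: int
    converged: bool
    message: str = ""
    start_ssrs: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "parameters": self.parameters,
            "sd": self.sd,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "identifiable": self.identifiable,
            "ssr": self.ssr,
            "n_measurements": self.n_measurements,
            "n_parameters": self.n_parameters,
            "dof": self.dof,
            "chi2_threshold": self.chi2_threshold,
            "accepted": self.accepted,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _predict(par: _Parameterisation, x: np.ndarray, feed: FeedLabeling,
             measured: MeasurementModel, times: np.ndarray):
    free_net, exchange, pools = par.split(x)
    fluxes = par.basis.complete(free_net, exchange)
    # infeasible completions (negative irreversible net) get a smooth penalty
    violation = 0.0
    for rxn in par.basis.network.reactions:
        if not rxn.reversible and fluxes.net[rxn.id] < 0:
            violation += -fluxes.net[rxn.id]
    if violation > 1e-9:
        return None, violation
    sim = simulate_inst(par.system, fluxes, pools, feed, times,
                        rtol=par.config.rtol, atol=par.config.atol)
    tidx = {t: i for i, t in enumerate(times)}
    out = {}
    for fid, meas in measured.series.items():
        rows = [tidx[t] for t in meas.times]
        out[fid] = MIDTimeSeries(fid, meas.times, sim[fid].mids[rows])
    return out, 0.0


def fit(network: MetabolicNetwork, system: LabelingSystem,
        measured: MeasurementModel, constraints: ConstraintSet,
        feed: FeedLabeling, measured_pools: dict[str, float],
        config: FitConfig | None = None) -> FitResult:
    """Multi-start bounded least squares over free fluxes and unmeasured pools."""
    config = config or FitConfig()
    basis = free_flux_basis(network, constraints)
    par = _Parameterisation(basis, system, measured_pools, config)
    times = measured.times
    n_meas = measured.n_measurements
    n_par = par.n

    if n_par == 0:
        sim, _ = _predict(par, np.empty(0), feed, measured, times)
        ssr = weighted_residual(sim, measured)
        chi = chi2_acceptance(ssr, n_meas, 0) if n_meas > 0 else None
        return FitResult({}, {}, {}, {}, ssr, n_meas, 0, chi.dof, chi.threshold,
                         chi.accepted, config.seed, 0, True, "no free parameters")

    def residuals(x):
        sim, violation = _predict(par, x, feed, measured, times)
        if sim is None:
            return np.full(n_meas, 1e3 * (1.0 + violation))
        return residual_vector(sim, measured)

    rng = np.random.default_rng(config.seed)
    starts = []
    if config.init is not None:
        x0 = np.array([config.init.get(name, 0.5 * (lo + hi))
                       for name, lo, hi in zip(par.names, par.lower, par.upper)])
        starts.append(np.clip(x0, par.lower, par.upper))
    while len(starts) < max(config.n_starts, 1):
        starts.append(par.lower + rng.random(n_par) * (par.upper - par.lower))

    best, start_ssrs = None, []
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(par.lower, par.upper),
                                method="trf", xtol=config.xtol)
        except Exception:
            start_ssrs.append(float("inf"))
            continue
        ssr = float(2.0 * res.cost)
        start_ssrs.append(ssr)
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise FitError("all optimisation starts failed")
    ssr, res = best

    chi = chi2_acceptance(ssr, n_meas, n_par)
    params = dict(zip(par.names, (float(v) for v in res.x)))
    # recompute the Jacobian with a controlled central-difference step: the
    # optimiser's tiny internal steps are dominated by ODE-solver noise,
    # which masks structurally flat directions
    jac = _fd_jacobian(residuals, res.x, par.lower, par.upper)
    sd, ci, ident = confidence_intervals_from_jacobian(jac, par.names, res.x,
                                                       abs_tol=2.0)
    return FitResult(params, sd, ci, ident, ssr, n_meas, n_par, chi.dof,
                     chi.threshold, chi.accepted, config.seed, len(starts),
                     bool(res.status > 0), res.message, start_ssrs)


def _fd_jacobian(residuals, x: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                 rel_step: float = 0.01) -> np.ndarray:
    """Central-difference Jacobian with steps scaled to the parameter box."""
    n = x.size
    cols = []
    for j in range(n):
        h = max(rel_step * (upper[j] - lower[j]), 1e-8)
        hi = min(x[j] + h, upper[j])
        lo = max(x[j] - h, lower[j])
        xp, xm = x.copy(), x.copy()
        xp[j], xm[j] = hi, lo
        cols.append((residuals(xp) - residuals(xm)) / (hi - lo))
    return np.column_stack(cols)


def confidence_intervals_from_jacobian(jac: np.ndarray, names: list[str],
                                       x: np.ndarray, z: float = 1.959964,
                                       abs_tol: float = 0.0):
    """Linearised sd/CI from the weighted Jacobian; cov = (J^T J)^-1.

    Directions with vanishing singular values are structurally
    unidentifiable: affected parameters get sd = inf and an explicit flag.
    ``abs_tol`` additionally treats directions whose singular value (in
    weighted-residual units per unit parameter) falls below it as flat.
    """
    U, s, Vt = np.linalg.svd(jac, full_matrices=False)
    tol = max(jac.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    identifiable_dir = s > max(tol, 1e-10 * (s[0] if s.size else 1.0), abs_tol)
    sd, ci, ident = {}, {}, {}
    # parameter is unidentifiable if it loads on a null direction
    null_load = np.sqrt(np.sum(Vt[~identifiable_dir] ** 2, axis=0)) \
        if (~identifiable_dir).any() else np.zeros(len(names))
    s_safe = np.where(identifiable_dir, s, np.inf)
    cov = (Vt.T * (1.0 / s_safe**2)) @ Vt
    for i, name in enumerate(names):
        if null_load[i] > 1e-6:
            sd[name], ci[name], ident[name] = float("inf"), (-float("inf"), float("inf")), False
        else:
            sdi = float(np.sqrt(cov[i, i]))
            sd[name] = sdi
            ci[name] = (float(x[i] - z * sdi), float(x[i] + z * sdi))
            ident[name] = True
    return sd, ci, ident
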