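"""Synthetic ground truths and noisy datasets with the labelling study's
statistical structure.

The default experiment design mirrors the wash-in experiment: feed of 80%
[1-13C1] + 20% [U-13C6] glucose and 100% 13C methanol, 20 sampling times
from 5 s growing exponentially to 6 h, and independent Gaussian noise of
2% relative standard deviation on every mass-isotopomer fraction
(truncated at zero, each MID renormalised to sum 1).  Concentration tables
get lognormal replicate noise; macroscopic rate tables are derived
carbon-balanced from the boundary fluxes of the ground truth before noise
is added.  Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balances import BiomassComposition, MacroRates
from .emu import FeedLabeling, LabelingSystem, MIDTimeSeries, simulate_inst
from .network import ConstraintSet, FluxDistribution, MetabolicNetwork, free_flux_basis


class SynthError(ValueError):
    pass


def exponential_time_grid(n: int = 20, t_first: float = 5.0 / 3600.0,
                          t_last: float = 6.0) -> np.ndarray:
    """t_k = t_first * (t_last/t_first)^(k/(n-1)), k = 0..n-1 (hours)."""
    k = np.arange(n)
    return t_first * (t_last / t_first) ** (k / (n - 1))


@dataclass
class ExperimentDesign:
    feed: FeedLabeling = field(default_factory=FeedLabeling.glucose_methanol)
    times: np.ndarray = field(default_factory=exponential_time_grid)
    rel_sigma: float = 0.02
    abs_floor: float = 0.002
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise SynthError("time grid must be strictly increasing")
        if self.rel_sigma < 0:
            raise SynthError("rel_sigma must be >= 0")


@dataclass
class GroundTruth:
    fluxes: FluxDistribution
    pools: dict[str, float]     # umol/gCDW, all balanced metabolites
    seed: int

    def __post_init__(self):
        for met, c in self.pools.items():
            if c <= 0:
                raise SynthError(f"{met}: non-positive pool in ground truth")


def sample_ground_truth(network: MetabolicNetwork, constraints: ConstraintSet,
                        seed: int,
                        net_bounds: dict[str, tuple[float, float]] | None = None,
                        default_net_bounds: tuple[float, float] = (0.0, 2.0),
                        exchange_range: tuple[float, float] = (0.0, 2.0),
                        pool_range: tuple[float, float] = (0.01, 20.0),
                        max_tries: int = 200) -> GroundTruth:
    """Uniformly sampled free fluxes completed to a steady flux vector,
    log-uniform pools in the physiological 0.01-20 umol/gCDW window.

    Rejection-samples until every irreversible net flux is non-negative.
    """
    rng = np.random.default_rng(seed)
    basis = free_flux_basis(network, constraints)
    net_bounds = net_bounds or {}
    for _ in range(max_tries):
        free = {}
        for rid in basis.free_net_ids:
            lo, hi = net_bounds.get(rid, default_net_bounds)
            free[rid] = float(rng.uniform(lo, hi))
        exchange = {rid: float(rng.uniform(*exchange_range))
                    for rid in basis.exchange_ids}
        fluxes = basis.complete(free, exchange)
        feasible = all(rxn.reversible or fluxes.net[rxn.id] >= 0
                       for rxn in network.reactions)
        if feasible:
            break
    else:
        raise SynthError(
            f"no feasible flux sample in {max_tries} tries; constraint set "
            "may be infeasible or bounds too wide")
    lo, hi = np.log(pool_range[0]), np.log(pool_range[1])
    pools = {m.id: float(np.exp(rng.uniform(lo, hi)))
             for m in network.species.values() if not m.is_boundary and not m.balance_only}
    return GroundTruth(fluxes, pools, seed)


def generate_labeling_dataset(system: LabelingSystem, truth: GroundTruth,
                              design: ExperimentDesign,
                              rtol: float = 1e-8) -> dict[str, MIDTimeSeries]:
    """simulate_inst at the design times plus truncated Gaussian noise.

    sigma = max(rel_sigma * value, abs_floor) per fraction; noisy MIDs are
    clipped at zero and renormalised to sum 1.  rel_sigma = 0 returns the
    noise-free simulation (with sigma still attached for fitting).
    """
    rng = np.random.default_rng(design.seed)
    sim = simulate_inst(system, truth.fluxes, truth.pools, design.feed,
                        design.times, rtol=rtol, atol=rtol * 1e-2)
    out = {}
    for fid, ts in sim.items():
        sigma = np.maximum(design.rel_sigma * np.abs(ts.mids), design.abs_floor)
        if design.rel_sigma == 0:
            out[fid] = MIDTimeSeries(fid, ts.times, ts.mids.copy(), sigma)
            continue
        noisy = ts.mids + rng.normal(0.0, 1.0, ts.mids.shape) * sigma
        noisy = np.clip(noisy, 0.0, None)
        noisy /= noisy.sum(axis=1, keepdims=True)
        out[fid] = MIDTimeSeries(fid, ts.times, noisy,
                                 np.maximum(design.rel_sigma * noisy, design.abs_floor))
    return out


def generate_concentration_dataset(concentrations: dict[str, float],
                                   n_replicates: int = 3, rel_sigma: float = 0.1,
                                   seed: int = 0) -> pd.DataFrame:
    """Lognormal replicate noise around true pools -> (metabolite, mean, sd, n).

    The table feeds straight into thermo.ranges_from_table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for met, c in concentrations.items():
        if c <= 0:
            raise SynthError(f"{met}: non-positive concentration")
        if rel_sigma == 0:
            rows.append((met, c, 0.0, n_replicates))
            continue
        reps = c * np.exp(rng.normal(0.0, rel_sigma, n_replicates))
        rows.append((met, float(np.mean(reps)), float(np.std(reps, ddof=1)),
                     n_replicates))
    return pd.DataFrame(rows, columns=["metabolite", "mean", "sd", "n"])


def rates_from_truth(truth: GroundTruth, network: MetabolicNetwork,
                     biomass: BiomassComposition | None = None,
                     uptake_ids: tuple[str, str] = ("upt_glc", "upt_metoh"),
                     co2_id: str = "co2_out",
                     biomass_prefix: str = "bm_",
                     secreted_ids: tuple[str, ...] = ("sec_treh",),
                     dilution_rate: float = 0.09) -> MacroRates:
    """Exact macroscopic rates implied by the boundary fluxes of a truth.

    q_biomass counts all non-CO2 carbon leaving the cell (precursor drains
    plus secreted product, in mCmol/gCDW/h) so that carbon recovery closes
    exactly; q_o2 closes the degree-of-reduction balance.
    """
    biomass = biomass or BiomassComposition()
    v = truth.fluxes.net
    carbons = {r.id: sum(len(t.atoms) for t in r.substrates)
               for r in network.reactions}
    q_glc = -v[uptake_ids[0]]
    q_met = -v[uptake_ids[1]]
    q_co2 = v[co2_id]
    q_x = sum(v[r.id] * carbons[r.id] for r in network.reactions
              if r.id.startswith(biomass_prefix))
    q_x += sum(v[rid] * carbons[rid] for rid in secreted_ids if rid in v)
    # close the electron balance for O2
    q_o2 = -(24.0 * abs(q_glc) + 6.0 * abs(q_met) - biomass.gamma * q_x) / 4.0
    return MacroRates(q_glc, q_met, q_o2, q_co2, q_x, dilution_rate)


def generate_rates_dataset(truth: GroundTruth, network: MetabolicNetwork,
                           rel_sigma: float = 0.015, seed: int = 0,
                           biomass: BiomassComposition | None = None,
                           **kwargs) -> MacroRates:
    """Carbon-balanced rates from the truth, perturbed with relative noise."""
    exact = rates_from_truth(truth, network, biomass, **kwargs)
    rng = np.random.default_rng(seed)
    vals = exact.vector()
    sds = np.abs(vals) * rel_sigma
    if rel_sigma > 0:
        vals = vals + rng.normal(0.0, 1.0, vals.size) * sds
        sd = {k: float(s) for k, s in zip(MacroRates._ORDER, sds)}
    else:
        sd = {k: max(abs(x) * 0.01, 1e-6) for k, x in zip(MacroRates._ORDER, vals)}
    return MacroRates(*vals, dilution_rate=exact.dilution_rate, sd=sd)
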