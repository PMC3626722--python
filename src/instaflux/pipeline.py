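"""Stage orchestration: simulate -> fit -> chi2 -> CI -> thermo -> balances.

Each ``run_*`` function takes a plain config mapping (usually loaded from
YAML), executes one stage through the library modules and writes
JSON-first reports plus CSV tables into the output directory.  Every
report embeds the seed and a hash of the resolved config so that runs are
reproducible and self-describing.  The thin click CLI in
:mod:`instaflux.cli` maps subcommands onto these functions, and the
numbered analysis scripts call them directly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import balances as bal
from . import data as fixtures
from . import io as fio
from . import thermo as th
from .emu import FeedLabeling, decompose, simulate_inst
from .fitting import FitConfig, MeasurementModel, fit
from .network import free_flux_basis, validate_steady_state
from .synth import (ExperimentDesign, GroundTruth, exponential_time_grid,
                    generate_labeling_dataset, sample_ground_truth)


class ConfigError(ValueError):
    pass


def _hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stamp(config: dict, payload: dict) -> dict:
    payload["seed"] = int(config.get("seed", 0))
    payload["config_hash"] = _hash(config)
    return payload


def _out_dir(config: dict) -> Path:
    out = Path(config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def _load_network(config: dict):
    src = config.get("network", "fixture")
    return fixtures.load_ppastoris_network() if src == "fixture" else fio.read_network(src)


def _load_constraints(config: dict):
    src = config.get("constraints", "fixture")
    if src == "fixture":
        return fixtures.load_ppastoris_constraints()
    return fio.read_constraints(src)


def _load_fragments(config: dict):
    src = config.get("fragments", "fixture")
    if src == "fixture":
        return fio.fragments_from_mapping(fixtures.load_ppastoris_fragments())
    return fio.read_fragments(src)


def _load_truth(config: dict, network):
    src = config.get("truth", "fixture")
    if src == "fixture":
        fluxes = fixtures.load_ppastoris_truth()
        pools = {m.id: m.measured_pool for m in network.metabolites}
        return GroundTruth(fluxes, pools, int(config.get("seed", 0)))
    import yaml as _yaml
    data = _yaml.safe_load(Path(src).read_text())
    fluxes = fio.read_fluxes_yaml(src)
    pools = data.get("pools") or {m.id: m.measured_pool
                                  for m in network.metabolites}
    return GroundTruth(fluxes, pools, int(config.get("seed", 0)))


def _times(config: dict) -> np.ndarray:
    t = config.get("times", {})
    return exponential_time_grid(int(t.get("n", 20)),
                                 float(t.get("t_first_h", 5.0 / 3600.0)),
                                 float(t.get("t_last_h", 6.0)))


def _feed(config: dict) -> FeedLabeling:
    if "feed" not in config:
        return FeedLabeling.glucose_methanol()
    return FeedLabeling({met: [(p, float(f)) for p, f in entries]
                         for met, entries in config["feed"].items()})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: dict) -> dict:
    """Deterministic forward simulation of the measured fragment MIDs."""
    out = _out_dir(config)
    network = _load_network(config)
    truth = _load_truth(config, network)
    truth.fluxes.validate(network)
    resid = validate_steady_state(network, truth.fluxes)
    if resid > 1e-6:
        raise ConfigError(f"flux distribution violates steady state ({resid:.2e})")
    fragments = _load_fragments(config)
    system = decompose(network, fragments)
    times = _times(config)
    series = simulate_inst(system, truth.fluxes, truth.pools, _feed(config), times)
    mid_path = out / "mid_timeseries.csv"
    fio.write_mid_csv(series, mid_path)
    report = _stamp(config, {
        "stage": "simulate",
        "n_fragments": len(fragments),
        "n_times": int(times.size),
        "n_fractions": int(sum(ts.mids.shape[1] for ts in series.values())),
        "steady_state_residual": resid,
        "mid_csv": str(mid_path),
    })
    _write_json(out / "simulate_report.json", report)
    return report


def run_synth(config: dict) -> dict:
    """Sampled or fixture ground truth plus a noisy labelling dataset."""
    out = _out_dir(config)
    network = _load_network(config)
    seed = int(config.get("seed", 0))
    if config.get("truth", "fixture") == "sampled":
        constraints = _load_constraints(config)
        truth = sample_ground_truth(network, constraints, seed)
    else:
        truth = _load_truth(config, network)
    fragments = _load_fragments(config)
    system = decompose(network, fragments)
    design = ExperimentDesign(feed=_feed(config), times=_times(config),
                              rel_sigma=float(config.get("rel_sigma", 0.02)),
                              seed=seed)
    series = generate_labeling_dataset(system, truth, design)
    mid_path = out / "synthetic_mids.csv"
    fio.write_mid_csv(series, mid_path, rel_sigma=design.rel_sigma)
    report = _stamp(config, {
        "stage": "synth",
        "rel_sigma": design.rel_sigma,
        "n_fragments": len(fragments),
        "mid_csv": str(mid_path),
    })
    _write_json(out / "synth_report.json", report)
    return report


def run_fit(config: dict) -> dict:
    """Weighted least-squares fit of free fluxes and unmeasured pools."""
    out = _out_dir(config)
    network = _load_network(config)
    constraints = _load_constraints(config)
    fragments = _load_fragments(config)
    system = decompose(network, fragments)
    data_path = config.get("data")
    if not data_path or not Path(data_path).exists():
        raise ConfigError(f"measured MID table not found: {data_path}")
    series, rel = fio.read_mid_csv(data_path)
    measured = MeasurementModel(series, rel_sigma=float(config.get("rel_sigma", rel)))
    measured_pools = {m.id: m.measured_pool for m in network.metabolites
                      if m.measured_pool is not None
                      and m.id in getattr(network, "measured_pool_ids", set())}
    fc = config.get("fit", {})
    cfg = FitConfig(n_starts=int(fc.get("n_starts", 10)),
                    seed=int(config.get("seed", 0)),
                    default_net_bounds=tuple(fc.get("net_bounds", (-5.0, 5.0))),
                    rtol=float(fc.get("rtol", 1e-8)),
                    init=fc.get("init"))
    result = fit(network, system, measured, constraints, _feed(config),
                 measured_pools, cfg)
    report = _stamp(config, {"stage": "fit", **result.summary()})
    _write_json(out / "fit_result.json", report)
    # residual table
    import pandas as pd
    rows = []
    basis = free_flux_basis(network, constraints)
    rows.append({"ssr": result.ssr, "dof": result.dof,
                 "threshold": result.chi2_threshold,
                 "n_free_fluxes": len(basis.free_net_ids) + len(basis.exchange_ids)})
    pd.DataFrame(rows).to_csv(out / "fit_summary.csv", index=False)
    return report


def run_thermo(config: dict) -> dict:
    """NET feasibility, range tightening and minimum cofactor ratios."""
    out = _out_dir(config)
    import pandas as pd
    src = config.get("thermo", "fixture")
    raw = fixtures.load_thermo_fixture() if src == "fixture" else \
        __import__("yaml").safe_load(Path(src).read_text())
    ph = config.get("ph", "7.2")
    model, raw = fio.load_thermo_inputs(raw, ph)
    variant = config.get("variant", "classical")
    directions = dict(raw["directions_channelled" if variant == "channelled"
                          else "directions"])
    conc_path = config.get("concentrations")
    if conc_path:
        table = pd.read_csv(conc_path)
        ranges = th.ranges_from_table(table, model)
    elif src == "fixture":
        # deterministic stand-in measurement table from the packaged pools:
        # mean = pool, 15% relative sd, sextuplicate (2 chemostats x 3)
        pools = fixtures.load_ppastoris_pools()
        meas = pools[pools.measured == 1]
        table = pd.DataFrame({"metabolite": meas.metabolite,
                              "mean": meas.pool_umol_gcdw,
                              "sd": 0.15 * meas.pool_umol_gcdw,
                              "n": 6})
        ranges = th.ranges_from_table(table, model)
    else:
        ranges = {}
    lo, hi = raw.get("default_ranges_mm", [1e-3, 10.0])
    needed = {m for rid in directions for m in model.reactions[rid].stoich}
    for met in needed:
        if met not in ranges:
            dlo, dhi = raw.get("cofactor_ranges_mm", {}).get(met, (lo, hi))
            ranges[met] = th.ConcentrationRange(met, dlo, dhi, "default")
    result = th.net_feasibility(model, directions, ranges)
    couples = [tuple(c) for c in config.get("couples", [["NAD", "NADH"]])]
    ratios = {}
    if result.feasible:
        for couple in couples:
            r = th.min_cofactor_ratio(model, directions, ranges, couple)
            ratios["/".join(couple)] = None if r.unbounded else r.min_ratio
    report = _stamp(config, {
        "stage": "thermo",
        "ph": float(ph),
        "variant": variant,
        "feasible": result.feasible,
        "violated": result.violated,
        "min_cofactor_ratios": ratios,
        "tightened_ranges_mm": {m: [r.lower, r.upper]
                                for m, r in result.ranges.items()},
        "gibbs_ranges_kj": {k: list(v) for k, v in result.gibbs_ranges.items()},
    })
    _write_json(out / f"net_report_{variant}_ph{ph}.json", report)
    (out / f"net_report_{variant}_ph{ph}.txt").write_text(result.report() + "\n")
    return report


def run_balance(config: dict) -> dict:
    """RQ, carbon recovery, reconciliation, cofactor and ATP accounting."""
    out = _out_dir(config)
    src = config.get("rates", "fixture")
    rates = fixtures.load_ppastoris_rates() if src == "fixture" else \
        fio.read_rates_csv(src)
    biomass = bal.BiomassComposition(**config.get("biomass", {}))
    rq = bal.respiratory_quotient(rates)
    recovery = bal.carbon_recovery(rates)
    rec = bal.reconcile_rates(rates, biomass)
    payload = {
        "stage": "balance",
        "rq": rq,
        "carbon_recovery_pct": recovery,
        "reconciliation": {
            "statistic": rec.statistic,
            "threshold": rec.threshold,
            "consistent": rec.consistent,
            "reconciled": dict(zip(bal.MacroRates._ORDER,
                                   rec.reconciled.vector())),
            "recovery_after_pct": bal.carbon_recovery(rec.reconciled),
        },
    }
    if config.get("fluxes", "fixture") is not None:
        network = _load_network(config)
        truth = _load_truth(config, network)
        cof_src = config.get("cofactors", "fixture")
        stoich = fixtures.load_ppastoris_cofactors(
            po_ratio=float(config.get("po_ratio", 1.48)),
            growth_atp=float(config.get("growth_atp", 5.9))) \
            if cof_src == "fixture" else fio.read_cofactors(cof_src)
        cof = bal.cofactor_rates(truth.fluxes, stoich)
        qo2 = bal.theoretical_qo2(max(cof["NADH"], 0.0), max(cof["FADH2"], 0.0),
                                  measured_our=rates.q_o2)
        atp = bal.atp_accounting(truth.fluxes, stoich, abs(rates.q_o2))
        payload.update({
            "cofactor_rates": cof,
            "theoretical_qo2": qo2.q_o2,
            "qo2_fraction_of_measured_pct": qo2.fraction_of_measured,
            "atp": {
                "total": atp.total,
                "substrate_level": atp.substrate_level,
                "oxphos": atp.oxphos,
                "oxphos_fraction_pct": 100.0 * atp.oxphos_fraction,
                "maintenance": atp.maintenance,
                "negative_maintenance": atp.negative_maintenance,
            },
        })
    report = _stamp(config, payload)
    _write_json(out / "balance_report.json", report)
    return report
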