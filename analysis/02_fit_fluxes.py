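#!/usr/bin/env python
"""Estimate fluxes and pool sizes from noisy synthetic labelling data.

Two demonstrations, both written to results/:

1. Full-network consistency: the weighted residual of the reference flux
   distribution against its own noisy dataset (2% relative error), with
   the chi-square acceptance bookkeeping at the study scale: 80 fractions
   x 20 times = 1600 measurements, 24 free fluxes + 10 unmeasured pools
   = 34 parameters, dof 1566.

2. A complete estimation round trip on a small identifiable network
   (branch point + buffer pool): multi-start weighted least squares,
   chi-square verdict and linearised confidence intervals.

The full 34-parameter fit of the reduced network is supported through the
same `fit` API but takes hours of ODE integrations; this driver keeps the
demonstration at a size that runs in minutes.
"""

import json
from pathlib import Path

from scipy.stats import chi2 as chi2_dist

from instaflux import data
from instaflux.emu import FeedLabeling, FragmentSpec, decompose
from instaflux.fitting import (FitConfig, MeasurementModel, chi2_acceptance,
                               fit, weighted_residual)
from instaflux.io import fragments_from_mapping
from instaflux.network import (ConstraintSet, FluxDistribution, free_flux_basis,
                               parse_network)
from instaflux.synth import (ExperimentDesign, GroundTruth,
                             exponential_time_grid, generate_labeling_dataset)

OUT = Path("results")
SEED = 2013


def full_network_residual() -> dict:
    net = data.load_ppastoris_network()
    truth = GroundTruth(data.load_ppastoris_truth(),
                        {m.id: m.measured_pool for m in net.metabolites}, SEED)
    fragments = fragments_from_mapping(data.load_ppastoris_fragments())
    system = decompose(net, fragments)
    design = ExperimentDesign(times=exponential_time_grid(), rel_sigma=0.02,
                              seed=SEED)
    noisy = generate_labeling_dataset(system, truth, design, rtol=1e-7)
    noise_free = generate_labeling_dataset(
        system, truth, ExperimentDesign(times=design.times, rel_sigma=0.0,
                                        seed=SEED), rtol=1e-7)
    ssr = weighted_residual(noise_free, MeasurementModel(noisy))
    basis = free_flux_basis(net, data.load_ppastoris_constraints())
    n = sum(ts.mids.size for ts in noisy.values())
    n_par = basis.n_free + 10
    chi = chi2_acceptance(ssr, n, n_par)
    return {
        "n_measurements": n,
        "n_parameters": n_par,
        "dof": chi.dof,
        "chi2_threshold_95": round(chi.threshold, 1),
        "ssr_at_truth": round(ssr, 2),
        "accepted": chi.accepted,
        "note": "renormalised MIDs carry ~n - n_mids*T independent fractions, "
                f"i.e. an effective dof of about {n - 15 * 20}",
    }


def toy_round_trip() -> dict:
    net = parse_network("""
@external Sx Px Qx
u:  Sx(ab) -> A(ab)
v1: A(ab) -> B(ab)
v2: A(ab) -> C(ba)
ob: B(ab) -> Px(ab)
oc: C(ab) -> Qx(ab)
w:  B(ab) <-> D(ba)
""")
    cons = ConstraintSet(fixed={"u": 1.0})
    truth = GroundTruth(FluxDistribution(
        {"u": 1.0, "v1": 0.6, "v2": 0.4, "ob": 0.6, "oc": 0.4, "w": 0.0},
        {"w": 0.5}), {"A": 2.0, "B": 10.0, "C": 6.0, "D": 8.0}, SEED)
    fragments = [FragmentSpec("b12", "B", (1, 2)), FragmentSpec("c12", "C", (1, 2)),
                 FragmentSpec("c1", "C", (1,)), FragmentSpec("d1", "D", (1,))]
    system = decompose(net, fragments)
    feed = FeedLabeling({"Sx": [("10", 0.5), ("11", 0.3), ("00", 0.2)]})
    design = ExperimentDesign(feed=feed, times=exponential_time_grid(12, 5 / 3600, 1.0),
                              rel_sigma=0.02, seed=SEED)
    noisy = generate_labeling_dataset(system, truth, design, rtol=1e-7)
    cfg = FitConfig(n_starts=3, seed=SEED, default_net_bounds=(0.0, 1.0),
                    rtol=1e-6, atol=1e-8)
    res = fit(net, system, MeasurementModel(noisy), cons, feed,
              {"A": 2.0, "B": 10.0, "D": 8.0}, cfg)
    return {
        "truth": {"net:v2": 0.4, "exch:w beta": 0.5 / 1.5, "pool:C": 6.0},
        "fit": res.summary(),
    }


def main() -> None:
    OUT.mkdir(exist_ok=True)
    print("full-network residual at the generating truth (2% noise):")
    full = full_network_residual()
    for k, v in full.items():
        print(f"  {k}: {v}")

    print("\nround-trip estimation on the identifiable toy network:")
    toy = toy_round_trip()
    f = toy["fit"]
    print(f"  SSR {f['ssr']:.1f} on dof {f['dof']} "
          f"(threshold {f['chi2_threshold']:.1f}) -> accepted={f['accepted']}")
    for name, value in f["parameters"].items():
        sd = f["sd"][name]
        print(f"  {name}: {value:.4f} +/- {sd:.4f}")

    (OUT / "fit_analysis.json").write_text(
        json.dumps({"full_network": full, "toy_round_trip": toy}, indent=2,
                   default=float))


if __name__ == "__main__":
    main()
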