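"""Readers and writers for the pipeline's file dialects.

MID tables are wide CSV (fragment_id, time_h, m0..mK, sigma_rel) with
NaN-padded tails for shorter fragments; rate tables are (rate, value, sd)
CSV; fragments, constraints, cofactor coefficients and thermodynamic
inputs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balances import CofactorStoichiometry, MacroRates
from .emu import FragmentSpec, MIDTimeSeries
from .network import ConstraintSet, FluxDistribution, MetabolicNetwork, parse_network
from .thermo import ThermoModel, ThermoReaction


def read_network(path: str | Path) -> MetabolicNetwork:
    return parse_network(Path(path).read_text())


def read_constraints(path: str | Path) -> ConstraintSet:
    return ConstraintSet.from_yaml(Path(path).read_text())


def read_fragments(path: str | Path) -> list[FragmentSpec]:
    data = yaml.safe_load(Path(path).read_text())
    return [FragmentSpec(fid, spec["metabolite"], tuple(spec["positions"]),
                         spec.get("formula")) for fid, spec in data.items()]


def fragments_from_mapping(data: dict) -> list[FragmentSpec]:
    return [FragmentSpec(fid, spec["metabolite"], tuple(spec["positions"]),
                         spec.get("formula")) for fid, spec in data.items()]


def write_mid_csv(series: dict[str, MIDTimeSeries], path: str | Path,
                  rel_sigma: float = 0.02) -> None:
    k_max = max(ts.mids.shape[1] for ts in series.values())
    rows = []
    for fid, ts in series.items():
        for i, t in enumerate(ts.times):
            row = {"fragment_id": fid, "time_h": float(t), "sigma_rel": rel_sigma}
            for k in range(ts.mids.shape[1]):
                row[f"m{k}"] = float(ts.mids[i, k])
            rows.append(row)
    cols = ["fragment_id", "time_h"] + [f"m{k}" for k in range(k_max)] + ["sigma_rel"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_mid_csv(path: str | Path) -> tuple[dict[str, MIDTimeSeries], float]:
    df = pd.read_csv(path)
    mcols = sorted((c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    out = {}
    rel = 0.02
    for fid, grp in df.groupby("fragment_id", sort=False):
        grp = grp.sort_values("time_h")
        mids = grp[mcols].to_numpy(dtype=float)
        mids = mids[:, ~np.isnan(mids).all(axis=0)]
        if np.isnan(mids).any():
            raise ValueError(f"{fid}: ragged MID rows in {path}")
        rel = float(grp["sigma_rel"].iloc[0]) if "sigma_rel" in grp else rel
        out[fid] = MIDTimeSeries(fid, grp["time_h"].to_numpy(dtype=float), mids)
    return out, rel


def read_rates_csv(path: str | Path, dilution_rate: float = 0.09) -> MacroRates:
    df = pd.read_csv(path).set_index("rate")
    vals = {k: float(df.loc[k, "value"]) for k in MacroRates._ORDER}
    sd = {k: float(df.loc[k, "sd"]) for k in MacroRates._ORDER}
    return MacroRates(**vals, dilution_rate=dilution_rate, sd=sd)


def write_rates_csv(rates: MacroRates, path: str | Path) -> None:
    sd = rates.sd_vector()
    pd.DataFrame({"rate": list(MacroRates._ORDER), "value": rates.vector(),
                  "sd": sd}).to_csv(path, index=False)


def read_cofactors(path: str | Path, po_ratio: float = 1.48,
                   growth_atp: float = 0.0) -> CofactorStoichiometry:
    data = yaml.safe_load(Path(path).read_text())
    return CofactorStoichiometry(data, po_ratio=po_ratio, growth_atp=growth_atp)


def read_fluxes_yaml(path: str | Path) -> FluxDistribution:
    data = yaml.safe_load(Path(path).read_text())
    return FluxDistribution(net=data["net"], exchange=data.get("exchange", {}))


def load_thermo_inputs(data: dict, ph: str | float = "7.2") -> tuple[ThermoModel, dict]:
    """Build a ThermoModel for one pH scenario from the thermo YAML mapping."""
    ph_key = str(ph)
    reactions = {}
    for rid, spec in data["reactions"].items():
        dgr_table = spec["dgr0"]
        if ph_key not in dgr_table:
            raise KeyError(f"{rid}: no Delta_rG'0 for pH {ph_key}")
        reactions[rid] = ThermoReaction(rid, dict(spec["stoich"]),
                                        float(dgr_table[ph_key]))
    model = ThermoModel(reactions,
                        temperature=float(data.get("temperature", 298.15)),
                        ph=float(ph_key),
                        ionic_strength=float(data.get("ionic_strength", 0.15)),
                        cell_volume=float(data.get("cell_volume", 1.7)))
    return model, data
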