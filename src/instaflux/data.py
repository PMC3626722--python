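"""Loaders for the shipped P. pastoris fixture and the file dialects used
throughout: network text, constraint YAML, pool CSV, fragment YAML,
MID time-series CSV, rate CSV and standard-Gibbs-energy YAML."""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd
import yaml

from .network import ConstraintSet, FluxDistribution, MetabolicNetwork, parse_network


def _read_text(name: str) -> str:
    return resources.files("instaflux.datafiles").joinpath(name).read_text()


def load_ppastoris_network() -> MetabolicNetwork:
    """Reduced glucose-methanol P. pastoris network with atom transitions."""
    net = parse_network(_read_text("ppastoris_network.txt"))
    pools = load_ppastoris_pools()
    net.set_pools(dict(zip(pools["metabolite"], pools["pool_umol_gcdw"])),
                  measured=set(pools.loc[pools["measured"] == 1, "metabolite"]))
    return net


def load_ppastoris_constraints() -> ConstraintSet:
    return ConstraintSet.from_yaml(_read_text("ppastoris_constraints.yaml"))


def load_ppastoris_pools() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(_read_text("ppastoris_pools.csv")))


def load_ppastoris_truth() -> FluxDistribution:
    data = yaml.safe_load(_read_text("ppastoris_truth.yaml"))
    return FluxDistribution(net=data["net"], exchange=data["exchange"])


def load_ppastoris_fragments() -> dict:
    return yaml.safe_load(_read_text("ppastoris_fragments.yaml"))


def load_isotope_table() -> dict:
    return yaml.safe_load(_read_text("isotopes.yaml"))


def load_thermo_fixture() -> dict:
    """Synthetic Delta_rG'0 tables, flux directions and default ranges."""
    return yaml.safe_load(_read_text("ppastoris_thermo.yaml"))


def load_ppastoris_rates(dilution_rate: float = 0.09):
    """Measured chemostat rates (Table-style CSV shipped with the package)."""
    from .balances import MacroRates
    df = pd.read_csv(io.StringIO(_read_text("ppastoris_rates.csv"))).set_index("rate")
    vals = {k: float(df.loc[k, "value"]) for k in MacroRates._ORDER}
    sd = {k: float(df.loc[k, "sd"]) for k in MacroRates._ORDER}
    return MacroRates(**vals, dilution_rate=dilution_rate, sd=sd)


def load_ppastoris_cofactors(po_ratio: float = 1.48, growth_atp: float = 0.0):
    from .balances import CofactorStoichiometry
    coeffs = yaml.safe_load(_read_text("ppastoris_cofactors.yaml"))
    return CofactorStoichiometry(coeffs, po_ratio=po_ratio, growth_atp=growth_atp)
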