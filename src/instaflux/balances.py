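"""Macroscopic rate handling and cofactor/ATP balance reconstruction.

Covers the chemostat bookkeeping around the labelling experiment:
respiratory quotient, carbon recovery, elemental-balance data
reconciliation with a gross-error test, and the reconstruction of NADH /
NADPH / ATP turnover from a fitted net flux distribution.  Sign
convention: uptake rates are negative, production rates positive, all in
mmol/gCDW/h (biomass in mCmol/gCDW/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .network import FluxDistribution


class BalanceError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Elemental formula CH_hO_oN_n per Cmol of dry biomass."""
    h: float = 1.761
    o: float = 0.636
    n: float = 0.143

    @property
    def gamma(self) -> float:
        """Degree of reduction per Cmol (NH3 as nitrogen reference)."""
        return 4.0 + self.h - 2.0 * self.o - 3.0 * self.n


@dataclass
class MacroRates:
    """Specific chemostat rates; uptakes negative, products positive."""
    q_glucose: float       # mmol/gCDW/h, < 0
    q_methanol: float      # mmol/gCDW/h, < 0
    q_o2: float            # mmol/gCDW/h, < 0 (|q_o2| = OUR)
    q_co2: float           # mmol/gCDW/h, > 0 (CER)
    q_biomass: float       # mCmol/gCDW/h, > 0
    dilution_rate: float = 0.09  # 1/h
    sd: dict[str, float] = field(default_factory=dict)

    _ORDER = ("q_glucose", "q_methanol", "q_o2", "q_co2", "q_biomass")

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER])

    def sd_vector(self, default_rel: float = 0.02) -> np.ndarray:
        out = []
        for k in self._ORDER:
            s = self.sd.get(k, abs(getattr(self, k)) * default_rel)
            if s <= 0:
                raise BalanceError(f"{k}: sd must be positive")
            out.append(s)
        return np.array(out)


def respiratory_quotient(rates: MacroRates) -> float:
    """RQ = CER / OUR."""
    if rates.q_o2 == 0:
        raise BalanceError("zero oxygen uptake rate")
    return rates.q_co2 / abs(rates.q_o2)


def carbon_recovery(rates: MacroRates) -> float:
    """Percent of substrate carbon recovered in biomass + CO2."""
    intake = 6.0 * abs(rates.q_glucose) + abs(rates.q_methanol)
    if intake == 0:
        raise BalanceError("zero carbon intake")
    return 100.0 * (rates.q_biomass + rates.q_co2) / intake


def elemental_matrix(biomass: BiomassComposition) -> np.ndarray:
    """Carbon and degree-of-reduction conservation rows over
    (glucose, methanol, O2, CO2, biomass)."""
    carbon = np.array([6.0, 1.0, 0.0, 1.0, 1.0])
    redox = np.array([24.0, 6.0, -4.0, 0.0, biomass.gamma])
    return np.vstack([carbon, redox])


@dataclass
class ReconciliationResult:
    reconciled: MacroRates
    statistic: float
    threshold: float
    consistent: bool
    balance_residuals: np.ndarray


def reconcile_rates(rates: MacroRates, biomass: BiomassComposition | None = None,
                    alpha: float = 0.05) -> ReconciliationResult:
    """Weighted least-squares projection onto the elemental-balance subspace.

    The test statistic h = r^T (E S E^T)^-1 r (r = E x, S the measurement
    covariance) follows chi-square with rank(E) degrees of freedom when the
    measured rates contain no gross errors.
    """
    biomass = biomass or BiomassComposition()
    E = elemental_matrix(biomass)
    x = rates.vector()
    sd = rates.sd_vector()
    S = np.diag(sd ** 2)
    ese = E @ S @ E.T
    if np.linalg.matrix_rank(ese) < ese.shape[0]:
        raise BalanceError("singular covariance of balance residuals")
    r = E @ x
    w = np.linalg.solve(ese, r)
    x_star = x - S @ E.T @ w
    h = float(r @ w)
    dof = np.linalg.matrix_rank(E)
    threshold = float(chi2_dist.ppf(1.0 - alpha, dof))
    rec = MacroRates(*x_star, dilution_rate=rates.dilution_rate, sd=dict(rates.sd))
    return ReconciliationResult(rec, h, threshold, h <= threshold, E @ x_star)


# ---------------------------------------------------------------------------
# cofactor and ATP accounting
# ---------------------------------------------------------------------------

@dataclass
class CofactorStoichiometry:
    """Per-reaction production coefficients for NADH, NADPH, ATP
    (substrate-level) and FADH2; unlisted reactions contribute zero."""
    coefficients: dict[str, dict[str, float]]
    po_ratio: float = 1.48             # mol ATP / mol O
    growth_atp: float = 0.0            # mmol ATP/gCDW/h growth-associated demand

    def __post_init__(self):
        if self.po_ratio <= 0:
            raise BalanceError("P/O ratio must be positive")


COFACTORS = ("NADH", "NADPH", "ATP", "FADH2")


def cofactor_rates(fluxes: FluxDistribution,
                   stoich: CofactorStoichiometry) -> dict[str, float]:
    """Net production rate of each cofactor: sum_j coeff_j * v_net,j."""
    out = dict.fromkeys(COFACTORS, 0.0)
    for rid, coeffs in stoich.coefficients.items():
        if rid not in fluxes.net:
            raise BalanceError(f"missing flux for reaction {rid}")
        v = fluxes.net[rid]
        for cof, coeff in coeffs.items():
            if cof not in out:
                raise BalanceError(f"unknown cofactor {cof}")
            out[cof] += coeff * v
    return out


@dataclass
class OxygenResult:
    q_o2: float                 # mmol O2/gCDW/h
    fraction_of_measured: float | None = None


def theoretical_qo2(nadh_surplus: float, fadh2_surplus: float = 0.0,
                    measured_our: float | None = None) -> OxygenResult:
    """O2 demand if all surplus NADH/FADH2 is respired: (NADH+FADH2)/2.

    Each cofactor carries 2 electrons; O2 accepts 4, i.e. one O per pair.
    """
    if nadh_surplus < 0 or fadh2_surplus < 0:
        raise BalanceError("negative cofactor surplus: balance the network first")
    q = (nadh_surplus + fadh2_surplus) / 2.0
    frac = None if measured_our is None else 100.0 * q / abs(measured_our)
    return OxygenResult(q, frac)


@dataclass
class AtpResult:
    total: float
    substrate_level: float
    oxphos: float
    substrate_fraction: float
    oxphos_fraction: float
    maintenance: float
    negative_maintenance: bool


def atp_accounting(fluxes: FluxDistribution, stoich: CofactorStoichiometry,
                   q_o2: float) -> AtpResult:
    """Total ATP = substrate-level + 2 * (P/O) * qO2; maintenance is the
    remainder after the growth-associated demand."""
    substrate = cofactor_rates(fluxes, stoich)["ATP"]
    oxphos = 2.0 * stoich.po_ratio * q_o2
    total = substrate + oxphos
    maintenance = total - stoich.growth_atp
    return AtpResult(
        total=total,
        substrate_level=substrate,
        oxphos=oxphos,
        substrate_fraction=substrate / total if total else 0.0,
        oxphos_fraction=oxphos / total if total else 0.0,
        maintenance=maintenance,
        negative_maintenance=maintenance < 0,
    )
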