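"""Network-embedded thermodynamic (NET) analysis.

Second-law consistency of metabolite concentrations with assumed flux
directions: every reaction carrying flux must run downhill in Gibbs
energy, Delta_rG' = Delta_rG'0 + RT ln Q < 0 in its flux direction.  In
log-concentration space these are linear constraints, so feasibility,
range tightening and extremal cofactor ratios are linear programs.

Standard Gibbs energies are inputs (kJ/mol at the stated pH, ionic
strength and temperature); pH scenarios are handled by supplying one
Delta_rG'0 table per pH.  Concentrations are intracellular, converted
from umol/gCDW to mM through the specific cell volume (1.7 ml/gCDW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.stats import t as t_dist

R_GAS = 8.314462618e-3  # kJ/mol/K


class ThermoError(ValueError):
    pass


@dataclass
class ThermoReaction:
    """Directed stoichiometry (products positive) with Delta_rG'0 in kJ/mol.

    Water and protons are excluded from the stoichiometry by convention;
    their contribution is folded into the transformed Delta_rG'0.
    """
    id: str
    stoich: dict[str, float]
    dgr0: float


@dataclass
class ThermoModel:
    reactions: dict[str, ThermoReaction]
    temperature: float = 298.15    # K
    ph: float = 7.2
    ionic_strength: float = 0.15   # M
    cell_volume: float = 1.7       # ml/gCDW

    def __post_init__(self):
        if not (6.0 <= self.ph <= 9.0):
            raise ThermoError(f"pH {self.ph} outside the supported 6..9 range")
        if self.cell_volume <= 0:
            raise ThermoError("cell volume must be positive")

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature


@dataclass
class ConcentrationRange:
    metabolite: str
    lower: float  # mM
    upper: float  # mM
    source: str = "default"

    def __post_init__(self):
        if not (0 < self.lower <= self.upper):
            raise ThermoError(
                f"{self.metabolite}: need 0 < lower <= upper, got [{self.lower}, {self.upper}]")


def to_molar(pool_umol_gcdw: float, volume_ml_gcdw: float = 1.7) -> float:
    """umol/gCDW -> mM via the specific cell volume (umol/ml = mM)."""
    if pool_umol_gcdw <= 0:
        raise ThermoError("pool size must be positive")
    if volume_ml_gcdw <= 0:
        raise ThermoError("cell volume must be positive")
    return pool_umol_gcdw / volume_ml_gcdw


def from_molar(conc_mm: float, volume_ml_gcdw: float = 1.7) -> float:
    if conc_mm <= 0:
        raise ThermoError("concentration must be positive")
    return conc_mm * volume_ml_gcdw


def mass_action_ratio(reaction: ThermoReaction, concentrations_mm: dict[str, float]) -> float:
    """Q = prod(products^nu) / prod(substrates^nu) at 1 M standard state."""
    log_q = 0.0
    for met, nu in reaction.stoich.items():
        c = concentrations_mm.get(met)
        if c is None:
            raise ThermoError(f"{reaction.id}: missing concentration for {met}")
        if c <= 0:
            raise ThermoError(f"{reaction.id}: non-positive concentration for {met}")
        log_q += nu * np.log(c / 1000.0)
    return float(np.exp(log_q))


def reaction_gibbs(model: ThermoModel, reaction: ThermoReaction | str,
                   concentrations_mm: dict[str, float]) -> float:
    """Delta_rG' = Delta_rG'0 + RT ln Q in kJ/mol."""
    rxn = model.reactions[reaction] if isinstance(reaction, str) else reaction
    q = mass_action_ratio(rxn, concentrations_mm)
    return float(rxn.dgr0 + model.rt * np.log(q))


def student_t_range(mean: float, sd: float, n: int,
                    confidence: float = 0.80) -> tuple[float, float]:
    """mean +/- t_{(1+c)/2, n-1} * sd / sqrt(n)."""
    if n < 2:
        raise ThermoError("at least two replicates required for a t interval")
    if sd < 0:
        raise ThermoError("sd must be non-negative")
    half = float(t_dist.ppf((1.0 + confidence) / 2.0, n - 1)) * sd / np.sqrt(n)
    return mean - half, mean + half


def ranges_from_table(table, model: ThermoModel, confidence: float = 0.80,
                      floor_mm: float = 1e-6) -> dict[str, ConcentrationRange]:
    """Measured (mean umol/gCDW, sd, n) rows -> mM ranges via t intervals."""
    out = {}
    for row in table.itertuples(index=False):
        lo, hi = student_t_range(row.mean, row.sd, int(row.n), confidence)
        lo_mm = max(to_molar(max(lo, floor_mm), model.cell_volume), floor_mm)
        hi_mm = to_molar(max(hi, floor_mm), model.cell_volume)
        out[row.metabolite] = ConcentrationRange(row.metabolite, lo_mm, max(lo_mm, hi_mm),
                                                 source="measured")
    return out


# ---------------------------------------------------------------------------
# the NET linear program
# ---------------------------------------------------------------------------

EPS_KJ = 1e-6  # strict second-law inequality margin


@dataclass
class NetResult:
    feasible: bool
    ranges: dict[str, ConcentrationRange]
    violated: list[str] = field(default_factory=list)
    gibbs_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def report(self) -> str:
        lines = [f"NET analysis: {'feasible' if self.feasible else 'INFEASIBLE'}"]
        if self.violated:
            lines.append("second-law violations involve: " + ", ".join(self.violated))
        for met, rng in sorted(self.ranges.items()):
            lines.append(f"  {met}: [{rng.lower:.4g}, {rng.upper:.4g}] mM ({rng.source})")
        for rid, (lo, hi) in sorted(self.gibbs_ranges.items()):
            lines.append(f"  DrG'({rid}) in [{lo:.2f}, {hi:.2f}] kJ/mol")
        return "\n".join(lines)


class _NetLP:
    def __init__(self, model: ThermoModel, directions: dict[str, float],
                 ranges: dict[str, ConcentrationRange]):
        self.model = model
        self.directed = [(rid, np.sign(d)) for rid, d in directions.items() if d != 0]
        for rid, _ in self.directed:
            if rid not in model.reactions:
                raise ThermoError(f"no Delta_rG'0 for directed reaction {rid}")
        mets = sorted({m for rid, _ in self.directed
                       for m in model.reactions[rid].stoich} | set(ranges))
        self.mets = mets
        self.idx = {m: i for i, m in enumerate(mets)}
        for rid, _ in self.directed:
            for m in model.reactions[rid].stoich:
                if m not in ranges:
                    raise ThermoError(f"{rid}: no concentration range for {m}")
        self.bounds = [(np.log(ranges[m].lower / 1000.0), np.log(ranges[m].upper / 1000.0))
                       for m in mets]
        rows, rhs = [], []
        rt = model.rt
        for rid, sign in self.directed:
            rxn = model.reactions[rid]
            row = np.zeros(len(mets))
            for m, nu in rxn.stoich.items():
                row[self.idx[m]] = sign * rt * nu
            rows.append(row)
            rhs.append(-sign * rxn.dgr0 - EPS_KJ)
        self.A_ub = np.array(rows) if rows else np.zeros((0, len(mets)))
        self.b_ub = np.array(rhs)

    def solve(self, c: np.ndarray):
        return linprog(c, A_ub=self.A_ub, b_ub=self.b_ub, bounds=self.bounds,
                       method="highs")

    def diagnose(self) -> list[str]:
        """Minimum-slack LP: reactions needing slack are the violated set."""
        n, m = len(self.mets), self.A_ub.shape[0]
        c = np.concatenate([np.zeros(n), np.ones(m)])
        A = np.hstack([self.A_ub, -np.eye(m)])
        bounds = self.bounds + [(0, None)] * m
        res = linprog(c, A_ub=A, b_ub=self.b_ub, bounds=bounds, method="highs")
        if not res.success:
            return [rid for rid, _ in self.directed]
        slack = res.x[n:]
        return [rid for (rid, _), s in zip(self.directed, slack) if s > 1e-7]


def net_feasibility(model: ThermoModel, directions: dict[str, float],
                    ranges: dict[str, ConcentrationRange]) -> NetResult:
    """Tighten concentration ranges under second-law constraints.

    Solves min/max ln c for every metabolite subject to Delta_rG' < 0 for
    all nonzero-direction reactions; infeasible systems return the set of
    constraints that cannot be satisfied together.  Also reports the
    attainable Delta_rG' interval per directed reaction.
    """
    lp = _NetLP(model, directions, ranges)
    probe = lp.solve(np.zeros(len(lp.mets)))
    if probe.status == 2:
        return NetResult(False, dict(ranges), violated=lp.diagnose())
    if not probe.success:
        raise ThermoError(f"NET LP failed: {probe.message}")

    tightened = {}
    for m in lp.mets:
        c = np.zeros(len(lp.mets))
        c[lp.idx[m]] = 1.0
        lo = lp.solve(c)
        hi = lp.solve(-c)
        if not (lo.success and hi.success):
            raise ThermoError(f"range LP failed for {m}")
        lo_mm = float(np.exp(lo.x[lp.idx[m]]) * 1000.0)
        hi_mm = float(np.exp(hi.x[lp.idx[m]]) * 1000.0)
        src = ranges[m].source if m in ranges else "default"
        tightened[m] = ConcentrationRange(m, min(lo_mm, hi_mm), max(lo_mm, hi_mm), src)

    gibbs = {}
    rt = model.rt
    for rid, sign in lp.directed:
        rxn = model.reactions[rid]
        c = np.zeros(len(lp.mets))
        for met, nu in rxn.stoich.items():
            c[lp.idx[met]] = rt * nu
        lo = lp.solve(c)
        hi = lp.solve(-c)
        gibbs[rid] = (float(rxn.dgr0 + lo.fun), float(rxn.dgr0 - hi.fun))
    return NetResult(True, tightened, gibbs_ranges=gibbs)


@dataclass
class CofactorRatioResult:
    couple: tuple[str, str]
    min_ratio: float | None
    unbounded: bool = False


def min_cofactor_ratio(model: ThermoModel, directions: dict[str, float],
                       ranges: dict[str, ConcentrationRange],
                       couple: tuple[str, str] = ("NAD", "NADH")) -> CofactorRatioResult:
    """Smallest feasible oxidised/reduced concentration ratio.

    Minimises ln c_ox - ln c_red under the NET constraints.  If neither
    species of the couple appears in any directed reaction or bound, the
    ratio is unconstrained and reported as unbounded.
    """
    ox, red = couple
    coupled = any(ox in model.reactions[rid].stoich or red in model.reactions[rid].stoich
                  for rid, d in directions.items() if d != 0)
    if not coupled:
        return CofactorRatioResult(couple, None, unbounded=True)
    work = dict(ranges)
    for species in couple:
        if species not in work:
            work[species] = ConcentrationRange(species, 1e-9, 1e9)  # effectively free
    lp = _NetLP(model, directions, work)
    c = np.zeros(len(lp.mets))
    c[lp.idx[ox]] = 1.0
    c[lp.idx[red]] = -1.0
    res = lp.solve(c)
    if res.status == 3:
        return CofactorRatioResult(couple, None, unbounded=True)
    if res.status == 2:
        raise ThermoError("NET constraints infeasible; run net_feasibility for diagnosis")
    if not res.success:
        raise ThermoError(f"cofactor ratio LP failed: {res.message}")
    return CofactorRatioResult(couple, float(np.exp(res.fun)))
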