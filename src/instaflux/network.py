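"""Atom-transition metabolic networks, stoichiometry and flux constraints.

A network is defined in a plain-text format, one reaction per line::

    # comment
    @external Glcx CO2x
    @balance_only CO2
    upt: Glcx(abcdef) -> Glc(abcdef)
    pgi: Glc6P(abcdef) <-> Fru6P(abcdef)
    scramble: SUCC(abcd) -> FUM(abcd) | FUM(dcba)

Each species instance carries a letter string naming its carbon atoms;
letters map substrate carbons to product carbons and must be bijective.
``<->`` marks a reversible reaction (net + exchange flux).  Alternative
right-hand sides separated by ``|`` are equally weighted atom-map variants
(scrambling at a symmetric product).  ``@external`` species are feed/sink
terminals excluded from balancing and from the metabolite tally;
``@balance_only`` species (CO2) are balanced stoichiometrically but carry
no labelling state or pool size.

Reversible reactions are counted as two fluxes (forward and backward) in
``MetabolicNetwork.n_reactions``, the convention used when central-carbon
models are reported "including bidirectional fluxes".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.linalg import null_space, qr


class NetworkError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    n_carbons: int
    measured_pool: float | None = None  # umol/gCDW
    is_boundary: bool = False           # feed/sink, excluded from balancing
    balance_only: bool = False          # balanced but no labelling state
    external: bool = False              # declared feed/sink terminal

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkError(f"{self.id}: negative carbon count")
        if self.is_boundary and self.measured_pool is not None:
            raise NetworkError(f"{self.id}: boundary metabolite cannot carry a pool size")


@dataclass(frozen=True)
class SpeciesTerm:
    """One species instance in a reaction with its carbon letters."""
    met: str
    atoms: str  # one letter per carbon, '' for carbon-free species


@dataclass
class AtomTransition:
    """One atom-map variant: substrate letters -> product letters, bijective."""
    substrates: tuple[SpeciesTerm, ...]
    products: tuple[SpeciesTerm, ...]
    weight: float = 1.0

    def reversed(self) -> "AtomTransition":
        return AtomTransition(self.products, self.substrates, self.weight)


@dataclass
class Reaction:
    id: str
    substrates: tuple[SpeciesTerm, ...]
    products: tuple[SpeciesTerm, ...]   # of the first (canonical) variant
    reversible: bool
    transitions: list[AtomTransition] = field(default_factory=list)

    def stoichiometry(self) -> dict[str, float]:
        """Net stoichiometric coefficients, substrates negative."""
        coeffs: dict[str, float] = {}
        for t in self.substrates:
            coeffs[t.met] = coeffs.get(t.met, 0.0) - 1.0
        for t in self.products:
            coeffs[t.met] = coeffs.get(t.met, 0.0) + 1.0
        return coeffs


@dataclass
class FluxDistribution:
    """Net (signed) and exchange (>= 0) fluxes, mmol/gCDW/h."""
    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def forward(self, rid: str) -> float:
        v, ex = self.net[rid], self.exchange.get(rid, 0.0)
        return max(v, 0.0) + ex

    def backward(self, rid: str) -> float:
        v, ex = self.net[rid], self.exchange.get(rid, 0.0)
        return max(-v, 0.0) + ex

    def validate(self, network: "MetabolicNetwork") -> None:
        for rxn in network.reactions:
            if rxn.id not in self.net:
                raise NetworkError(f"missing net flux for {rxn.id}")
            ex = self.exchange.get(rxn.id, 0.0)
            if ex < 0:
                raise NetworkError(f"{rxn.id}: exchange flux must be >= 0")
            if not rxn.reversible:
                if ex != 0:
                    raise NetworkError(f"{rxn.id}: irreversible reaction with exchange flux")
                if self.net[rxn.id] < -1e-9:
                    raise NetworkError(f"{rxn.id}: irreversible reaction with negative net flux")


_TERM_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*(?:\(([A-Za-z]*)\))?\s*$")


def _parse_side(text: str, rid: str) -> tuple[SpeciesTerm, ...]:
    terms = []
    for chunk in text.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise NetworkError(f"{rid}: cannot parse species term {chunk!r}")
        terms.append(SpeciesTerm(m.group(1), m.group(2) or ""))
    return tuple(terms)


def _check_transition(rid: str, subs, prods) -> None:
    left = "".join(t.atoms for t in subs)
    right = "".join(t.atoms for t in prods)
    if len(left) != len(right):
        raise NetworkError(
            f"{rid}: carbon count mismatch ({len(left)} substrate vs {len(right)} product carbons)")
    if sorted(left) != sorted(right) or len(set(left)) != len(left) or len(set(right)) != len(right):
        raise NetworkError(f"{rid}: atom map is not a bijection over carbons")


class MetabolicNetwork:
    """Metabolites, reactions, atom maps and the stoichiometric matrix."""

    def __init__(self, species: dict[str, Metabolite], reactions: list[Reaction]):
        self.species = species
        self.reactions = reactions
        self._by_id = {r.id: r for r in reactions}
        self._flag_auto_boundary()

    # -- construction -----------------------------------------------------

    def _flag_auto_boundary(self) -> None:
        """Internal species never produced or never consumed are boundary.

        Reversible reactions produce and consume both sides, so a pure
        buffer pool attached through one reversible reaction stays balanced.
        """
        produced: set[str] = set()
        consumed: set[str] = set()
        for rxn in self.reactions:
            subs = {t.met for t in rxn.substrates}
            prods = {t.met for t in rxn.products}
            consumed |= subs
            produced |= prods
            if rxn.reversible:
                consumed |= prods
                produced |= subs
        for met in self.species.values():
            if met.external:
                met.is_boundary = True
            if met.is_boundary or met.balance_only:
                continue
            if met.id not in produced or met.id not in consumed:
                met.is_boundary = True

    # -- views ------------------------------------------------------------

    @property
    def metabolites(self) -> list[Metabolite]:
        """Carbon-pool metabolites (externals and balance-only species excluded)."""
        return [m for m in self.species.values() if not (m.balance_only or m.external)]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        """Flux count with reversible reactions counted forward + backward."""
        return len(self.reactions) + sum(r.reversible for r in self.reactions)

    def reaction(self, rid: str) -> Reaction:
        return self._by_id[rid]

    @property
    def balanced_ids(self) -> list[str]:
        return [m.id for m in self.species.values() if not m.is_boundary]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """S over balanced species (rows) x net fluxes (columns)."""
        rows = self.balanced_ids
        idx = {m: i for i, m in enumerate(rows)}
        cols = [r.id for r in self.reactions]
        S = np.zeros((len(rows), len(cols)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry().items():
                if met in idx:
                    S[idx[met], j] += coeff
        return S, rows, cols

    def set_pools(self, pools: dict[str, float], measured: set[str] | None = None) -> None:
        for mid, value in pools.items():
            met = self.species[mid]
            if met.is_boundary:
                raise NetworkError(f"{mid}: boundary metabolite cannot carry a pool size")
            met.measured_pool = float(value)
        self.measured_pool_ids = set(measured) if measured is not None else set(pools)


def parse_network(text: str) -> MetabolicNetwork:
    """Parse a network definition; validates carbon balance and atom maps."""
    external: dict[str, bool] = {}
    balance_only: set[str] = set()
    reactions: list[Reaction] = []
    carbons: dict[str, int] = {}
    seen: set[str] = set()

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@external"):
            for name in line.split()[1:]:
                external[name] = True
            continue
        if line.startswith("@balance_only"):
            balance_only.update(line.split()[1:])
            continue
        if ":" not in line:
            raise NetworkError(f"cannot parse line: {line!r}")
        rid, body = (s.strip() for s in line.split(":", 1))
        if rid in seen:
            raise NetworkError(f"duplicate reaction id: {rid}")
        seen.add(rid)
        reversible = "<->" in body
        lhs, rhs = re.split(r"<->|->", body, maxsplit=1)
        subs = _parse_side(lhs, rid)
        variants = []
        for alt in rhs.split("|"):
            prods = _parse_side(alt, rid)
            _check_transition(rid, subs, prods)
            variants.append(prods)
        w = 1.0 / len(variants)
        transitions = [AtomTransition(subs, prods, w) for prods in variants]
        for term in list(subs) + [t for v in variants for t in v]:
            n = len(term.atoms)
            if term.met in carbons and carbons[term.met] != n:
                # external sinks (e.g. a biomass drain) accept any fragment
                if term.met not in external:
                    raise NetworkError(
                        f"{rid}: {term.met} used with {n} carbons, previously {carbons[term.met]}")
            else:
                carbons[term.met] = n
        reactions.append(Reaction(rid, subs, variants[0], reversible, transitions))

    species = {}
    for name, n in carbons.items():
        species[name] = Metabolite(name, n, is_boundary=external.get(name, False),
                                   balance_only=name in balance_only,
                                   external=external.get(name, False))
    for name in external:
        if name not in species:
            raise NetworkError(f"@external species {name} never used")
    return MetabolicNetwork(species, reactions)


# ---------------------------------------------------------------------------
# constraints and free-flux basis
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Fixed net fluxes and equality ties between net fluxes."""
    fixed: dict[str, float] = field(default_factory=dict)
    ties: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixed) + len(self.ties)

    @classmethod
    def from_yaml(cls, text: str) -> "ConstraintSet":
        data = yaml.safe_load(text) or {}
        fixed, ties = {}, []
        for key, value in data.items():
            if isinstance(value, str):
                m = re.match(r"^\s*==\s*([A-Za-z_][A-Za-z0-9_]*)\s*$", value)
                if not m:
                    raise NetworkError(f"cannot parse constraint {key}: {value!r}")
                ties.append((key, m.group(1)))
            else:
                fixed[key] = float(value)
        return cls(fixed, ties)


@dataclass
class FluxBasis:
    """Free coordinates spanning the constrained steady-state flux space."""
    network: MetabolicNetwork
    free_net_ids: list[str]
    exchange_ids: list[str]
    _cols: list[str]
    _particular: np.ndarray
    _null: np.ndarray

    @property
    def n_free(self) -> int:
        return len(self.free_net_ids) + len(self.exchange_ids)

    def complete(self, free_net: dict[str, float],
                 exchange: dict[str, float] | None = None) -> FluxDistribution:
        """Unique full flux distribution from values of the free coordinates."""
        if set(free_net) != set(self.free_net_ids):
            raise NetworkError(f"free fluxes required: {sorted(self.free_net_ids)}")
        col_idx = {c: i for i, c in enumerate(self._cols)}
        rows = [col_idx[r] for r in self.free_net_ids]
        Nf = self._null[rows, :]
        rhs = np.array([free_net[r] for r in self.free_net_ids]) - self._particular[rows]
        alpha = np.linalg.solve(Nf, rhs)
        v = self._particular + self._null @ alpha
        exchange = dict(exchange or {})
        for rid in self.exchange_ids:
            exchange.setdefault(rid, 0.0)
        return FluxDistribution({c: float(v[i]) for i, c in enumerate(self._cols)}, exchange)


def free_flux_basis(network: MetabolicNetwork, constraints: ConstraintSet) -> FluxBasis:
    """Free flux ids + completion map for S.v = 0 plus the constraint set.

    The basis dimension is dim null(S) minus the number of independent
    constraints; exchange fluxes of reversible reactions are additional free
    coordinates on top of the net-flux basis.
    """
    S, _, cols = network.stoichiometric_matrix()
    col_idx = {c: i for i, c in enumerate(cols)}
    n = len(cols)
    crows, rhs = [], []
    for rid, value in constraints.fixed.items():
        row = np.zeros(n)
        row[col_idx[rid]] = 1.0
        crows.append(row)
        rhs.append(value)
    for a, b in constraints.ties:
        row = np.zeros(n)
        row[col_idx[a]] = 1.0
        row[col_idx[b]] = -1.0
        crows.append(row)
        rhs.append(0.0)
    A = np.vstack([S] + crows) if crows else S.copy()
    b = np.concatenate([np.zeros(S.shape[0]), np.array(rhs)])

    rank_A = np.linalg.matrix_rank(A)
    rank_aug = np.linalg.matrix_rank(np.column_stack([A, b]))
    if rank_aug > rank_A:
        raise NetworkError("constraints are inconsistent with S.v = 0 (no solution)")
    particular, *_ = np.linalg.lstsq(A, b, rcond=None)
    N = null_space(A)
    k = N.shape[1]
    if k == 0:
        free_ids = []
    else:
        # pick k flux rows of N forming a well-conditioned square block
        _, _, piv = qr(N.T, pivoting=True)
        free_ids = [cols[i] for i in sorted(piv[:k])]
    exchange_ids = [r.id for r in network.reactions if r.reversible]
    return FluxBasis(network, free_ids, exchange_ids, cols, particular, N)


def validate_steady_state(network: MetabolicNetwork, fluxes: FluxDistribution,
                          tol: float = 1e-6) -> float:
    """Max absolute metabolite imbalance of S.v_net; <= tol means balanced."""
    S, _, cols = network.stoichiometric_matrix()
    try:
        v = np.array([fluxes.net[c] for c in cols])
    except KeyError as exc:
        raise NetworkError(f"missing flux value for reaction {exc.args[0]}") from None
    resid = S @ v
    return float(np.max(np.abs(resid))) if resid.size else 0.0
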