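"""EMU decomposition and mass-isotopomer simulation.

An elementary metabolite unit (EMU) is a subset of a metabolite's carbons
whose mass-isotopomer distribution (MID) can be balanced independently of
the rest of the molecule.  Starting from the measured fragments, the
decomposition traces each EMU back through the atom maps to the feed
substrates, recording condensation reactions as convolution sources.  The
resulting balance for EMU ``e`` hosted by a pool of size ``c`` (umol/gCDW)
is

    c * dx_e/dt = sum_j f_j * (x_src(j) - x_e)

with ``f_j`` the flux (mmol/gCDW/h) of the j-th producing term and
``x_src(j)`` the MID of its source (a feed MID, another EMU, or the
convolution of several EMUs).  Because fluxes are stationary, outflow at
pool composition balances inflow and no explicit dilution term is needed.

The instationary solver integrates the full cascade with a stiff BDF
method; the stationary solver solves the same balances size by size as
linear systems and equals the long-time limit of the transient solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .network import FluxDistribution, MetabolicNetwork, NetworkError


class LabelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """A detected fragment: metabolite, 1-based carbon positions, ion formula."""
    id: str
    metabolite: str
    positions: tuple[int, ...]
    formula: str | None = None

    def __post_init__(self):
        if len(set(self.positions)) != len(self.positions) or not self.positions:
            raise LabelingError(f"{self.id}: positions must be non-empty and unique")

    @property
    def size(self) -> int:
        return len(self.positions)


class FeedLabeling:
    """Positional isotopomer composition of the feed substrates.

    ``patterns`` maps a substrate id to ``[(pattern, fraction), ...]`` where
    a pattern is a string of 0/1 per carbon ('1' = 13C).  Substrates absent
    from the map are taken as unlabelled.
    """

    def __init__(self, patterns: dict[str, list[tuple[str, float]]]):
        for met, entries in patterns.items():
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-9:
                raise LabelingError(f"{met}: feed fractions sum to {total}, not 1")
            sizes = {len(p) for p, _ in entries}
            if len(sizes) != 1:
                raise LabelingError(f"{met}: inconsistent pattern lengths")
        self.patterns = {m: list(v) for m, v in patterns.items()}

    def mid(self, met: str, positions: tuple[int, ...]) -> np.ndarray:
        """MID of the EMU of `met` restricted to `positions` (1-based)."""
        k = len(positions)
        out = np.zeros(k + 1)
        if met not in self.patterns:
            out[0] = 1.0
            return out
        for pattern, frac in self.patterns[met]:
            weight = sum(int(pattern[p - 1]) for p in positions)
            out[weight] += frac
        return out

    @classmethod
    def glucose_methanol(cls, glc: str = "Glcx", metoh: str = "Metohx",
                         f_1_13c: float = 0.80, f_u_13c: float = 0.20) -> "FeedLabeling":
        """The study's feed: glucose 80% [1-13C1] + 20% [U-13C6], methanol 100% 13C."""
        return cls({glc: [("100000", f_1_13c), ("111111", f_u_13c)],
                    metoh: [("1", 1.0)]})


@dataclass
class MIDTimeSeries:
    """Mass-isotopomer fractions of one fragment over time.

    ``mids`` has shape (n_times, k+1); ``sigma`` matches or is None.
    """
    fragment_id: str
    times: np.ndarray
    mids: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mids = np.asarray(self.mids, dtype=float)
        if self.times.ndim != 1 or self.mids.shape[0] != self.times.size:
            raise LabelingError(f"{self.fragment_id}: shape mismatch")
        if np.any(np.diff(self.times) <= 0) or (self.times.size and self.times[0] < 0):
            raise LabelingError(f"{self.fragment_id}: times must be strictly increasing, >= 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise LabelingError(f"{self.fragment_id}: sigma must be positive")


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

EmuKey = tuple[str, tuple[int, ...]]  # (metabolite, sorted positions)


@dataclass
class _Term:
    """One producing term of an internal EMU."""
    rid: str
    forward: bool
    weight: float
    sources: list  # entries: ("emu", EmuKey) | ("const", np.ndarray key into feeds)
    # resolved at simulation time


@dataclass
class LabelingSystem:
    """Minimal EMU system for a set of target fragments."""
    network: MetabolicNetwork
    targets: list[FragmentSpec]
    emus: list[EmuKey]                      # internal EMUs, sorted by size
    terms: dict[EmuKey, list[_Term]]
    feed_emus: list[EmuKey]                 # terminal EMUs on external/balance-only species
    target_emu: dict[str, EmuKey] = field(default_factory=dict)

    @property
    def n_state(self) -> int:
        return sum(len(p) + 1 for _, p in self.emus)

    def state_slices(self) -> dict[EmuKey, slice]:
        out, offset = {}, 0
        for key in self.emus:
            n = len(key[1]) + 1
            out[key] = slice(offset, offset + n)
            offset += n
        return out


def decompose(network: MetabolicNetwork, targets: list[FragmentSpec]) -> LabelingSystem:
    """Trace the target fragments back to the feed, collecting the minimal
    EMU set; condensation reactions become convolution sources."""
    species = network.species
    for frag in targets:
        met = species.get(frag.metabolite)
        if met is None:
            raise LabelingError(f"{frag.id}: unknown metabolite {frag.metabolite}")
        if any(p < 1 or p > met.n_carbons for p in frag.positions):
            raise LabelingError(f"{frag.id}: positions outside 1..{met.n_carbons}")

    def is_terminal(met_id: str) -> bool:
        m = species[met_id]
        return m.is_boundary or m.balance_only

    # producing (reaction, direction, transition) tuples per metabolite
    producers: dict[str, list] = {}
    for rxn in network.reactions:
        for tr in rxn.transitions:
            # one entry per transition even if it yields the metabolite twice;
            # product instances are expanded during tracing
            for met in {term.met for term in tr.products}:
                producers.setdefault(met, []).append((rxn.id, True, tr))
            if rxn.reversible:
                rt = tr.reversed()
                for met in {term.met for term in rt.products}:
                    producers.setdefault(met, []).append((rxn.id, False, rt))

    terms: dict[EmuKey, list[_Term]] = {}
    feed_emus: set[EmuKey] = set()
    target_emu: dict[str, EmuKey] = {}
    stack: list[EmuKey] = []
    for frag in targets:
        key = (frag.metabolite, tuple(sorted(frag.positions)))
        target_emu[frag.id] = key
        met = species[frag.metabolite]
        if is_terminal(frag.metabolite):
            if met.is_boundary and not (met.external or met.balance_only):
                raise LabelingError(
                    f"{frag.id}: {frag.metabolite} is disconnected from the feed "
                    "(internal metabolite without producing reactions)")
            feed_emus.add(key)
        elif key not in terms:
            terms[key] = []
            stack.append(key)

    while stack:
        met_id, positions = key = stack.pop()
        produced = producers.get(met_id, [])
        if not produced:
            raise LabelingError(
                f"EMU {met_id}{list(positions)} has no producing reaction: "
                "metabolite is disconnected from the feed")
        for rid, fwd, tr in produced:
            # a transition may yield the metabolite more than once (instances)
            for inst in [t for t in tr.products if t.met == met_id]:
                letters = [inst.atoms[p - 1] for p in positions]
                # locate each letter in the substrate instances
                per_sub: dict[int, list[int]] = {}
                for letter in letters:
                    for si, sub in enumerate(tr.substrates):
                        pos = sub.atoms.find(letter)
                        if pos >= 0:
                            per_sub.setdefault(si, []).append(pos + 1)
                            break
                    else:  # pragma: no cover - parser guarantees bijectivity
                        raise LabelingError(f"{rid}: unmapped atom {letter}")
                sources = []
                for si, subpos in sorted(per_sub.items()):
                    sub = tr.substrates[si]
                    skey = (sub.met, tuple(sorted(subpos)))
                    if is_terminal(sub.met):
                        sources.append(("const", skey))
                        feed_emus.add(skey)
                    else:
                        sources.append(("emu", skey))
                        if skey not in terms:
                            terms[skey] = []
                            stack.append(skey)
                terms[key].append(_Term(rid, fwd, tr.weight, sources))

    emus = sorted(terms, key=lambda k: (len(k[1]), k))
    return LabelingSystem(network, list(targets), emus, terms, sorted(feed_emus),
                          target_emu)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _term_fluxes(system: LabelingSystem, fluxes: FluxDistribution) -> dict[EmuKey, list[float]]:
    out = {}
    for key, tlist in system.terms.items():
        vals = []
        for t in tlist:
            f = fluxes.forward(t.rid) if t.forward else fluxes.backward(t.rid)
            vals.append(f * t.weight)
        out[key] = vals
    return out


def _feed_mids(system: LabelingSystem, feed: FeedLabeling) -> dict[EmuKey, np.ndarray]:
    mids = {}
    for met, positions in system.feed_emus:
        if system.network.species[met].balance_only:
            mid = np.zeros(len(positions) + 1)
            mid[0] = 1.0  # stoichiometry-only species (CO2) treated as unlabelled
        else:
            mid = feed.mid(met, positions)
        mids[(met, positions)] = mid
    return mids


def _check_pools(system: LabelingSystem, pools: dict[str, float]) -> None:
    for met_id, _ in system.emus:
        c = pools.get(met_id)
        if c is None or c <= 0:
            raise LabelingError(f"{met_id}: positive pool size required for labelling balance")


def _source_mid(src, x: dict[EmuKey, np.ndarray], feeds) -> np.ndarray:
    kind, skey = src
    return feeds[skey] if kind == "const" else x[skey]


def _combined_source(sources, x, feeds) -> np.ndarray:
    mid = _source_mid(sources[0], x, feeds)
    for src in sources[1:]:
        mid = np.convolve(mid, _source_mid(src, x, feeds))
    return mid


def simulate_inst(system: LabelingSystem, fluxes: FluxDistribution,
                  pools: dict[str, float], feed: FeedLabeling,
                  times: np.ndarray, init: np.ndarray | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10) -> dict[str, MIDTimeSeries]:
    """Integrate the instationary EMU cascade and return target fragment MIDs.

    `pools` in umol/gCDW, fluxes in mmol/gCDW/h, times in h.  The default
    initial state is fully unlabelled (all m+0), matching abundance-corrected
    measurements at the feed switch.
    """
    times = np.asarray(times, dtype=float)
    _check_pools(system, pools)
    feeds = _feed_mids(system, feed)
    fvals = _term_fluxes(system, fluxes)
    slices = system.state_slices()
    n = system.n_state

    inv_pool = {}
    total_in = {}
    for key in system.emus:
        met_id = key[0]
        inv_pool[key] = 1000.0 / pools[met_id]  # umol -> mmol conversion
        total_in[key] = sum(fvals[key])

    if init is None:
        x0 = np.zeros(n)
        for key in system.emus:
            x0[slices[key].start] = 1.0
    else:
        x0 = np.asarray(init, dtype=float)

    def rhs(_t, y):
        x = {key: y[slices[key]] for key in system.emus}
        dy = np.empty_like(y)
        for key in system.emus:
            acc = -total_in[key] * x[key]
            for t, f in zip(system.terms[key], fvals[key]):
                if f == 0.0:
                    continue
                acc = acc + f * _combined_source(t.sources, x, feeds)
            dy[slices[key]] = acc * inv_pool[key]
        return dy

    sparsity = lil_matrix((n, n))
    for key in system.emus:
        sl = slices[key]
        sparsity[sl, sl] = 1
        for t in system.terms[key]:
            for kind, skey in t.sources:
                if kind == "emu":
                    sparsity[sl, slices[skey]] = 1

    t_span = (0.0, float(times[-1]))
    sol = solve_ivp(rhs, t_span, x0, method="BDF", t_eval=times,
                    rtol=rtol, atol=atol, jac_sparsity=sparsity.tocsr())
    if not sol.success:
        detail = ", ".join(
            f"{m}={pools[m]:.3g}" for m, _ in system.emus[:5])
        raise LabelingError(
            f"stiff integration failed: {sol.message} (pools e.g. {detail}; "
            f"check for vanishing pools or unbalanced fluxes)")

    out = {}
    for frag in system.targets:
        key = system.target_emu[frag.id]
        if key in slices:
            mids = sol.y[slices[key], :].T
        else:  # fragment sits on a feed species
            mids = np.tile(feeds[key], (times.size, 1))
        sums = mids.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise LabelingError(f"{frag.id}: simulated MID drifted from sum 1")
        out[frag.id] = MIDTimeSeries(frag.id, times, mids / sums[:, None])
    return out


def simulate_steady(system: LabelingSystem, fluxes: FluxDistribution,
                    feed: FeedLabeling) -> dict[str, np.ndarray]:
    """Isotopically stationary MIDs: solve the algebraic balances size by size."""
    feeds = _feed_mids(system, feed)
    fvals = _term_fluxes(system, fluxes)
    solved: dict[EmuKey, np.ndarray] = {}

    by_size: dict[int, list[EmuKey]] = {}
    for key in system.emus:
        by_size.setdefault(len(key[1]), []).append(key)

    for size in sorted(by_size):
        block = by_size[size]
        idx = {key: i for i, key in enumerate(block)}
        m = len(block)
        A = np.zeros((m, m))
        B = np.zeros((m, size + 1))
        for key in block:
            i = idx[key]
            A[i, i] = sum(fvals[key])
            for t, f in zip(system.terms[key], fvals[key]):
                if f == 0.0:
                    continue
                if len(t.sources) == 1 and t.sources[0][0] == "emu" \
                        and len(t.sources[0][1][1]) == size:
                    A[i, idx[t.sources[0][1]]] -= f
                else:
                    B[i] += f * _combined_source(t.sources, solved, feeds)
        if m and (np.linalg.matrix_rank(A) < m or not np.all(np.diag(A) > 0)):
            bad = [k for k in block if sum(fvals[k]) == 0]
            raise LabelingError(
                f"singular labelling balance at EMU size {size}: "
                f"flux-disconnected EMUs {bad or block}")
        X = np.linalg.solve(A, B) if m else B
        for key in block:
            solved[key] = X[idx[key]]

    out = {}
    for frag in system.targets:
        key = system.target_emu[frag.id]
        mid = solved[key] if key in solved else feeds[key]
        out[frag.id] = mid / mid.sum()
    return out
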