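"""Brute-force positional-isotopomer reference simulator.

Enumerates every positional isotopomer (2**n states per n-carbon pool) and
integrates the full isotopomer balance ODEs directly from the atom maps,
with no EMU reduction.  Exponential in network size, so only usable on
small test networks (roughly <= 12 internal carbons), where it provides an
independent oracle for the EMU cascade: both make the same assumptions
(well-mixed pools, stationary fluxes, independent substrate pools) but
share no code path or variable reduction.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .emu import FeedLabeling, FragmentSpec, LabelingError
from .network import FluxDistribution, MetabolicNetwork


def _is_terminal(network: MetabolicNetwork, met_id: str) -> bool:
    m = network.species[met_id]
    return m.is_boundary or m.balance_only


def _terminal_dist(network: MetabolicNetwork, met_id: str, feed: FeedLabeling) -> np.ndarray:
    n = network.species[met_id].n_carbons
    dist = np.zeros(2 ** n)
    if network.species[met_id].balance_only or met_id not in feed.patterns:
        dist[0] = 1.0
        return dist
    for pattern, frac in feed.patterns[met_id]:
        idx = sum((1 << (p - 1)) for p in range(1, n + 1) if pattern[p - 1] == "1")
        dist[idx] += frac
    return dist


def simulate_isotopomers(network: MetabolicNetwork, fluxes: FluxDistribution,
                         pools: dict[str, float], feed: FeedLabeling,
                         times: np.ndarray, fragments: list[FragmentSpec],
                         rtol: float = 1e-9, atol: float = 1e-11) -> dict[str, np.ndarray]:
    """Fragment MIDs over `times` from the full isotopomer ODE system.

    Returns {fragment_id: array (n_times, k+1)}; initial state unlabelled.
    """
    times = np.asarray(times, dtype=float)
    internal = [m.id for m in network.species.values()
                if not (m.is_boundary or m.balance_only)]
    sizes = {m: network.species[m].n_carbons for m in internal}
    total_c = sum(sizes.values())
    if total_c > 14:
        raise LabelingError(f"oracle limited to small networks ({total_c} carbons)")
    offsets, off = {}, 0
    for m in internal:
        offsets[m] = off
        off += 2 ** sizes[m]
    n_state = off

    # precompile production operators: (flux_value, substrate ids, joint->product map)
    ops: list[tuple[float, list[str], dict[str, np.ndarray], int]] = []
    terminal_cache: dict[str, np.ndarray] = {}
    for rxn in network.reactions:
        for forward in (True, False):
            if not forward and not rxn.reversible:
                continue
            f_dir = fluxes.forward(rxn.id) if forward else fluxes.backward(rxn.id)
            if f_dir == 0.0:
                continue
            for tr in rxn.transitions:
                t = tr if forward else tr.reversed()
                sub_ids = [s.met for s in t.substrates]
                joint_size = int(np.prod([2 ** len(s.atoms) for s in t.substrates]))
                # bit position of each letter within the joint index
                letter_bit: dict[str, int] = {}
                shift = 0
                for s in t.substrates:
                    for i, letter in enumerate(s.atoms):
                        letter_bit[letter] = shift + i
                    shift += len(s.atoms)
                joint = np.arange(joint_size)
                maps: dict[str, np.ndarray] = {}
                for inst_no, prod in enumerate(t.products):
                    if _is_terminal(network, prod.met):
                        continue
                    pmap = np.zeros(joint_size, dtype=np.int64)
                    for i, letter in enumerate(prod.atoms):
                        pmap |= ((joint >> letter_bit[letter]) & 1) << i
                    maps[f"{prod.met}#{inst_no}"] = pmap
                if maps:
                    ops.append((f_dir * t.weight, sub_ids, maps, joint_size))
                for s in t.substrates:
                    if _is_terminal(network, s.met) and s.met not in terminal_cache:
                        terminal_cache[s.met] = _terminal_dist(network, s.met, feed)

    total_in = dict.fromkeys(internal, 0.0)
    for f, _sub, maps, _n in ops:
        for key in maps:
            total_in[key.split("#")[0]] += f

    inv_pool = {}
    for m in internal:
        if total_in[m] == 0.0:
            continue
        c = pools.get(m)
        if c is None or c <= 0:
            raise LabelingError(f"{m}: positive pool size required")
        inv_pool[m] = 1000.0 / c

    def dist_of(met, y):
        if met in terminal_cache:
            return terminal_cache[met]
        sl = slice(offsets[met], offsets[met] + 2 ** sizes[met])
        return y[sl]

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for m in internal:
            if total_in[m]:
                sl = slice(offsets[m], offsets[m] + 2 ** sizes[m])
                dy[sl] = -total_in[m] * y[sl]
        for f, sub_ids, maps, joint_size in ops:
            joint = dist_of(sub_ids[0], y)
            for s in sub_ids[1:]:
                joint = np.kron(dist_of(s, y), joint)  # later substrates in high bits
            for key, pmap in maps.items():
                met = key.split("#")[0]
                sl = slice(offsets[met], offsets[met] + 2 ** sizes[met])
                dy[sl] += f * np.bincount(pmap, weights=joint, minlength=2 ** sizes[met])
        for m in internal:
            if total_in[m]:
                sl = slice(offsets[m], offsets[m] + 2 ** sizes[m])
                dy[sl] *= inv_pool[m]
        return dy

    x0 = np.zeros(n_state)
    for m in internal:
        x0[offsets[m]] = 1.0
    sol = solve_ivp(rhs, (0.0, float(times[-1])), x0, method="BDF",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise LabelingError(f"oracle integration failed: {sol.message}")

    out = {}
    for frag in fragments:
        n = sizes.get(frag.metabolite)
        if n is None:
            dist_t = np.tile(terminal_cache.get(
                frag.metabolite, _terminal_dist(network, frag.metabolite, feed)),
                (times.size, 1))
        else:
            sl = slice(offsets[frag.metabolite], offsets[frag.metabolite] + 2 ** n)
            dist_t = sol.y[sl, :].T
        idx = np.arange(dist_t.shape[1])
        weight = np.zeros_like(idx)
        for p in frag.positions:
            weight += (idx >> (p - 1)) & 1
        mids = np.zeros((times.size, len(frag.positions) + 1))
        for w in range(len(frag.positions) + 1):
            mids[:, w] = dist_t[:, weight == w].sum(axis=1)
        out[frag.id] = mids / mids.sum(axis=1, keepdims=True)
    return out
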