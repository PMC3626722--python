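"""EMU decomposition and isotopomer dynamics, checked against closed forms
and the brute-force positional-isotopomer oracle."""

import numpy as np
import pytest

from instaflux.emu import (FeedLabeling, FragmentSpec, LabelingError, decompose,
                           simulate_inst, simulate_steady)
from instaflux.network import FluxDistribution, parse_network
from instaflux.oracle import simulate_isotopomers

GLC_FEED = FeedLabeling.glucose_methanol()


def _grid(n=8, t_last=3.0):
    return np.concatenate([[0.0], 0.01 * (t_last / 0.01) ** (np.arange(n) / (n - 1))])


class TestDecompose:
    def test_single_pool_single_emu(self):
        net = parse_network("u: Sx(ab) -> A(ab)\no: A(ab) -> Px(ab)\n")
        system = decompose(net, [FragmentSpec("a", "A", (1, 2))])
        assert len(system.emus) == 1

    def test_condensation_becomes_convolution(self):
        net = parse_network(
            "u1: Sx(abc) -> A(abc)\nu2: Tx(abc) -> B(abc)\n"
            "c: A(abc) + B(def) -> F(abcdef)\no: F(abcdef) -> Px(abcdef)\n")
        system = decompose(net, [FragmentSpec("f", "F", (1, 2, 3, 4, 5, 6))])
        term = system.terms[("F", (1, 2, 3, 4, 5, 6))][0]
        assert len(term.sources) == 2  # convolution over two size-3 EMUs

    def test_emu_state_smaller_than_isotopomer_space(self, ppastoris):
        net = ppastoris["network"]
        system = decompose(net, ppastoris["fragments"])
        isotopomer_states = sum(2 ** m.n_carbons for m in net.metabolites)
        assert system.n_state < isotopomer_states

    def test_disconnected_target_raises(self):
        net = parse_network("u: Sx(a) -> A(a)\no: A(a) -> Px(a)\nx: Z(a) -> Qx(a)\n")
        with pytest.raises(LabelingError, match="disconnected|producing"):
            decompose(net, [FragmentSpec("z", "Z", (1,))])


class TestSimulateInst:
    def test_washin_matches_closed_form(self):
        net = parse_network("u: Sx(a) -> A(a)\no: A(a) -> Px(a)\n")
        system = decompose(net, [FragmentSpec("a", "A", (1,))])
        feed = FeedLabeling({"Sx": [("1", 1.0)]})
        times = np.array([0.1, 0.5, 1.0, 2.0, 4.0])
        # v/c = 1/h with c = 1000 umol/gCDW and v = 1 mmol/gCDW/h
        res = simulate_inst(system, FluxDistribution({"u": 1.0, "o": 1.0}),
                            {"A": 1000.0}, feed, times)
        np.testing.assert_allclose(res["a"].mids[:, 1], 1.0 - np.exp(-times),
                                   atol=1e-7)

    def test_initial_state_unlabelled(self, branch_toy):
        times = np.array([0.0, 0.5])
        res = simulate_inst(branch_toy["system"], branch_toy["truth"].fluxes,
                            branch_toy["truth"].pools, branch_toy["feed"], times)
        for ts in res.values():
            assert ts.mids[0, 0] == pytest.approx(1.0, abs=1e-9)
            assert np.all(ts.mids[0, 1:] < 1e-9)

    def test_mids_normalised_at_all_times(self, branch_toy):
        res = simulate_inst(branch_toy["system"], branch_toy["truth"].fluxes,
                            branch_toy["truth"].pools, branch_toy["feed"],
                            branch_toy["times"])
        for ts in res.values():
            np.testing.assert_allclose(ts.mids.sum(axis=1), 1.0, atol=1e-8)

    def test_monotone_washin_and_precursor_ordering(self):
        """Fully labelled feed into an irreversible chain: fractional
        labelling is non-decreasing in time and never exceeds the sole
        precursor's."""
        net = parse_network(
            "u: Sx(ab) -> A(ab)\nr1: A(ab) -> B(ab)\nr2: B(ab) -> C(ab)\n"
            "o: C(ab) -> Px(ab)\n")
        frags = [FragmentSpec(m.lower(), m, (1, 2)) for m in "ABC"]
        system = decompose(net, frags)
        feed = FeedLabeling({"Sx": [("11", 1.0)]})
        fluxes = FluxDistribution({"u": 1.0, "r1": 1.0, "r2": 1.0, "o": 1.0})
        res = simulate_inst(system, fluxes, {"A": 3.0, "B": 5.0, "C": 2.0},
                            feed, _grid())
        label = {f: res[f].mids[:, 2] for f in ("a", "b", "c")}
        for frac in label.values():
            assert np.all(np.diff(frac) >= -1e-9)
        assert np.all(label["b"] <= label["a"] + 1e-9)
        assert np.all(label["c"] <= label["b"] + 1e-9)

    def test_zero_pool_raises(self, branch_toy):
        pools = dict(branch_toy["truth"].pools, B=0.0)
        with pytest.raises(LabelingError, match="pool"):
            simulate_inst(branch_toy["system"], branch_toy["truth"].fluxes,
                          pools, branch_toy["feed"], np.array([0.1]))

    def test_tca_labels_slower_than_upper_glycolysis(self, ppastoris):
        """With physiological pools the TCA fragments take longer to reach
        95% of their steady labelling than upper-glycolysis fragments."""
        system = decompose(ppastoris["network"], ppastoris["fragments"])
        times = np.concatenate([[0.0], 5 / 3600 * (6.0 / (5 / 3600))
                                ** (np.arange(30) / 29)])
        res = simulate_inst(system, ppastoris["truth"], ppastoris["pools"],
                            GLC_FEED, times, rtol=1e-6, atol=1e-9)
        steady = simulate_steady(system, ppastoris["truth"], GLC_FEED)

        def t95(fid):
            target = 1.0 - steady[fid][0]  # labelled fraction at steady state
            frac = 1.0 - res[fid].mids[:, 0]
            above = np.nonzero(frac >= 0.95 * target)[0]
            return times[above[0]] if above.size else np.inf

        assert t95("succ") > t95("fru6p")
        assert t95("glu") > t95("dhap")


class TestSimulateSteady:
    def test_chain_fully_labelled_feed_propagates(self):
        net = parse_network(
            "u: Sx(ab) -> A(ab)\nr: A(ab) -> B(ab)\no: B(ab) -> Px(ab)\n")
        system = decompose(net, [FragmentSpec("b", "B", (1, 2))])
        feed = FeedLabeling({"Sx": [("11", 0.7), ("00", 0.3)]})
        mids = simulate_steady(system, FluxDistribution(
            {"u": 1.0, "r": 1.0, "o": 1.0}), feed)
        np.testing.assert_allclose(mids["b"], [0.3, 0.0, 0.7], atol=1e-12)

    def test_reversible_pair_equilibrates(self):
        net = parse_network(
            "u: Sx(a) -> A(a)\nr: A(a) <-> B(a)\no: B(a) -> Px(a)\n")
        frags = [FragmentSpec("a", "A", (1,)), FragmentSpec("b", "B", (1,))]
        system = decompose(net, frags)
        feed = FeedLabeling({"Sx": [("1", 0.42), ("0", 0.58)]})
        mids = simulate_steady(system, FluxDistribution(
            {"u": 1.0, "r": 1.0, "o": 1.0}, {"r": 5.0}), feed)
        np.testing.assert_allclose(mids["a"], mids["b"], atol=1e-12)

    def test_matches_long_time_instationary_limit(self, branch_toy):
        horizon = np.array([0.1, 200.0])
        inst = simulate_inst(branch_toy["system"], branch_toy["truth"].fluxes,
                             branch_toy["truth"].pools, branch_toy["feed"],
                             horizon, rtol=1e-10, atol=1e-12)
        steady = simulate_steady(branch_toy["system"], branch_toy["truth"].fluxes,
                                 branch_toy["feed"])
        for fid, mid in steady.items():
            np.testing.assert_allclose(inst[fid].mids[-1], mid, atol=1e-6)

    def test_disconnected_emu_is_singular(self):
        net = parse_network(
            "u: Sx(a) -> A(a)\no: A(a) -> Px(a)\nr: B(a) <-> C(a)\n"
            "ob: B(a) -> Qx(a)\nib: Rx(a) -> B(a)\n")
        system = decompose(net, [FragmentSpec("c", "C", (1,))])
        # zero flux through the reversible step leaves C unconstrained
        fluxes = FluxDistribution({"u": 1, "o": 1, "r": 0.0, "ob": 1.0, "ib": 1.0},
                                  {"r": 0.0})
        with pytest.raises(LabelingError, match="singular|disconnected"):
            simulate_steady(system, fluxes, FeedLabeling({"Rx": [("1", 1.0)]}))


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _oracle_cases():
    branch = parse_network("""
@external Sx Px Qx
u:  Sx(ab) -> A(ab)
v1: A(ab) -> B(ab)
v2: A(ab) -> C(ba)
ob: B(ab) -> Px(ab)
oc: C(ab) -> Qx(ab)
w:  B(ab) <-> D(ba)
""")
    scramble = parse_network("""
@external Sx Tx Px
u1: Sx(ab) -> A(ab)
u2: Tx(c) -> E(c)
c1: A(ab) + E(c) -> F(abc) | F(bac)
r:  F(abc) <-> G(cba)
o:  G(abc) -> Px(abc)
""")
    # condensation + cleavage with a two-instance product (12 carbons total)
    cleave = parse_network("""
@external Sx Px
u:  Sx(abc) -> A(abc)
c:  A(abc) + A(def) -> T(abcdef)
s:  T(abcdef) -> B(abc) + B(def)
ob: B(abc) -> Px(abc)
oa: A(abc) -> Px(abc)
""")
    return [
        pytest.param(
            branch,
            FluxDistribution({"u": 1.0, "v1": 0.6, "v2": 0.4, "ob": 0.6,
                              "oc": 0.4, "w": 0.0}, {"w": 0.5}),
            {"A": 2.0, "B": 10.0, "C": 6.0, "D": 8.0},
            FeedLabeling({"Sx": [("10", 0.5), ("11", 0.3), ("00", 0.2)]}),
            [FragmentSpec("b", "B", (1, 2)), FragmentSpec("c1", "C", (1,)),
             FragmentSpec("d", "D", (1, 2))],
            id="branch-flip-buffer"),
        pytest.param(
            scramble,
            FluxDistribution({"u1": 1.0, "u2": 1.0, "c1": 1.0, "r": 1.0,
                              "o": 1.0}, {"r": 0.7}),
            {"A": 4.0, "E": 2.0, "F": 6.0, "G": 3.0},
            FeedLabeling({"Sx": [("10", 0.8), ("11", 0.2)],
                          "Tx": [("1", 0.5), ("0", 0.5)]}),
            [FragmentSpec("f", "F", (1, 2, 3)), FragmentSpec("g12", "G", (1, 2))],
            id="condensation-scrambling"),
        pytest.param(
            cleave,
            FluxDistribution({"u": 1.0, "c": 0.3, "s": 0.3, "ob": 0.6, "oa": 0.4}),
            {"A": 3.0, "T": 12.0, "B": 5.0},
            FeedLabeling({"Sx": [("100", 0.7), ("111", 0.3)]}),
            [FragmentSpec("t", "T", (1, 2, 3, 4, 5, 6)),
             FragmentSpec("b13", "B", (1, 3))],
            id="dimer-cleavage"),
    ]


@pytest.mark.parametrize("net,fluxes,pools,feed,frags", _oracle_cases())
def test_emu_matches_isotopomer_oracle(net, fluxes, pools, feed, frags):
    """On every small test network the EMU cascade agrees with the full
    2^n positional-isotopomer ODE system to 1e-6 in every fraction."""
    times = _grid()
    emu_res = simulate_inst(decompose(net, frags), fluxes, pools, feed, times,
                            rtol=1e-10, atol=1e-12)
    oracle_res = simulate_isotopomers(net, fluxes, pools, feed, times, frags)
    for frag in frags:
        np.testing.assert_allclose(emu_res[frag.id].mids, oracle_res[frag.id],
                                   atol=1e-6)
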