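"""Shared fixtures: toy networks with known flux distributions and the
packaged P. pastoris network."""

from __future__ import annotations

import numpy as np
import pytest

from instaflux import data
from instaflux.emu import FeedLabeling, FragmentSpec, decompose
from instaflux.network import ConstraintSet, FluxDistribution, parse_network
from instaflux.synth import GroundTruth, exponential_time_grid

@pytest.fixture(scope="session")
def ppastoris():
    """Packaged network + constraints + reference flux distribution."""
    net = data.load_ppastoris_network()
    return {
        "network": net,
        "constraints": data.load_ppastoris_constraints(),
        "truth": data.load_ppastoris_truth(),
        "pools": {m.id: m.measured_pool for m in net.metabolites},
        "fragments": [FragmentSpec(k, v["metabolite"], tuple(v["positions"]),
                                   v.get("formula"))
                      for k, v in data.load_ppastoris_fragments().items()],
    }


@pytest.fixture(scope="session")
def branch_toy():
    """Small identifiable network: branch point, carbon flip, buffer pool.

    One free net flux (the branch split), one exchange flux (the buffer),
    one unmeasured pool (C): all three structurally identifiable from the
    fragment dynamics.
    """
    net = parse_network("""
@external Sx Px Qx
u:  Sx(ab) -> A(ab)
v1: A(ab) -> B(ab)
v2: A(ab) -> C(ba)
ob: B(ab) -> Px(ab)
oc: C(ab) -> Qx(ab)
w:  B(ab) <-> D(ba)
""")
    constraints = ConstraintSet(fixed={"u": 1.0})
    fluxes = FluxDistribution(
        {"u": 1.0, "v1": 0.6, "v2": 0.4, "ob": 0.6, "oc": 0.4, "w": 0.0},
        {"w": 0.5})
    pools = {"A": 2.0, "B": 10.0, "C": 6.0, "D": 8.0}
    fragments = [FragmentSpec("b12", "B", (1, 2)), FragmentSpec("c12", "C", (1, 2)),
                 FragmentSpec("c1", "C", (1,)), FragmentSpec("d1", "D", (1,))]
    feed = FeedLabeling({"Sx": [("10", 0.5), ("11", 0.3), ("00", 0.2)]})
    return {
        "network": net,
        "constraints": constraints,
        "truth": GroundTruth(fluxes, pools, 0),
        "fragments": fragments,
        "system": decompose(net, fragments),
        "feed": feed,
        "measured_pools": {"A": 2.0, "B": 10.0, "D": 8.0},
        "times": exponential_time_grid(12, 5 / 3600, 1.0),
    }


@pytest.fixture(scope="session")
def chain5_toy():
    """Five-carbon linear chain with whole-molecule fragments, used for
    chi-square calibration (large fragments keep the renormalisation
    deficit small)."""
    net = parse_network("""
@external Sx Px
u:  Sx(abcde) -> A(abcde)
r1: A(abcde) -> B(abcde)
r2: B(abcde) -> C(abcde)
o:  C(abcde) -> Px(abcde)
""")
    fluxes = FluxDistribution({"u": 1.0, "r1": 1.0, "r2": 1.0, "o": 1.0})
    pools = {"A": 5.0, "B": 8.0, "C": 3.0}
    fragments = [FragmentSpec(f, m, (1, 2, 3, 4, 5))
                 for f, m in [("a", "A"), ("b", "B"), ("c", "C")]]
    # near-uniform steady MIDs: every fraction well away from 0, so the
    # truncated-Gaussian noise model stays effectively Gaussian
    sixth = 1.0 / 6.0
    feed = FeedLabeling({"Sx": [("00000", sixth), ("10000", sixth),
                                ("11000", sixth), ("11100", sixth),
                                ("11110", sixth), ("11111", 1.0 - 5 * sixth)]})
    return {
        "network": net,
        "truth": GroundTruth(fluxes, pools, 0),
        "fragments": fragments,
        "system": decompose(net, fragments),
        "feed": feed,
        "times": exponential_time_grid(10, 5 / 3600, 0.5),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
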