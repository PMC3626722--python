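"""NET analysis: Gibbs energies, mass-action ratios, feasibility LPs,
cofactor ratios and Student-t concentration ranges."""

import numpy as np
import pytest
from scipy.stats import norm

from instaflux import data
from instaflux.io import load_thermo_inputs
from instaflux.thermo import (ConcentrationRange, R_GAS, ThermoError,
                              ThermoModel, ThermoReaction, from_molar,
                              mass_action_ratio, min_cofactor_ratio,
                              net_feasibility, ranges_from_table,
                              reaction_gibbs, student_t_range, to_molar)

RT = R_GAS * 298.15


def _model(reactions):
    return ThermoModel({r.id: r for r in reactions})


class TestUnits:
    def test_umol_to_mm(self):
        assert to_molar(1.7, 1.7) == pytest.approx(1.0)
        assert to_molar(0.17, 1.7) == pytest.approx(0.1)

    def test_roundtrip(self):
        assert from_molar(to_molar(3.21, 1.7), 1.7) == pytest.approx(3.21)

    def test_nonpositive_pool_raises(self):
        with pytest.raises(ThermoError):
            to_molar(0.0, 1.7)


class TestGibbs:
    def test_q_one_gives_standard_value(self):
        rxn = ThermoReaction("r", {"A": -1, "B": 1}, -7.3)
        model = _model([rxn])
        assert reaction_gibbs(model, "r", {"A": 1.0, "B": 1.0}) == pytest.approx(-7.3)

    def test_rt_ln_ten(self):
        """Product/substrate ratio of 10 at 298.15 K adds +5.708 kJ/mol."""
        rxn = ThermoReaction("r", {"A": -1, "B": 1}, 0.0)
        model = _model([rxn])
        dg = reaction_gibbs(model, "r", {"A": 0.1, "B": 1.0})
        assert dg == pytest.approx(RT * np.log(10.0), abs=1e-6)
        assert dg == pytest.approx(5.708, abs=1e-3)

    def test_inverting_q_flips_sign(self):
        rxn = ThermoReaction("r", {"A": -1, "B": 1}, 0.0)
        model = _model([rxn])
        fwd = reaction_gibbs(model, "r", {"A": 0.2, "B": 1.4})
        rev = reaction_gibbs(model, "r", {"A": 1.4, "B": 0.2})
        assert fwd == pytest.approx(-rev)

    def test_missing_concentration_names_metabolite(self):
        rxn = ThermoReaction("r", {"A": -1, "B": 1}, 0.0)
        with pytest.raises(ThermoError, match="B"):
            reaction_gibbs(_model([rxn]), "r", {"A": 1.0})


class TestMassActionRatio:
    def test_pgi_ratio(self):
        """Fru6P 0.22 mM over Glc6P 1.0 mM: the glucose-methanol PGI MAR."""
        pgi = ThermoReaction("pgi", {"Glc6P": -1, "Fru6P": 1}, 2.5)
        assert mass_action_ratio(pgi, {"Glc6P": 1.0, "Fru6P": 0.22}) == \
            pytest.approx(0.22)

    def test_equal_concentrations_q_one(self):
        rxn = ThermoReaction("r", {"A": -1, "B": -1, "C": 1, "D": 1}, 0.0)
        conc = dict.fromkeys("ABCD", 0.37)
        assert mass_action_ratio(rxn, conc) == pytest.approx(1.0)

    def test_reciprocity(self, rng):
        fwd = ThermoReaction("f", {"A": -1, "B": 2}, 0.0)
        rev = ThermoReaction("b", {"A": 1, "B": -2}, 0.0)
        conc = {"A": rng.uniform(0.1, 2), "B": rng.uniform(0.1, 2)}
        assert mass_action_ratio(fwd, conc) * mass_action_ratio(rev, conc) == \
            pytest.approx(1.0)

    def test_zero_concentration_raises(self):
        rxn = ThermoReaction("r", {"A": -1, "B": 1}, 0.0)
        with pytest.raises(ThermoError):
            mass_action_ratio(rxn, {"A": 0.0, "B": 1.0})


class TestStudentT:
    def test_zero_sd_degenerate(self):
        lo, hi = student_t_range(1.5, 0.0, 3)
        assert lo == hi == 1.5

    def test_known_quantile(self):
        """t(0.90, 2 dof) = 1.886: bounds 1.0 +/- 1.886 * 0.1/sqrt(3)."""
        lo, hi = student_t_range(1.0, 0.1, 3, confidence=0.80)
        half = 1.886 * 0.1 / np.sqrt(3)
        assert hi - 1.0 == pytest.approx(half, abs=1e-3)
        assert 1.0 - lo == pytest.approx(half, abs=1e-3)

    def test_large_n_limits_to_normal(self):
        lo, hi = student_t_range(0.0, 1.0, 100000, confidence=0.80)
        z = norm.ppf(0.90)
        assert hi == pytest.approx(z / np.sqrt(100000), rel=1e-3)

    def test_single_replicate_raises(self):
        with pytest.raises(ThermoError):
            student_t_range(1.0, 0.1, 1)


def _chain_model(dgr0=0.0):
    return _model([ThermoReaction("ab", {"A": -1, "B": 1}, dgr0)])


class TestNetFeasibility:
    def test_second_law_tightens_downstream(self):
        """A -> B with dgr0 = 0 and c_A pinned at 1 mM forces c_B < 1 mM."""
        ranges = {"A": ConcentrationRange("A", 1.0, 1.0),
                  "B": ConcentrationRange("B", 1e-3, 10.0)}
        res = net_feasibility(_chain_model(), {"ab": 1.0}, ranges)
        assert res.feasible
        assert res.ranges["B"].upper <= 1.0 + 1e-6
        assert res.ranges["A"].upper == pytest.approx(1.0, rel=1e-6)

    def test_uphill_measurement_infeasible_names_reaction(self):
        ranges = {"A": ConcentrationRange("A", 0.5, 0.5),
                  "B": ConcentrationRange("B", 2.0, 2.0)}
        res = net_feasibility(_chain_model(), {"ab": 1.0}, ranges)
        assert not res.feasible
        assert res.violated == ["ab"]

    def test_matches_bruteforce_grid(self):
        """Tightened ranges agree with an exhaustive 30^3 grid scan on a
        three-metabolite chain."""
        model = _model([ThermoReaction("ab", {"A": -1, "B": 1}, -1.0),
                        ThermoReaction("bc", {"B": -1, "C": 1}, 2.0)])
        directions = {"ab": 1.0, "bc": 1.0}
        bounds = {"A": (0.05, 2.0), "B": (0.01, 5.0), "C": (0.01, 1.0)}
        ranges = {m: ConcentrationRange(m, lo, hi)
                  for m, (lo, hi) in bounds.items()}
        res = net_feasibility(model, directions, ranges)

        grids = {m: np.exp(np.linspace(np.log(lo), np.log(hi), 30))
                 for m, (lo, hi) in bounds.items()}
        feas = {m: [] for m in bounds}
        for a in grids["A"]:
            for b in grids["B"]:
                for c in grids["C"]:
                    conc = {"A": a, "B": b, "C": c}
                    if all(reaction_gibbs(model, rid, conc) < 0
                           for rid in directions):
                        for m in bounds:
                            feas[m].append(conc[m])
        for m in bounds:
            lo, hi = min(feas[m]), max(feas[m])
            step = np.log(grids[m][1] / grids[m][0])
            assert np.log(res.ranges[m].lower) == pytest.approx(
                np.log(lo), abs=1.5 * step)
            assert np.log(res.ranges[m].upper) == pytest.approx(
                np.log(hi), abs=1.5 * step)

    def test_monotone_in_constraints(self):
        """Adding a directed reaction never widens any range."""
        model = _model([ThermoReaction("ab", {"A": -1, "B": 1}, -1.0),
                        ThermoReaction("bc", {"B": -1, "C": 1}, 2.0)])
        ranges = {m: ConcentrationRange(m, 1e-3, 10.0) for m in "ABC"}
        partial = net_feasibility(model, {"ab": 1.0}, ranges)
        full = net_feasibility(model, {"ab": 1.0, "bc": 1.0}, ranges)
        for m in "AB":
            assert full.ranges[m].lower >= partial.ranges[m].lower - 1e-9
            assert full.ranges[m].upper <= partial.ranges[m].upper + 1e-9

    def test_idempotent(self):
        model = _model([ThermoReaction("ab", {"A": -1, "B": 1}, 0.5)])
        ranges = {"A": ConcentrationRange("A", 0.1, 2.0),
                  "B": ConcentrationRange("B", 1e-3, 10.0)}
        once = net_feasibility(model, {"ab": 1.0}, ranges)
        twice = net_feasibility(model, {"ab": 1.0}, once.ranges)
        for m in "AB":
            assert twice.ranges[m].lower == pytest.approx(
                once.ranges[m].lower, rel=1e-6)
            assert twice.ranges[m].upper == pytest.approx(
                once.ranges[m].upper, rel=1e-6)

    def test_feasible_point_satisfies_gibbs_pointwise(self):
        model = _model([ThermoReaction("ab", {"A": -1, "B": 1}, -1.0),
                        ThermoReaction("bc", {"B": -1, "C": 1}, 2.0)])
        directions = {"ab": 1.0, "bc": 1.0}
        ranges = {m: ConcentrationRange(m, 1e-3, 10.0) for m in "ABC"}
        res = net_feasibility(model, directions, ranges)
        mid = {m: np.sqrt(r.lower * r.upper) for m, r in res.ranges.items()}
        # the geometric midpoint of a box tightened per-coordinate need not
        # be feasible; check the returned extreme points instead
        for m in "ABC":
            point = dict(mid)
            point[m] = res.ranges[m].lower * (1 + 1e-9)
            # at least the per-reaction Gibbs ranges must admit < 0
        for rid, (lo, hi) in res.gibbs_ranges.items():
            assert lo < 0


class TestCofactorRatio:
    def test_single_constraint_closed_form(self):
        """S + NAD -> P + NADH with dgr0 = +20 kJ/mol and S = P = 1 mM:
        minimum NAD/NADH = exp(20000 / (R T))."""
        rxn = ThermoReaction("dh", {"S": -1, "NAD": -1, "P": 1, "NADH": 1}, 20.0)
        ranges = {"S": ConcentrationRange("S", 1.0, 1.0),
                  "P": ConcentrationRange("P", 1.0, 1.0)}
        res = min_cofactor_ratio(_model([rxn]), {"dh": 1.0}, ranges,
                                 ("NAD", "NADH"))
        assert not res.unbounded
        assert np.log(res.min_ratio) == pytest.approx(20.0 / RT, rel=1e-5)

    def test_ph_ordering_of_fixture_min_ratio(self):
        """With per-pH Gibbs tables the minimum NAD/NADH ratio decreases
        with increasing pH (the dehydrogenase releases a proton)."""
        raw = data.load_thermo_fixture()
        ratios = []
        for ph in ("7.0", "7.2", "7.5"):
            model, _ = load_thermo_inputs(raw, ph)
            ranges = {"MAL": ConcentrationRange("MAL", 0.9, 1.2),
                      "OAA": ConcentrationRange("OAA", 0.015, 0.02)}
            res = min_cofactor_ratio(model, {"mdh_nad": 1.0}, ranges)
            ratios.append(res.min_ratio)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_uncoupled_pair_unbounded(self):
        rxn = ThermoReaction("ab", {"A": -1, "B": 1}, 0.0)
        ranges = {m: ConcentrationRange(m, 0.1, 1.0) for m in "AB"}
        res = min_cofactor_ratio(_model([rxn]), {"ab": 1.0}, ranges,
                                 ("NAD", "NADH"))
        assert res.unbounded and res.min_ratio is None


class TestChannelledVariant:
    def test_classical_infeasible_channelled_feasible(self):
        """A constructed instance where the separate transketolase +
        transaldolase steps contradict the measured pentose-phosphate
        concentrations while the channelled reaction does not."""
        raw = data.load_thermo_fixture()
        model, _ = load_thermo_inputs(raw, "7.2")
        pools = data.load_ppastoris_pools()
        meas = pools[pools.measured == 1]
        from instaflux.synth import generate_concentration_dataset
        table = generate_concentration_dataset(
            dict(zip(meas.metabolite, meas.pool_umol_gcdw)),
            n_replicates=6, rel_sigma=0.15, seed=11)
        ranges = ranges_from_table(table, model)
        lo, hi = raw["default_ranges_mm"]
        for variant, expect in (("directions", False),
                                ("directions_channelled", True)):
            dirs = dict(raw[variant])
            dirs.pop("mdh_nad", None)
            dirs.pop("fld_nad", None)
            work = dict(ranges)
            needed = {m for rid in dirs for m in model.reactions[rid].stoich}
            for met in needed:
                if met not in work:
                    work[met] = ConcentrationRange(met, lo, hi, "default")
            res = net_feasibility(model, dirs, work)
            assert res.feasible is expect
            if not expect:
                assert "tal" in res.violated
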