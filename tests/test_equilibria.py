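"""Equilibrium enumeration, Jacobian and ESS classification."""

import numpy as np
import pytest

from recyclegame import (
    StrategyState,
    classify_equilibrium,
    enumerate_equilibria,
    equilibria_to_frame,
    ess_set,
    jacobian_at,
    replicator_field,
    symbolic_stability_conditions,
)
from recyclegame.equilibria import EquilibriumReport, interior_equilibrium

from conftest import random_parameters, random_interior_state


def by_label(reports):
    return {r.label: r for r in reports}


class TestEnumeration:
    def test_baseline_has_five_points_with_interior_saddle(self, baseline):
        reports = enumerate_equilibria(baseline)
        assert len(reports) == 5
        assert [r.label for r in reports] == ["E1", "E2", "E3", "E4", "E5"]
        e5 = by_label(reports)["E5"]
        assert e5.admissible
        assert e5.coordinates.phi == pytest.approx(15.0 / 49.0)
        assert e5.coordinates.omega == pytest.approx(120.0 / 330.0)

    def test_large_reward_shifts_interior_point(self, baseline):
        reports = enumerate_equilibria(baseline.replace(m=200.0))
        e5 = by_label(reports)["E5"]
        assert e5.admissible
        assert e5.coordinates.phi == pytest.approx(15.0 / 169.0)
        assert e5.coordinates.omega == pytest.approx(120.0 / 210.0)

    def test_interior_point_outside_square_is_inadmissible(self, baseline):
        # s = 300 puts omega* = 120 / (300-260-80) = -3 outside (0,1)
        reports = enumerate_equilibria(baseline.replace(s=300.0))
        e5 = by_label(reports)["E5"]
        assert not e5.admissible
        assert e5.classification is None
        assert sum(1 for r in reports if r.admissible) == 4

    def test_degenerate_denominator_drops_interior_point(self, baseline):
        # m = t1 - t2 = 31 makes the resident bracket slope vanish
        assert interior_equilibrium(baseline.replace(m=31.0)) is None
        assert len(enumerate_equilibria(baseline.replace(m=31.0))) == 4


class TestJacobian:
    def test_baseline_corner_diagonals(self, baseline):
        j1 = jacobian_at(baseline, StrategyState(1.0, 1.0))
        assert (j1.j11, j1.j22) == (-210.0, -34.0)
        assert (j1.j12, j1.j21) == (0.0, 0.0)
        assert j1.det == 7140.0 and j1.trace == -244.0
        j3 = jacobian_at(baseline, StrategyState(0.0, 0.0))
        assert (j3.j11, j3.j22) == (-120.0, -15.0)
        assert j3.det == 1800.0 and j3.trace == -135.0

    def test_baseline_interior_point_is_traceless(self, baseline):
        e5 = interior_equilibrium(baseline)
        jac = jacobian_at(baseline, e5)
        assert jac.j11 == pytest.approx(0.0, abs=1e-12)
        assert jac.j22 == pytest.approx(0.0, abs=1e-12)
        assert jac.trace == pytest.approx(0.0, abs=1e-12)
        # det = -j12 * j21 with j12 = phi*(1-phi*)*330, j21 = omega*(1-omega*)*49
        j12 = (15 / 49) * (34 / 49) * 330.0
        j21 = (120 / 330) * (210 / 330) * 49.0
        assert jac.det == pytest.approx(-j12 * j21)
        assert jac.det < 0

    def test_eigenvalues_solve_characteristic_polynomial(self, baseline, center):
        jac = jacobian_at(baseline, center)
        for ev in jac.eigenvalues:
            residual = ev * ev - jac.trace * ev + jac.det
            assert abs(residual) < 1e-8 * max(1.0, abs(jac.det))

    def test_matches_finite_differences_of_field(self, rng):
        """Central finite differences of the vector field reproduce Eq.-level Jacobian."""
        step = 1e-6
        for _ in range(100):
            params = random_parameters(rng)
            state = random_interior_state(rng)
            jac = jacobian_at(params, state)
            num = np.empty((2, 2))
            for col, (dphi, domega) in enumerate(((step, 0.0), (0.0, step))):
                plus = replicator_field(
                    params, StrategyState(state.phi + dphi, state.omega + domega)
                )
                minus = replicator_field(
                    params, StrategyState(state.phi - dphi, state.omega - domega)
                )
                num[0, col] = (plus.dphi_dt - minus.dphi_dt) / (2 * step)
                num[1, col] = (plus.domega_dt - minus.domega_dt) / (2 * step)
            analytic = np.array([[jac.j11, jac.j12], [jac.j21, jac.j22]])
            scale = max(1.0, np.abs(analytic).max())
            assert np.allclose(num, analytic, atol=1e-4 * scale)


class TestClassification:
    def test_baseline_is_bistable(self, baseline):
        reports = by_label(enumerate_equilibria(baseline))
        assert reports["E1"].classification == "ESS"
        assert reports["E3"].classification == "ESS"
        assert reports["E2"].classification == "source"
        assert reports["E4"].classification == "source"
        assert reports["E5"].classification == "saddle"
        assert reports["E5"].jacobian.trace == 0.0

    def test_non_equilibrium_input_rejected(self, baseline, center):
        fake = EquilibriumReport(label="E1", coordinates=center, admissible=True)
        with pytest.raises(ValueError, match="residual"):
            classify_equilibrium(baseline, fake)

    def test_bifurcation_boundary_is_non_hyperbolic(self, baseline):
        # m = t1 zeroes one E1 eigenvalue
        reports = by_label(enumerate_equilibria(baseline.replace(m=46.0)))
        assert reports["E1"].classification == "non-hyperbolic"

    def test_corner_classification_matches_closed_form_eigenvalues(self, rng):
        """Oracle check on 1,000 draws: diagonal corner eigenvalues decide ESS."""
        for _ in range(1000):
            params = random_parameters(rng)
            reports = by_label(enumerate_equilibria(params))
            net = params.s - params.c1 - params.c2 - params.m
            closed = {
                "E1": (-net, -(params.m - params.t1)),
                "E2": (net, params.t2),
                "E3": (-params.c1, -params.t2),
                "E4": (params.c1, params.m - params.t1),
            }
            for label, eigs in closed.items():
                expected_ess = all(e < -1e-9 for e in eigs)
                assert reports[label].is_ess == expected_ess, (label, params)

    def test_defection_and_cooperation_are_the_only_candidate_ess(self, rng):
        """E2/E4 never ESS; interior E5 traceless with det <= 0; ESS set in {E1,E3}."""
        for _ in range(400):
            params = random_parameters(rng)
            reports = by_label(enumerate_equilibria(params))
            assert not reports["E2"].is_ess
            assert not reports["E4"].is_ess
            e5 = reports.get("E5")
            if e5 is not None and e5.admissible:
                assert not e5.is_ess
                assert e5.jacobian.trace == pytest.approx(0.0, abs=1e-9)
                assert e5.jacobian.det <= 1e-9
            stable = ess_set(params)
            assert len(stable) <= 2
            assert set(stable) <= {"E1", "E3"}


class TestSymbolicConditions:
    def test_baseline_printed_conditions(self, baseline):
        conditions = symbolic_stability_conditions(baseline)
        assert conditions["E1"].printed and conditions["E1"].eigenvalue
        assert conditions["E3"].printed and conditions["E3"].eigenvalue
        assert not conditions["E4"].printed  # m + c1 - t1 = 154 > 0
        assert not conditions["E2"].eigenvalue

    def test_printed_e2_condition_is_infeasible_for_nonnegative_parameters(self, rng):
        """The printed E2 conjunction needs s-c1-c2-m > 0 and s+t2-c1-c2 < 0 at
        once, i.e. m < -t2, impossible for nonnegative rewards — so for every
        draw both the printed and the eigenvalue verdicts are false."""
        for _ in range(300):
            conditions = symbolic_stability_conditions(random_parameters(rng))
            assert not conditions["E2"].printed
            assert not conditions["E2"].eigenvalue
            assert conditions["E2"].agree


class TestExport:
    def test_flat_table_round_trip(self, baseline, tmp_path):
        frame = equilibria_to_frame(enumerate_equilibria(baseline))
        path = tmp_path / "equilibria.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        loaded = pd.read_csv(path)
        assert list(loaded["label"]) == ["E1", "E2", "E3", "E4", "E5"]
        assert loaded["det"].tolist() == pytest.approx(frame["det"].tolist())
        assert loaded["trace"].tolist() == pytest.approx(frame["trace"].tolist())
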