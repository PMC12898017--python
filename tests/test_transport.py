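"""Displacement charge, currents, crossings, conductance, conductivity."""

from __future__ import annotations

import numpy as np
import pytest

from paraperm.constants import PA_PER_E_NS
from paraperm.errors import ConfigurationError, DomainError, InsufficientDataError
from paraperm.species import charges
from paraperm.traj import Topology, ion_selection, select, unwrap_coordinates
from paraperm.transport import (
    BoxGeometry,
    ConductanceResult,
    DisplacementSeries,
    IVPoint,
    bulk_conductivity,
    conductance,
    conductivity_regression,
    count_crossings,
    current_from_displacement,
    displacement_charge,
    iv_r2_through_origin,
    per_pore,
)

from conftest import ion_atom, make_traj

L = 100.0


def ion_traj(paths: dict[str, np.ndarray], box=(L, L, L), wrap=True):
    """Build a trajectory from per-species x-paths (wrapped on store by default)."""
    species = list(paths)
    top = Topology([ion_atom(i + 1, sp) for i, sp in enumerate(species)])
    n_frames = len(next(iter(paths.values())))
    coords = np.full((n_frames, len(species), 3), 50.0)
    for k, sp in enumerate(species):
        x = np.asarray(paths[sp], dtype=float)
        coords[:, k, 0] = np.mod(x, box[0]) if wrap else x
    return make_traj(top, coords, box=box)


class TestDisplacementCharge:
    def test_stationary_is_zero(self):
        traj = ion_traj({"NA": np.full(5, 20.0)})
        s = displacement_charge(traj, ion_selection(), charges(), "x")
        assert np.allclose(s.q_disp_e, 0.0)

    def test_full_traversal_is_one(self):
        traj = ion_traj({"NA": np.linspace(10.0, 10.0 + L, 21)})
        un = unwrap_coordinates(traj, axes=("x",))
        s = displacement_charge(un, ion_selection(), charges(), "x")
        assert s.q_disp_e[-1] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_charges_cancel(self):
        path = np.linspace(10.0, 10.0 + L, 21)
        traj = ion_traj({"NA": path, "CL": path.copy()})
        un = unwrap_coordinates(traj, axes=("x",))
        s = displacement_charge(un, ion_selection(), charges(), "x")
        assert s.q_disp_e[-1] == pytest.approx(0.0, abs=1e-12)

    def test_additive_over_disjoint_selections(self):
        rng = np.random.default_rng(2)
        pna = 10 + np.cumsum(rng.uniform(-5, 8, 30))
        pcl = 40 + np.cumsum(rng.uniform(-6, 6, 30))
        traj = ion_traj({"NA": pna, "CL": pcl})
        un = unwrap_coordinates(traj, axes=("x",))
        both = displacement_charge(un, ion_selection(), charges(), "x")
        na = displacement_charge(un, ion_selection(["NA"]), charges(), "x")
        cl = displacement_charge(un, ion_selection(["CL"]), charges(), "x")
        assert np.allclose(both.q_disp_e, na.q_disp_e + cl.q_disp_e, atol=1e-12)

    def test_missing_charge_entry(self):
        traj = ion_traj({"NA": np.full(3, 20.0)})
        with pytest.raises(ConfigurationError):
            displacement_charge(traj, ion_selection(), {"CL": -1.0}, "x")


class TestCurrent:
    def test_linear_series_conversion(self):
        # 1 e over 10 ns → 0.1 e/ns = 16.02 pA
        t = np.linspace(0, 10, 11)
        s = DisplacementSeries(t, 0.1 * t)
        i = current_from_displacement(s, fit_window=(0, 10))
        assert i == pytest.approx(0.1 * PA_PER_E_NS, rel=1e-9)
        assert i == pytest.approx(16.02, abs=0.01)

    def test_flat_series_zero(self):
        s = DisplacementSeries(np.linspace(0, 5, 6), np.zeros(6))
        assert current_from_displacement(s) == 0.0

    def test_window_excludes_initial_transient(self):
        t = np.linspace(0, 10, 101)
        q = np.where(t < 2, 0.0, 0.2 * (t - 2))  # transient then linear
        s = DisplacementSeries(t, q)
        full = current_from_displacement(s, fit_window=(0, 10))
        late = current_from_displacement(s, fit_window=(2, 10))
        assert late == pytest.approx(0.2 * PA_PER_E_NS, rel=1e-9)
        assert full < late

    def test_endpoint_method_states_charge_conservation(self):
        t = np.linspace(0, 4, 41)
        rng = np.random.default_rng(0)
        q = np.concatenate([[0.0], np.cumsum(rng.normal(0.05, 0.1, 40))])
        s = DisplacementSeries(t, q)
        i = current_from_displacement(s, fit_window=(0, 4), method="endpoint")
        assert i * 4 / PA_PER_E_NS == pytest.approx(q[-1], abs=1e-12)

    def test_empty_window_rejected(self):
        s = DisplacementSeries(np.linspace(0, 5, 6), np.zeros(6))
        with pytest.raises(InsufficientDataError):
            current_from_displacement(s, fit_window=(10, 12))


class TestCrossings:
    def _counts(self, path, lo=40.0, hi=60.0):
        # already-unwrapped coordinates, stored as such
        traj = ion_traj({"NA": np.asarray(path, dtype=float)}, wrap=False)
        return count_crossings(traj, ion_selection(), "x", lo, hi).get("NA", 0)

    def test_monotone_traversal(self):
        assert self._counts(np.linspace(10, 90, 30)) == 1

    def test_enter_and_retreat(self):
        assert self._counts([10, 30, 50, 55, 45, 20, 10]) == 0

    def test_alternating_full_crossings(self):
        # below → above → below → above: net +1
        assert self._counts([10, 70, 90, 20, 10, 80, 90]) == 1

    def test_reverse_traversal_negative(self):
        assert self._counts(np.linspace(90, 10, 30)) == -1

    def test_periodic_drift_counts_every_image(self):
        # three full box lengths of drift → 3 crossings
        path = np.linspace(10.0, 10.0 + 3 * L, 200)
        assert self._counts(path) == 3

    def test_state_machine_oracle_on_random_paths(self):
        rng = np.random.default_rng(42)
        lo, hi = 40.0, 60.0
        for _ in range(30):
            path = [10.0]
            for _ in range(60):
                path.append(path[-1] + rng.uniform(-35, 40))
            got = self._counts(np.asarray(path))
            # explicit state machine on the finely resolved path
            fine = np.concatenate(
                [
                    np.linspace(a, b, 200, endpoint=False)
                    for a, b in zip(path[:-1], path[1:])
                ]
                + [[path[-1]]]
            )
            state = None
            net = 0
            for x in fine:
                frac = np.mod(x - lo, L)
                if frac > hi - lo:  # outside any slab image
                    g = int(np.floor((x - hi) / L)) + 1
                    if state is not None:
                        net += g - state
                    state = g
            assert got == net


class TestConductance:
    def test_exact_ratios(self):
        pts = [IVPoint(200, 10), IVPoint(-200, -10)]
        g = conductance(pts)
        assert g.g_pS == pytest.approx(50.0)
        assert g.sd_pS == pytest.approx(0.0, abs=1e-12)

    def test_single_point(self):
        g = conductance([IVPoint(100, 5)])
        assert (g.g_pS, g.sd_pS, g.n_points) == (pytest.approx(50.0), 0.0, 1)

    def test_estimators_agree_on_ohmic_noisy_data(self):
        rng = np.random.default_rng(8)
        true_g = 0.05  # nS
        pts = [
            IVPoint(v, true_g * v + rng.normal(0, 0.5))
            for v in (-800, -400, 400, 800) * 3
        ]
        pv = conductance(pts, "per_voltage_mean")
        os_ = conductance(pts, "origin_slope")
        assert abs(pv.g_pS - os_.g_pS) < 3 * max(pv.sd_pS, os_.sd_pS)
        assert iv_r2_through_origin(pts) > 0.99

    def test_all_zero_voltage_rejected(self):
        with pytest.raises(DomainError):
            conductance([IVPoint(0, 1)])

    def test_per_pore_scaling(self):
        g = ConductanceResult(150.0, 30.0, "per_voltage_mean", 4)
        out = per_pore(g, BoxGeometry(100, 100, 3))
        assert (out.g_pS, out.sd_pS) == (pytest.approx(50.0), pytest.approx(10.0))
        ident = per_pore(g, BoxGeometry(100, 100, 1))
        assert ident.g_pS == g.g_pS


class TestBulkConductivity:
    def test_unit_arithmetic(self):
        g = ConductanceResult(1000.0, 0.0, "per_voltage_mean", 2)  # 1 nS
        sigma = bulk_conductivity(g, BoxGeometry(100.0, 1e4, 1))
        assert sigma == pytest.approx(0.1)

    def test_intensivity(self):
        g = ConductanceResult(500.0, 0.0, "per_voltage_mean", 2)
        g2 = ConductanceResult(1000.0, 0.0, "per_voltage_mean", 2)
        s1 = bulk_conductivity(g, BoxGeometry(100.0, 1e4, 1))
        s2 = bulk_conductivity(g2, BoxGeometry(100.0, 2e4, 1))
        assert s1 == pytest.approx(s2)

    def test_zero_conductance(self):
        g = ConductanceResult(0.0, 0.0, "per_voltage_mean", 2)
        assert bulk_conductivity(g, BoxGeometry(50.0, 2500.0, 1)) == 0.0


class TestConductivityRegression:
    def test_exact_proportionality(self):
        x = {"NaCl": 1.0, "KCl": 2.0, "CsCl": 3.0}
        y = {k: 2 * v for k, v in x.items()}
        slope, r2 = conductivity_regression(x, y)
        assert (slope, r2) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_affine_with_intercept(self):
        x = {"a": 1.0, "b": 2.0, "c": 4.0}
        y = {k: v + 1 for k, v in x.items()}
        slope, r2 = conductivity_regression(x, y, intercept=True)
        assert (slope, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        salts = [f"s{i}" for i in range(7)]
        xv = rng.uniform(0.5, 12, 7)
        yv = rng.uniform(0.5, 12, 7)
        x = dict(zip(salts, xv))
        y = dict(zip(salts, yv))
        slope, r2 = conductivity_regression(x, y, intercept=True)
        A = np.column_stack([xv, np.ones(7)])
        beta = np.linalg.solve(A.T @ A, A.T @ yv)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        resid = yv - A @ beta
        r2_oracle = 1 - np.sum(resid**2) / np.sum((yv - yv.mean()) ** 2)
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)
        slope_ni, _ = conductivity_regression(x, y, intercept=False)
        assert slope_ni == pytest.approx(float(xv @ yv / (xv @ xv)), abs=1e-12)

    def test_too_few_salts(self):
        with pytest.raises(InsufficientDataError):
            conductivity_regression({"a": 1, "b": 2}, {"a": 1, "b": 2})
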