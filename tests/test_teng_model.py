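"""Device electrostatics: closed forms, the 2D Poisson solver, curves."""

import numpy as np
import pytest

from teng_neuron import (
    EPS0,
    MicropatternSpec,
    TENGConfig,
    TENGCurve,
    build_curve,
    closed_form_capacitance,
    closed_form_voc,
    default_gap_grid,
    extract_voc_capacitance,
    query_curve,
    solve_poisson_2d,
)
from teng_neuron.teng_model import SolverError


class TestClosedForms:
    def test_voc_zero_at_contact(self, teng_cfg):
        assert closed_form_voc(0.0, teng_cfg) == 0.0

    def test_voc_linearity(self, teng_cfg):
        v1 = closed_form_voc(1e-4, teng_cfg)
        assert closed_form_voc(2e-4, teng_cfg) == pytest.approx(2 * v1, rel=1e-12)
        assert v1 == pytest.approx(teng_cfg.sigma * 1e-4 / EPS0, rel=1e-12)

    def test_voc_negative_gap_rejected(self, teng_cfg):
        with pytest.raises(ValueError):
            closed_form_voc(-1e-6, teng_cfg)

    def test_capacitance_at_contact_is_series_stack(self, teng_cfg):
        # independent evaluation of eps0*A/(d_silk/eps_s + d_kapton/eps_k)
        expected = 8.8541878128e-12 * 15e-5 / (7e-7 / 2.6 + 7e-7 / 3.4)
        assert closed_form_capacitance(0.0, teng_cfg) == pytest.approx(
            expected, rel=1e-12
        )

    def test_capacitance_limits_and_monotonicity(self, teng_cfg):
        gaps = np.geomspace(1e-7, 1e-2, 12)
        caps = [closed_form_capacitance(g, teng_cfg) for g in gaps]
        assert np.all(np.diff(caps) < 0)
        assert caps[-1] < 1e-3 * caps[0]  # C -> 0 as the gap opens


class TestPoissonSolver:
    def test_flat_voc_matches_closed_form(self, teng_cfg):
        sol = solve_poisson_2d(teng_cfg, 2e-4, cells_per_layer=128)
        expected = closed_form_voc(2e-4, teng_cfg)
        assert sol.voc == pytest.approx(expected, rel=0.02)

    def test_flat_capacitance_matches_series_stack(self, teng_cfg):
        sol = solve_poisson_2d(teng_cfg, 2e-4, cells_per_layer=64,
                               compute_convergence=False)
        assert sol.capacitance == pytest.approx(
            closed_form_capacitance(2e-4, teng_cfg), rel=0.02
        )

    def test_zero_charge_gives_zero_potential(self, teng_cfg):
        import dataclasses

        cfg0 = dataclasses.replace(teng_cfg, sigma=0.0)
        sol = solve_poisson_2d(cfg0, 2e-4, cells_per_layer=16,
                               compute_convergence=False)
        assert np.max(np.abs(sol.grid_potential)) < 1e-12
        assert sol.voc == pytest.approx(0.0, abs=1e-12)

    def test_patterned_voc_at_least_flat(self, teng_cfg):
        import dataclasses

        gap = 2e-4
        flat = solve_poisson_2d(teng_cfg, gap, cells_per_layer=16,
                                compute_convergence=False)
        cube_cfg = dataclasses.replace(
            teng_cfg, pattern=MicropatternSpec(shape="cube")
        )
        cube = solve_poisson_2d(cube_cfg, gap, cells_per_layer=16,
                                compute_convergence=False)
        assert cube.voc >= flat.voc

    def test_gap_zero_rejected(self, teng_cfg):
        with pytest.raises(SolverError):
            solve_poisson_2d(teng_cfg, 0.0)

    def test_mesh_convergence_first_order(self, teng_cfg):
        gap = 2e-4
        expected = closed_form_voc(gap, teng_cfg)
        errs = []
        for n in (16, 32, 64):
            sol = solve_poisson_2d(teng_cfg, gap, cells_per_layer=n,
                                   compute_convergence=False)
            errs.append(abs(sol.voc - expected) / expected)
        assert errs[0] > errs[1] > errs[2]
        # halving the cell roughly halves the error (first order)
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.3)


class TestExtraction:
    def test_eq1_identity_to_machine_precision(self, teng_cfg):
        sol = solve_poisson_2d(teng_cfg, 3e-4, cells_per_layer=32,
                               compute_convergence=False)
        voc, cap = extract_voc_capacitance(sol, teng_cfg)
        q = teng_cfg.sigma * teng_cfg.plate_area
        assert cap * voc == pytest.approx(q, rel=1e-12)
        assert q == pytest.approx(5e-5 * 15e-5, rel=1e-15)

    def test_capacitance_invariant_under_sigma(self, teng_cfg):
        import dataclasses

        sol1 = solve_poisson_2d(teng_cfg, 3e-4, cells_per_layer=32,
                                compute_convergence=False)
        cfg2 = dataclasses.replace(teng_cfg, sigma=2 * teng_cfg.sigma)
        sol2 = solve_poisson_2d(cfg2, 3e-4, cells_per_layer=32,
                                compute_convergence=False)
        v1, c1 = extract_voc_capacitance(sol1, teng_cfg)
        v2, c2 = extract_voc_capacitance(sol2, cfg2)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)
        assert c2 == pytest.approx(c1, rel=1e-9)

    def test_zero_voc_falls_back_to_series_form(self, teng_cfg):
        import dataclasses

        cfg0 = dataclasses.replace(teng_cfg, sigma=0.0)
        sol = solve_poisson_2d(cfg0, 2e-4, cells_per_layer=16,
                               compute_convergence=False)
        voc, cap = extract_voc_capacitance(sol, cfg0)
        assert voc == pytest.approx(0.0, abs=1e-12)
        assert cap == pytest.approx(
            closed_form_capacitance(2e-4, cfg0), rel=1e-6
        )


class TestCurves:
    def test_closed_form_curve_monotone(self, flat_curve):
        assert np.all(np.diff(flat_curve.voc) > 0)
        assert np.all(np.diff(flat_curve.cap_total) < 0)
        np.testing.assert_allclose(
            flat_curve.cap_per_area,
            flat_curve.cap_total / (flat_curve.plate_area * 1e4),
        )

    def test_poisson_flat_curve_agrees_with_closed_form(self, teng_cfg):
        gaps = np.linspace(1e-4, 5e-4, 5)
        c_cf = build_curve(teng_cfg, gaps, method="closed_form")
        c_ps = build_curve(teng_cfg, gaps, method="poisson_2d",
                           cells_per_layer=64)
        np.testing.assert_allclose(c_ps.voc, c_cf.voc, rtol=0.02)
        np.testing.assert_allclose(c_ps.cap_total, c_cf.cap_total, rtol=0.02)

    def test_cube_curve_lower_capacitance_than_flat(self, teng_cfg):
        import dataclasses

        gaps = default_gap_grid(n=11)
        flat = build_curve(teng_cfg, gaps, method="poisson_2d",
                           cells_per_layer=12)
        cube = build_curve(
            dataclasses.replace(teng_cfg, pattern=MicropatternSpec(shape="cube")),
            gaps, method="poisson_2d", cells_per_layer=12,
        )
        sel = gaps > 0
        assert np.all(cube.cap_total[sel] < flat.cap_total[sel])
        assert np.all(cube.voc[sel] > flat.voc[sel])

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            TENGCurve(gaps=[0.0, 1e-4], voc=[1.0, 0.5],  # decreasing voc
                      cap_total=[1e-9, 5e-10], plate_area=15e-5,
                      provenance="fixture_table")
        with pytest.raises(ValueError):
            TENGCurve(gaps=[1e-4, 0.0], voc=[0.0, 1.0],  # unsorted gaps
                      cap_total=[1e-9, 5e-10], plate_area=15e-5,
                      provenance="fixture_table")


class TestQueries:
    def test_node_identity(self, flat_curve):
        k = 7
        voc, cpa, _, _ = query_curve(flat_curve, flat_curve.gaps[k])
        assert voc == pytest.approx(flat_curve.voc[k], rel=1e-14)
        assert cpa == pytest.approx(flat_curve.cap_per_area[k], rel=1e-14)

    def test_linear_voc_slope_is_sigma_over_eps0(self, flat_curve, teng_cfg):
        xs = np.linspace(flat_curve.gaps[1], flat_curve.gaps[-2], 17)
        for x in xs:
            _, _, dvoc, _ = query_curve(flat_curve, float(x))
            assert dvoc == pytest.approx(teng_cfg.sigma / EPS0, rel=1e-9)

    def test_constant_capacitance_derivative_zero(self):
        from teng_neuron import fixture_curve

        curve = fixture_curve("linear_voc_const_C")
        _, _, _, dcap = query_curve(curve, 2.3e-4)
        assert dcap == 0.0

    def test_out_of_range_rejected(self, flat_curve):
        with pytest.raises(ValueError):
            query_curve(flat_curve, flat_curve.gaps[-1] * 1.01)
        with pytest.raises(ValueError):
            query_curve(flat_curve, -1e-9)
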