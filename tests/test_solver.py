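"""Finite-volume conduction solver: assembly, oracles, conservation,
and the structural properties of the two-terminal linear problem."""

import numpy as np
import pytest

import emdasim as em
from emdasim.phantom import SIGMA_ELECTRODE_S_PER_M
from emdasim.solver import SolverError, TopologyError

from conftest import make_concentric_spheres, make_slab, sphere_profile_error

MM = 1e-3


def two_block_terminals(grid, sigma=1.0, excluded=None):
    """Terminals on the two x-end planes of an arbitrary grid."""
    if excluded is None:
        excluded = np.zeros(grid.shape, dtype=bool)
    cond = em.ConductivityVolume(grid=grid, sigma=sigma * np.ones(grid.shape),
                                 excluded=excluded)
    src = np.zeros(grid.shape, dtype=bool)
    src[0] = True
    ret = np.zeros(grid.shape, dtype=bool)
    ret[-1] = True
    terms = em.TerminalSet(
        terminals=[em.Terminal("a", src, "source"), em.Terminal("b", ret, "return")])
    return cond, terms


class TestAssembly:
    def test_two_voxel_face_is_harmonic_mean(self):
        """Single face conductance = (A/h) * 2 s1 s2 / (s1 + s2)."""
        grid = em.VoxelGrid(shape=(1, 1, 4), spacing=(2.0, 3.0, 5.0))
        s1, s2 = 0.2, 0.02
        sigma = np.array([SIGMA_ELECTRODE_S_PER_M, s1, s2,
                          SIGMA_ELECTRODE_S_PER_M]).reshape(1, 1, 4)
        cond = em.ConductivityVolume(grid=grid, sigma=sigma,
                                     excluded=np.zeros(grid.shape, dtype=bool))
        src = np.zeros(grid.shape, dtype=bool)
        src[0, 0, 0] = True
        ret = np.zeros(grid.shape, dtype=bool)
        ret[0, 0, 3] = True
        terms = em.TerminalSet(terminals=[em.Terminal("a", src, "source"),
                                          em.Terminal("b", ret, "return")])
        system = em.assemble_system(cond, terms)
        area = (2.0 * MM) * (3.0 * MM)
        h = 5.0 * MM
        expected = (area / h) * 2 * s1 * s2 / (s1 + s2)
        # off-diagonal entry between the two interior voxels
        assert system.matrix[0, 1] == pytest.approx(-expected, rel=1e-12)

    def test_homogeneous_column_second_difference(self):
        """Interior rows reduce to sigma*A/h * [-1, 2, -1]."""
        sigma = 0.5
        cond, terms = make_slab(n_layers=6, sigma_layers=sigma, spacing_mm=10.0,
                                nx=1, ny=1)
        system = em.assemble_system(cond, terms)
        A = system.matrix.toarray()
        g = sigma * (10 * MM) ** 2 / (10 * MM)
        for row in range(1, 5):  # away from the plate-adjacent rows
            assert A[row, row] == pytest.approx(2 * g, rel=1e-12)
            assert A[row, row - 1] == pytest.approx(-g, rel=1e-12)
            assert A[row, row + 1] == pytest.approx(-g, rel=1e-12)

    def test_row_sums_zero(self):
        """Operator rows sum to zero (pure conductance network)."""
        rng = np.random.default_rng(11)
        grid = em.VoxelGrid(shape=(6, 6, 6), spacing=(1, 1, 1))
        cond = em.ConductivityVolume(grid=grid,
                                     sigma=rng.uniform(0.01, 2.0, grid.shape),
                                     excluded=np.zeros(grid.shape, dtype=bool))
        _, terms = two_block_terminals(grid)
        terms_cond = em.ConductivityVolume(grid=grid, sigma=cond.sigma,
                                           excluded=cond.excluded)
        system = em.assemble_system(terms_cond, terms)
        rowsum = np.asarray(system.matrix.sum(axis=1)).ravel()
        assert np.allclose(rowsum, 0.0, atol=1e-15)

    def test_disconnected_terminals_raise(self):
        grid = em.VoxelGrid(shape=(7, 3, 3), spacing=(1, 1, 1))
        excluded = np.zeros(grid.shape, dtype=bool)
        excluded[3] = True  # insulating wall splits the domain
        cond, terms = two_block_terminals(grid, excluded=excluded)
        with pytest.raises(TopologyError):
            em.assemble_system(cond, terms)


class TestSlabOracles:
    def test_homogeneous_slab_ohms_law(self):
        """L=0.1 m, sigma=0.2, A=0.01 m^2, I=20 mA -> V=1.0 V, |E|=10 V/m."""
        cond, terms = make_slab(n_layers=10, sigma_layers=0.2, spacing_mm=10.0)
        system = em.assemble_system(cond, terms)
        sol = em.solve_potential(system, cond, terms, tol=1e-10)
        assert sol.terminal_report["voltage_between_terminals_V"] == pytest.approx(1.0, rel=1e-6)
        emag = sol.E_mag[sol.valid]
        assert np.allclose(emag, 10.0, rtol=1e-6)

    def test_two_layer_slab_series_resistance(self):
        """Equal layers of 0.2 and 0.02 S/m: R = R1 + R2, field ratio 1:10."""
        cond, terms = make_slab(n_layers=10, sigma_layers=0.1, spacing_mm=10.0)
        cond.sigma[:, :, 1:6] = 0.2
        cond.sigma[:, :, 6:11] = 0.02
        system = em.assemble_system(cond, terms)
        sol = em.solve_potential(system, cond, terms, tol=1e-10)
        area = 0.01
        r_expected = 0.05 / (0.2 * area) + 0.05 / (0.02 * area)
        v = sol.terminal_report["voltage_between_terminals_V"]
        assert v == pytest.approx(terms.injected_current_A * r_expected, rel=1e-6)
        e1 = sol.E_mag[5, 5, 2]  # inside high-sigma layer, away from interface
        e2 = sol.E_mag[5, 5, 9]
        assert e2 / e1 == pytest.approx(10.0, rel=1e-6)


class TestSphereOracle:
    def test_profile_within_2pct_at_1mm(self):
        """Voxel solve matches the analytic 1/r potential within 2%."""
        assert sphere_profile_error(1.0) < 0.02

    def test_error_decreases_under_refinement(self):
        assert sphere_profile_error(1.0) < sphere_profile_error(2.0)

    def test_radial_flux_conserved(self):
        """|J| * 4 pi r^2 recovers the injected current within 3% per shell."""
        cond, terms, r = make_concentric_spheres(1.0)
        system = em.assemble_system(cond, terms)
        sol = em.solve_potential(system, cond, terms, tol=1e-8)
        I = terms.injected_current_A
        for r0 in np.arange(10.0, 41.0, 5.0):
            m = (r >= r0) & (r < r0 + 1.0) & sol.valid
            rm = np.mean(r[m]) * MM
            flux = np.nanmean(sol.J_mag[m]) * 4 * np.pi * rm**2
            assert flux == pytest.approx(I, rel=0.03), r0


class TestFields:
    def test_linear_ramp_constant_field(self):
        """E of a linear potential is exact everywhere, including next to
        boundaries (one-sided differences)."""
        grid = em.VoxelGrid(shape=(6, 5, 7), spacing=(1, 2, 4))
        cond = em.ConductivityVolume(grid=grid, sigma=np.full(grid.shape, 0.3),
                                     excluded=np.zeros(grid.shape, dtype=bool))
        x, y, z = grid.coordinate_arrays()
        V = 2.0 * (x * MM) - 1.0 * (y * MM) + 0.5 * (z * MM)
        V = V + np.zeros(grid.shape)
        E, J, valid = em.compute_fields(V, cond)
        assert valid.all()
        assert np.allclose(E[..., 0], -2.0)
        assert np.allclose(E[..., 1], 1.0)
        assert np.allclose(E[..., 2], -0.5)
        assert np.allclose(np.linalg.norm(J, axis=-1),
                           0.3 * np.linalg.norm(E, axis=-1))


class TestConservation:
    def test_default_solve_conserves_current(self, default_solution):
        """Net source current equals the configured 20 mA within 0.1%."""
        sol, system = default_solution
        rep = em.check_current_conservation(sol, system)
        assert rep["relative_imbalance_source"] <= 1e-3
        assert rep["relative_imbalance_pair"] <= 1e-3

    def test_imbalance_grows_with_tol(self):
        cond, terms, _ = make_concentric_spheres(2.0)
        system = em.assemble_system(cond, terms)
        divs = []
        for tol in (1e-3, 1e-6, 1e-9):
            sol = em.solve_potential(system, cond, terms, tol=tol)
            divs.append(em.check_current_conservation(sol, system)[
                "max_interior_divergence_rel"])
        assert divs[0] > divs[2]
        assert divs[1] > divs[2]

    def test_interior_divergence_bounded_by_residual(self):
        """max interior divergence <= tol * ||rhs|| of the unit solve."""
        tol = 1e-8
        cond, terms, _ = make_concentric_spheres(2.0)
        system = em.assemble_system(cond, terms)
        sol = em.solve_potential(system, cond, terms, tol=tol)
        rep = em.check_current_conservation(sol, system)
        n = system.n_interior
        rhs = -system.matrix[:n, n:].toarray() @ np.array([1.0, 0.0])
        # divergence of the scaled solve; compare on the unit-solve scale
        k = sol.node_v[system.source_node] - sol.node_v[system.return_node]
        assert rep["max_interior_divergence_A"] / k <= tol * np.linalg.norm(rhs)


class TestProperties:
    def test_linearity_in_current(self):
        """Doubling I scales V, E, J by exactly two."""
        cond, terms, _ = make_concentric_spheres(2.0)
        system = em.assemble_system(cond, terms)
        sol1 = em.solve_potential(system, cond, terms, tol=1e-8)
        import dataclasses
        terms2 = dataclasses.replace(terms, injected_current_A=0.040)
        sol2 = em.solve_potential(system, cond, terms2, tol=1e-8)
        assert np.array_equal(sol2.V[sol2.valid], 2.0 * sol1.V[sol1.valid])
        assert np.array_equal(sol2.E[sol2.valid], 2.0 * sol1.E[sol1.valid])
        assert np.array_equal(sol2.J[sol2.valid], 2.0 * sol1.J[sol1.valid])

    def test_maximum_principle(self):
        """V extrema sit on the terminals: interior strictly between them."""
        rng = np.random.default_rng(3)
        grid = em.VoxelGrid(shape=(8, 8, 8), spacing=(2, 2, 2))
        cond = em.ConductivityVolume(grid=grid,
                                     sigma=rng.uniform(0.01, 2.0, grid.shape),
                                     excluded=np.zeros(grid.shape, dtype=bool))
        _, terms = two_block_terminals(grid)
        cond2 = em.ConductivityVolume(grid=grid, sigma=cond.sigma,
                                      excluded=cond.excluded)
        system = em.assemble_system(cond2, terms)
        sol = em.solve_potential(system, cond2, terms, tol=1e-10)
        v_src = sol.terminal_report["source"]["potential_V"]
        v_ret = sol.terminal_report["return"]["potential_V"]
        interior = sol.V[sol.valid]
        assert interior.max() <= v_src + 1e-9
        assert interior.min() >= v_ret - 1e-9

    def test_reciprocity_under_terminal_swap(self):
        """Swapping source and return negates V up to a constant and leaves
        |E| unchanged at every voxel."""
        rng = np.random.default_rng(5)
        grid = em.VoxelGrid(shape=(8, 6, 6), spacing=(2, 2, 2))
        cond = em.ConductivityVolume(grid=grid,
                                     sigma=rng.uniform(0.05, 1.0, grid.shape),
                                     excluded=np.zeros(grid.shape, dtype=bool))
        src = np.zeros(grid.shape, dtype=bool)
        src[0] = True
        ret = np.zeros(grid.shape, dtype=bool)
        ret[-1] = True
        fwd = em.TerminalSet(terminals=[em.Terminal("a", src, "source"),
                                        em.Terminal("b", ret, "return")])
        rev = em.TerminalSet(terminals=[em.Terminal("b", ret, "source"),
                                        em.Terminal("a", src, "return")])
        s_f = em.assemble_system(cond, fwd)
        s_r = em.assemble_system(cond, rev)
        sol_f = em.solve_potential(s_f, cond, fwd, tol=1e-12)
        sol_r = em.solve_potential(s_r, cond, rev, tol=1e-12)
        vsum = sol_f.V + sol_r.V  # should be the constant terminal voltage
        assert np.nanstd(vsum) < 1e-8 * np.nanmax(np.abs(sol_f.V))
        assert np.allclose(sol_f.E_mag[sol_f.valid], sol_r.E_mag[sol_r.valid],
                           rtol=1e-6, atol=1e-12)

    def test_contact_layer_limits(self):
        """g -> infinity recovers the no-layer solve; finite g raises the
        terminal voltage at fixed current but not the interior fields."""
        import dataclasses

        def solve_with(g, contact):
            cond, terms = make_slab(n_layers=8, sigma_layers=0.2)
            terms = dataclasses.replace(terms, contact_conductance_S_per_m2=g)
            if contact:
                terms.terminals[1].contact_layer = True
            system = em.assemble_system(cond, terms)
            return em.solve_potential(system, cond, terms, tol=1e-12)

        base = solve_with(2.0, contact=False)
        huge = solve_with(1e12, contact=True)
        finite = solve_with(2.0, contact=True)
        v = lambda s: s.terminal_report["voltage_between_terminals_V"]
        assert v(huge) == pytest.approx(v(base), rel=1e-6)
        assert v(finite) > v(base)
        assert np.allclose(finite.E_mag[finite.valid], base.E_mag[base.valid],
                           rtol=1e-6)

    def test_nonconvergence_raises(self):
        """An unreachable iteration cap surfaces as SolverError, not a
        silently unconverged field."""
        import unittest.mock as mock
        from scipy.sparse.linalg import cg as scipy_cg

        cond, terms, _ = make_concentric_spheres(2.0)
        system = em.assemble_system(cond, terms)
        capped = lambda A, b, **kw: scipy_cg(A, b, **{**kw, "maxiter": 2})
        with mock.patch("emdasim.solver.cg", capped):
            with pytest.raises(SolverError, match="converge"):
                em.solve_potential(system, cond, terms, tol=1e-12)
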