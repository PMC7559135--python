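"""Pressure solve, Darcy velocity and the coupled poroelastic loop."""

import numpy as np
import pytest

from cedflow import flow, phantom, tissue
from cedflow.flow import CatheterSpec, build_source_region
from cedflow.grid import ScalarField, VoxelGrid


def _uniform_box_state(n=17, spacing=2.0, beta2=0.0, K=1e-8, csf_planes=True):
    """A rectangular slab of uniform white matter, optionally CSF end planes."""
    grid = VoxelGrid((n, n, n), (spacing,) * 3, origin=(0, 0, 0))
    labels = np.full(grid.shape, int(tissue.TissueClass.WHITE), dtype=np.int8)
    if csf_planes:
        labels[0, :, :] = int(tissue.TissueClass.CSF)
        labels[-1, :, :] = int(tissue.TissueClass.CSF)
    tmap = tissue.TissueClassMap(grid, labels)
    par = tmap.parenchyma_mask
    phi = np.where(par, 0.2, 1.0)
    return tissue.HydraulicState(
        grid=grid,
        phi0=phi.copy(),
        phi=phi.copy(),
        K=np.where(par, K, 0.0),
        cap_conductance=np.where(par, beta2, 0.0),
        parenchyma_mask=par,
        csf_mask=tmap.csf_mask,
    )


class TestSourceRegion:
    def test_point_source_single_voxel(self):
        grid = VoxelGrid((9, 9, 9), (2.0, 2.0, 2.0))
        par = np.ones(grid.shape, dtype=bool)
        cath = CatheterSpec(tip=(8.0, 8.0, 8.0), backflow_length=0.0, flow_rate=0.5)
        src = build_source_region(cath, grid, par)
        assert len(src.voxels) == 1
        assert tuple(src.voxels[0]) == (4, 4, 4)
        assert src.weights[0] == 1.0
        assert src.total_flux == pytest.approx(0.5 * 1000 / 3600)

    def test_axis_aligned_segment_weights(self):
        # a 2-spacing segment starting at a voxel center crosses two boundary
        # planes: lengths 1/2, 1, 1/2 voxel in the three traversed voxels
        grid = VoxelGrid((9, 9, 9), (2.0, 2.0, 2.0))
        par = np.ones(grid.shape, dtype=bool)
        cath = CatheterSpec(
            tip=(8.0, 8.0, 8.0), direction=(1, 0, 0), backflow_length=4.0
        )
        src = build_source_region(cath, grid, par)
        order = np.argsort(src.voxels[:, 0])
        assert [tuple(v) for v in src.voxels[order]] == [(4, 4, 4), (5, 4, 4), (6, 4, 4)]
        assert src.weights[order] == pytest.approx([0.25, 0.5, 0.25])

    def test_oblique_segment_weights_sum_to_one(self):
        grid = VoxelGrid((9, 9, 9), (2.0, 2.0, 2.0))
        par = np.ones(grid.shape, dtype=bool)
        cath = CatheterSpec(
            tip=(8.0, 8.0, 8.0), direction=(1, 1, 0.3), backflow_length=5.0
        )
        src = build_source_region(cath, grid, par)
        assert src.weights.sum() == pytest.approx(1.0)

    def test_tip_in_csf_rejected(self):
        grid = VoxelGrid((9, 9, 9), (2.0, 2.0, 2.0))
        par = np.ones(grid.shape, dtype=bool)
        par[4, 4, 4] = False
        cath = CatheterSpec(tip=(8.0, 8.0, 8.0), backflow_length=0.0)
        with pytest.raises(ValueError, match=r"\(4, 4, 4\)"):
            build_source_region(cath, grid, par)


class TestSolvePressure:
    def test_zero_source_gives_zero(self):
        hyd = _uniform_box_state()
        p, diag = flow.solve_pressure(hyd, np.zeros(hyd.grid.shape))
        assert np.all(p.values == 0.0)
        assert diag.conservation_error == 0.0

    def test_mirror_symmetry(self):
        hyd = _uniform_box_state(n=15)
        q = np.zeros(hyd.grid.shape)
        q[7, 7, 7] = 0.1  # center: symmetric under y/z mirror
        p, _ = flow.solve_pressure(hyd, q)
        assert np.allclose(p.values, p.values[:, ::-1, :], atol=1e-10)
        assert np.allclose(p.values, p.values[:, :, ::-1], atol=1e-10)

    def test_linearity_in_flux(self):
        hyd = _uniform_box_state(n=13)
        q = np.zeros(hyd.grid.shape)
        q[6, 6, 6] = 0.05
        p1, _ = flow.solve_pressure(hyd, q)
        p2, _ = flow.solve_pressure(hyd, 2 * q)
        assert np.allclose(p2.values, 2 * p1.values, rtol=1e-8, atol=1e-12)
        assert np.all(p2.values >= p1.values - 1e-12)

    def test_conservation(self):
        hyd = _uniform_box_state(n=13, beta2=1e-7)
        q = np.zeros(hyd.grid.shape)
        q[6, 6, 6] = 0.05
        _, diag = flow.solve_pressure(hyd, q)
        assert diag.conservation_error < 1e-6
        assert diag.capillary_loss > 0 and diag.csf_outflux > 0

    def test_maximum_principle_at_source(self):
        hyd = _uniform_box_state(n=13, beta2=0.0)
        q = np.zeros(hyd.grid.shape)
        q[3, 8, 5] = 0.05
        p, _ = flow.solve_pressure(hyd, q)
        assert np.unravel_index(np.argmax(p.values), p.values.shape) == (3, 8, 5)

    def test_singular_without_anchor(self):
        hyd = _uniform_box_state(beta2=0.0, csf_planes=False)
        hyd.csf_mask[:] = False
        q = np.zeros(hyd.grid.shape)
        q[5, 5, 5] = 0.1
        with pytest.raises(ValueError, match="anchor|undetermined"):
            flow.solve_pressure(hyd, q)

    def test_point_source_analytic_oracle(self, uniform_sphere):
        # p(r) = Q/(4 pi K) (1/r - 1/R) inside a uniform sphere with a
        # grounded CSF shell; mid-radius voxels must agree within 5%
        hyd, grid, center = uniform_sphere
        Q = 0.5 * 1000 / 3600
        q = np.zeros(grid.shape)
        q[center] = Q
        p, diag = flow.solve_pressure(hyd, q)
        K = hyd.K[hyd.parenchyma_mask].max()
        R = 56.0  # inner radius of the CSF shell
        X, Y, Z = grid.coordinate_arrays()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        mid = (r > 10.0) & (r < 0.6 * R) & hyd.parenchyma_mask
        analytic = Q / (4 * np.pi * K) * (1.0 / r[mid] - 1.0 / R)
        rel = np.abs(p.values[mid] - analytic) / analytic
        assert np.median(rel) < 0.05
        assert diag.conservation_error < 1e-6


class TestDarcyVelocity:
    def test_constant_pressure_zero_velocity(self):
        hyd = _uniform_box_state()
        p = ScalarField(hyd.grid, np.where(hyd.parenchyma_mask, 5.0, 0.0))
        v = flow.darcy_velocity(p, hyd)
        interior = hyd.parenchyma_mask.copy()
        interior[[1, -2], :, :] = False  # CSF-adjacent planes see the jump
        assert np.allclose(v.values[:, interior], 0.0)

    def test_linear_pressure_exact_gradient(self):
        hyd = _uniform_box_state(csf_planes=False)
        hyd.cap_conductance[:] = 1e-7  # anchor so state is self-consistent
        X, _, _ = hyd.grid.coordinate_arrays()
        slope = 3.0
        p = ScalarField(hyd.grid, slope * X)
        v = flow.darcy_velocity(p, hyd)
        interior = np.zeros(hyd.grid.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.allclose(v.values[0][interior], -1e-8 * slope, rtol=1e-10)
        assert np.allclose(v.values[1][interior], 0.0)
        assert np.allclose(v.values[2][interior], 0.0)


class TestPoroelasticLoop:
    def test_rigid_tissue_single_iteration(self):
        hyd = _uniform_box_state(n=13, beta2=1e-7)
        alpha = np.full(hyd.grid.shape, 0.99)
        B = np.full(hyd.grid.shape, np.inf)  # rigid: delta phi = 0
        cath = CatheterSpec(tip=(12.0, 12.0, 12.0), backflow_length=0.0, flow_rate=0.5)
        src = build_source_region(cath, hyd.grid, hyd.parenchyma_mask)
        sol = flow.iterate_poroelastic(hyd, [src], alpha, B)
        assert sol.iterations == 1
        assert sol.converged
        assert np.allclose(sol.hydraulic.phi[hyd.parenchyma_mask], 0.2)

    def test_phantom_converges_quickly(self, compact_flow):
        assert compact_flow.converged
        assert compact_flow.iterations <= 6
        assert compact_flow.residual_history[-1] < 1e-3

    def test_phantom_phi_bounds(self, compact_flow, compact_hydraulic):
        par = compact_hydraulic.parenchyma_mask
        phi = compact_flow.hydraulic.phi[par]
        assert np.all(phi < 1.0)
        assert np.all(phi >= compact_hydraulic.phi0[par] - 1e-9)

    def test_phantom_expansion_in_white_matter(self, compact_flow, compact_phantom):
        # white matter near the source must expand substantially; gray rim
        # far from the source should barely move
        white = compact_phantom.tissue.mask(tissue.TissueClass.WHITE)
        gray = compact_phantom.tissue.mask(tissue.TissueClass.GRAY)
        phi = compact_flow.hydraulic.phi
        assert phi[white].max() > 0.4
        assert phi[gray].max() < 0.35

    def test_phantom_conservation(self, compact_flow):
        assert compact_flow.diagnostics.conservation_error < 1e-6

    def test_pressure_zero_on_csf(self, compact_flow, compact_hydraulic):
        assert np.all(compact_flow.pressure.values[compact_hydraulic.csf_mask] == 0.0)
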