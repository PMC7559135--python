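"""Solute transport: analytic oracles, binding kinetics, mass accounting."""

import numpy as np
import pytest

from cedflow import flow, phantom, tissue, transport
from cedflow.flow import CatheterSpec, build_source_region
from cedflow.grid import VoxelGrid
from cedflow.transport import (
    BindingParams,
    ConcentrationState,
    InfusionProtocol,
    TransportOperators,
    TransportParams,
    drug_diffusivity,
    make_bc,
    run_infusion,
    step_binding,
    step_transport,
)


def _quiescent_flow(n=21, spacing=1.0, phi=0.2):
    """Zero-velocity flow solution on a uniform box with CSF end planes."""
    grid = VoxelGrid((n, n, n), (spacing,) * 3, origin=(0, 0, 0))
    labels = np.full(grid.shape, int(tissue.TissueClass.WHITE), dtype=np.int8)
    labels[0, :, :] = int(tissue.TissueClass.CSF)
    labels[-1, :, :] = int(tissue.TissueClass.CSF)
    tmap = tissue.TissueClassMap(grid, labels)
    par = tmap.parenchyma_mask
    hyd = tissue.HydraulicState(
        grid=grid,
        phi0=np.where(par, phi, 1.0),
        phi=np.where(par, phi, 1.0),
        K=np.where(par, 1e-8, 0.0),
        cap_conductance=np.zeros(grid.shape),
        parenchyma_mask=par,
        csf_mask=tmap.csf_mask,
    )
    alpha = np.full(grid.shape, 0.99)
    B = np.full(grid.shape, np.inf)
    return flow.iterate_poroelastic(hyd, [], alpha, B), grid, hyd


class TestDrugDiffusivity:
    def test_identity_at_ratio_one(self):
        assert drug_diffusivity(1e-3, 1.0) == 1e-3

    def test_cuberoot_scaling(self):
        assert drug_diffusivity(1e-3, 1000.0) == pytest.approx(1e-4)

    def test_gd_vs_hsa(self):
        d_gd = drug_diffusivity(1e-3, 938.0 / 18.0)
        d_hsa = drug_diffusivity(1e-3, 66000.0 / 18.0)
        assert d_gd / d_hsa == pytest.approx((66000.0 / 938.0) ** (1 / 3), rel=1e-12)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            drug_diffusivity(1e-3, 0.5)


class TestStepTransport:
    def test_stays_zero_without_source(self):
        sol, grid, hyd = _quiescent_flow()
        params = TransportParams(D=1e-4, loss_rate=1e-6)
        bc = make_bc([], grid, hyd.csf_mask)
        state = ConcentrationState(np.zeros(grid.shape), np.zeros(grid.shape))
        ops = TransportOperators(sol, params)
        state = step_transport(state, sol, params, bc, ops.dt_max, ops=ops)
        assert np.all(state.c == 0.0) and np.all(state.b == 0.0)

    def test_exponential_clearance(self):
        # v = 0, D = 0: d(phi c)/dt = -k c  =>  c(t) = c0 exp(-k t / phi)
        phi, k = 0.2, 1e-4
        sol, grid, hyd = _quiescent_flow(phi=phi)
        params = TransportParams(D=0.0, loss_rate=np.where(hyd.parenchyma_mask, k, 0.0))
        bc = make_bc([], grid, hyd.csf_mask)
        c0 = np.where(hyd.parenchyma_mask, 1.0, 0.0)
        state = ConcentrationState(c0.copy(), np.zeros(grid.shape))
        ops = TransportOperators(sol, params)
        t_end = phi / k  # k t / phi = 1
        nstep = int(np.ceil(t_end / ops.dt_max))
        dt = t_end / nstep
        ledger = transport.MassLedger()
        for _ in range(nstep):
            state = step_transport(state, sol, params, bc, dt, ops=ops, ledger=ledger)
        expected = np.exp(-1.0)
        inner = hyd.parenchyma_mask.copy()
        inner[[1, -2], :, :] = False  # skip CSF-adjacent cells (Dirichlet c=0)
        assert np.abs(state.c[inner] / expected - 1).max() < 1e-3
        assert ledger.capillary_lost > 0

    def test_gaussian_diffusion_second_moment(self):
        # v = 0, k = 0, uniform phi: point mass spreads with variance 2 D t
        phi, D = 0.2, 2e-3
        sol, grid, hyd = _quiescent_flow(n=31, spacing=1.0, phi=phi)
        params = TransportParams(D=np.where(hyd.parenchyma_mask, D, 0.0), loss_rate=0.0)
        bc = make_bc([], grid, hyd.csf_mask)
        c = np.zeros(grid.shape)
        c[15, 15, 15] = 1.0
        state = ConcentrationState(c, np.zeros(grid.shape))
        ops = TransportOperators(sol, params)
        t_end = 4000.0
        nstep = int(np.ceil(t_end / ops.dt_max))
        dt = t_end / nstep
        for _ in range(nstep):
            state = step_transport(state, sol, params, bc, dt, ops=ops)
        X, Y, Z = grid.coordinate_arrays()
        m = state.c.sum()
        ybar = (state.c * Y).sum() / m
        var = (state.c * (Y - ybar) ** 2).sum() / m
        # one initial-voxel variance correction: the point mass has width h^2/12
        expected = 2 * D * t_end + grid.spacing[1] ** 2 / 12.0
        assert var == pytest.approx(expected, rel=0.02)

    def test_dt_bound_enforced(self):
        sol, grid, hyd = _quiescent_flow()
        params = TransportParams(D=1e-3, loss_rate=0.0)
        bc = make_bc([], grid, hyd.csf_mask)
        ops = TransportOperators(sol, params)
        state = ConcentrationState(np.zeros(grid.shape), np.zeros(grid.shape))
        with pytest.raises(ValueError, match="admissible dt"):
            step_transport(state, sol, params, bc, 10 * ops.dt_max, ops=ops)


class TestBinding:
    def test_unbinding_decay(self):
        params = BindingParams(k1=0.0, k2=1e-3, kirr=5e-4, B_sites=1.0)
        b = np.array([1.0])
        c = np.array([0.0])
        dt, t_end = 1.0, 2000.0
        for _ in range(int(t_end / dt)):
            c, b, _ = step_binding(c, b, params, dt)
        assert b[0] == pytest.approx(np.exp(-(1e-3 + 5e-4) * t_end), rel=1e-2)

    def test_equilibrium_with_held_concentration(self):
        params = BindingParams(k1=1e-3, k2=2e-3, kirr=0.0, B_sites=1.0)
        c_held = 4.0
        b = np.array([0.0])
        for _ in range(20000):
            _, b, _ = step_binding(np.array([c_held]), b, params, 1.0)
        expected = 1.0 * params.k1 * c_held / (params.k1 * c_held + params.k2)
        assert b[0] == pytest.approx(expected, rel=1e-3)

    def test_no_sites_no_binding(self):
        params = BindingParams(k1=1e-3, k2=1e-3, kirr=0.0, B_sites=0.0)
        c, b, internal = step_binding(np.array([2.0]), np.array([0.0]), params, 1.0)
        assert b[0] == 0.0 and c[0] == 2.0 and internal[0] == 0.0

    def test_bound_never_exceeds_sites(self):
        params = BindingParams(k1=1.0, k2=0.0, kirr=0.0, B_sites=1.0)
        b = np.array([0.9])
        for _ in range(100):
            _, b, _ = step_binding(np.array([10.0]), b, params, 0.05)
        assert b[0] <= 1.0


@pytest.fixture(scope="module")
def gd_params(compact_phantom, compact_hydraulic):
    from cedflow import dce

    loss = dce.ktrans_to_loss_rate(
        compact_phantom.ktrans.values,
        molecule="gd_dtpa",
        coverage_mask=compact_phantom.dce_coverage,
    )
    loss = np.where(compact_hydraulic.parenchyma_mask, loss, 0.0)
    return TransportParams(D=2.1e-4, loss_rate=loss)


class TestInfusionRuns:

    def test_source_and_csf_bc(self, compact_flow, gd_params, compact_phantom):
        grid = compact_phantom.grid
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=0.5,
            snapshot_times=[0.5],
        )
        res = run_infusion(protocol, compact_flow, gd_params, grid)
        src_mask = compact_flow.sources[0].mask(grid)
        assert np.allclose(res.final.c[src_mask], 1.0)
        assert np.all(res.final.c[compact_phantom.csf_mask] == 0.0)
        assert np.all(res.final.c >= 0.0)

    def test_mass_ledger_closes(self, compact_flow, gd_params, compact_phantom):
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=6.0,
            snapshot_times=[6.0],
        )
        res = run_infusion(protocol, compact_flow, gd_params, compact_phantom.grid)
        assert res.ledger.closure_error < 0.005
        assert res.ledger.infused > 0
        # CSF tally is cumulative, hence non-decreasing over the history
        csf = [h["csf_lost"] for h in res.ledger_history]
        assert all(b >= a - 1e-12 for a, b in zip(csf, csf[1:]))

    def test_vd_monotone_growth_uniform_loss(
        self, compact_flow, gd_params, compact_phantom
    ):
        from cedflow import quantify

        grid = compact_phantom.grid
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=8.0,
            snapshot_times=[4.0, 8.0],
        )
        res = run_infusion(
            protocol, compact_flow, gd_params, grid, uniform_loss_override=1e-6
        )
        vds = [
            quantify.compute_vd(s.c, 0.1, grid).Vd_mL for s in res.snapshots
        ]
        assert vds[1] >= vds[0] > 0

    def test_advective_transport_is_size_independent(
        self, compact_flow, compact_phantom, compact_hydraulic
    ):
        # the advection operator carries no molecular-size dependence: with
        # diffusion disabled and no clearance, a small molecule and an
        # albumin-sized one produce identical concentration fields
        grid = compact_phantom.grid
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=6.0,
            snapshot_times=[6.0],
        )
        fields = []
        for ratio in (938.0 / 18.0, 66000.0 / 18.0):
            params = TransportParams(
                D=np.where(
                    compact_hydraulic.parenchyma_mask,
                    drug_diffusivity(7.7e-4, ratio),
                    0.0,
                ),
                loss_rate=0.0,
            )
            res = run_infusion(
                protocol, compact_flow, params, grid, diffusion_off=True
            )
            fields.append(res.final.c)
        assert np.array_equal(fields[0], fields[1])

    def test_diffusion_only_enlarges_the_distribution(
        self, compact_flow, compact_phantom, compact_hydraulic
    ):
        # disabling diffusion can only shrink Vd (advection unchanged), and
        # for albumin-scale D the advective contribution must dominate
        from cedflow import quantify

        grid = compact_phantom.grid
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=6.0,
            snapshot_times=[6.0],
        )
        hsa_D = drug_diffusivity(7.7e-4, 66000.0 / 18.0)
        params = TransportParams(
            D=np.where(compact_hydraulic.parenchyma_mask, hsa_D, 0.0),
            loss_rate=np.where(compact_hydraulic.parenchyma_mask, 1e-6, 0.0),
        )
        vd = {}
        for off in (False, True):
            res = run_infusion(protocol, compact_flow, params, grid, diffusion_off=off)
            vd[off] = quantify.compute_vd(res.final.c, 0.1, grid).Vd_mL
        assert vd[True] <= vd[False]
        assert vd[True] > 0.5 * vd[False]

    def test_elevated_tumor_loss_reduces_coverage(
        self, compact_flow, gd_params, compact_phantom
    ):
        from cedflow import quantify

        grid = compact_phantom.grid
        protocol = InfusionProtocol(
            catheters=[phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))],
            duration=8.0,
            snapshot_times=[8.0],
        )
        cov = {}
        for name, override in (("elevated", None), ("uniform", 1e-6)):
            res = run_infusion(
                protocol, compact_flow, gd_params, grid, uniform_loss_override=override
            )
            cov[name] = quantify.compute_vd(
                res.final.c, 0.1, grid, tumor_mask=compact_phantom.tumor_mask
            ).tumor_coverage
        assert cov["elevated"] < cov["uniform"]
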