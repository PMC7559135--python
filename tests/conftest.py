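import numpy as np
import pytest

from cedflow import flow, phantom, tissue


@pytest.fixture(scope="session")
def compact_phantom():
    return phantom.make_phantom(phantom.PhantomSpec.compact(seed=1))


@pytest.fixture(scope="session")
def compact_hydraulic(compact_phantom):
    return tissue.build_hydraulic_state(compact_phantom.tissue, compact_phantom.adc)


@pytest.fixture(scope="session")
def compact_flow(compact_phantom, compact_hydraulic):
    """Converged poroelastic flow for the default compact phantom (expensive)."""
    ph = compact_phantom
    alpha, B = tissue.build_poroelastic_fields(ph.tissue)
    cath = phantom.default_catheter(phantom.PhantomSpec.compact(seed=1))
    src = flow.build_source_region(cath, ph.grid, compact_hydraulic.parenchyma_mask)
    return flow.iterate_poroelastic(compact_hydraulic, [src], alpha, B)


@pytest.fixture(scope="session")
def uniform_sphere():
    """Rigid uniform-K sphere with a CSF shell: the analytic point-source setup.

    Returns (hydraulic state, grid, center index).  ADC is uniform at the
    normal-brain anchor so phi0 = 0.2 everywhere inside; no tumor, no
    ventricle (they are placed but overwritten below by relabelling).
    """
    spec = phantom.PhantomSpec(seed=0)
    ph = phantom.make_phantom(spec)
    labels = ph.tissue.labels.copy()
    # homogenise: tumor and ventricle become white matter
    labels[labels == int(tissue.TissueClass.TUMOR_ENHANCING)] = int(tissue.TissueClass.WHITE)
    grid = ph.grid
    X, Y, Z = grid.coordinate_arrays()
    r = np.sqrt(X**2 + Y**2 + Z**2)
    inner = r <= spec.brain_radius - spec.csf_shell_thickness
    labels[inner] = int(tissue.TissueClass.WHITE)
    tmap = tissue.TissueClassMap(grid, labels)
    adc = tissue.ScalarField(
        grid,
        np.where(tmap.parenchyma_mask, 0.77e-5, np.where(tmap.csf_mask, 2.7e-5, 0.0)),
        units="cm^2/s",
    )
    hyd = tissue.build_hydraulic_state(tmap, adc)
    hyd.cap_conductance[:] = 0.0  # beta^2 = 0: pure Poisson with CSF anchor
    center = tuple(int(round(i)) for i in grid.world_to_index((0.0, 0.0, 0.0))[0])
    return hyd, grid, center
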