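"""Per-voxel hydraulic and poroelastic tissue properties.

This module turns imaging-derived tissue maps into the coefficient fields
of the fluid problem:

* an apparent-diffusion-coefficient (ADC) map is converted into a baseline
  interstitial volume ("pore") fraction phi0, anchored at normal brain
  (ADC 0.77e-5 cm^2/s -> phi 0.2) and CSF (ADC >= 2.6e-5 cm^2/s -> phi 1);
* hydraulic conductivity follows a Kozeny-Carman law in phi, so a threefold
  pore-fraction increase amplifies conductivity by more than two orders of
  magnitude — the dominant nonlinearity of convection-enhanced delivery;
* linear poroelasticity (Biot-Willis coefficient alpha, drained bulk
  modulus B) relates the infusion-induced pressure rise to the pore-fraction
  increase, d(phi)/dp = (alpha - phi)(1 - phi)/B, integrated in closed form;
* capillary density (S/V, hence the capillary conductance beta^2 = Lp*S/V)
  shrinks with the solid fraction as tissue expands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .grid import ScalarField, VoxelGrid

__all__ = [
    "TissueClass",
    "TissueClassMap",
    "PoroelasticParams",
    "HydraulicState",
    "TissueConfig",
    "adc_to_pore_fraction",
    "kozeny_carman",
    "poisson_ratio",
    "pore_fraction_increment",
    "pore_fraction_increment_general",
    "integrate_pore_fraction",
    "blend_poroelastic",
    "scale_capillary_density",
    "build_hydraulic_state",
    "build_poroelastic_fields",
]

# ADC anchors (cm^2/s) and pore-fraction anchors
ADC_NORMAL_BRAIN = 0.77e-5  # normal parenchyma -> phi 0.2
ADC_CSF = 2.6e-5  # at/above this -> CSF, phi 1.0
PHI_NORMAL = 0.2
PHI_MIN = 0.05  # numerical floor; avoids K -> 0 in near-zero-ADC voxels
PHI_CEILING = 1.0 - 1e-9


class TissueClass(IntEnum):
    BACKGROUND = 0
    CSF = 1
    GRAY = 2
    WHITE = 3
    TUMOR_ENHANCING = 4


@dataclass
class TissueClassMap:
    """Per-voxel categorical tissue labels plus an optional white-matter fraction."""

    grid: VoxelGrid
    labels: np.ndarray
    white_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        valid = np.isin(labels, [int(t) for t in TissueClass])
        if not valid.all():
            raise ValueError("unknown tissue label present")
        self.labels = labels.astype(np.int8)
        if self.white_fraction is not None:
            wf = np.asarray(self.white_fraction, dtype=float)
            if wf.shape != self.grid.shape:
                raise ValueError("white_fraction shape does not match grid")
            inside = np.isin(self.labels, [TissueClass.GRAY, TissueClass.WHITE])
            if not np.all(np.isfinite(wf[inside])):
                raise ValueError("white_fraction must be finite in gray/white matter")
            if wf[inside].min() < 0 or wf[inside].max() > 1:
                raise ValueError("white_fraction must lie in [0, 1]")
            self.white_fraction = wf

    def mask(self, *classes: TissueClass) -> np.ndarray:
        return np.isin(self.labels, [int(c) for c in classes])

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return self.mask(TissueClass.GRAY, TissueClass.WHITE, TissueClass.TUMOR_ENHANCING)

    @property
    def csf_mask(self) -> np.ndarray:
        return self.mask(TissueClass.CSF)


@dataclass(frozen=True)
class PoroelasticParams:
    """Drained linear-poroelastic constants of a tissue class.

    alpha is the Biot-Willis coefficient (phi <= alpha <= 1), B_drained the
    drained bulk modulus in Pa (0 for a suspension; small in edematous white
    matter), G_shear the shear modulus in Pa.  K_s, if given, is the solid
    constituent bulk modulus and bounds B via 0 <= B <= (1 - phi) K_s.
    """

    alpha: float
    B_drained: float
    G_shear: float = 0.0
    K_s: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.B_drained < 0:
            raise ValueError("B_drained must be >= 0")
        if self.G_shear < 0:
            raise ValueError("G_shear must be >= 0")

    def validate_against(self, phi: float) -> None:
        if not phi <= self.alpha:
            raise ValueError(f"alpha ({self.alpha}) must be >= phi ({phi})")
        if self.K_s is not None and self.B_drained > (1.0 - phi) * self.K_s:
            raise ValueError("B_drained exceeds (1 - phi) * K_s")


@dataclass
class HydraulicState:
    """Coefficients of the fluid problem: phi0, current phi, K, beta^2.

    Units: K in mm^2 Pa^-1 s^-1 (so v [mm/s] = -K grad p [Pa/mm]);
    cap_conductance beta^2 = Lp * S/V in Pa^-1 s^-1.
    """

    grid: VoxelGrid
    phi0: np.ndarray
    phi: np.ndarray
    K: np.ndarray
    cap_conductance: np.ndarray
    parenchyma_mask: np.ndarray
    csf_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phi0", "phi", "K", "cap_conductance"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            setattr(self, name, arr)
        par = self.parenchyma_mask
        if np.any(self.phi[par] <= 0) or np.any(self.phi[par] >= 1):
            raise ValueError("phi must lie in (0, 1) inside parenchyma")
        if np.any(self.K[par] <= 0):
            raise ValueError("K must be positive inside parenchyma")
        if np.any(self.cap_conductance < 0):
            raise ValueError("capillary conductance must be >= 0")

    def copy(self) -> "HydraulicState":
        return HydraulicState(
            self.grid,
            self.phi0.copy(),
            self.phi.copy(),
            self.K.copy(),
            self.cap_conductance.copy(),
            self.parenchyma_mask,
            self.csf_mask,
        )


@dataclass(frozen=True)
class TissueConfig:
    """Defaults for the tissue-property stage (config block ``[tissue]``).

    The poroelastic constants are literature-informed placeholders: white
    matter is chosen suspension-like (small B, alpha near 1) so that a
    0.2 -> 0.6 pore-fraction expansion is reachable at CED-scale pressures,
    while gray matter barely expands.
    """

    adc_normal: float = ADC_NORMAL_BRAIN
    adc_csf: float = ADC_CSF
    phi_normal: float = PHI_NORMAL
    phi_min: float = PHI_MIN
    K_ref: float = 2e-7  # mm^2 / (Pa s) at phi = phi_normal
    beta2_ref: float = 1e-7  # Pa^-1 s^-1, Lp * S/V in unexpanded tissue
    gray: PoroelasticParams = PoroelasticParams(alpha=0.7, B_drained=5000.0, G_shear=1000.0)
    white: PoroelasticParams = PoroelasticParams(alpha=0.99, B_drained=500.0, G_shear=1000.0)
    tumor: PoroelasticParams = PoroelasticParams(alpha=0.7, B_drained=5000.0, G_shear=1000.0)


# ---------------------------------------------------------------------------
# ADC -> pore fraction
# ---------------------------------------------------------------------------


def _adc_spline(adc_normal: float, adc_csf: float, phi_normal: float, phi_min: float):
    # Monotone convex cubic Hermite between the normal-brain and CSF anchors:
    # slope at the lower anchor continues the linear segment below it, slope 0
    # at the CSF anchor where the map plateaus at 1.
    m_low = (phi_normal - phi_min) / adc_normal
    return CubicHermiteSpline(
        [adc_normal, adc_csf], [phi_normal, 1.0], [m_low, 0.0]
    )


def adc_to_pore_fraction(
    adc,
    *,
    adc_normal: float = ADC_NORMAL_BRAIN,
    adc_csf: float = ADC_CSF,
    phi_normal: float = PHI_NORMAL,
    phi_min: float = PHI_MIN,
):
    """Map ADC (cm^2/s) to pore fraction.

    Monotone piecewise map: linear from (0, phi_min) to the normal-brain
    anchor (adc_normal, phi_normal), a monotone cubic to the CSF anchor
    (adc_csf, 1.0), and constant 1.0 above.  Output clamped to
    [phi_min, 1.0].

    Raises
    ------
    ValueError
        If any ADC value is negative.
    """
    adc_arr = np.asarray(adc, dtype=float)
    if np.any(adc_arr < 0):
        raise ValueError("ADC must be non-negative")
    spline = _adc_spline(adc_normal, adc_csf, phi_normal, phi_min)
    m_low = (phi_normal - phi_min) / adc_normal
    phi = np.where(
        adc_arr <= adc_normal,
        phi_min + m_low * adc_arr,
        np.where(adc_arr >= adc_csf, 1.0, spline(np.clip(adc_arr, adc_normal, adc_csf))),
    )
    phi = np.clip(phi, phi_min, 1.0)
    return float(phi) if np.isscalar(adc) else phi


# ---------------------------------------------------------------------------
# Kozeny-Carman conductivity
# ---------------------------------------------------------------------------


def kozeny_carman(phi, phi0, K0):
    """Hydraulic conductivity K(phi) = K0 (phi/phi0)^3 ((1-phi0)/(1-phi))^2.

    Strictly increasing in phi on (0, 1); K(phi0) = K0 exactly.  CSF voxels
    (phi = 1) are handled by boundary conditions, not by this formula.
    """
    phi_arr = np.asarray(phi, dtype=float)
    phi0_arr = np.asarray(phi0, dtype=float)
    K0_arr = np.asarray(K0, dtype=float)
    if np.any(phi_arr >= 1) or np.any(phi_arr <= 0):
        raise ValueError("phi must lie in (0, 1)")
    if np.any(phi0_arr >= 1) or np.any(phi0_arr <= 0):
        raise ValueError("phi0 must lie in (0, 1)")
    if np.any(K0_arr <= 0):
        raise ValueError("K0 must be positive")
    out = K0_arr * (phi_arr / phi0_arr) ** 3 * ((1.0 - phi0_arr) / (1.0 - phi_arr)) ** 2
    return float(out) if np.isscalar(phi) and np.isscalar(phi0) else out


# ---------------------------------------------------------------------------
# Poroelastic pore-fraction response
# ---------------------------------------------------------------------------


def poisson_ratio(params: PoroelasticParams) -> float:
    """Drained Poisson ratio nu = (3B - 2G) / (2 (3B + G))."""
    denom = 3.0 * params.B_drained + params.G_shear
    if denom <= 0:
        raise ValueError("3B + G must be positive")
    return 0.5 * (3.0 * params.B_drained - 2.0 * params.G_shear) / denom


def pore_fraction_increment(phi, dp, params: PoroelasticParams):
    """Differential pore-fraction change for incompressible constituents.

    d(phi) = (alpha - phi)(1 - phi)/B * dp.  This form respects the bounds
    phi <= alpha <= 1.  At B = 0 (suspension limit) the update saturates at
    alpha; callers wanting the finite update should use
    :func:`integrate_pore_fraction`.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0) or np.any(phi_arr >= 1):
        raise ValueError("phi must lie in (0, 1)")
    if params.B_drained == 0:
        raise ValueError(
            "B = 0 is the suspension limit: phi saturates at alpha; "
            "use integrate_pore_fraction for the finite update"
        )
    out = (params.alpha - phi_arr) * (1.0 - phi_arr) / params.B_drained * dp
    return float(out) if np.isscalar(phi) and np.isscalar(dp) else out


def pore_fraction_increment_general(phi, dp, params: PoroelasticParams):
    """General linear-poroelastic increment (cross-check form).

    d(phi) = (alpha - phi) [1 - alpha (1 - (1+nu)/(3(1-nu)))] dp / B with nu
    the drained Poisson ratio.  Coincides with
    :func:`pore_fraction_increment` in the suspension limit B -> 0 with
    alpha -> phi.  Not used in the main loop.
    """
    nu = poisson_ratio(params)
    if nu >= 1.0:
        raise ValueError("Poisson ratio must be < 1")
    if params.B_drained == 0:
        raise ValueError("B = 0 suspension limit: see pore_fraction_increment")
    phi_arr = np.asarray(phi, dtype=float)
    bracket = 1.0 - params.alpha * (1.0 - (1.0 + nu) / (3.0 * (1.0 - nu)))
    out = (params.alpha - phi_arr) * bracket * dp / params.B_drained
    return float(out) if np.isscalar(phi) and np.isscalar(dp) else out


def integrate_pore_fraction(phi0, dp, alpha, B, floor: float = 1e-6):
    """Integrated form of d(phi)/dp = (alpha - phi)(1 - phi)/B.

    Exact solution by partial fractions.  With r = (1 - phi)/(alpha - phi),
    r(p) = r(0) * exp((1 - alpha) dp / B) and phi = (r alpha - 1)/(r - 1);
    for alpha = 1 the closed form is phi = 1 - (1 - phi0)/(1 + (1 - phi0) dp/B).

    The update is monotone in dp and never exceeds alpha (nor 1).  B = 0 is
    the suspension limit: phi jumps to alpha for any dp > 0.  Voxels whose
    baseline phi0 already meets or exceeds alpha are left unchanged.
    All arguments broadcast.
    """
    phi0_a, dp_a, alpha_a, B_a = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (phi0, dp, alpha, B))
    )
    out = np.array(phi0_a, dtype=float, copy=True)

    active = (phi0_a < alpha_a) & (dp_a != 0)
    suspension = active & (B_a == 0)
    out[suspension & (dp_a > 0)] = alpha_a[suspension & (dp_a > 0)]

    finite = active & (B_a > 0)
    near_one = finite & (np.abs(1.0 - alpha_a) < 1e-6)
    general = finite & ~near_one

    if np.any(near_one):
        p0, d, b = phi0_a[near_one], dp_a[near_one], B_a[near_one]
        denom = 1.0 + (1.0 - p0) * d / b
        # negative dp large enough to blow up the denominator -> floor
        phi_new = np.where(denom > 0, 1.0 - (1.0 - p0) / np.maximum(denom, 1e-300), floor)
        out[near_one] = phi_new

    if np.any(general):
        p0, d, a, b = (arr[general] for arr in (phi0_a, dp_a, alpha_a, B_a))
        r0 = (1.0 - p0) / (a - p0)
        expo = np.clip((1.0 - a) * d / b, -700.0, 700.0)
        r = r0 * np.exp(expo)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_new = (r * a - 1.0) / (r - 1.0)
        # r <= 1 is past the finite-pressure blow-down; clamp at the floor
        phi_new = np.where(r <= 1.0 + 1e-12, floor, phi_new)
        out[general] = phi_new

    out = np.minimum(out, np.minimum(alpha_a, PHI_CEILING))
    out = np.maximum(out, floor)
    return float(out) if out.ndim == 0 else out


def blend_poroelastic(
    white_fraction: float, gray: PoroelasticParams, white: PoroelasticParams
) -> PoroelasticParams:
    """Convex combination of gray- and white-matter poroelastic constants."""
    f = float(white_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("white_fraction must lie in [0, 1]")

    def mix(a, b):
        return (1.0 - f) * a + f * b

    ks = None
    if gray.K_s is not None and white.K_s is not None:
        ks = mix(gray.K_s, white.K_s)
    return PoroelasticParams(
        alpha=mix(gray.alpha, white.alpha),
        B_drained=mix(gray.B_drained, white.B_drained),
        G_shear=mix(gray.G_shear, white.G_shear),
        K_s=ks,
    )


def scale_capillary_density(sv0, phi0, phi):
    """Capillary density S/V scaled by the solid-fraction ratio (1-phi)/(1-phi0).

    Tissue expansion dilutes the capillaries proportionally to the solid
    fraction; the scaled S/V is decreasing in phi and vanishes as phi -> 1.
    """
    phi_arr = np.asarray(phi, dtype=float)
    phi0_arr = np.asarray(phi0, dtype=float)
    out = np.asarray(sv0, dtype=float) * (1.0 - phi_arr) / (1.0 - phi0_arr)
    return float(out) if np.isscalar(sv0) and np.isscalar(phi) else out


# ---------------------------------------------------------------------------
# Field assembly
# ---------------------------------------------------------------------------


def build_poroelastic_fields(
    tissue: TissueClassMap, config: TissueConfig = TissueConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (alpha, B) arrays from labels + white-matter fraction.

    Gray/white voxels interpolate linearly with the white fraction (or use
    the pure class values if no fraction map is given); enhancing tumor uses
    its own parameter set.
    """
    shape = tissue.grid.shape
    alpha = np.zeros(shape)
    B = np.zeros(shape)
    gw = tissue.mask(TissueClass.GRAY, TissueClass.WHITE)
    if tissue.white_fraction is not None:
        wf = tissue.white_fraction
    else:
        wf = np.where(tissue.mask(TissueClass.WHITE), 1.0, 0.0)
    alpha[gw] = (1 - wf[gw]) * config.gray.alpha + wf[gw] * config.white.alpha
    B[gw] = (1 - wf[gw]) * config.gray.B_drained + wf[gw] * config.white.B_drained
    tm = tissue.mask(TissueClass.TUMOR_ENHANCING)
    alpha[tm] = config.tumor.alpha
    B[tm] = config.tumor.B_drained
    return alpha, B


def build_hydraulic_state(
    tissue: TissueClassMap,
    adc: ScalarField,
    config: TissueConfig = TissueConfig(),
) -> HydraulicState:
    """Baseline hydraulic state from a tissue map and an ADC volume.

    phi0 comes from the ADC map (clamped below 1 inside parenchyma so the
    Kozeny-Carman formula stays valid); K is the Kozeny-Carman value relative
    to (phi_normal, K_ref); the capillary conductance beta^2 is uniform at its
    reference value in parenchyma and zero elsewhere.
    """
    if not tissue.grid.same_geometry(adc.grid):
        raise ValueError("tissue map and ADC grids differ")
    par = tissue.parenchyma_mask
    csf = tissue.csf_mask
    phi0 = np.full(tissue.grid.shape, np.nan)
    phi0[csf] = 1.0
    phi_par = adc_to_pore_fraction(
        adc.values[par],
        adc_normal=config.adc_normal,
        adc_csf=config.adc_csf,
        phi_normal=config.phi_normal,
        phi_min=config.phi_min,
    )
    phi0[par] = np.clip(phi_par, config.phi_min, 0.95)
    K = np.zeros(tissue.grid.shape)
    K[par] = kozeny_carman(phi0[par], config.phi_normal, config.K_ref)
    beta2 = np.zeros(tissue.grid.shape)
    beta2[par] = config.beta2_ref
    phi = phi0.copy()
    phi[~(par | csf)] = np.nan
    return HydraulicState(
        grid=tissue.grid,
        phi0=phi0,
        phi=phi,
        K=K,
        cap_conductance=beta2,
        parenchyma_mask=par,
        csf_mask=csf,
    )
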