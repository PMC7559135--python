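"""Synthetic brain-like phantoms with known ground truth.

The phantom is a nested-sphere "brain": a CSF shell, a gray-matter rim, an
expandable white-matter core holding an enhancing tumor with elevated
capillary permeability, and an off-center CSF ventricle.  ADC values are
set so the normal-parenchyma and CSF anchors of the ADC-to-pore-fraction
map are exercised, and the tumor Ktrans is elevated (2e-4 s^-1) over the
normal-tissue loss rate (1e-6 s^-1).  Synthetic DCE series and SPGR image
pairs are generated from known Kety parameters and a known T1 map so the
fitting and T1-inversion code can be validated against ground truth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dce import AIF, KetyParams, kety_forward
from .flow import CatheterSpec
from .grid import ScalarField, VoxelGrid
from .quantify import SPGRPair, spgr_signal
from .tissue import TissueClass, TissueClassMap

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "make_phantom",
    "default_catheter",
    "synth_aif",
    "synth_dce",
    "synth_spgr",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry (mm, centered world coordinates) and property values.

    Defaults describe a 65^3 grid at 2 mm spacing — a 13 cm sphere-brain.
    Use :meth:`compact` for the 33^3 variant used in fast tests.
    """

    shape: tuple[int, int, int] = (65, 65, 65)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radius: float = 60.0
    csf_shell_thickness: float = 4.0
    gray_rim_thickness: float = 6.0
    ventricle_center: tuple[float, float, float] = (18.0, 0.0, 0.0)
    ventricle_radius: float = 6.0
    tumor_center: tuple[float, float, float] = (-15.0, 0.0, 0.0)
    tumor_radius: float = 10.0
    adc_parenchyma: float = 0.77e-5  # cm^2/s, normal-brain anchor
    adc_tumor: float = 1.0e-5
    adc_csf: float = 2.7e-5  # above the CSF anchor
    ktrans_tumor: float = 2e-4  # s^-1
    ktrans_normal: float = 0.0  # outside DCE coverage; loss defaults applied later
    seed: int = 0

    def __post_init__(self) -> None:
        if self.csf_shell_thickness + self.gray_rim_thickness >= self.brain_radius:
            raise ValueError("shell and rim leave no white core")
        white_radius = self.brain_radius - self.csf_shell_thickness - self.gray_rim_thickness
        for name, center, radius in (
            ("tumor", self.tumor_center, self.tumor_radius),
            ("ventricle", self.ventricle_center, self.ventricle_radius),
        ):
            if np.linalg.norm(center) + radius >= white_radius:
                raise ValueError(f"{name} is not nested inside the white core")
        half_extent = min(n * s for n, s in zip(self.shape, self.spacing)) / 2.0
        if self.brain_radius > half_extent:
            raise ValueError("brain does not fit inside the grid")

    @classmethod
    def compact(cls, seed: int = 0) -> "PhantomSpec":
        """33^3 variant with proportionally shrunk anatomy."""
        return cls(
            shape=(33, 33, 33),
            brain_radius=30.0,
            csf_shell_thickness=4.0,
            gray_rim_thickness=4.0,
            ventricle_center=(12.0, 0.0, 0.0),
            ventricle_radius=4.0,
            tumor_center=(-9.0, 0.0, 0.0),
            tumor_radius=6.0,
            seed=seed,
        )

    def grid(self) -> VoxelGrid:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))
        return VoxelGrid(self.shape, self.spacing, origin)


@dataclass
class PhantomData:
    grid: VoxelGrid
    tissue: TissueClassMap
    adc: ScalarField
    ktrans: ScalarField
    tumor_mask: np.ndarray
    csf_mask: np.ndarray
    dce_coverage: np.ndarray
    truth: dict = field(default_factory=dict)


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomData:
    """Build the deterministic nested-sphere phantom for a spec."""
    grid = spec.grid()
    X, Y, Z = grid.coordinate_arrays()
    r = np.sqrt(X**2 + Y**2 + Z**2)

    labels = np.full(grid.shape, int(TissueClass.BACKGROUND), dtype=np.int8)
    inside = r <= spec.brain_radius
    labels[inside] = int(TissueClass.CSF)
    gray_outer = spec.brain_radius - spec.csf_shell_thickness
    labels[r <= gray_outer] = int(TissueClass.GRAY)
    white_outer = gray_outer - spec.gray_rim_thickness
    labels[r <= white_outer] = int(TissueClass.WHITE)

    def sphere(center, radius):
        cx, cy, cz = center
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2

    vent = sphere(spec.ventricle_center, spec.ventricle_radius)
    labels[vent] = int(TissueClass.CSF)
    tumor = sphere(spec.tumor_center, spec.tumor_radius)
    labels[tumor] = int(TissueClass.TUMOR_ENHANCING)

    white_fraction = np.zeros(grid.shape)
    white_fraction[labels == int(TissueClass.WHITE)] = 1.0
    tissue = TissueClassMap(grid, labels, white_fraction=white_fraction)

    adc = np.zeros(grid.shape)
    adc[tissue.parenchyma_mask] = spec.adc_parenchyma
    adc[tumor] = spec.adc_tumor
    adc[tissue.csf_mask] = spec.adc_csf

    ktrans = np.full(grid.shape, spec.ktrans_normal)
    ktrans[tumor] = spec.ktrans_tumor
    ktrans[~tissue.parenchyma_mask] = 0.0

    truth = {
        "seed": spec.seed,
        "tumor_volume_mL": float(tumor.sum()) * grid.voxel_volume_mL,
        "analytic_tumor_volume_mL": 4.0 / 3.0 * np.pi * spec.tumor_radius**3 / 1000.0,
        "ktrans_tumor": spec.ktrans_tumor,
    }
    return PhantomData(
        grid=grid,
        tissue=tissue,
        adc=ScalarField(grid, adc, units="cm^2/s"),
        ktrans=ScalarField(grid, ktrans, units="1/s"),
        tumor_mask=tumor,
        csf_mask=tissue.csf_mask,
        dce_coverage=tumor.copy(),
        truth=truth,
    )


def default_catheter(spec: PhantomSpec, flow_rate: float = 0.5,
                     concentration: float = 1.0) -> CatheterSpec:
    """A catheter entering the tumor from +x, tip inside the enhancing rim."""
    cx, cy, cz = spec.tumor_center
    tip = (cx + 0.3 * spec.tumor_radius, cy, cz)
    backflow = 0.6 * spec.tumor_radius
    return CatheterSpec(
        tip=tip,
        direction=(1.0, 0.0, 0.0),
        backflow_length=backflow,
        flow_rate=flow_rate,
        infusate_concentration=concentration,
    )


def synth_aif(
    duration_s: float = 300.0,
    dt_s: float = 5.0,
    arrival_s: float = 10.0,
    A1: float = 5.0,
    m1: float = 2.0e-3,
    A2: float = 1.0,
    m2: float = 1.7e-4,
) -> AIF:
    """Biexponential bolus AIF: Cp = A1 e^(-m1 t') + A2 e^(-m2 t') after arrival.

    Amplitudes in mM, decay rates in s^-1, sampled every ``dt_s`` seconds
    (5 s default, matching a dynamic acquisition).  Cp = 0 before arrival.
    """
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    tp = t - arrival_s
    Cp = np.where(tp > 0, A1 * np.exp(-m1 * np.clip(tp, 0, None))
                  + A2 * np.exp(-m2 * np.clip(tp, 0, None)), 0.0)
    return AIF(t=t, Cp=Cp)


def synth_dce(
    phantom: PhantomData,
    kety_truth: dict[int, KetyParams],
    aif: AIF | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, AIF, dict]:
    """Synthetic 4-D DCE concentration series from per-tissue Kety truth.

    ``kety_truth`` maps tissue labels to KetyParams; voxels of unlisted
    labels stay zero.  Gaussian noise of standard deviation ``noise_sd``
    (concentration units) is added when requested.  Returns the 4-D series
    (t last axis), the AIF, and the ground-truth maps for recovery tests.
    """
    if aif is None:
        aif = synth_aif()
    rng = np.random.default_rng(seed)
    nt = len(aif.t)
    series = np.zeros(phantom.grid.shape + (nt,))
    truth_maps = {
        "Ktrans": np.zeros(phantom.grid.shape),
        "ve": np.zeros(phantom.grid.shape),
        "vp": np.zeros(phantom.grid.shape),
    }
    for label, params in kety_truth.items():
        mask = phantom.tissue.labels == int(label)
        if not mask.any():
            continue
        ct = kety_forward(params, aif)
        series[mask, :] = ct
        truth_maps["Ktrans"][mask] = params.Ktrans
        truth_maps["ve"][mask] = params.ve
        truth_maps["vp"][mask] = params.vp
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, series.shape)
    return series, aif, truth_maps


def synth_spgr(
    T1_ms: np.ndarray,
    M0: np.ndarray | float = 1000.0,
    angles: tuple[float, float] = (6.0, 34.0),
    TR_ms: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SPGRPair:
    """Forward-model an SPGR flip-angle pair from a known T1 map."""
    T1_ms = np.asarray(T1_ms, dtype=float)
    if np.any(T1_ms <= 0):
        raise ValueError("T1 must be positive")
    rng = np.random.default_rng(seed)
    s_low = spgr_signal(M0, T1_ms, angles[0], TR_ms)
    s_high = spgr_signal(M0, T1_ms, angles[1], TR_ms)
    if noise_sd > 0:
        s_low = np.maximum(s_low + rng.normal(0, noise_sd, s_low.shape), 0.0)
        s_high = np.maximum(s_high + rng.normal(0, noise_sd, s_high.shape), 0.0)
    return SPGRPair(S_low=s_low, S_high=s_high, angles=angles, TR_ms=TR_ms)
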