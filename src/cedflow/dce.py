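"""Extended Kety (Tofts) DCE model: forward curves, fitting, loss-rate maps.

The tissue tracer concentration is

    Ct(t) = vp * Cp(t) + Ktrans * (Cp conv exp(-kep t))(t),   kep = Ktrans/ve,

with Cp the arterial input function (AIF).  The fitted Ktrans (s^-1) doubles
as the capillary loss rate of the small Gd-DTPA tracer in the transport
equation; for the 200-fold less permeable ^124I-HSA albumin the rate is
Ktrans / 200.  Voxels without DCE coverage fall back to the normal-tissue
rate 1e-6 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AIF",
    "KetyParams",
    "KetyFit",
    "HematocritConvention",
    "kety_forward",
    "fit_kety",
    "plasma_fraction",
    "ktrans_to_loss_rate",
    "MOLECULE_SCALES",
]

MOLECULE_SCALES = {"gd_dtpa": 1.0, "hsa": 200.0}


@dataclass(frozen=True)
class AIF:
    """Arterial input function: plasma concentration Cp on a time grid (s).

    Times must be strictly increasing with Cp >= 0 and Cp(0) = 0 (the bolus
    has not arrived at the first sample).
    """

    t: np.ndarray
    Cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        Cp = np.asarray(self.Cp, dtype=float)
        if t.ndim != 1 or t.shape != Cp.shape:
            raise ValueError("t and Cp must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(Cp < 0):
            raise ValueError("Cp must be >= 0")
        if Cp[0] != 0:
            raise ValueError("Cp(0) must be 0 (pre-bolus baseline)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "Cp", Cp)


@dataclass(frozen=True)
class KetyParams:
    """Ktrans (s^-1), EES fraction ve, plasma fraction vp; kep = Ktrans/ve."""

    Ktrans: float
    ve: float
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.Ktrans < 0:
            raise ValueError("Ktrans must be >= 0")
        if self.Ktrans > 0 and not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1] when Ktrans > 0 (kep undefined)")
        if self.ve < 0 or self.ve > 1:
            raise ValueError("ve must lie in [0, 1]")
        if not 0 <= self.vp < 1:
            raise ValueError("vp must lie in [0, 1)")
        if self.ve + self.vp > 1 + 1e-12:
            raise ValueError("ve + vp must not exceed 1")

    @property
    def kep(self) -> float:
        return self.Ktrans / self.ve if self.Ktrans > 0 else 0.0


@dataclass(frozen=True)
class HematocritConvention:
    Hct: float = 0.42

    def __post_init__(self) -> None:
        if not 0 < self.Hct < 1:
            raise ValueError("hematocrit must lie in (0, 1)")


def _exp_convolution(t: np.ndarray, Cp: np.ndarray, kep: float) -> np.ndarray:
    """Trapezoidal (Cp conv exp(-kep s))(t_i) on the (possibly nonuniform) grid."""
    # integrand at (i, j): Cp(t_j) * exp(-kep (t_i - t_j)) for t_j <= t_i
    dtm = t[:, None] - t[None, :]
    kern = np.where(dtm >= 0, np.exp(-kep * np.clip(dtm, 0, None)), 0.0)
    f = kern * Cp[None, :]
    # trapezoid over j up to i
    dt = np.diff(t)
    seg = 0.5 * (f[:, :-1] + f[:, 1:]) * dt[None, :]
    # segment (t_j, t_{j+1}) contributes to I_i only when j + 1 <= i
    mask = np.tril(np.ones((len(t), len(t) - 1)), k=-1)
    return (seg * mask).sum(axis=1)


def kety_forward(params: KetyParams, aif: AIF) -> np.ndarray:
    """Tissue concentration curve Ct(t) of the extended Kety model."""
    conv = _exp_convolution(aif.t, aif.Cp, params.kep) if params.Ktrans > 0 else 0.0
    return params.vp * aif.Cp + params.Ktrans * conv


@dataclass
class KetyFit:
    params: KetyParams
    residual_norm: float
    converged: bool
    degenerate: bool = False


def fit_kety(
    ct: np.ndarray,
    aif: AIF,
    init: KetyParams | None = None,
    bounds: tuple | None = None,
) -> KetyFit:
    """Bounded least-squares fit of (Ktrans, ve, vp) to a tissue curve.

    Multi-start local optimisation (low / medium / high Ktrans starts) to
    avoid the shallow local minima of the exponential-convolution model; an
    all-zero curve returns Ktrans = vp = 0 with a degenerate flag.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.shape != aif.t.shape:
        raise ValueError("tissue curve and AIF must share the time grid")
    if len(ct) < 10:
        raise ValueError("need at least 10 samples to fit three parameters")
    if not np.any(ct):
        return KetyFit(KetyParams(0.0, 0.5, 0.0), 0.0, True, degenerate=True)

    lb, ub = bounds if bounds is not None else (
        np.array([0.0, 1e-3, 0.0]),
        np.array([0.1, 1.0, 0.99]),
    )

    def residuals(theta):
        ktrans, ve, vp = theta
        kep = ktrans / ve
        conv = _exp_convolution(aif.t, aif.Cp, kep)
        return vp * aif.Cp + ktrans * conv - ct

    starts = []
    if init is not None:
        starts.append([init.Ktrans, init.ve, init.vp])
    starts += [
        [1e-4, 0.2, 0.02],
        [1e-3, 0.3, 0.05],
        [1e-2, 0.5, 0.05],
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    ktrans, ve, vp = best.x
    if ktrans < 1e-12:
        ktrans = 0.0
    return KetyFit(
        params=KetyParams(Ktrans=float(ktrans), ve=float(ve), vp=float(min(vp, 1 - 1e-9))),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )


def plasma_fraction(vb, hct: HematocritConvention = HematocritConvention()):
    """vp = (1 - Hct) vb: plasma is the extracellular part of the blood fraction."""
    vb_arr = np.asarray(vb, dtype=float)
    if np.any(vb_arr < 0) or np.any(vb_arr > 1):
        raise ValueError("blood volume fraction must lie in [0, 1]")
    out = (1.0 - hct.Hct) * vb_arr
    return float(out) if np.isscalar(vb) else out


def ktrans_to_loss_rate(
    ktrans_map,
    molecule: str | float = "gd_dtpa",
    coverage_mask=None,
    default_rate: float = 1e-6,
):
    """Capillary loss-rate field k (s^-1) from a Ktrans map.

    Gd-DTPA uses Ktrans directly; HSA divides by 200 (molecule-size
    permeability scaling); a numeric value is a custom divisor.  Voxels
    outside ``coverage_mask`` (no DCE data) get the normal-tissue
    ``default_rate``.
    """
    if isinstance(molecule, str):
        try:
            scale = MOLECULE_SCALES[molecule]
        except KeyError:
            raise ValueError(f"unknown molecule {molecule!r}") from None
    else:
        scale = float(molecule)
    if scale <= 0:
        raise ValueError("permeability scale must be positive")
    kt = np.asarray(ktrans_map, dtype=float)
    if np.any(kt < 0):
        raise ValueError("Ktrans must be >= 0")
    k = kt / scale
    if coverage_mask is not None:
        k = np.where(np.asarray(coverage_mask, dtype=bool), k, default_rate)
    return float(k) if np.isscalar(ktrans_map) else k
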