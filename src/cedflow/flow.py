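"""Coupled pressure / pore-fraction solver and the Darcy velocity field.

The steady interstitial pressure obeys

    -div(K grad p) + beta^2 p = q,

with q the volumetric source density of the catheter(s) (the flux boundary
condition realised as a right-hand-side density over the backflow segment),
p = 0 on CSF voxels (CSF is the baseline pressure) and zero flux across the
outer domain boundary.  Discretisation is cell-centered finite volume with
harmonic averaging of conductivity on faces, which handles the
discontinuous coefficients at gray/white/tumor interfaces.

The infusion pressure expands the tissue — raising phi, hence K by orders
of magnitude (Kozeny-Carman) and diluting the capillary density — so K and
beta^2 are steep functions of the local pressure.  Plain alternation
(solve p on frozen coefficients, update phi/K, re-solve) oscillates for
realistic parameters, so the coupled solve is a damped Newton iteration in
which face conductivities are *pressure-integrated* (Kirchhoff) means,

    T_ij = coef * harm(S_i, S_j),  S_i = [U_i(p_i) - U_i(p_j)]/(p_i - p_j),

with U_i(p) = int_0^p K_i(s) ds the per-voxel conductivity integral.  This
reduces exactly to harmonic point-K averaging when K is pressure
independent, and is the standard cure for the fold-type divergence of
Picard iteration on strongly conductivity-coupled flows.  The outer loop
retained around it (update phi by the integrated poroelastic relation,
update K and beta^2, re-solve) certifies self-consistency: its maximum
relative phi change collapses below tolerance within a couple of
iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg, splu

from .grid import ScalarField, VectorField, VoxelGrid
from .tissue import HydraulicState, integrate_pore_fraction, kozeny_carman

__all__ = [
    "CatheterSpec",
    "SourceRegion",
    "FlowSolution",
    "build_source_region",
    "combine_sources",
    "solve_pressure",
    "solve_pressure_coupled",
    "face_transmissibility",
    "face_fluxes",
    "darcy_velocity",
    "iterate_poroelastic",
]

MM3_PER_ML = 1000.0
PHI_CLIP = (1e-6, 0.995)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CatheterSpec:
    """An infusion catheter: tip position, shaft axis, backflow and rate.

    ``direction`` points from the tip back toward the entry point; infusate
    effluxes over the backflow segment [tip, tip + backflow_length * direction].
    ``flow_rate`` is in mL/h, ``infusate_concentration`` in the infusate's
    own units (mM for Gd-DTPA, uCi/mL for a PET tracer).
    """

    tip: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    backflow_length: float = 0.0
    flow_rate: float = 0.5
    infusate_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be >= 0")
        if self.backflow_length < 0:
            raise ValueError("backflow_length must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(self, "direction", tuple(d / n))
        object.__setattr__(self, "tip", tuple(float(x) for x in self.tip))

    @property
    def flow_rate_mm3_s(self) -> float:
        return self.flow_rate * MM3_PER_ML / 3600.0


@dataclass
class SourceRegion:
    """Weighted source voxels of one catheter (weights sum to 1)."""

    voxels: np.ndarray  # (n, 3) int indices
    weights: np.ndarray  # (n,), sums to 1
    total_flux: float  # mm^3/s
    concentration: float = 1.0

    def flux_density(self, grid: VoxelGrid) -> np.ndarray:
        """Per-voxel volumetric flux Q_i (mm^3/s) on the full grid."""
        q = np.zeros(grid.shape)
        q[tuple(self.voxels.T)] += self.weights * self.total_flux
        return q

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def build_source_region(
    catheter: CatheterSpec, grid: VoxelGrid, parenchyma_mask: np.ndarray
) -> SourceRegion:
    """Voxels traversed by the backflow segment, weighted by intersected length.

    Exact parametric traversal: the segment is cut at every voxel-boundary
    plane crossing and each piece is assigned to the voxel containing its
    midpoint.  A zero-length segment yields the single voxel containing the
    tip with weight 1.

    Raises
    ------
    ValueError
        If the tip or any traversed voxel lies outside the parenchyma
        (e.g. in CSF) — the failure mode where infusate would leak straight
        into CSF — naming the offending voxel.
    """
    tip = np.asarray(catheter.tip, dtype=float)
    direction = np.asarray(catheter.direction, dtype=float)
    L = catheter.backflow_length

    start_idx = grid.world_to_index(tip)[0]
    if L == 0:
        vox = np.round(start_idx).astype(int)
        _check_source_voxel(vox, grid, parenchyma_mask)
        return SourceRegion(
            voxels=vox[None, :],
            weights=np.array([1.0]),
            total_flux=catheter.flow_rate_mm3_s,
            concentration=catheter.infusate_concentration,
        )

    end = tip + L * direction
    a = grid.world_to_index(tip)[0]
    b = grid.world_to_index(end)[0]
    # Parameter values t in [0,1] where the segment crosses half-integer
    # voxel-boundary planes along each axis (voxel i spans [i-1/2, i+1/2]).
    ts = [0.0, 1.0]
    for ax in range(3):
        if b[ax] == a[ax]:
            continue
        lo, hi = sorted((a[ax], b[ax]))
        planes = np.arange(np.floor(lo + 0.5) + 0.5, hi, 1.0)
        ts.extend(((planes - a[ax]) / (b[ax] - a[ax])).tolist())
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mids = a[None, :] + ((ts[:-1] + ts[1:]) / 2.0)[:, None] * (b - a)[None, :]
    lengths = (ts[1:] - ts[:-1]) * L
    keep = lengths > 1e-12 * max(L, 1.0)
    voxels = np.round(mids[keep]).astype(int)
    lengths = lengths[keep]
    # merge duplicates (possible from corner grazing)
    uniq, inv = np.unique(voxels, axis=0, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inv, lengths)
    for vox in uniq:
        _check_source_voxel(vox, grid, parenchyma_mask)
    return SourceRegion(
        voxels=uniq,
        weights=w / w.sum(),
        total_flux=catheter.flow_rate_mm3_s,
        concentration=catheter.infusate_concentration,
    )


def _check_source_voxel(vox: np.ndarray, grid: VoxelGrid, parenchyma: np.ndarray) -> None:
    ijk = tuple(int(v) for v in vox)
    if not grid.contains_index(ijk):
        raise ValueError(f"catheter segment leaves the grid at voxel {ijk}")
    if not parenchyma[ijk]:
        raise ValueError(
            f"catheter segment crosses non-parenchymal voxel {ijk} "
            "(CSF or background): infusate would leak out of tissue"
        )


def combine_sources(sources: list[SourceRegion], grid: VoxelGrid) -> np.ndarray:
    """Sum per-catheter flux densities into one q array (mm^3/s per voxel)."""
    q = np.zeros(grid.shape)
    for s in sources:
        q += s.flux_density(grid)
    return q


# ---------------------------------------------------------------------------
# Discretisation helpers
# ---------------------------------------------------------------------------


def _lohi(ax: int):
    lo = tuple(slice(None, -1) if a == ax else slice(None) for a in range(3))
    hi = tuple(slice(1, None) if a == ax else slice(None) for a in range(3))
    return lo, hi


def face_transmissibility(hydraulic: HydraulicState) -> list[np.ndarray]:
    """Per-axis face transmissibilities T (mm^3 s^-1 Pa^-1) for frozen K.

    T between parenchymal neighbours uses the harmonic mean of K; a face
    between parenchyma and CSF uses the parenchymal K (one-sided, Dirichlet
    p = 0 on the CSF side); faces touching background carry no flow.
    Array ``T[ax]`` has the grid shape reduced by one along ``ax`` and
    refers to the face between cells i and i+1.
    """
    grid = hydraulic.grid
    K = hydraulic.K
    par = hydraulic.parenchyma_mask
    csf = hydraulic.csf_mask
    out = []
    for ax in range(3):
        lo, hi = _lohi(ax)
        # T = A * K / d with face area A = V / d, i.e. V K / d^2
        coef = grid.voxel_volume_mm3 / grid.spacing[ax] ** 2
        K_lo, K_hi = K[lo], K[hi]
        p_lo, p_hi = par[lo], par[hi]
        c_lo, c_hi = csf[lo], csf[hi]
        T = np.zeros(K_lo.shape)
        both = p_lo & p_hi
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = np.where(K_lo + K_hi > 0, 2.0 * K_lo * K_hi / (K_lo + K_hi), 0.0)
        T[both] = coef * harm[both]
        pc = p_lo & c_hi
        T[pc] = coef * K_lo[pc]
        cp = c_lo & p_hi
        T[cp] = coef * K_hi[cp]
        out.append(T)
    return out


def _face_masks(hydraulic: HydraulicState, ax: int):
    par = hydraulic.parenchyma_mask
    csf = hydraulic.csf_mask
    lo, hi = _lohi(ax)
    return par[lo], par[hi], csf[lo], csf[hi], lo, hi


@dataclass
class PressureDiagnostics:
    total_source: float
    capillary_loss: float
    csf_outflux: float
    solver: str = "cg"
    inner_iterations: int = 0

    @property
    def conservation_error(self) -> float:
        if self.total_source == 0:
            return abs(self.capillary_loss + self.csf_outflux)
        return abs(
            self.total_source - self.capillary_loss - self.csf_outflux
        ) / abs(self.total_source)


class _IterCounter:
    def __init__(self) -> None:
        self.n = 0

    def __call__(self, _xk) -> None:
        self.n += 1


def solve_pressure(
    hydraulic: HydraulicState,
    q: np.ndarray,
    rtol: float = 1e-12,
) -> tuple[ScalarField, PressureDiagnostics]:
    """Solve -div(K grad p) + beta^2 p = q with p = 0 on CSF, K frozen.

    ``q`` is the per-voxel volumetric source (mm^3/s, already integrated
    over the cell).  Returns the pressure field (Pa, zero outside
    parenchyma) and conservation diagnostics: to solver tolerance,
    total source flux = capillary loss integral + flux into CSF.
    """
    grid = hydraulic.grid
    par = hydraulic.parenchyma_mask
    n = int(par.sum())
    if n == 0:
        raise ValueError("no parenchymal voxels to solve on")
    if hydraulic.csf_mask.sum() == 0 and hydraulic.cap_conductance[par].max() == 0:
        raise ValueError(
            "singular pressure system: no CSF voxels and beta^2 = 0 "
            "leave the pressure level undetermined"
        )
    index = np.full(grid.shape, -1, dtype=np.int64)
    index[par] = np.arange(n)

    V = grid.voxel_volume_mm3
    diag = hydraulic.cap_conductance[par] * V
    T_ax = face_transmissibility(hydraulic)

    rows, cols, vals = [], [], []
    csf_T = np.zeros(n)  # Dirichlet-face conductance per parenchymal cell
    for ax in range(3):
        p_lo, p_hi, c_lo, c_hi, lo_sl, hi_sl = _face_masks(hydraulic, ax)
        T = T_ax[ax]
        idx_lo = index[lo_sl]
        idx_hi = index[hi_sl]
        both = p_lo & p_hi
        i, j, t = idx_lo[both], idx_hi[both], T[both]
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-t, -t])
        np.add.at(diag, i, t)
        np.add.at(diag, j, t)
        pc = p_lo & c_hi
        np.add.at(diag, idx_lo[pc], T[pc])
        np.add.at(csf_T, idx_lo[pc], T[pc])
        cp = c_lo & p_hi
        np.add.at(diag, idx_hi[cp], T[cp])
        np.add.at(csf_T, idx_hi[cp], T[cp])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    b = np.asarray(q, dtype=float)[par]

    solver = "cg"
    it_count = 0
    if b.any():
        d_inv = 1.0 / A.diagonal()
        M = LinearOperator((n, n), matvec=lambda x: d_inv * x)
        counter = _IterCounter()
        x, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=20 * n, M=M, callback=counter)
        it_count = counter.n
        if info != 0:  # pragma: no cover - CG on an SPD system should converge
            x = splu(A.tocsc()).solve(b)
            solver = "splu"
    else:
        x = np.zeros(n)

    p = np.zeros(grid.shape)
    p[par] = x
    diagn = PressureDiagnostics(
        total_source=float(b.sum()),
        capillary_loss=float((hydraulic.cap_conductance[par] * V * x).sum()),
        csf_outflux=float((csf_T * x).sum()),
        solver=solver,
        inner_iterations=it_count,
    )
    return ScalarField(grid, p, units="Pa"), diagn


# ---------------------------------------------------------------------------
# Coupled (poroelastic) pressure solve
# ---------------------------------------------------------------------------


class _PoroelasticTables:
    """Per-voxel K(p) and U(p) = int_0^p K ds on a shared pressure ladder.

    Built once from the baseline state (phi0, K0, beta^2_0, alpha, B); the
    coupled Newton solve interpolates these tables, so its cost per
    iteration is one sparse assembly + factorisation.
    """

    P_MAX = 1.0e6  # Pa; far above CED-scale pressures
    N_POINTS = 200

    def __init__(self, hydraulic0: HydraulicState, alpha: np.ndarray, B: np.ndarray):
        par = hydraulic0.parenchyma_mask
        self.par = par
        self.phi0 = hydraulic0.phi0[par]
        self.K0 = hydraulic0.K[par]
        self.beta2_0 = hydraulic0.cap_conductance[par]
        self.alpha = np.maximum(alpha, hydraulic0.phi0)[par]
        self.B = B[par]
        self.p_grid = np.concatenate(
            [[0.0], np.geomspace(0.1, self.P_MAX, self.N_POINTS - 1)]
        )
        phi_tab = np.clip(
            integrate_pore_fraction(
                self.phi0[:, None], self.p_grid[None, :],
                self.alpha[:, None], self.B[:, None],
            ),
            *PHI_CLIP,
        )
        self.K_tab = kozeny_carman(phi_tab, self.phi0[:, None], self.K0[:, None])
        dp = np.diff(self.p_grid)
        self.U_tab = np.concatenate(
            [
                np.zeros((len(self.phi0), 1)),
                np.cumsum(
                    0.5 * (self.K_tab[:, 1:] + self.K_tab[:, :-1]) * dp[None, :],
                    axis=1,
                ),
            ],
            axis=1,
        )

    def _locate(self, p):
        j = np.clip(np.searchsorted(self.p_grid, p) - 1, 0, len(self.p_grid) - 2)
        t = (p - self.p_grid[j]) / (self.p_grid[j + 1] - self.p_grid[j])
        return j, t

    def K_at(self, rows, p):
        j, t = self._locate(p)
        return self.K_tab[rows, j] * (1 - t) + self.K_tab[rows, j + 1] * t

    def U_at(self, rows, p):
        j, t = self._locate(p)
        return self.U_tab[rows, j] * (1 - t) + self.U_tab[rows, j + 1] * t

    def phi_at(self, p):
        phi = integrate_pore_fraction(self.phi0, p, self.alpha, self.B)
        return np.clip(phi, *PHI_CLIP)

    def secant_K(self, rows, pa, pb):
        """Mean conductivity of material ``rows`` between pressures pa, pb."""
        d = pa - pb
        small = np.abs(d) < 1e-9
        mid = self.K_at(rows, 0.5 * (pa + pb))
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (self.U_at(rows, pa) - self.U_at(rows, pb)) / np.where(small, 1.0, d)
        return np.where(small, mid, s)


def solve_pressure_coupled(
    hydraulic0: HydraulicState,
    q: np.ndarray,
    alpha: np.ndarray,
    B: np.ndarray,
    tables: _PoroelasticTables | None = None,
    p_init: np.ndarray | None = None,
    f_rtol: float = 1e-10,
    max_newton: int = 40,
) -> tuple[ScalarField, np.ndarray, list[np.ndarray], PressureDiagnostics]:
    """Newton solve of the pressure equation with K(p), beta^2(p) coupled in.

    Returns (pressure field, consistent phi array, effective face
    transmissibilities at the solution, diagnostics).  The effective
    transmissibilities reproduce the converged discrete fluxes exactly, so
    conservation holds to the Newton tolerance and downstream transport is
    discretely consistent with the flow.
    """
    grid = hydraulic0.grid
    par = hydraulic0.parenchyma_mask
    csf = hydraulic0.csf_mask
    n = int(par.sum())
    if n == 0:
        raise ValueError("no parenchymal voxels to solve on")
    if csf.sum() == 0 and hydraulic0.cap_conductance[par].max() == 0:
        raise ValueError(
            "singular pressure system: no CSF voxels and beta^2 = 0 "
            "leave the pressure level undetermined"
        )
    if tables is None:
        tables = _PoroelasticTables(hydraulic0, alpha, B)
    index = np.full(grid.shape, -1, dtype=np.int64)
    index[par] = np.arange(n)
    V = grid.voxel_volume_mm3
    qv = np.asarray(q, dtype=float)[par]
    q_total = float(qv.sum())

    pairs = []  # (idx_lo, idx_hi, coef) parenchyma-parenchyma faces per axis
    dirf = []  # (idx, coef) parenchyma-CSF Dirichlet faces
    for ax in range(3):
        lo_sl, hi_sl = _lohi(ax)
        coef = V / grid.spacing[ax] ** 2
        p_lo, p_hi = par[lo_sl], par[hi_sl]
        c_lo, c_hi = csf[lo_sl], csf[hi_sl]
        both = p_lo & p_hi
        pairs.append((index[lo_sl][both], index[hi_sl][both], coef))
        pc = p_lo & c_hi
        dirf.append((index[lo_sl][pc], coef))
        cp = c_lo & p_hi
        dirf.append((index[hi_sl][cp], coef))

    zeros = np.zeros(n)

    def residual(p, want_jac: bool):
        phi = tables.phi_at(p)
        beta2 = tables.beta2_0 * (1.0 - phi) / (1.0 - tables.phi0)
        F = beta2 * V * p - qv
        if want_jac:
            dphi = (tables.alpha - phi) * (1.0 - phi) / tables.B
            dphi = np.where(np.isfinite(dphi), dphi, 0.0)
            dbeta2 = -tables.beta2_0 / (1.0 - tables.phi0) * dphi
            diag = V * (beta2 + p * dbeta2)
            rows_, cols_, vals_ = [], [], []
        for i_idx, j_idx, coef in pairs:
            pi, pj = p[i_idx], p[j_idx]
            d = pi - pj
            Si = tables.secant_K(i_idx, pi, pj)
            Sj = tables.secant_K(j_idx, pi, pj)
            s = Si + Sj
            H = 2.0 * Si * Sj / s
            f = coef * H * d
            np.add.at(F, i_idx, f)
            np.add.at(F, j_idx, -f)
            if want_jac:
                dHi = 2.0 * (Sj / s) ** 2
                dHj = 2.0 * (Si / s) ** 2
                Kii = tables.K_at(i_idx, pi)
                Kij = tables.K_at(i_idx, pj)
                Kji = tables.K_at(j_idx, pi)
                Kjj = tables.K_at(j_idx, pj)
                dfi = coef * (dHi * (Kii - Si) + dHj * (Kji - Sj) + H)
                dfj = coef * (-(dHi * (Kij - Si) + dHj * (Kjj - Sj)) - H)
                np.add.at(diag, i_idx, dfi)
                np.add.at(diag, j_idx, -dfj)
                rows_.append(i_idx)
                cols_.append(j_idx)
                vals_.append(dfj)
                rows_.append(j_idx)
                cols_.append(i_idx)
                vals_.append(-dfi)
        for i_idx, coef in dirf:
            pi = p[i_idx]
            Si = tables.secant_K(i_idx, pi, zeros[: len(pi)])
            np.add.at(F, i_idx, coef * Si * pi)
            if want_jac:
                np.add.at(diag, i_idx, coef * tables.K_at(i_idx, pi))
        if not want_jac:
            return F, None
        rows_.append(np.arange(n))
        cols_.append(np.arange(n))
        vals_.append(diag)
        J = coo_matrix(
            (np.concatenate(vals_), (np.concatenate(rows_), np.concatenate(cols_))),
            shape=(n, n),
        ).tocsc()
        return F, J

    p = np.zeros(n) if p_init is None else np.maximum(p_init[par], 0.0)
    newton_its = 0
    f_scale = max(abs(q_total), 1e-300)
    converged = not qv.any()
    for _ in range(max_newton):
        F, J = residual(p, want_jac=True)
        nf = float(np.linalg.norm(F))
        if nf <= f_rtol * f_scale:
            converged = True
            break
        dp = splu(J).solve(-F)
        lam = 1.0
        accepted = False
        while lam > 1e-10:
            F2, _ = residual(np.maximum(p + lam * dp, 0.0), want_jac=False)
            if np.linalg.norm(F2) < (1.0 - 1e-4 * lam) * nf:
                accepted = True
                break
            lam *= 0.5
        p = np.maximum(p + lam * dp, 0.0)
        newton_its += 1
        logger.debug(
            "newton it %d: |F|/Q = %.3e, step %.3g", newton_its, nf / f_scale, lam
        )
        if not accepted:
            break
    if not converged:
        F, _ = residual(p, want_jac=False)
        if np.linalg.norm(F) > 1e-6 * f_scale:  # pragma: no cover - robustness net
            warnings.warn(
                "coupled pressure solve stalled at relative residual "
                f"{np.linalg.norm(F) / f_scale:.2e}",
                RuntimeWarning,
                stacklevel=2,
            )

    phi = tables.phi_at(p)
    beta2 = tables.beta2_0 * (1.0 - phi) / (1.0 - tables.phi0)

    # effective face transmissibilities at the solution
    p_full = np.zeros(grid.shape)
    p_full[par] = p
    eff_T = []
    for ax, (i_idx, j_idx, coef) in enumerate(pairs):
        lo_sl, hi_sl = _lohi(ax)
        T = np.zeros(tuple(np.subtract(grid.shape, np.eye(3, dtype=int)[ax])))
        pi, pj = p[i_idx], p[j_idx]
        Si = tables.secant_K(i_idx, pi, pj)
        Sj = tables.secant_K(j_idx, pi, pj)
        Tv = coef * 2.0 * Si * Sj / (Si + Sj)
        # scatter back to face positions
        p_lo, p_hi = par[lo_sl], par[hi_sl]
        both = p_lo & p_hi
        T[both] = Tv
        c_lo, c_hi = csf[lo_sl], csf[hi_sl]
        pc = p_lo & c_hi
        lo_rows = index[lo_sl][pc]
        T[pc] = coef * tables.secant_K(lo_rows, p[lo_rows], zeros[: len(lo_rows)])
        cp = c_lo & p_hi
        hi_rows = index[hi_sl][cp]
        T[cp] = coef * tables.secant_K(hi_rows, p[hi_rows], zeros[: len(hi_rows)])
        eff_T.append(T)

    csf_flux = 0.0
    for ax in range(3):
        lo_sl, hi_sl = _lohi(ax)
        p_lo, p_hi = par[lo_sl], par[hi_sl]
        c_lo, c_hi = csf[lo_sl], csf[hi_sl]
        pc = p_lo & c_hi
        csf_flux += float((eff_T[ax][pc] * p_full[lo_sl][pc]).sum())
        cp = c_lo & p_hi
        csf_flux += float((eff_T[ax][cp] * p_full[hi_sl][cp]).sum())

    phi_full = hydraulic0.phi.copy()
    phi_full[par] = phi
    diagn = PressureDiagnostics(
        total_source=q_total,
        capillary_loss=float((beta2 * V * p).sum()),
        csf_outflux=csf_flux,
        solver="newton-kirchhoff",
        inner_iterations=newton_its,
    )
    return ScalarField(grid, p_full, units="Pa"), phi_full, eff_T, diagn


def face_fluxes(
    pressure: ScalarField,
    hydraulic: HydraulicState,
    face_T: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Fluid volume flux across each face, F = T (p_lo - p_hi) in mm^3/s.

    Positive flux flows from the low-index to the high-index cell.  CSF
    voxels carry p = 0; faces not touching parenchyma carry no flux.  With
    ``face_T`` from a coupled solve these are the discretely conservative
    fluxes of the converged nonlinear system; otherwise the frozen-K
    harmonic transmissibilities are used.
    """
    p = pressure.values
    T_ax = face_T if face_T is not None else face_transmissibility(hydraulic)
    out = []
    for ax in range(3):
        p_lo_m, p_hi_m, c_lo, c_hi, lo_sl, hi_sl = _face_masks(hydraulic, ax)
        p_lo = np.where(p_lo_m, p[lo_sl], 0.0)
        p_hi = np.where(p_hi_m, p[hi_sl], 0.0)
        out.append(T_ax[ax] * (p_lo - p_hi))
    return out


def darcy_velocity(pressure: ScalarField, hydraulic: HydraulicState) -> VectorField:
    """Darcy velocity v = -K grad(p) (mm/s), zero outside the brain mask.

    Central differences inside the parenchyma; where a neighbour is
    background (no-flow) its pressure is mirrored so the one-sided gradient
    contribution vanishes; CSF neighbours contribute p = 0.
    """
    grid = hydraulic.grid
    p = pressure.values
    par = hydraulic.parenchyma_mask
    csf = hydraulic.csf_mask
    known = par | csf  # voxels with a defined pressure (CSF: 0)
    v = np.zeros((3,) + grid.shape)
    for ax in range(3):
        p_plus = np.empty_like(p)
        p_minus = np.empty_like(p)
        sl_src_p = tuple(slice(1, None) if a == ax else slice(None) for a in range(3))
        sl_dst_p = tuple(slice(None, -1) if a == ax else slice(None) for a in range(3))
        # neighbour value, mirrored at domain edges / background
        p_plus[sl_dst_p] = np.where(known[sl_src_p], p[sl_src_p], p[sl_dst_p])
        edge = tuple(slice(-1, None) if a == ax else slice(None) for a in range(3))
        p_plus[edge] = p[edge]
        p_minus[sl_src_p] = np.where(known[sl_dst_p], p[sl_dst_p], p[sl_src_p])
        edge0 = tuple(slice(0, 1) if a == ax else slice(None) for a in range(3))
        p_minus[edge0] = p[edge0]
        v[ax] = -hydraulic.K * (p_plus - p_minus) / (2.0 * grid.spacing[ax])
    v[:, ~par] = 0.0
    return VectorField(grid, v, units="mm/s")


# ---------------------------------------------------------------------------
# Outer poroelastic loop
# ---------------------------------------------------------------------------


@dataclass
class FlowSolution:
    """Converged pressure, velocity and hydraulic state of one infusion."""

    pressure: ScalarField
    velocity: VectorField
    hydraulic: HydraulicState
    iterations: int
    residual_history: list[float]
    converged: bool
    diagnostics: PressureDiagnostics
    sources: list[SourceRegion] = field(default_factory=list)
    face_T: list[np.ndarray] | None = None

    @property
    def grid(self) -> VoxelGrid:
        return self.hydraulic.grid

    def fluid_face_fluxes(self) -> list[np.ndarray]:
        return face_fluxes(self.pressure, self.hydraulic, face_T=self.face_T)


def iterate_poroelastic(
    hydraulic0: HydraulicState,
    sources: list[SourceRegion],
    alpha: np.ndarray,
    B: np.ndarray,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> FlowSolution:
    """Iterate pressure and tissue expansion to self-consistency.

    Each outer iteration solves the pressure (coupled Newton-Kirchhoff
    solve, see module docstring), maps the pressure through the integrated
    poroelastic relation to the pore fraction (from the *baseline* phi0 —
    the relation integrates from the unpressurised state), updates K by
    Kozeny-Carman and rescales the capillary conductance by the
    solid-fraction ratio, then re-solves.  Iteration stops when the maximum
    relative phi change drops below ``tol``; because the inner solve is
    consistent, this happens within a couple of iterations (one for rigid
    tissue, where phi never moves).

    Non-convergence within ``max_iter`` returns the best iterate with
    ``converged=False`` and a warning rather than a hard failure.
    """
    grid = hydraulic0.grid
    par = hydraulic0.parenchyma_mask
    q = combine_sources(sources, grid)
    tables = _PoroelasticTables(hydraulic0, alpha, B)
    state = hydraulic0.copy()

    history: list[float] = []
    pressure = ScalarField(grid, np.zeros(grid.shape), units="Pa")
    eff_T: list[np.ndarray] | None = None
    diagn = PressureDiagnostics(0.0, 0.0, 0.0)
    converged = False
    iterations = 0
    p_prev: np.ndarray | None = None
    for it in range(1, max_iter + 1):
        iterations = it
        pressure, phi_full, eff_T, diagn = solve_pressure_coupled(
            hydraulic0, q, alpha, B, tables=tables, p_init=p_prev
        )
        p_prev = pressure.values
        phi_old = state.phi[par]
        phi_new = phi_full[par]
        delta = (
            float(np.max(np.abs(phi_new - phi_old) / phi_old)) if len(phi_old) else 0.0
        )
        history.append(delta)
        state.phi[par] = phi_new
        state.K[par] = kozeny_carman(
            np.clip(phi_new, *PHI_CLIP), hydraulic0.phi0[par], hydraulic0.K[par]
        )
        state.cap_conductance[par] = hydraulic0.cap_conductance[par] * (
            (1.0 - phi_new) / (1.0 - hydraulic0.phi0[par])
        )
        if delta < tol:
            converged = True
            break

    if not converged:  # pragma: no cover - the consistent solve converges fast
        warnings.warn(
            f"poroelastic loop did not converge in {max_iter} iterations "
            f"(last relative phi change {history[-1]:.2e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    velocity = darcy_velocity(pressure, state)
    return FlowSolution(
        pressure=pressure,
        velocity=velocity,
        hydraulic=state,
        iterations=iterations,
        residual_history=history,
        converged=converged,
        diagnostics=diagn,
        sources=list(sources),
        face_T=eff_T,
    )
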