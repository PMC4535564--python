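"""Quasi-static equilibrium of the pressurized eye shell.

The wall is modelled as an incompressible Ogden membrane (plane stress,
thickness stretch ``1/(lam1*lam2)``).  Internal pressure acts perpendicular
to the deforming inner surface (a follower load); because the surface is
closed and watertight the follower pressure is conservative with potential
``-p * V(enclosed volume)``, so static equilibrium is found by minimizing

    Pi(x) = sum_faces A0 * t0 * W(lam1, lam2)  -  p * V(x)

with an analytic gradient (L-BFGS).  The gradient of ``Pi`` is exactly the
out-of-balance nodal force vector, so its norm is the equilibrium residual.

Steady-state solutions use only the hyperelastic part of the material: the
exponential relaxation kernel decays, so the static response is
rate-independent.  A transient ramp mode with the viscoelastic convolution
carried per facet is provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .constitutive import MaterialParams
from .geometry import REGIONS, EyeMesh

__all__ = [
    "MMHG_TO_MPA",
    "mmhg_to_mpa",
    "PressureLoad",
    "SolverConfig",
    "FieldResult",
    "ConvergenceError",
    "solve_pressurized",
    "solve_ramp",
    "regional_summary",
    "peak_in_central_area",
    "lc_peak_is_central",
    "cornea_peak_is_central",
    "low_stress_area_fraction",
]

#: 1 mmHg = 133.322 Pa = 1.33322e-4 MPa.
MMHG_TO_MPA = 1.33322e-4


def mmhg_to_mpa(iop: float) -> float:
    """Convert an IOP in mmHg to MPa; negative input is a domain error."""
    if iop < 0.0:
        raise ValueError("IOP must be non-negative")
    return iop * MMHG_TO_MPA


@dataclass(frozen=True)
class PressureLoad:
    iop_mmhg: float

    def __post_init__(self) -> None:
        if self.iop_mmhg < 0.0:
            raise ValueError("IOP must be non-negative")

    @property
    def pressure_mpa(self) -> float:
        return mmhg_to_mpa(self.iop_mmhg)


@dataclass(frozen=True)
class SolverConfig:
    tol_rel: float = 1e-6  # residual 2-norm below tol_rel * p * total area
    max_iter: int = 40000
    n_load_steps: int = 2  # pressure increments (continuation)
    strict: bool = True  # raise on non-convergence


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class FieldResult:
    """Converged fields: nodal displacement plus per-facet membrane state."""

    displacement: np.ndarray  # (N, 3) mm, centroid-recentred
    principal_stress: np.ndarray  # (M, 2) MPa, in-plane Cauchy principals
    eq_stress: np.ndarray  # (M,) von Mises, MPa
    eq_strain: np.ndarray  # (M,) von Mises-equivalent log strain
    region: np.ndarray  # (M,) codes carried through from the mesh
    diagnostics: dict


# --- membrane kernel --------------------------------------------------------


class _MembraneModel:
    """Precomputed reference state + vectorized energy/gradient evaluation."""

    def __init__(self, mesh: EyeMesh, materials: dict[str, MaterialParams]):
        self.mesh = mesh
        for code in np.unique(mesh.region):
            name = REGIONS[code]
            if name not in materials:
                raise KeyError(f"no material assigned to region '{name}'")
        # per-facet Ogden terms, zero-padded to the widest material
        n_terms = max(materials[REGIONS[c]].n_terms for c in np.unique(mesh.region))
        a_f = np.zeros((mesh.n_faces, n_terms))
        m_f = np.zeros((mesh.n_faces, n_terms))
        for code in np.unique(mesh.region):
            mat = materials[REGIONS[code]]
            mask = mesh.region == code
            a_f[mask, : mat.n_terms] = mat.alphas
            m_f[mask, : mat.n_terms] = mat.mus
        a_f[a_f == 0.0] = 1.0  # padded terms get mu = 0 so alpha is inert
        self.alpha = a_f
        self.mu = m_f

        tri = mesh.points[mesh.faces]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        n = np.cross(e1, e2)
        self.area0 = 0.5 * np.linalg.norm(n, axis=1)
        u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        nn = n / np.linalg.norm(n, axis=1, keepdims=True)
        v = np.cross(nn, u)
        # reference edge matrix in the local 2-D frame and its inverse
        d11 = np.einsum("ij,ij->i", e1, u)
        d12 = np.einsum("ij,ij->i", e2, u)
        d22 = np.einsum("ij,ij->i", e2, v)
        det = d11 * d22
        self.dm_inv = np.zeros((mesh.n_faces, 2, 2))
        self.dm_inv[:, 0, 0] = d22 / det
        self.dm_inv[:, 0, 1] = -d12 / det
        self.dm_inv[:, 1, 1] = d11 / det
        self.vol_scale = self.area0 * mesh.thickness  # A0 * t0 per facet
        self.faces = mesh.faces

    # -- kinematics

    def _def_grad(self, x: np.ndarray) -> np.ndarray:
        tri = x[self.faces]
        d = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)  # (M,3,2)
        return d @ self.dm_inv  # F, (M, 3, 2)

    @staticmethod
    def _principal(C11, C22, C12):
        mid = 0.5 * (C11 + C22)
        disc = np.sqrt(np.maximum(0.25 * (C11 - C22) ** 2 + C12 ** 2, 0.0))
        c1 = np.maximum(mid + disc, 1e-14)
        c2 = np.maximum(mid - disc, 1e-14)
        return np.sqrt(c1), np.sqrt(c2), disc

    def stretches(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        F = self._def_grad(x)
        C11 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 0])
        C22 = np.einsum("ik,ik->i", F[:, :, 1], F[:, :, 1])
        C12 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 1])
        l1, l2, _ = self._principal(C11, C22, C12)
        return l1, l2

    def _stress_principal(self, l1, l2):
        """In-plane principal Cauchy stresses of the incompressible
        plane-stress Ogden law: sigma_i = sum_j mu_j (l_i^a_j - (l1 l2)^-a_j)."""
        a, m = self.alpha, self.mu
        J2 = (l1 * l2)[:, None]
        p_term = J2 ** (-a)
        s1 = np.sum(m * (l1[:, None] ** a - p_term), axis=1)
        s2 = np.sum(m * (l2[:, None] ** a - p_term), axis=1)
        return s1, s2

    def energy_and_grad(self, x_flat: np.ndarray, pressure: float,
                        s_visc: np.ndarray | None = None):
        x = x_flat.reshape(-1, 3)
        F = self._def_grad(x)
        C11 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 0])
        C22 = np.einsum("ik,ik->i", F[:, :, 1], F[:, :, 1])
        C12 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 1])
        l1, l2, disc = self._principal(C11, C22, C12)

        a, m = self.alpha, self.mu
        with np.errstate(over="ignore", invalid="ignore"):
            J2 = (l1 * l2)[:, None]
            p_term = J2 ** (-a)
            W = np.sum((m / a) * (l1[:, None] ** a + l2[:, None] ** a + p_term - 3.0),
                       axis=1)
            # principal 2nd Piola-Kirchhoff values s_i = sigma_i / l_i^2
            sig1, sig2 = self._stress_principal(l1, l2)
        s1 = sig1 / l1 ** 2
        s2 = sig2 / l2 ** 2

        # eigenvector of C for the larger principal value
        use_col = np.abs(l1 ** 2 - C11) <= np.abs(l1 ** 2 - C22)
        n1 = np.where(use_col, C12, l1 ** 2 - C22)
        n2 = np.where(use_col, l1 ** 2 - C11, C12)
        norm = np.sqrt(n1 ** 2 + n2 ** 2)
        degenerate = (disc < 1e-12) | (norm < 1e-14)
        n1 = np.where(degenerate, 1.0, n1 / np.where(norm == 0, 1.0, norm))
        n2 = np.where(degenerate, 0.0, n2 / np.where(norm == 0, 1.0, norm))

        S = np.empty((len(l1), 2, 2))
        S[:, 0, 0] = s1 * n1 ** 2 + s2 * n2 ** 2
        S[:, 1, 1] = s1 * n2 ** 2 + s2 * n1 ** 2
        S[:, 0, 1] = S[:, 1, 0] = (s1 - s2) * n1 * n2
        if s_visc is not None:
            S = S + s_visc

        P = F @ S  # first Piola-Kirchhoff, (M, 3, 2)
        G = self.vol_scale[:, None, None] * (P @ np.transpose(self.dm_inv, (0, 2, 1)))
        grad = np.zeros_like(x)
        np.add.at(grad, self.faces[:, 1], G[:, :, 0])
        np.add.at(grad, self.faces[:, 2], G[:, :, 1])
        np.add.at(grad, self.faces[:, 0], -(G[:, :, 0] + G[:, :, 1]))

        energy = float(np.sum(self.vol_scale * W))
        if s_visc is not None:
            # pseudo-energy keeping the gradient consistent for the frozen
            # viscous prestress: 0.5 * S_v : C  per facet
            Ev = 0.5 * (s_visc[:, 0, 0] * C11 + s_visc[:, 1, 1] * C22
                        + 2.0 * s_visc[:, 0, 1] * C12)
            energy += float(np.sum(self.vol_scale * Ev))

        # enclosed volume and its gradient (follower pressure potential)
        tri = x[self.faces]
        va, vb, vc = tri[:, 0], tri[:, 1], tri[:, 2]
        vol = float(np.sum(np.einsum("ij,ij->i", va, np.cross(vb, vc)))) / 6.0
        gv = np.zeros_like(x)
        np.add.at(gv, self.faces[:, 0], np.cross(vb, vc) / 6.0)
        np.add.at(gv, self.faces[:, 1], np.cross(vc, va) / 6.0)
        np.add.at(gv, self.faces[:, 2], np.cross(va, vb) / 6.0)

        total = energy - pressure * vol
        grad = grad - pressure * gv
        if not np.isfinite(total):
            total = 1e100
            grad = np.where(np.isfinite(grad), grad, 0.0)
        return total, grad.ravel()


def _von_mises_plane_stress(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return np.sqrt(np.maximum(s1 ** 2 - s1 * s2 + s2 ** 2, 0.0))


def _eq_log_strain(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    e1, e2 = np.log(l1), np.log(l2)
    e3 = -(e1 + e2)  # incompressible
    return np.sqrt(2.0 / 3.0 * (e1 ** 2 + e2 ** 2 + e3 ** 2))


def _fields_from_state(model: _MembraneModel, mesh: EyeMesh, x: np.ndarray,
                       materials: dict[str, MaterialParams],
                       diagnostics: dict) -> FieldResult:
    l1, l2 = model.stretches(x)
    with np.errstate(over="ignore", invalid="ignore"):
        s1, s2 = model._stress_principal(l1, l2)
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        bad = ~(np.isfinite(s1) & np.isfinite(s2))
        name = REGIONS[int(mesh.region[np.flatnonzero(bad)[0]])]
        raise FloatingPointError(
            f"material in region '{name}' caused numerical overflow")
    disp = x - mesh.points
    disp = disp - disp.mean(axis=0)  # remove rigid translation for reporting
    return FieldResult(displacement=disp,
                       principal_stress=np.stack([s1, s2], axis=1),
                       eq_stress=_von_mises_plane_stress(s1, s2),
                       eq_strain=_eq_log_strain(l1, l2),
                       region=mesh.region.copy(),
                       diagnostics=diagnostics)


def solve_pressurized(mesh: EyeMesh, materials: dict[str, MaterialParams],
                      load: PressureLoad,
                      config: SolverConfig | None = None) -> FieldResult:
    """Solve static equilibrium of the shell at the given IOP.

    Zero load short-circuits to identically zero fields.  Raises
    :class:`ConvergenceError` (when ``config.strict``) if the residual does
    not reach ``tol_rel`` times the load resultant ``p * area``.
    """
    config = config or SolverConfig()
    model = _MembraneModel(mesh, materials)
    p = load.pressure_mpa
    if p == 0.0:
        zeros = np.zeros(mesh.n_faces)
        return FieldResult(displacement=np.zeros_like(mesh.points),
                           principal_stress=np.zeros((mesh.n_faces, 2)),
                           eq_stress=zeros, eq_strain=zeros.copy(),
                           region=mesh.region.copy(),
                           diagnostics={"residual_norm": 0.0, "tol": 0.0,
                                        "iterations": 0, "pressure_mpa": 0.0})

    area_total = float(model.area0.sum())
    tol = config.tol_rel * p * area_total
    x = mesh.points.copy().ravel()
    total_iter = 0
    for k in range(1, config.n_load_steps + 1):
        pk = p * k / config.n_load_steps
        res = minimize(model.energy_and_grad, x, args=(pk,), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": config.max_iter,
                                "maxfun": 2 * config.max_iter,
                                "ftol": 1e-18, "gtol": tol * 1e-3})
        x = res.x
        total_iter += res.nit
    _, grad = model.energy_and_grad(x, p)
    residual = float(np.linalg.norm(grad))
    diagnostics = {"residual_norm": residual, "tol": tol,
                   "iterations": total_iter, "pressure_mpa": p,
                   "load_resultant": p * area_total}
    if residual > tol and config.strict:
        raise ConvergenceError(
            f"equilibrium residual {residual:.3e} above tolerance {tol:.3e} "
            f"after {total_iter} iterations", diagnostics)
    return _fields_from_state(model, mesh, x.reshape(-1, 3), materials, diagnostics)


def solve_ramp(mesh: EyeMesh, materials: dict[str, MaterialParams],
               load: PressureLoad, duration: float, n_steps: int = 20,
               config: SolverConfig | None = None) -> FieldResult:
    """Transient pressure ramp carrying the viscoelastic convolution.

    Pressure ramps linearly over ``duration`` seconds.  At each step the
    per-facet viscous 2nd Piola-Kirchhoff stress is updated with the
    exact-exponential recursion on the Green-strain increments of the
    previous converged state, then frozen while the step equilibrium is
    solved (semi-implicit operator split).
    """
    config = config or SolverConfig(n_load_steps=1, strict=False)
    model = _MembraneModel(mesh, materials)
    p_final = load.pressure_mpa
    dt = duration / n_steps
    beta = np.zeros(mesh.n_faces)
    g = np.zeros(mesh.n_faces)
    for code in np.unique(mesh.region):
        mat = materials[REGIONS[code]]
        mask = mesh.region == code
        beta[mask] = mat.beta
        g[mask] = mat.g_visc

    x = mesh.points.copy().ravel()
    s_visc = np.zeros((mesh.n_faces, 3))  # E11, E22, E12 components packed
    E_prev = np.zeros((mesh.n_faces, 3))
    area_total = float(model.area0.sum())
    total_iter = 0
    for k in range(1, n_steps + 1):
        pk = p_final * k / n_steps
        F = model._def_grad(x.reshape(-1, 3))
        C11 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 0])
        C22 = np.einsum("ik,ik->i", F[:, :, 1], F[:, :, 1])
        C12 = np.einsum("ik,ik->i", F[:, :, 0], F[:, :, 1])
        E_now = 0.5 * np.stack([C11 - 1.0, C22 - 1.0, 2.0 * C12], axis=1)
        dE = E_now - E_prev
        E_prev = E_now
        decay = np.exp(-beta * dt)[:, None]
        half = np.exp(-beta * dt / 2.0)[:, None]
        s_visc = decay * s_visc + g[:, None] * dE * half
        Sv = np.zeros((mesh.n_faces, 2, 2))
        Sv[:, 0, 0] = s_visc[:, 0]
        Sv[:, 1, 1] = s_visc[:, 1]
        Sv[:, 0, 1] = Sv[:, 1, 0] = 0.5 * s_visc[:, 2]
        res = minimize(model.energy_and_grad, x, args=(pk, Sv), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": config.max_iter, "ftol": 1e-16})
        x = res.x
        total_iter += res.nit
    _, grad = model.energy_and_grad(x, p_final)
    diagnostics = {"residual_norm": float(np.linalg.norm(grad)),
                   "tol": config.tol_rel * p_final * area_total,
                   "iterations": total_iter, "pressure_mpa": p_final,
                   "transient": True}
    return _fields_from_state(model, mesh, x.reshape(-1, 3), materials, diagnostics)


# --- post-processing --------------------------------------------------------


def regional_summary(mesh: EyeMesh, result: FieldResult,
                     stress_threshold: float | None = None) -> pd.DataFrame:
    """Area-weighted per-region statistics of the equivalent fields.

    ``stress_threshold`` (MPa) adds the area fraction of each region whose
    equivalent stress exceeds it.
    """
    x = mesh.points + result.displacement
    areas = mesh.face_areas(points=x)
    rows = []
    for code in np.unique(mesh.region):
        mask = mesh.region == code
        w = areas[mask]
        s = result.eq_stress[mask]
        e = result.eq_strain[mask]
        row = {
            "region": REGIONS[code],
            "area_mm2": float(w.sum()),
            "stress_min_mpa": float(s.min()),
            "stress_mean_mpa": float(np.average(s, weights=w)),
            "stress_max_mpa": float(s.max()),
            "strain_min": float(e.min()),
            "strain_mean": float(np.average(e, weights=w)),
            "strain_max": float(e.max()),
        }
        if stress_threshold is not None:
            row["area_frac_above_threshold"] = float(
                w[s > stress_threshold].sum() / w.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def peak_in_central_area(key: np.ndarray, areas: np.ndarray,
                         values: np.ndarray, frac: float = 0.5) -> bool:
    """True iff the argmax of ``values`` lies within the ``frac`` of total
    area closest to the centre (smallest ``key``)."""
    order = np.argsort(key, kind="stable")
    cum = np.cumsum(areas[order])
    cutoff_idx = int(np.searchsorted(cum, frac * cum[-1]))
    cutoff_key = key[order][min(cutoff_idx, len(key) - 1)]
    return bool(key[int(np.argmax(values))] <= cutoff_key)


def lc_peak_is_central(mesh: EyeMesh, result: FieldResult, frac: float = 0.5,
                       lc_axes: tuple[float, float] = (4.60, 3.68)) -> bool:
    """Is the LC peak equivalent stress inside the central ``frac`` (by area)
    of the LC ellipse?  Centrality is ranked by normalized elliptical radius."""
    mask = mesh.region_mask("lamina_cribrosa")
    cent = mesh.face_centroids()[mask]
    rho = np.sqrt((cent[:, 0] / (lc_axes[0] / 2.0)) ** 2
                  + (cent[:, 1] / (lc_axes[1] / 2.0)) ** 2)
    areas = mesh.face_areas()[mask]
    return peak_in_central_area(rho, areas, result.eq_stress[mask], frac)


def cornea_peak_is_central(mesh: EyeMesh, result: FieldResult,
                           frac: float = 0.5) -> bool:
    """Is the corneal peak equivalent stress inside the central ``frac`` (by
    area) of the corneal cap?  Centrality is ranked by angle from the apex."""
    mask = mesh.region_mask("cornea")
    cent = mesh.face_centroids()[mask]
    c_norm = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    theta = np.arccos(np.clip(c_norm[:, 2], -1.0, 1.0))
    areas = mesh.face_areas()[mask]
    return peak_in_central_area(theta, areas, result.eq_stress[mask], frac)


def low_stress_area_fraction(mesh: EyeMesh, result: FieldResult,
                             region: str = "posterior_sclera",
                             quantile: float = 0.25) -> float:
    """Area fraction of ``region`` below the given quantile of the
    whole-globe equivalent-stress range."""
    smin, smax = float(result.eq_stress.min()), float(result.eq_stress.max())
    threshold = smin + quantile * (smax - smin)
    mask = mesh.region_mask(region)
    areas = mesh.face_areas()[mask]
    return float(areas[result.eq_stress[mask] <= threshold].sum() / areas.sum())
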