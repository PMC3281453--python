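"""Steric energy, components, and analytic gradients.

Functional forms (all energies kcal/mol, lengths A, angles rad):

* stretch        sum k_b (r - r0)^2
* bend           sum k_theta (theta - theta0)^2
* torsion        sum V_n/2 (1 + cos(n phi - gamma))
* van der Waals  Lennard-Jones 12-6, Lorentz-Berthelot combined, 1-2/1-3
                 excluded, 1-4 scaled, hard cutoff
* electrostatic  Coulomb q_i q_j / (eps_r r), same exclusions/cutoff
* hydrogen bond  10-12 term on donor-H...acceptor pairs inside its own cutoff

The analytic gradient of the total is validated against central finite
differences in the test suite; the gradient of an isolated system sums to
zero (translation invariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_CONSTANT
from .errors import DivergenceError, SingularGeometryError
from .structures_io import ParameterizedSystem

_COINCIDENT = 1e-6  # A; closer counts as singular geometry


@dataclass(frozen=True)
class EnergyBreakdown:
    """Steric-energy components; ``total`` is their exact sum."""

    stretch: float
    bend: float
    torsion: float
    vdw: float
    electrostatic: float
    hbond: float

    @property
    def total(self) -> float:
        return (self.stretch + self.bend + self.torsion
                + self.vdw + self.electrostatic + self.hbond)

    def as_dict(self) -> dict:
        return {
            "stretch": self.stretch, "bend": self.bend,
            "torsion": self.torsion, "vdw": self.vdw,
            "electrostatic": self.electrostatic, "hbond": self.hbond,
            "total": self.total,
        }


def _terms(system: ParameterizedSystem, coords: np.ndarray, do_grad: bool):
    """Shared energy/gradient kernel; returns (breakdown, gradient or None)."""
    x = np.asarray(coords, dtype=float)
    n = system.n_atoms
    if x.shape != (n, 3):
        raise ValueError(f"coords shape {x.shape} != ({n}, 3)")
    grad = np.zeros_like(x) if do_grad else None

    # ---- stretch ----------------------------------------------------------
    e_stretch = 0.0
    if len(system.stretch_idx):
        i, j = system.stretch_idx[:, 0], system.stretch_idx[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < _COINCIDENT):
            raise SingularGeometryError("coincident bonded atoms")
        dr = r - system.stretch_r0
        e_stretch = float(np.sum(system.stretch_k * dr ** 2))
        if do_grad:
            f = (2.0 * system.stretch_k * dr / r)[:, None] * d
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

    # ---- bend -------------------------------------------------------------
    e_bend = 0.0
    if len(system.bend_idx):
        ii, jj, kk = (system.bend_idx[:, 0], system.bend_idx[:, 1],
                      system.bend_idx[:, 2])
        u = x[ii] - x[jj]
        v = x[kk] - x[jj]
        p = np.cross(u, v)
        pn = np.linalg.norm(p, axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        theta = np.arctan2(pn, dot)
        dt = theta - system.bend_theta0
        e_bend = float(np.sum(system.bend_k * dt ** 2))
        if do_grad:
            ok = pn > 1e-10  # strictly linear angles have zero usable gradient
            u2 = np.einsum("ij,ij->i", u, u)
            v2 = np.einsum("ij,ij->i", v, v)
            with np.errstate(divide="ignore", invalid="ignore"):
                dthe_di = np.cross(u, p) / (u2 * pn)[:, None]
                dthe_dk = -np.cross(v, p) / (v2 * pn)[:, None]
            dthe_di[~ok] = 0.0
            dthe_dk[~ok] = 0.0
            coef = (2.0 * system.bend_k * dt)[:, None]
            np.add.at(grad, ii, coef * dthe_di)
            np.add.at(grad, kk, coef * dthe_dk)
            np.add.at(grad, jj, -coef * (dthe_di + dthe_dk))

    # ---- torsion ----------------------------------------------------------
    e_torsion = 0.0
    if len(system.torsion_idx):
        ti, tj, tk, tl = (system.torsion_idx[:, 0], system.torsion_idx[:, 1],
                          system.torsion_idx[:, 2], system.torsion_idx[:, 3])
        b1 = x[tj] - x[ti]
        b2 = x[tk] - x[tj]
        b3 = x[tl] - x[tk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / np.maximum(b2n, 1e-12)[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m, n2),
                         np.einsum("ij,ij->i", n1, n2))
        arg = system.torsion_n * phi - system.torsion_gamma
        e_torsion = float(np.sum(0.5 * system.torsion_v * (1.0 + np.cos(arg))))
        if do_grad:
            dV = -0.5 * system.torsion_v * system.torsion_n * np.sin(arg)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            ok = (n1sq > 1e-16) & (n2sq > 1e-16)
            with np.errstate(divide="ignore", invalid="ignore"):
                dphi_di = (b2n / n1sq)[:, None] * n1
                dphi_dl = -(b2n / n2sq)[:, None] * n2
                c1 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
                c2 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
            for arr in (dphi_di, dphi_dl, c1, c2):
                arr[~ok] = 0.0
            dphi_dj = -(1.0 + c1) * dphi_di + c2 * dphi_dl
            dphi_dk = -dphi_di - dphi_dj - dphi_dl
            coef = dV[:, None]
            np.add.at(grad, ti, coef * dphi_di)
            np.add.at(grad, tj, coef * dphi_dj)
            np.add.at(grad, tk, coef * dphi_dk)
            np.add.at(grad, tl, coef * dphi_dl)

    # ---- nonbonded (LJ + Coulomb) -----------------------------------------
    e_vdw = 0.0
    e_elec = 0.0
    if len(system.nb_pairs):
        pi, pj = system.nb_pairs[:, 0], system.nb_pairs[:, 1]
        d = x[pi] - x[pj]
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < _COINCIDENT ** 2):
            raise SingularGeometryError("coincident nonbonded atoms")
        cutoff = system.options["cutoff"]
        within = r2 < cutoff ** 2
        if np.any(within):
            d = d[within]
            r2w = r2[within]
            r = np.sqrt(r2w)
            scale = system.nb_scale[within]
            epsw = system.nb_eps[within]
            sigw = system.nb_sigma[within]
            qqw = system.nb_qq[within]
            sr6 = (sigw ** 2 / r2w) ** 3
            sr12 = sr6 ** 2
            e_lj = 4.0 * epsw * (sr12 - sr6) * scale
            e_vdw = float(np.sum(e_lj))
            ke = COULOMB_CONSTANT / system.options["dielectric"]
            e_c = ke * qqw / r * scale
            e_elec = float(np.sum(e_c))
            if do_grad:
                # dE/dr for LJ and Coulomb, then project on the pair vector
                dlj = 4.0 * epsw * (-12.0 * sr12 + 6.0 * sr6) / r * scale
                dc = -e_c / r
                f = ((dlj + dc) / r)[:, None] * d
                np.add.at(grad, pi[within], f)
                np.add.at(grad, pj[within], -f)

    # ---- hydrogen bonds ---------------------------------------------------
    e_hb = 0.0
    if len(system.hbond_pairs):
        hb = system.options["hbond"]
        hi, ai = system.hbond_pairs[:, 0], system.hbond_pairs[:, 1]
        d = x[hi] - x[ai]
        r = np.linalg.norm(d, axis=1)
        within = r < hb["cutoff"]
        if np.any(within):
            d = d[within]
            r = r[within]
            if np.any(r < _COINCIDENT):
                raise SingularGeometryError("coincident H-bond pair")
            s10 = (hb["r0"] / r) ** 10
            s12 = s10 * (hb["r0"] / r) ** 2
            e = hb["epsilon"] * (5.0 * s12 - 6.0 * s10)
            e_hb = float(np.sum(e))
            if do_grad:
                dr = hb["epsilon"] * (-60.0 * s12 + 60.0 * s10) / r
                f = (dr / r)[:, None] * d
                np.add.at(grad, hi[within], f)
                np.add.at(grad, ai[within], -f)

    breakdown = EnergyBreakdown(e_stretch, e_bend, e_torsion,
                                e_vdw, e_elec, e_hb)
    return breakdown, grad


def compute_energy(system: ParameterizedSystem,
                   coords: np.ndarray) -> EnergyBreakdown:
    """Steric energy of *coords* under *system*'s parameters."""
    breakdown, _ = _terms(system, coords, do_grad=False)
    return breakdown


def compute_gradient(system: ParameterizedSystem,
                     coords: np.ndarray) -> np.ndarray:
    """Analytic gradient dE/dx of the total steric energy, kcal/mol/A,
    shape (n_atoms, 3)."""
    _, grad = _terms(system, coords, do_grad=True)
    return grad


def compute_energy_and_gradient(system: ParameterizedSystem,
                                coords: np.ndarray):
    return _terms(system, coords, do_grad=True)


def minimize(system: ParameterizedSystem, coords: np.ndarray,
             tol: float = 0.05, max_iter: int = 2000):
    """Gradient descent with backtracking until max-norm gradient <= tol.

    Energy never increases across accepted steps.  Returns
    ``(coords, EnergyBreakdown, n_accepted_steps)``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.array(coords, dtype=float)
    frozen = system.frozen

    def grad_of(g):
        if frozen is not None:
            g = g.copy()
            g[frozen] = 0.0
        return g

    bd, g = _terms(system, x, do_grad=True)
    g = grad_of(g)
    e = bd.total
    if not np.isfinite(e):
        raise DivergenceError("non-finite energy at the starting geometry")
    step = 1e-3
    accepted = 0
    for _ in range(max_iter):
        gmax = np.abs(g).max() if g.size else 0.0
        if gmax <= tol:
            break
        trial = x - step * g
        try:
            bd_t, g_t = _terms(system, trial, do_grad=True)
        except SingularGeometryError:
            step *= 0.5
            continue
        if not np.isfinite(bd_t.total):
            raise DivergenceError("non-finite energy during minimization")
        if bd_t.total <= e:
            x, e, bd, g = trial, bd_t.total, bd_t, grad_of(g_t)
            accepted += 1
            step = min(step * 1.2, 0.1)
        else:
            step *= 0.5
            if step < 1e-14:
                break
    return x, bd, accepted
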