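"""Host-guest complexation and the stability index Ds.

The stability index is the percent decrease of the complex's steric energy
``E_k`` relative to the sum of the isolated host (``E_Chit``) and guest
(``E_Insectic``) energies:

    Ds = 100 * (E_Chit + E_Insectic - E_k) / |E_Chit + E_Insectic|

Complexes with Ds > 50 are classified stable and Ds < 35 unstable; the
boundary values themselves fall in the medium class, mirroring the strict
inequalities of the source convention.  The denominator carries an absolute
value so the "percent decrease" keeps its sign meaning even if a parameter
set yields a negative combined steric energy (documented design choice).

``run_complexation`` is the pipeline: minimize host and guest alone, scatter
rigid guest poses around the host, anneal each pose with short thermostatted
dynamics, minimize, take the lowest complex energy as ``E_k``, and summarize
inter-molecular hydrogen bonds from the winning pose's trajectory tail.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .dynamics import DynamicsConfig, run_dynamics
from .errors import (
    ComplexationFailureError,
    DivergenceError,
    UndefinedIndexError,
)
from .forcefield import minimize
from .structures_io import (
    ParameterizedSystem,
    Structure,
    assign_parameters,
    merge_structures,
)

STABLE_THRESHOLD = 50.0    # Ds strictly above -> stable
UNSTABLE_THRESHOLD = 35.0  # Ds strictly below -> unstable
MIN_CONTACT_DISTANCE = 1.5  # A; poses with closer host-guest atoms resampled


def stability_index(host_energy: float, guest_energy: float,
                    complex_energy: float) -> float:
    """Ds in percent; raises :class:`UndefinedIndexError` when the reference
    energy |E_host + E_guest| is numerically zero."""
    reference = host_energy + guest_energy
    if abs(reference) <= 1e-9:
        raise UndefinedIndexError(
            f"|E_host + E_guest| = {abs(reference):.2e} is too small to "
            "define a percent decrease"
        )
    return 100.0 * (reference - complex_energy) / abs(reference)


def classify_stability(ds: float) -> str:
    """Map a Ds value to 'stable' (> 50), 'unstable' (< 35) or 'medium'."""
    if not np.isfinite(ds):
        raise ValueError("Ds must be finite")
    if ds > STABLE_THRESHOLD:
        return "stable"
    if ds < UNSTABLE_THRESHOLD:
        return "unstable"
    return "medium"


@dataclass
class ComplexResult:
    """Energies (kcal/mol), stability index/class, and pose bookkeeping."""

    host_energy: float
    guest_energy: float
    complex_energy: float
    ds: float
    stability_class: str
    n_poses_sampled: int
    best_pose: Structure | None = None
    hbond_mean_count: float = 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("best_pose")
        return d

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion draw."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_poses(host: Structure, guest: Structure, n_poses: int,
                 seed: int, clearance: tuple[float, float] = (3.0, 6.0)
                 ) -> list[Structure]:
    """Rigidly place the guest around the host.

    Each pose applies a uniform random rotation to the guest and translates
    it along a random direction so the host-guest surface gap along that
    direction is a uniform draw from ``clearance`` A.  Poses with any
    host-guest contact below 1.5 A are rejected and resampled (at most 100
    attempts each).  Deterministic given ``seed``.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    hx = host.coords
    h_center = hx.mean(0)
    gx0 = guest.coords
    g_center0 = gx0.mean(0)
    poses = []
    for _ in range(n_poses):
        for _attempt in range(100):
            rot = _random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            gap = rng.uniform(*clearance)
            gx = (gx0 - g_center0) @ rot.T
            host_extent = float(((hx - h_center) @ direction).max())
            guest_extent = float((gx @ -direction).max())
            center = (h_center + direction
                      * (host_extent + guest_extent + gap))
            gx_placed = gx + center
            dmin = np.sqrt(
                ((hx[:, None, :] - gx_placed[None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin >= MIN_CONTACT_DISTANCE:
                break
        else:
            raise ComplexationFailureError(
                "could not place a clash-free pose in 100 attempts")
        placed = guest.with_coords(gx_placed)
        poses.append(merge_structures(host, placed,
                                      name=f"{host.name}:{guest.name}"))
    return poses


def _anneal_and_minimize(system: ParameterizedSystem, coords, config,
                         seed_offset: int, tol: float, max_iter: int):
    """Short thermostatted dynamics followed by minimization; the one
    relaxation protocol used for host, guest and every pose."""
    cfg = dataclasses.replace(config, seed=config.seed + seed_offset)
    # brief pre-relaxation removes construction strain so the annealing MD
    # stays stable at protocol step sizes
    coords, _, _ = minimize(system, coords, tol, max_iter=300)
    traj = run_dynamics(system, coords, cfg)
    if not traj.completed:
        raise ComplexationFailureError(f"anneal blew up: {traj.error}")
    out, bd, _ = minimize(system, traj.final_state.coords, tol, max_iter)
    if not np.isfinite(bd.total):
        raise ComplexationFailureError("non-finite minimized energy")
    return out, bd.total, traj


def run_complexation(host: Structure, guest: Structure,
                     config: DynamicsConfig | None = None,
                     n_poses: int = 20, paramset: str = "minimal",
                     minimize_tol: float = 0.05,
                     minimize_max_iter: int = 2000,
                     rigid_host: bool = True) -> ComplexResult:
    """Full complexation run: isolated relaxations, pose annealing, Ds.

    ``E_Chit`` and ``E_Insectic`` are the energies of the isolated host and
    guest after one anneal-and-minimize pass (short thermostatted dynamics,
    default 10 ps at 300 K, then gradient minimization).  Poses are built
    from the relaxed structures; each pose is annealed with the same
    protocol and minimized, and ``E_k`` is the lowest minimized complex
    energy over poses.  With ``rigid_host`` (the default) the host is held
    fixed in its relaxed conformation during pose refinement, so its internal
    energy cancels exactly in Ds and the index isolates the host-guest
    interaction; flexible-receptor refinement is deliberately out of scope.
    Deterministic given ``config.seed``.
    """
    if config is None:
        config = DynamicsConfig(duration_ps=10.0)
    host_sys = assign_parameters(host, paramset)
    guest_sys = assign_parameters(guest, paramset)
    # the isolated host and guest get exactly the same anneal-then-minimize
    # treatment as each pose, so all three energies sit in comparable basins;
    # poses are then built from the relaxed structures
    host_x, e_host, _ = _anneal_and_minimize(host_sys, host.coords, config,
                                             0, minimize_tol,
                                             minimize_max_iter)
    guest_x, e_guest, _ = _anneal_and_minimize(guest_sys, guest.coords,
                                               config, 0, minimize_tol,
                                               minimize_max_iter)

    poses = sample_poses(host.with_coords(host_x),
                         guest.with_coords(guest_x), n_poses, config.seed)
    best = None  # (energy, pose index, coords, trajectory, system)
    n_failed = 0
    for k, pose in enumerate(poses):
        pose_sys = assign_parameters(pose, paramset)
        if rigid_host:
            mask = np.zeros(pose_sys.n_atoms, dtype=bool)
            mask[:host.n_atoms] = True
            pose_sys.frozen = mask
        try:
            coords, e_pose, traj = _anneal_and_minimize(
                pose_sys, pose.coords, config, k + 1,
                minimize_tol, minimize_max_iter)
        except (ComplexationFailureError, DivergenceError):
            n_failed += 1
            continue
        if best is None or e_pose < best[0]:
            best = (e_pose, k, coords, traj, pose_sys)
    if best is None:
        raise ComplexationFailureError(
            f"all {n_poses} poses failed ({n_failed} blow-ups)")

    e_k, _, best_coords, best_traj, best_sys = best
    ds = stability_index(e_host, e_guest, e_k)

    # mean inter-molecular H-bond count over the final 20% of snapshots
    times = best_traj.times_fs
    if times:
        t_cut = times[0] + 0.8 * (times[-1] - times[0])
        tail = [t for t in times if t >= t_cut]
        counts = {t: 0 for t in tail}
        for rec in best_traj.hbonds:
            if rec.t_fs in counts:
                counts[rec.t_fs] += 1
        hb_mean = float(np.mean(list(counts.values()))) if tail else 0.0
    else:
        hb_mean = 0.0

    best_pose = best_sys.structure.with_coords(best_coords)
    return ComplexResult(
        host_energy=e_host, guest_energy=e_guest, complex_energy=e_k,
        ds=ds, stability_class=classify_stability(ds),
        n_poses_sampled=n_poses, best_pose=best_pose,
        hbond_mean_count=hb_mean,
    )
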