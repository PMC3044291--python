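"""Rigid-body superposition of binding sites by Monte-Carlo minimization.

The probe site is treated as rigid, so its placement in the template's
property fields has six degrees of freedom: a Cartesian offset of the probe
centroid and three Euler angles applied about that centroid.  The global
optimizer is pseudo-Brownian Monte-Carlo: a random rigid move, local
gradient minimization (bounded number of steps), and a Metropolis
accept/reject on the minimized energy.  The search terminates when the
energy-evaluation budget (default 10,000, counting every evaluation
including those inside the local minimizer) is exhausted, and the best pose
ever seen is polished against, and rescored with, the exact direct-sum
energy (see ``_polish_direct``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize
from scipy.spatial.transform import Rotation

from . import apf_core
from .apf_core import EnergyModel
from .site_io import Atom, Site

GRAD_TOL = 1e-6


def _rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _drot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]])


def _drot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]])


def _drot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[-s, -c, 0], [c, -s, 0], [0, 0, 0]])


@dataclass(frozen=True)
class Pose:
    """Rigid placement: rotate about ``center`` by Euler angles, then shift.

    Maps a probe point r to ``center + translation + R(angles) (r - center)``
    with R = Rz(az) Ry(ay) Rx(ax) (extrinsic x-y-z order).  ``center`` is
    the probe-site centroid, recorded so the same transform can be applied
    to other atom sets (e.g. the ligand for validation).
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("translation", "angles", "center"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = self.angles
        return _rot_z(az) @ _rot_y(ay) @ _rot_x(ax)

    def rotation_and_derivatives(self) -> tuple[np.ndarray, list[np.ndarray]]:
        ax, ay, az = self.angles
        rx, ry, rz = _rot_x(ax), _rot_y(ay), _rot_z(az)
        rot = rz @ ry @ rx
        return rot, [rz @ ry @ _drot_x(ax), rz @ _drot_y(ay) @ rx,
                     _drot_z(az) @ ry @ rx]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return (coords - self.center) @ self.rotation_matrix().T + (
            self.center + self.translation
        )

    def matrix(self) -> np.ndarray:
        """The pose as a 4x4 homogeneous transform."""
        m = np.eye(4)
        rot = self.rotation_matrix()
        m[:3, :3] = rot
        m[:3, 3] = self.center + self.translation - rot @ self.center
        return m

    def inverse(self) -> "Pose":
        rot_inv = self.rotation_matrix().T
        angles = Rotation.from_matrix(rot_inv).as_euler("xyz")
        return Pose(
            translation=-self.translation,
            angles=angles,
            center=self.center + self.translation,
        )

    def canonical(self) -> "Pose":
        """Re-derive angles from the rotation matrix (kept in [-pi, pi])."""
        angles = Rotation.from_matrix(self.rotation_matrix()).as_euler("xyz")
        return replace(self, angles=angles)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.angles])

    def with_params(self, params: np.ndarray) -> "Pose":
        params = np.asarray(params, dtype=float)
        return replace(self, translation=params[:3].copy(),
                       angles=params[3:].copy())


@dataclass
class MCConfig:
    """Monte-Carlo search settings.

    ``kt_eff`` is the effective Metropolis temperature expressed directly in
    pseudo-energy units (the score is unitless; reading it as kcal/mol, the
    default of 10 corresponds to roughly a 5000 K physical temperature).
    """

    max_evaluations: int = 10_000
    local_min_steps: int = 100
    kt_eff: float = 10.0
    step_translation: float = 1.0  # A
    step_rotation: float = 0.25  # rad
    seed: int = 0
    start_mode: str = "centroid"  # or "random"
    grid_spacing: float = apf_core.DEFAULT_SPACING
    carve_radius: float = 6.0
    final_polish: bool = True

    def __post_init__(self) -> None:
        if self.max_evaluations <= 0 or self.local_min_steps <= 0:
            raise ValueError("evaluation and step budgets must be positive")
        if self.kt_eff <= 0:
            raise ValueError("kt_eff must be positive")
        if self.start_mode not in ("centroid", "random"):
            raise ValueError("start_mode must be 'centroid' or 'random'")


@dataclass
class SuperpositionResult:
    best_pose: Pose
    e_apf: float  # direct-sum rescored energy at the best pose
    e_apf_grid: float  # grid energy at the best pose (pre-rescoring)
    evaluations_used: int
    accepted_moves: int
    seed: int
    best_energy_trace: list[float] = field(default_factory=list)


class _EvalCounter:
    def __init__(self, limit: int) -> None:
        self.limit = limit
        self.count = 0

    @property
    def remaining(self) -> int:
        return self.limit - self.count


class _BudgetExhausted(Exception):
    pass


def _random_rotation_angles(rng: np.random.Generator) -> np.ndarray:
    # uniform rotation from a random unit quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_euler("xyz")


def initial_pose(
    template: Site,
    probe: Site,
    mode: str = "centroid",
    rng: np.random.Generator | int | None = None,
) -> Pose:
    """Starting pose: superpose centroids, optionally with a random rotation."""
    if len(template) == 0 or len(probe) == 0:
        raise ValueError("sites must be non-empty")
    center = probe.centroid
    translation = template.centroid - center
    if mode == "centroid":
        angles = np.zeros(3)
    elif mode == "random":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        angles = _random_rotation_angles(rng)
    else:
        raise ValueError(f"unknown initial pose mode {mode!r}")
    return Pose(translation=translation, angles=angles, center=center)


def random_step(pose: Pose, config: MCConfig, rng: np.random.Generator) -> Pose:
    """Pseudo-Brownian move: Gaussian increments on all six pose variables."""
    translation = pose.translation + rng.normal(0.0, config.step_translation, 3)
    angles = pose.angles + rng.normal(0.0, config.step_rotation, 3)
    return replace(pose, translation=translation, angles=angles)


def metropolis_accept(
    delta_e: float, kt_eff: float, rng: np.random.Generator
) -> bool:
    """Accept downhill moves always, uphill with probability exp(-dE/kT)."""
    if kt_eff <= 0:
        raise ValueError("kt_eff must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / kt_eff)


def local_minimize(
    pose: Pose,
    grid: apf_core.APFGrid,
    probe: Site,
    model: EnergyModel,
    max_steps: int = 100,
    counter: _EvalCounter | None = None,
    grad_tol: float = GRAD_TOL,
) -> tuple[Pose, float]:
    """Bounded gradient minimization of E_APF over the 6 pose variables.

    Quasi-Newton (L-BFGS-B) with the analytic gradient; each objective
    evaluation counts one energy evaluation.  Never returns a pose worse
    than the input.
    """
    if max_steps <= 0:
        raise ValueError("max_steps must be positive")
    best: dict = {}

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        if counter is not None:
            if counter.remaining <= 0:
                raise _BudgetExhausted
            counter.count += 1
        energy, grad = apf_core.apf_energy_and_gradient(
            grid, probe, pose.with_params(params), model
        )
        if not best or energy < best["energy"]:
            best["energy"] = energy
            best["params"] = np.array(params, dtype=float)
        return energy, grad

    try:
        minimize(
            objective,
            pose.params,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_steps, "maxfun": max_steps * 3,
                     "gtol": grad_tol},
        )
    except _BudgetExhausted:
        pass
    if not best:  # budget was already exhausted before the first evaluation
        return pose, apf_core.apf_energy(grid, probe, pose, model)
    return pose.with_params(best["params"]), float(best["energy"])


def _polish_direct(
    template: Site,
    probe: Site,
    pose: Pose,
    model: EnergyModel,
    max_steps: int,
) -> Pose:
    """Refine a grid-derived pose against the exact direct-sum energy.

    The grid landscape places its minima up to a fraction of a cell away
    from the true ones; a short off-grid quasi-Newton descent removes that
    residual interpolation bias from the reported pose and energy.
    """
    best: dict = {}

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        energy, grad = apf_core.apf_energy_and_gradient_direct(
            template, probe, pose.with_params(params), model
        )
        if not best or energy < best["energy"]:
            best["energy"] = energy
            best["params"] = np.array(params, dtype=float)
        return energy, grad

    minimize(
        objective,
        pose.params,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": 1e-9},
    )
    return pose.with_params(best["params"])


def monte_carlo_superpose(
    template: Site,
    probe: Site,
    config: MCConfig | None = None,
    model: EnergyModel | None = None,
    grid: apf_core.APFGrid | None = None,
) -> SuperpositionResult:
    """Find the probe pose minimizing E_APF in the template's potentials.

    Fully deterministic for fixed inputs, configuration, and seed.  The
    returned energy is rescored with the direct Gaussian sum so that the
    reported optimum is free of grid-interpolation bias.
    """
    config = config or MCConfig()
    model = model or EnergyModel()
    if len(template) == 0 or len(probe) == 0:
        raise ValueError("sites must be non-empty")
    if config.max_evaluations < 2:
        raise ValueError(
            "evaluation budget too small for one minimization cycle"
        )
    if grid is None:
        grid = apf_core.build_grids(
            template, spacing=config.grid_spacing, width=model.kernel_width
        )
    rng = np.random.default_rng(config.seed)
    counter = _EvalCounter(config.max_evaluations)
    pose = initial_pose(template, probe, config.start_mode, rng)
    pose, energy = local_minimize(
        pose, grid, probe, model, config.local_min_steps, counter
    )
    best_pose, best_energy = pose, energy
    trace = [best_energy]
    accepted = 0
    while counter.remaining >= 2:
        candidate = random_step(pose, config, rng)
        candidate, cand_energy = local_minimize(
            candidate, grid, probe, model, config.local_min_steps, counter
        )
        if cand_energy < best_energy:
            best_pose, best_energy = candidate, cand_energy
        if metropolis_accept(cand_energy - energy, config.kt_eff, rng):
            pose, energy = candidate.canonical(), cand_energy
            accepted += 1
        trace.append(best_energy)
    if config.final_polish:
        best_pose = _polish_direct(
            template, probe, best_pose, model, config.local_min_steps
        )
    e_direct = apf_core.apf_energy_direct(template, probe, best_pose, model)
    return SuperpositionResult(
        best_pose=best_pose,
        e_apf=e_direct,
        e_apf_grid=best_energy,
        evaluations_used=counter.count,
        accepted_moves=accepted,
        seed=config.seed,
        best_energy_trace=trace,
    )


# ---------------------------------------------------------------------------
# applying poses and validating with the ligand


def apply_pose(atoms: list[Atom], pose: Pose) -> list[Atom]:
    """Rigidly transform a list of atoms by the pose."""
    coords = pose.apply(np.array([a.coords for a in atoms]))
    return [replace(a, coords=c) for a, c in zip(atoms, coords)]


def _heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() != "H"]


def ligand_rmsd(
    ligand_a: list[Atom], ligand_b: list[Atom], pose: Pose
) -> float:
    """RMSD between ligand A and the pose-transformed ligand B (heavy atoms).

    The ligands never took part in the superposition; a low value indicates
    that aligning the property fields of the pockets also aligned their
    bound ligands.  Atoms are matched by identical names when the residue
    codes agree, otherwise by a minimum-cost element-constrained assignment.
    """
    a = _heavy(ligand_a)
    b = _heavy(apply_pose(ligand_b, pose))
    if not a or not b or len(a) != len(b):
        raise ValueError(
            f"cannot match ligands with {len(a)} vs {len(b)} heavy atoms"
        )
    codes_a = {x.residue_name for x in a}
    codes_b = {x.residue_name for x in b}
    names_a = [x.name for x in a]
    if (
        codes_a == codes_b
        and len(set(names_a)) == len(names_a)
        and set(names_a) == {x.name for x in b}
    ):
        by_name = {x.name: x for x in b}
        pairs = [(x, by_name[x.name]) for x in a]
    else:
        if sorted(x.element for x in a) != sorted(x.element for x in b):
            raise ValueError("ligand element compositions differ; no correspondence")
        ca = np.array([x.coords for x in a])
        cb = np.array([x.coords for x in b])
        cost = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
        mismatch = np.array(
            [[x.element != y.element for y in b] for x in a]
        )
        cost[mismatch] = 1e9
        rows, cols = linear_sum_assignment(cost)
        if mismatch[rows, cols].any():
            raise ValueError("no element-consistent atom correspondence found")
        pairs = [(a[i], b[j]) for i, j in zip(rows, cols)]
    deltas = np.array([x.coords - y.coords for x, y in pairs])
    return float(np.sqrt(np.mean(np.sum(deltas**2, axis=1))))


def site_rmsd(site_a: Site, site_b: Site, pose: Pose) -> float:
    """RMSD between corresponding site atoms after posing site B.

    Assumes one-to-one atom correspondence by order (e.g. a site and its
    perturbed copy); used for ground-truth recovery checks.
    """
    if len(site_a) != len(site_b):
        raise ValueError("sites must have equal atom counts")
    moved = pose.apply(site_b.coords)
    return float(np.sqrt(np.mean(np.sum((site_a.coords - moved) ** 2, axis=1))))
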