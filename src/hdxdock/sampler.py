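"""Toy rigid-body Metropolis docking with HDX-penalty guidance.

This sampler exercises the contract "restraint violations discourage
acceptance" on synthetic complexes. The antibody moves as a rigid body
about its C-alpha centroid; the antigen stays fixed (relative motion is all
that matters). Each step proposes a Gaussian perturbation (3 Angstrom, 8
degrees by default), scores the pose with a coarse surrogate plus, when
enabled, the HDX flat-harmonic penalty at a 1:1 default ratio, and accepts
by the Metropolis rule.

The surrogate score is deliberately non-physical: it exists only to give
the sampler a funnel to balance against the restraints. It counts
inter-partner C-alpha pairs: clashes (< 3.5 Angstrom) cost +10 each,
contacts (3.5 to 8 Angstrom) reward -1 each; lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import AtomRecord, DockingConfig, StructureModel
from .restraints import flat_harmonic

CLASH_CUTOFF = 3.5  # Angstrom
CONTACT_CUTOFF = 8.0
CLASH_WEIGHT = 10.0
CONTACT_WEIGHT = 1.0


class SamplerError(ValueError):
    pass


@dataclass(frozen=True)
class Pose:
    """Rigid motion of the antibody about its original C-alpha centroid."""

    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # Angstrom
    seed: int = 0
    step: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise SamplerError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise SamplerError("rotation determinant must be +1")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise SamplerError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        return (coords - centroid) @ np.asarray(self.rotation).T + centroid + np.asarray(
            self.translation
        )

    def compose(self, rotation: np.ndarray, translation: np.ndarray, step: int) -> "Pose":
        # A rotation about the *current* centroid followed by a translation
        # composes as R <- Rp R, t <- t + tp in the original-centroid frame.
        return Pose(
            rotation=np.asarray(rotation) @ np.asarray(self.rotation),
            translation=np.asarray(self.translation) + np.asarray(translation),
            seed=self.seed,
            step=step,
        )


@dataclass(frozen=True)
class SamplerConfig:
    displacement: float = 10.0  # initial scrambling displacement, Angstrom
    rotation_deg: float = 60.0  # nominal interface-scrambling rotation
    perturb_trans_sd: float = 3.0  # Angstrom
    perturb_rot_sd: float = 8.0  # degrees
    steps: int = 500
    temperature: float = 1.0  # Metropolis scale, surrogate-score units
    hdx_ratio: float = 1.0  # weight of the HDX penalty vs the surrogate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "displacement",
            "rotation_deg",
            "perturb_trans_sd",
            "perturb_rot_sd",
            "temperature",
            "hdx_ratio",
        ):
            if getattr(self, name) <= 0:
                raise SamplerError(f"{name} must be positive")


@dataclass(frozen=True)
class TrajectoryStep:
    step: int
    surrogate: float
    hdx_penalty: float
    total: float
    accepted: bool


# ---------------------------------------------------------------------------
# Random rigid motions
# ---------------------------------------------------------------------------


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rotation_uniform(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def axis_angle_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def gaussian_perturbation(
    rng: np.random.Generator, trans_sd: float, rot_sd_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-uniform rotation with Gaussian angle, plus a Gaussian-length translation."""
    angle = np.deg2rad(rng.normal(0.0, rot_sd_deg))
    R = axis_angle_rotation(random_unit_vector(rng), angle)
    t = random_unit_vector(rng) * rng.normal(0.0, trans_sd)
    return R, t


# ---------------------------------------------------------------------------
# Scoring machinery
# ---------------------------------------------------------------------------


class _ComplexArrays:
    """Index-based coordinate views of one complex, for fast pose scoring."""

    def __init__(self, complex_model: StructureModel, config: DockingConfig):
        ab_cas = complex_model.ca_map(complex_model.ab_chains)
        ag_cas = complex_model.ca_map(complex_model.ag_chains)
        if not ab_cas or not ag_cas:
            raise SamplerError("complex must have C-alpha atoms on both partners")
        names = complex_model.residue_names()
        self.ab_keys = sorted(ab_cas)
        self.ag_keys = sorted(ag_cas)
        self.ab_ca = np.array([ab_cas[k] for k in self.ab_keys])
        self.ag_ca = np.array([ag_cas[k] for k in self.ag_keys])
        self.centroid = self.ab_ca.mean(axis=0)
        self.cdr_idx = np.array(
            [i for i, k in enumerate(self.ab_keys) if config.cdrs.contains(k)], dtype=int
        )
        if self.cdr_idx.size == 0:
            raise SamplerError("no CDR C-alpha atoms found on the antibody")
        spec = config.restraint_spec
        self.peptide_idx: list[tuple[str, np.ndarray]] = []
        for pep in config.hdx_peptides:
            idx = [
                i
                for i, k in enumerate(self.ag_keys)
                if pep.covers(k) and not (spec.exclude_proline and names.get(k) == "PRO")
            ]
            if len(idx) < spec.k:
                raise SamplerError(
                    f"peptide {pep.label}: fewer than k={spec.k} eligible residues"
                )
            self.peptide_idx.append((pep.label, np.array(idx, dtype=int)))
        self.d = spec.d
        self.k = spec.k
        # all antibody atoms, for exporting final models
        self.ab_atoms = complex_model.partner_atoms("ab")
        self.ab_atom_xyz = np.array([a.coords for a in self.ab_atoms]).reshape(-1, 3)


def surrogate_score_from_coords(ab_ca: np.ndarray, ag_ca: np.ndarray) -> float:
    dists = cdist(ab_ca, ag_ca)
    clashes = int((dists < CLASH_CUTOFF).sum())
    contacts = int(((dists >= CLASH_CUTOFF) & (dists < CONTACT_CUTOFF)).sum())
    return CLASH_WEIGHT * clashes - CONTACT_WEIGHT * contacts


def surrogate_score(model: StructureModel) -> float:
    """Coarse inter-partner score of a posed model (lower is better)."""
    ab = np.array([a.coords for a in model.partner_atoms("ab") if a.atom_name == "CA"])
    ag = np.array([a.coords for a in model.partner_atoms("ag") if a.atom_name == "CA"])
    if ab.size == 0 or ag.size == 0:
        raise SamplerError("both partners need C-alpha atoms")
    return surrogate_score_from_coords(ab, ag)


def _hdx_penalty_from_coords(arrays: _ComplexArrays, ab_ca: np.ndarray) -> float:
    cdr = ab_ca[arrays.cdr_idx]
    total = 0.0
    for _, idx in arrays.peptide_idx:
        per_res_min = cdist(arrays.ag_ca[idx], cdr).min(axis=1)
        x = np.partition(per_res_min, arrays.k - 1)[arrays.k - 1]
        total += flat_harmonic(float(x), arrays.d)
    return total


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def scramble_start(
    complex_model: StructureModel, config: DockingConfig, sampler_config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> Pose:
    """Scramble the interface: displace the antibody by exactly
    ``displacement`` Angstrom in a random direction, randomize its
    orientation uniformly, then apply one Gaussian perturbation."""
    if rng is None:
        rng = np.random.default_rng(sampler_config.seed)
    t0 = sampler_config.displacement * random_unit_vector(rng)
    R0 = random_rotation_uniform(rng)
    pose = Pose(rotation=R0, translation=t0, seed=sampler_config.seed, step=0)
    Rp, tp = gaussian_perturbation(
        rng, sampler_config.perturb_trans_sd, sampler_config.perturb_rot_sd
    )
    return pose.compose(Rp, tp, step=0)


def apply_pose(complex_model: StructureModel, pose: Pose) -> StructureModel:
    """Return a copy of the complex with the pose applied to every antibody atom."""
    ab_ca = np.array(
        [
            a.coords
            for a in complex_model.atoms
            if a.chain_id in complex_model.ab_chains and a.atom_name == "CA"
        ]
    )
    centroid = ab_ca.mean(axis=0)
    atoms = []
    for a in complex_model.atoms:
        if a.chain_id in complex_model.ab_chains:
            xyz = pose.apply(np.asarray(a.coords), centroid)
            atoms.append(replace(a, coords=(float(xyz[0]), float(xyz[1]), float(xyz[2]))))
        else:
            atoms.append(a)
    return complex_model.with_atoms(atoms)


def metropolis_run(
    complex_model: StructureModel,
    config: DockingConfig,
    sampler_config: SamplerConfig,
    use_hdx: bool = True,
    start_pose: Pose | None = None,
) -> tuple[list[TrajectoryStep], Pose, StructureModel]:
    """One Metropolis trajectory from a scrambled start.

    Returns the per-step trajectory, the final pose, and the final posed
    model. Fully reproducible from ``sampler_config.seed``.
    """
    if sampler_config.steps < 0:
        raise SamplerError("steps must be >= 0")
    rng = np.random.default_rng(sampler_config.seed)
    arrays = _ComplexArrays(complex_model, config)

    pose = start_pose if start_pose is not None else scramble_start(
        complex_model, config, sampler_config, rng
    )

    def energy(p: Pose) -> tuple[float, float, float]:
        ab_ca = p.apply(arrays.ab_ca, arrays.centroid)
        surr = surrogate_score_from_coords(ab_ca, arrays.ag_ca)
        hdx = _hdx_penalty_from_coords(arrays, ab_ca)
        total = surr + sampler_config.hdx_ratio * hdx if use_hdx else surr
        return surr, hdx, total

    surr, hdx, total = energy(pose)
    trajectory = [TrajectoryStep(step=0, surrogate=surr, hdx_penalty=hdx, total=total, accepted=True)]
    for step in range(1, sampler_config.steps + 1):
        Rp, tp = gaussian_perturbation(
            rng, sampler_config.perturb_trans_sd, sampler_config.perturb_rot_sd
        )
        candidate = pose.compose(Rp, tp, step=step)
        c_surr, c_hdx, c_total = energy(candidate)
        delta = c_total - total
        accepted = delta <= 0 or rng.random() < np.exp(-delta / sampler_config.temperature)
        if accepted:
            pose, surr, hdx, total = candidate, c_surr, c_hdx, c_total
        trajectory.append(
            TrajectoryStep(
                step=step,
                surrogate=c_surr if accepted else surr,
                hdx_penalty=c_hdx if accepted else hdx,
                total=c_total if accepted else total,
                accepted=accepted,
            )
        )
    return trajectory, pose, apply_pose(complex_model, pose)
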