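"""Deterministic synthetic fixtures: toy complexes, decoy ensembles, uptake tables.

The toy complex is an idealized C-alpha-trace antibody-antigen pair built on
a 3.8-Angstrom grid. The antigen is a single extended chain along x; the two
antibody chains run parallel above it, with their CDR residues dipped to
about 6.7 Angstrom from the antigen C-alphas (within the 10-Angstrom
restraint threshold) and framework residues held above 12 Angstrom. Each
residue carries a couple of pendant heavy atoms so that interface and
native-contact definitions, which work on heavy atoms, are exercised; CDR
residues carry a pendant that reaches under 5 Angstrom of an antigen atom,
giving the reference a well-defined contact set.

Planted interacting peptides span the epitope; planted allosteric peptides
are placed down-chain so that no near-native pose can satisfy them. The
geometry emulates the restraint logic of real complexes, not real protein
shapes: there is no secondary structure, no side chains, and no
self-avoidance, which is irrelevant for every quantity this toolkit computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import compute_quality
from .hdx_filter import UptakeRecord
from .model_io import (
    AtomRecord,
    CDRDefinition,
    CDRSegment,
    DockingConfig,
    HDXPeptide,
    RestraintSpec,
    StructureModel,
)
from .restraints import model_hdx_penalty, penalty_table
from .sampler import Pose, axis_angle_rotation, random_rotation_uniform, random_unit_vector

CA_SPACING = 3.8  # Angstrom


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Everything needed to regenerate a synthetic study deterministically."""

    seed: int = 0
    n_ab_per_chain: int = 24
    n_ag_residues: int = 60
    n_decoys: int = 200
    # planted peptide spans in antigen author numbering (inclusive)
    interacting_spans: tuple[tuple[int, int], ...] = ((27, 34), (33, 40))
    allosteric_spans: tuple[tuple[int, int], ...] = ()
    # decoy perturbation ranges (controls the iRMSD spread)
    near_native_fraction: float = 0.4
    near_disp_max: float = 2.0  # Angstrom
    near_rot_max: float = 5.0  # degrees
    far_disp_max: float = 20.0
    far_rot_max: float = 40.0
    # base-score model: score = offset + slope * iRMSD + noise_sd * N(0,1)
    score_offset: float = -30.0
    score_slope: float = 1.0
    score_noise_sd: float = 0.5
    restraint: RestraintSpec = field(default_factory=RestraintSpec)

    def __post_init__(self) -> None:
        if self.n_ag_residues < 10 or self.n_ab_per_chain < 16:
            raise FixtureError("toy complex needs >= 10 antigen and >= 16 antibody residues")


AB_FRAMEWORK_Z = 12.0
AB_CDR_Z = 6.0
AB_Y = 3.0
CDR_START_IDX = 9  # 0-based; CDR residues 10..15 in author numbering
CDR_END_IDX = 14
H_X_OFFSET_RES = 20  # chain H starts at antigen residue-grid index 20
L_X_SHIFT = 2 * CA_SPACING


def _residue_atoms(
    chain: str, seq: int, ca: np.ndarray, cdr_pendant: bool
) -> list[AtomRecord]:
    """CA plus pendant heavy atoms; CDR residues get a pendant reaching toward
    the antigen so the reference complex has sub-5-Angstrom contacts."""
    x, y, z = (float(v) for v in ca)
    atoms = [
        AtomRecord(chain, seq, "", "ALA", "CA", (x, y, z), "C"),
        AtomRecord(chain, seq, "", "ALA", "O", (x + 1.2, y - 0.8, z + 0.6), "O"),
    ]
    if cdr_pendant:
        atoms.append(AtomRecord(chain, seq, "", "ALA", "CB", (x, y - 1.0, z - 2.5), "C"))
    else:
        atoms.append(AtomRecord(chain, seq, "", "ALA", "CB", (x, y + 1.0, z - 1.2), "C"))
    return atoms


def make_toy_complex(spec: FixtureSpec) -> tuple[StructureModel, DockingConfig]:
    """Reference complex plus a matching docking configuration.

    By construction every planted interacting peptide has an effective
    CA-CA distance to the CDRs of about 6.7-7 Angstrom (satisfied at the
    default 10-Angstrom threshold) and every planted allosteric peptide sits
    beyond 10 Angstrom in the reference.
    """
    atoms: list[AtomRecord] = []
    # antigen chain A along x, zig-zagged in y so its CA set is never collinear
    # (a collinear receptor would leave the superposition roll undetermined)
    for i in range(spec.n_ag_residues):
        x = CA_SPACING * i
        y = 0.6 * (-1) ** i
        atoms.append(AtomRecord("A", i + 1, "", "ALA", "CA", (x, y, 0.0), "C"))
        atoms.append(AtomRecord("A", i + 1, "", "ALA", "CB", (x, y - 1.0, -1.2), "C"))
        atoms.append(AtomRecord("A", i + 1, "", "ALA", "O", (x + 1.2, y - 0.8, 0.6), "O"))
    # antibody chains H (y=+3) and L (y=-3), CDR residues dipped toward the antigen
    for chain, y_sign, x_shift in (("H", 1.0, 0.0), ("L", -1.0, L_X_SHIFT)):
        x0 = CA_SPACING * H_X_OFFSET_RES + x_shift
        for j in range(spec.n_ab_per_chain):
            is_cdr = CDR_START_IDX <= j <= CDR_END_IDX
            z = AB_CDR_Z if is_cdr else AB_FRAMEWORK_Z
            ca = np.array([x0 + CA_SPACING * j, y_sign * AB_Y, z])
            atoms.extend(_residue_atoms(chain, j + 1, ca, cdr_pendant=is_cdr))

    reference = StructureModel(
        model_id="reference", atoms=atoms, ab_chains=frozenset("HL"), ag_chains=frozenset("A")
    )
    peptides = [
        HDXPeptide(label=f"pep{i + 1}", chain_id="A", start=s, end=e)
        for i, (s, e) in enumerate(spec.interacting_spans)
    ] + [
        HDXPeptide(label=f"allo{i + 1}", chain_id="A", start=s, end=e)
        for i, (s, e) in enumerate(spec.allosteric_spans)
    ]
    config = DockingConfig(
        ab_chains=frozenset("HL"),
        ag_chains=frozenset("A"),
        cdrs=CDRDefinition(
            segments=(
                CDRSegment("H", CDR_START_IDX + 1, CDR_END_IDX + 1),
                CDRSegment("L", CDR_START_IDX + 1, CDR_END_IDX + 1),
            )
        ),
        hdx_peptides=peptides,
        restraint_spec=spec.restraint,
    )
    # construction self-check: planted geometry must realize its labels
    mp = model_hdx_penalty(reference, peptides, config.cdrs, spec.restraint)
    for pp in mp.peptides:
        if pp.label.startswith("pep") and pp.x > spec.restraint.d:
            raise FixtureError(f"planted interacting peptide {pp.label} not satisfied (x={pp.x:.1f})")
        if pp.label.startswith("allo") and pp.x <= spec.restraint.d:
            raise FixtureError(f"planted allosteric peptide {pp.label} too close (x={pp.x:.1f})")
    return reference, config


def _perturbed_model(
    reference: StructureModel,
    model_id: str,
    translation: np.ndarray,
    rotation: np.ndarray,
) -> StructureModel:
    pose = Pose(rotation=rotation, translation=translation)
    from .sampler import apply_pose

    model = apply_pose(reference, pose)
    return reference.with_atoms(model.atoms, model_id=model_id)


def make_decoy_ensemble(
    reference: StructureModel,
    spec: FixtureSpec,
) -> tuple[list[StructureModel], dict[str, float], dict[str, float]]:
    """Rigid-body decoys of the antibody plus a base interface-score table.

    Returns ``(models, base_scores, irmsd_by_model)``. Base scores are a
    monotone (slope > 0) function of the decoy's true iRMSD plus Gaussian
    noise, so ranking quality is tunable; with zero noise the score ranking
    is exactly the iRMSD ranking.
    """
    rng = np.random.default_rng(spec.seed)
    models: list[StructureModel] = []
    base_scores: dict[str, float] = {}
    irmsd: dict[str, float] = {}
    n_near = int(round(spec.near_native_fraction * spec.n_decoys))
    for i in range(spec.n_decoys):
        near = i < n_near
        disp_max = spec.near_disp_max if near else spec.far_disp_max
        rot_max = spec.near_rot_max if near else spec.far_rot_max
        t = random_unit_vector(rng) * rng.uniform(0.0, disp_max)
        angle = np.deg2rad(rng.uniform(0.0, rot_max))
        R = axis_angle_rotation(random_unit_vector(rng), angle)
        model_id = f"decoy_{i:04d}"
        model = _perturbed_model(reference, model_id, t, R)
        q = compute_quality(model, reference)
        models.append(model)
        irmsd[model_id] = q.irmsd
        base_scores[model_id] = (
            spec.score_offset
            + spec.score_slope * q.irmsd
            + spec.score_noise_sd * rng.normal()
        )
    return models, base_scores, irmsd


# ---------------------------------------------------------------------------
# Allostery study cases
# ---------------------------------------------------------------------------


@dataclass
class AllosteryCase:
    reference: StructureModel
    config: DockingConfig
    models: list[StructureModel]
    base_scores: dict[str, float]
    irmsd: dict[str, float]
    penalties: "object"  # pandas DataFrame: model x peptide
    planted_allosteric: list[str]


FAILURE_MODE_ALLO_SPAN = (43, 47)  # reachable by a shifted non-native pose
FAR_ALLO_SPANS = ((53, 58), (48, 52))


def make_allostery_case(
    seed: int,
    n_interacting: int = 2,
    n_allosteric: int = 1,
    failure_mode: bool = False,
    n_decoys: int = 120,
) -> AllosteryCase:
    """A decoy ensemble with planted allosteric peptide(s) in the restraint set.

    In the default construction the allosteric peptide(s) sit far down the
    antigen chain, so every model near the true epitope carries a residual
    penalty and the top-10 mean weighted HDX score is driven above the
    detection threshold.

    With ``failure_mode=True`` the allosteric peptide is placed close enough
    that a shifted, non-native pose can satisfy the whole restraint set at
    once; those poses are additionally given the most favorable base scores.
    This reproduces the known blind spot of the metric: the dataset contains
    an allosteric peptide yet is not flagged, because the best-scoring decoys
    happen to satisfy it.
    """
    if n_allosteric < 1:
        raise FixtureError("an allostery case needs at least one planted allosteric peptide")
    interacting = (((27, 34), (33, 40), (24, 30))[:n_interacting])
    if failure_mode:
        allosteric = (FAILURE_MODE_ALLO_SPAN,)[:n_allosteric]
    else:
        allosteric = FAR_ALLO_SPANS[:n_allosteric]
    spec = FixtureSpec(
        seed=seed,
        n_decoys=n_decoys,
        interacting_spans=interacting,
        allosteric_spans=allosteric,
    )
    reference, config = make_toy_complex(spec)
    models, base_scores, irmsd = make_decoy_ensemble(reference, spec)

    if failure_mode:
        rng = np.random.default_rng(seed + 1)
        shift = _find_satisfying_shift(reference, config)
        n_planted = max(10, n_decoys // 8)
        for i in range(n_planted):
            jitter = random_unit_vector(rng) * rng.uniform(0.0, 0.5)
            model_id = f"shifted_{i:04d}"
            model = _perturbed_model(reference, model_id, shift + jitter, np.eye(3))
            q = compute_quality(model, reference)
            models.append(model)
            irmsd[model_id] = q.irmsd
            # these non-native poses win the base-score ranking outright
            base_scores[model_id] = -40.0 + rng.uniform(0.0, 0.5)

    penalties = penalty_table(models, config.hdx_peptides, config.cdrs, config.restraint_spec)
    return AllosteryCase(
        reference=reference,
        config=config,
        models=models,
        base_scores=base_scores,
        irmsd=irmsd,
        penalties=penalties,
        planted_allosteric=[p.label for p in config.hdx_peptides if p.label.startswith("allo")],
    )


def _find_satisfying_shift(reference: StructureModel, config: DockingConfig) -> np.ndarray:
    """Grid-search an x-translation of the antibody that satisfies every
    restraint, including the planted allosteric one."""
    margin = 0.75  # Angstrom of slack so pose jitter cannot re-violate
    for dx in np.arange(5.0, 80.0, 0.5):
        shift = np.array([dx, 0.0, 0.0])
        model = _perturbed_model(reference, "probe", shift, np.eye(3))
        mp = model_hdx_penalty(
            model, config.hdx_peptides, config.cdrs, config.restraint_spec
        )
        if all(p.x <= config.restraint_spec.d - margin for p in mp.peptides):
            return shift
    raise FixtureError("no x-shift satisfies the full restraint set; geometry infeasible")


# ---------------------------------------------------------------------------
# Uptake tables
# ---------------------------------------------------------------------------


def make_uptake_table(
    spec: FixtureSpec,
    timepoints: tuple[float, ...] = (100.0, 1000.0),
    protected_diff: tuple[float, ...] = (0.8, 0.9),
    noise_sd: float = 0.0,
    replicate_sd: float = 0.03,
    n_noise_peptides: int = 4,
) -> tuple[list[UptakeRecord], set[str]]:
    """Synthetic bound/unbound uptake table with known truth labels.

    Planted peptides (the spec's interacting and allosteric spans — both are
    genuinely protected in an HDX experiment) receive protection differences
    clearing every significance gate; filler peptides get zero-mean noise.
    Returns ``(records, truth_labels)``.
    """
    if len(protected_diff) != len(timepoints):
        raise FixtureError("protected_diff must have one value per timepoint")
    rng = np.random.default_rng(spec.seed)
    records: list[UptakeRecord] = []
    truth: set[str] = set()
    spans = [
        (f"pep{i + 1}", s, e) for i, (s, e) in enumerate(spec.interacting_spans)
    ] + [(f"allo{i + 1}", s, e) for i, (s, e) in enumerate(spec.allosteric_spans)]
    for label, s, e in spans:
        unbound = tuple(3.0 + 0.5 * np.log10(t) for t in timepoints)
        bound = tuple(
            u - d + noise_sd * rng.normal() for u, d in zip(unbound, protected_diff)
        )
        records.append(
            UptakeRecord(
                label=label,
                chain_id="A",
                start=s,
                end=e,
                timepoints=timepoints,
                unbound_mean=unbound,
                bound_mean=bound,
                unbound_sd=(replicate_sd,) * len(timepoints),
                bound_sd=(replicate_sd,) * len(timepoints),
            )
        )
        truth.add(label)
    used_to = max((e for _, _, e in spans), default=0)
    for i in range(n_noise_peptides):
        start = used_to + 2 + 6 * i
        unbound = tuple(3.0 + 0.5 * np.log10(t) for t in timepoints)
        bound = tuple(u - 0.05 * rng.normal() for u in unbound)
        records.append(
            UptakeRecord(
                label=f"noise{i + 1}",
                chain_id="A",
                start=start,
                end=start + 5,
                timepoints=timepoints,
                unbound_mean=unbound,
                bound_mean=bound,
                unbound_sd=(replicate_sd,) * len(timepoints),
                bound_sd=(replicate_sd,) * len(timepoints),
            )
        )
    return records, truth
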