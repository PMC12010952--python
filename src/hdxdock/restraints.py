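"""HDX-derived distance restraints and flat-harmonic penalty scores.

Each HDX-interacting peptide on the antigen is turned into a restraint: at
least ``k`` of its non-proline residues must place a C-alpha within ``d``
Angstrom of any C-alpha in the antibody CDRs. A model's violation of a
restraint is measured by the effective shortest C-alpha distance ``x`` and
penalized with a flat harmonic: zero for ``x <= d``, ``(x - d)**2`` beyond.
The per-model HDX penalty is the sum over all peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import (
    CDRDefinition,
    HDXPeptide,
    RestraintSpec,
    StructureModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RestraintSpec",
    "PeptidePenalty",
    "ModelPenalty",
    "flat_harmonic",
    "peptide_effective_distance",
    "model_hdx_penalty",
    "penalty_table",
    "percent_normalize",
    "RestraintError",
]


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class PeptidePenalty:
    label: str
    x: float  # effective shortest CA-CA distance, Angstrom
    penalty: float  # flat-harmonic value, squared-Angstrom


@dataclass(frozen=True)
class ModelPenalty:
    model_id: str
    peptides: tuple[PeptidePenalty, ...]

    @property
    def total(self) -> float:
        return float(sum(p.penalty for p in self.peptides))


def flat_harmonic(x: float, d: float) -> float:
    """Flat-harmonic restraint penalty: 0 inside the threshold, squared excess outside."""
    if d <= 0:
        raise RestraintError(f"threshold d must be positive, got {d}")
    x = float(x)
    return 0.0 if x <= d else (x - d) ** 2


def _cdr_ca_coords(model: StructureModel, cdrs: CDRDefinition) -> np.ndarray:
    cas = model.ca_map(model.ab_chains)
    coords = [xyz for key, xyz in cas.items() if cdrs.contains(key)]
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def _peptide_ca_coords(
    model: StructureModel, peptide: HDXPeptide, exclude_proline: bool
) -> np.ndarray:
    cas = model.ca_map(model.ag_chains)
    names = model.residue_names()
    coords = []
    n_span = 0
    for key, xyz in cas.items():
        if not peptide.covers(key):
            continue
        n_span += 1
        if exclude_proline and names.get(key) == "PRO":
            continue
        coords.append(xyz)
    expected = peptide.end - peptide.start + 1
    if n_span < expected:
        # Peptides from homologous strains may not map residue-for-residue;
        # absent residues simply drop out of the distance search.
        logger.info(
            "peptide %s: %d of %d residues present in model %s",
            peptide.label,
            n_span,
            expected,
            model.model_id,
        )
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def peptide_effective_distance(
    model: StructureModel,
    peptide: HDXPeptide,
    cdrs: CDRDefinition,
    spec: RestraintSpec,
) -> float:
    """Effective shortest CA-CA distance between a peptide and the CDRs.

    For each eligible peptide residue the minimum distance to any CDR CA is
    taken; the k-th smallest of those per-residue minima is returned. At
    k = 1 this is the global shortest CA-CA distance.
    """
    pep_xyz = _peptide_ca_coords(model, peptide, spec.exclude_proline)
    if pep_xyz.shape[0] == 0:
        raise RestraintError(
            f"peptide {peptide.label}: no eligible residues with CA in model "
            f"{model.model_id} (all-proline span or residues absent)"
        )
    cdr_xyz = _cdr_ca_coords(model, cdrs)
    if cdr_xyz.shape[0] == 0:
        raise RestraintError(
            f"peptide {peptide.label}: no CDR CA atoms parsed in model {model.model_id}"
        )
    if pep_xyz.shape[0] < spec.k:
        raise RestraintError(
            f"peptide {peptide.label}: only {pep_xyz.shape[0]} eligible residues "
            f"but spec requires k={spec.k}"
        )
    per_residue_min = cdist(pep_xyz, cdr_xyz).min(axis=1)
    return float(np.partition(per_residue_min, spec.k - 1)[spec.k - 1])


def model_hdx_penalty(
    model: StructureModel,
    peptides: Sequence[HDXPeptide],
    cdrs: CDRDefinition,
    spec: RestraintSpec,
) -> ModelPenalty:
    """Sum of flat-harmonic penalties over all HDX peptides for one model."""
    parts = []
    for pep in peptides:
        x = peptide_effective_distance(model, pep, cdrs, spec)
        parts.append(PeptidePenalty(label=pep.label, x=x, penalty=flat_harmonic(x, spec.d)))
    return ModelPenalty(model_id=model.model_id, peptides=tuple(parts))


def penalty_table(
    models: Iterable[StructureModel],
    peptides: Sequence[HDXPeptide],
    cdrs: CDRDefinition,
    spec: RestraintSpec,
) -> pd.DataFrame:
    """Per-model, per-peptide penalty matrix (rows: model_id, columns: peptide label).

    The row sum is the model's raw HDX score; keeping the per-peptide
    breakdown is what makes the leave-one-out allostery scan possible
    without re-measuring any distance.
    """
    records: dict[str, dict[str, float]] = {}
    for model in models:
        mp = model_hdx_penalty(model, peptides, cdrs, spec)
        records[model.model_id] = {p.label: p.penalty for p in mp.peptides}
    df = pd.DataFrame.from_dict(records, orient="index")
    df = df.reindex(columns=[p.label for p in peptides])
    df.index.name = "model_id"
    return df


def percent_normalize(penalties: Sequence[float]) -> np.ndarray:
    """Express raw penalties as a percentage of the ensemble maximum.

    Used to compare restraint stringency settings across ensembles; an
    all-zero list (every model satisfies every restraint) maps to zeros.
    """
    arr = np.asarray(penalties, dtype=float)
    if arr.size == 0:
        raise RestraintError("cannot normalize an empty penalty list")
    m = arr.max()
    if m == 0:
        return np.zeros_like(arr)
    return 100.0 * arr / m
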