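"""Model-quality and scoring-performance metrics.

Accuracy of a docked pose is measured against a reference complex with the
standard CAPRI quantities: fnat (fraction of native inter-partner residue
contacts reproduced, heavy-atom pairs under 5 Angstrom), L-RMSD (antibody
C-alpha RMSD after superposing on the antigen), and iRMSD (C-alpha RMSD
over the reference-defined interface residues after superposing on those
same C-alphas). The interface is every residue with a heavy atom within
10 Angstrom of the partner. Classes:

    high        fnat >= 0.5  and (L-RMSD <= 1  or iRMSD <= 1)
    medium      fnat >= 0.3  and (L-RMSD <= 5  or iRMSD <= 2)
    acceptable  fnat >= 0.1  and (L-RMSD <= 10 or iRMSD <= 4)
    incorrect   otherwise

with the best class satisfied taken. "Near-native" means acceptable or
better; a docking run is "successful" if at least one near-native model is
in the top 10 by score.

Scoring performance of a ranked ensemble uses the enrichment statistic
(TP/(TP+FP)) * ((P+N)/P) over the top-10%-by-score positives, and the
two-sample Kolmogorov-Smirnov test between iRMSD distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .model_io import ResidueKey, StructureModel

FNAT_CONTACT_CUTOFF = 5.0  # Angstrom, heavy-atom, CAPRI convention
INTERFACE_CUTOFF = 10.0  # Angstrom, heavy-atom

NEAR_NATIVE_CLASSES = frozenset({"acceptable", "medium", "high"})


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class QualityMetrics:
    fnat: float
    lrmsd: float
    irmsd: float
    capri_class: str

    @property
    def near_native(self) -> bool:
        return self.capri_class in NEAR_NATIVE_CLASSES


@dataclass(frozen=True)
class EnrichmentResult:
    P: int
    N: int
    TP: int
    FP: int
    enrichment: float


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def superpose_rmsd(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of paired coordinate lists.

    Returns ``(R, t, rmsd)`` with the proper rotation R (never a reflection)
    and translation t such that ``x @ R.T + t`` best maps mobile onto target.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise EvaluationError(
            f"coordinate lists must be equal-shape Nx3, got {mobile.shape} vs {target.shape}"
        )
    if mobile.shape[0] < 3:
        raise EvaluationError("superposition needs at least 3 paired points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _heavy_coords_by_residue(
    model: StructureModel, chains: frozenset[str]
) -> tuple[list[ResidueKey], np.ndarray, np.ndarray]:
    """Flat heavy-atom coordinate array plus a residue index per atom."""
    keys: list[ResidueKey] = []
    key_index: dict[ResidueKey, int] = {}
    coords = []
    res_idx = []
    for a in model.heavy_atoms(chains):
        if a.residue_key not in key_index:
            key_index[a.residue_key] = len(keys)
            keys.append(a.residue_key)
        coords.append(a.coords)
        res_idx.append(key_index[a.residue_key])
    return keys, np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(res_idx, dtype=int)


def _residue_contact_pairs(
    model: StructureModel, cutoff: float
) -> set[tuple[ResidueKey, ResidueKey]]:
    ab_keys, ab_xyz, ab_idx = _heavy_coords_by_residue(model, model.ab_chains)
    ag_keys, ag_xyz, ag_idx = _heavy_coords_by_residue(model, model.ag_chains)
    if ab_xyz.size == 0 or ag_xyz.size == 0:
        raise EvaluationError(f"model {model.model_id}: a partner has no heavy atoms")
    close = cdist(ab_xyz, ag_xyz) < cutoff
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    ii, jj = np.nonzero(close)
    for i, j in zip(ii, jj):
        pairs.add((ab_keys[ab_idx[i]], ag_keys[ag_idx[j]]))
    return pairs


def interface_residues(
    reference: StructureModel, cutoff: float = INTERFACE_CUTOFF
) -> set[ResidueKey]:
    """Residues on either partner with any heavy atom within ``cutoff`` of the other."""
    pairs = _residue_contact_pairs(reference, cutoff)
    out: set[ResidueKey] = set()
    for ab_key, ag_key in pairs:
        out.add(ab_key)
        out.add(ag_key)
    return out


# ---------------------------------------------------------------------------
# CAPRI quality
# ---------------------------------------------------------------------------


def capri_class(fnat: float, lrmsd: float, irmsd: float) -> str:
    """Assign the best quality class whose gates are satisfied."""
    if fnat >= 0.5 and (lrmsd <= 1.0 or irmsd <= 1.0):
        return "high"
    if fnat >= 0.3 and (lrmsd <= 5.0 or irmsd <= 2.0):
        return "medium"
    if fnat >= 0.1 and (lrmsd <= 10.0 or irmsd <= 4.0):
        return "acceptable"
    return "incorrect"


def _paired_ca(
    model: StructureModel,
    reference: StructureModel,
    keys: Sequence[ResidueKey],
) -> tuple[np.ndarray, np.ndarray]:
    model_ca = model.ca_map()
    ref_ca = reference.ca_map()
    shared = [k for k in keys if k in model_ca and k in ref_ca]
    if len(shared) < 3:
        raise EvaluationError(
            f"model {model.model_id}: fewer than 3 shared CA residues with the reference"
        )
    return (
        np.array([model_ca[k] for k in shared]),
        np.array([ref_ca[k] for k in shared]),
    )


def compute_quality(model: StructureModel, reference: StructureModel) -> QualityMetrics:
    """fnat / L-RMSD / iRMSD / CAPRI class of a model against the reference."""
    ref_contacts = _residue_contact_pairs(reference, FNAT_CONTACT_CUTOFF)
    if not ref_contacts:
        raise EvaluationError("reference complex has no inter-partner contacts")
    model_contacts = _residue_contact_pairs(model, FNAT_CONTACT_CUTOFF)
    fnat = len(ref_contacts & model_contacts) / len(ref_contacts)

    # L-RMSD: superpose on the antigen (receptor), measure over the antibody (ligand)
    ag_keys = sorted(reference.ca_map(reference.ag_chains))
    ab_keys = sorted(reference.ca_map(reference.ab_chains))
    m_ag, r_ag = _paired_ca(model, reference, ag_keys)
    R, t, _ = superpose_rmsd(m_ag, r_ag)
    m_ab, r_ab = _paired_ca(model, reference, ab_keys)
    moved_ab = m_ab @ R.T + t
    lrmsd = float(np.sqrt(np.mean(np.sum((moved_ab - r_ab) ** 2, axis=1))))

    # iRMSD: superpose on and measure over the reference-defined interface CAs
    iface = sorted(interface_residues(reference))
    m_if, r_if = _paired_ca(model, reference, iface)
    _, _, irmsd = superpose_rmsd(m_if, r_if)

    return QualityMetrics(
        fnat=float(fnat),
        lrmsd=lrmsd,
        irmsd=irmsd,
        capri_class=capri_class(fnat, lrmsd, irmsd),
    )


# ---------------------------------------------------------------------------
# Ensemble scoring performance
# ---------------------------------------------------------------------------


def enrichment(
    scores: Mapping[str, float],
    irmsd: Mapping[str, float],
    fraction: float = 0.10,
) -> EnrichmentResult:
    """Enrichment of accurate models among the top-scoring decile.

    Positives P are the ceil(fraction*N) lowest-score models; true positives
    are positives that also fall in the ceil(fraction*N) lowest-iRMSD models
    of the whole ensemble. Enrichment = (TP/(TP+FP)) * ((P+N)/P); 1 is the
    random expectation and (P+N)/P (10 at the default fraction) the maximum.
    """
    ids = sorted(scores)
    if set(ids) != set(irmsd):
        raise EvaluationError("score and iRMSD tables cover different models")
    n = len(ids)
    if n < 10:
        raise EvaluationError(f"enrichment needs at least 10 models, got {n}")
    p = math.ceil(fraction * n)
    by_score = sorted(ids, key=lambda m: (scores[m], m))
    by_irmsd = sorted(ids, key=lambda m: (irmsd[m], m))
    positives = set(by_score[:p])
    accurate = set(by_irmsd[:p])
    tp = len(positives & accurate)
    fp = p - tp
    return EnrichmentResult(P=p, N=n - p, TP=tp, FP=fp, enrichment=(tp / p) * (n / p))


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the maximum absolute difference between the two empirical CDFs;
    larger D means more discrepant iRMSD distributions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("KS test needs two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def class_counts(metrics: Sequence[QualityMetrics]) -> dict[str, int]:
    counts = {"high": 0, "medium": 0, "acceptable": 0, "incorrect": 0}
    for m in metrics:
        counts[m.capri_class] += 1
    return counts


def docking_success(top_metrics: Sequence[QualityMetrics]) -> bool:
    """A run succeeds if any top-selected model is near-native."""
    return any(m.near_native for m in top_metrics)
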