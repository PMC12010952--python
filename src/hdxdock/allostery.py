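"""Detection of allosteric peptides in an HDX restraint set.

An allosteric peptide shows genuine protection in the HDX experiment but
sits away from the true epitope, so no physically reasonable pose can
satisfy its restraint together with the real ones. The signature, computable
without a native structure, is that even the best-scoring models carry a
residual HDX penalty: the mean weighted (normalized x weight) HDX score of
the top-10 models by combined score stays above a threshold (default 0.75).

The offending peptide is identified by leave-one-out: each peptide is
excluded in turn, the raw HDX scores are re-summed from the stored
per-peptide penalties, renormalized over the full ensemble, recombined with
the base score, and a fresh top-10 selected. The exclusion that drives the
new top-10 mean weighted HDX score lowest names the candidate; if the mean
remains above the threshold the scan repeats on the reduced set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    DEFAULT_HDX_WEIGHT,
    DEFAULT_TOP_N,
    ScoreRow,
    rescore,
    select_top_n,
)

logger = logging.getLogger(__name__)

DEFAULT_ALLOSTERY_THRESHOLD = 0.75


class AllosteryError(ValueError):
    pass


@dataclass
class AllosteryReport:
    mean_weighted_hdx: float
    flagged: bool
    threshold: float
    scan: list[list[tuple[str, float]]] = field(default_factory=list)
    predicted_allosteric: list[str] = field(default_factory=list)
    iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_weighted_hdx": self.mean_weighted_hdx,
            "flagged": self.flagged,
            "threshold": self.threshold,
            "scan": [
                {label: value for label, value in round_} for round_ in self.scan
            ],
            "predicted_allosteric": list(self.predicted_allosteric),
            "iterations": self.iterations,
        }


def mean_weighted_hdx(rows: Sequence[ScoreRow], n: int = DEFAULT_TOP_N) -> float:
    """Mean weighted HDX score of the top-n models by combined score."""
    if not rows:
        raise AllosteryError("empty ensemble")
    top = select_top_n(rows, n)
    return float(np.mean([r.hdx_weighted for r in top]))


def _rescore_subset(
    penalties: pd.DataFrame,
    base_scores: Mapping[str, float],
    include: Sequence[str],
    weight: float,
) -> list[ScoreRow]:
    raw = penalties[list(include)].sum(axis=1) if include else pd.Series(0.0, index=penalties.index)
    return rescore(base_scores, raw.to_dict(), weight=weight)


def loo_exclusion_scan(
    penalties: pd.DataFrame,
    base_scores: Mapping[str, float],
    peptide_labels: Sequence[str] | None = None,
    weight: float = DEFAULT_HDX_WEIGHT,
    n: int = DEFAULT_TOP_N,
) -> list[tuple[str, float]]:
    """Leave-one-out scan over peptides.

    ``penalties`` is the per-model (rows) x per-peptide (columns) penalty
    matrix from :func:`hdxdock.restraints.penalty_table`. Returns, for each
    peptide, the new top-n mean weighted HDX score after excluding it,
    ordered ascending (the head is the allosteric candidate).
    """
    labels = list(peptide_labels) if peptide_labels is not None else list(penalties.columns)
    if len(labels) < 2:
        raise AllosteryError(
            "leave-one-out needs at least 2 peptides (excluding the only "
            "peptide would empty the restraint set)"
        )
    results = []
    for excluded in labels:
        keep = [l for l in labels if l != excluded]
        ranked = _rescore_subset(penalties, base_scores, keep, weight)
        results.append((excluded, mean_weighted_hdx(ranked, n)))
    results.sort(key=lambda t: (t[1], t[0]))
    return results


def detect_allosteric_iterative(
    penalties: pd.DataFrame,
    base_scores: Mapping[str, float],
    threshold: float = DEFAULT_ALLOSTERY_THRESHOLD,
    weight: float = DEFAULT_HDX_WEIGHT,
    n: int = DEFAULT_TOP_N,
) -> AllosteryReport:
    """Flag an HDX dataset and name its allosteric peptides one at a time.

    Pure function of its inputs: identical tables give a byte-identical
    report. Termination: mean drops to or below the threshold, or fewer
    than 2 active peptides remain.
    """
    active = list(penalties.columns)
    if not active:
        raise AllosteryError("penalty table has no peptides")
    ranked = _rescore_subset(penalties, base_scores, active, weight)
    initial_mean = mean_weighted_hdx(ranked, n)
    report = AllosteryReport(
        mean_weighted_hdx=initial_mean,
        flagged=initial_mean > threshold,
        threshold=threshold,
    )
    current_mean = initial_mean
    while current_mean > threshold and len(active) >= 2:
        scan = loo_exclusion_scan(penalties, base_scores, active, weight, n)
        report.scan.append(scan)
        candidate, new_mean = scan[0]
        report.predicted_allosteric.append(candidate)
        report.iterations += 1
        active.remove(candidate)
        current_mean = new_mean
        logger.info(
            "iteration %d: excluded %s, new top-%d mean weighted HDX %.3f",
            report.iterations,
            candidate,
            n,
            new_mean,
        )
    if current_mean > threshold and len(active) < 2:
        logger.warning(
            "mean weighted HDX %.3f still above threshold %.2f but only %d "
            "peptide(s) remain; stopping",
            current_mean,
            threshold,
            len(active),
        )
    return report
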