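"""Combined HDX + interface-energy model selection score.

The raw HDX penalty (squared-Angstrom) lives on a different scale from the
Rosetta-style interface score (REU), so it is first rescaled by the ratio of
the two columns' trimmed ranges,

    normalized = (iface_high - iface_low) / (hdx_high - hdx_low) * hdx_raw,

where "high"/"low" are the means of the top and bottom 10 % of each column.
The combined selection score is then

    combined = weight * normalized + interface_score,

with a default weight of 4.5. Scores are lower-is-better throughout;
penalties are non-negative, so HDX evidence can only disfavor a model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HDX_WEIGHT = 4.5
DEFAULT_TOP_N = 10


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreRow:
    model_id: str
    interface_score: float
    hdx_raw: float
    hdx_normalized: float = float("nan")
    hdx_weighted: float = float("nan")
    combined: float = float("nan")
    rank: int = 0


def make_rows(
    base_scores: Mapping[str, float], hdx_raw: Mapping[str, float]
) -> list[ScoreRow]:
    """Pair base interface scores with raw HDX penalties by model id."""
    missing = set(base_scores) - set(hdx_raw)
    if missing:
        raise ScoringError(f"models missing HDX penalties: {sorted(missing)[:5]}")
    return [
        ScoreRow(model_id=mid, interface_score=float(base_scores[mid]), hdx_raw=float(hdx_raw[mid]))
        for mid in base_scores
    ]


def trimmed_extremes(values: Sequence[float], fraction: float = 0.10) -> tuple[float, float]:
    """Means of the bottom and top ``fraction`` of the values.

    The extreme count is ceil(fraction * N) with a minimum of one element,
    so short lists still yield a well-defined range.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ScoringError("trimmed_extremes of an empty list")
    m = max(1, math.ceil(fraction * arr.size))
    return float(arr[:m].mean()), float(arr[-m:].mean())


def normalize_hdx_scores(
    rows: Sequence[ScoreRow], fraction: float = 0.10
) -> list[ScoreRow]:
    """Fill ``hdx_normalized`` by rescaling raw penalties to the interface-score range."""
    if len(rows) < 2:
        raise ScoringError("normalization needs at least 2 models")
    iface_low, iface_high = trimmed_extremes([r.interface_score for r in rows], fraction)
    hdx_low, hdx_high = trimmed_extremes([r.hdx_raw for r in rows], fraction)
    if hdx_high == hdx_low:
        # Every model carries the same penalty: the scale is undefined and the
        # HDX term cannot discriminate, so it is dropped from the combined score.
        logger.info(
            "HDX penalty range is degenerate (all %.3g); normalized scores set to 0",
            hdx_low,
        )
        return [replace(r, hdx_normalized=0.0) for r in rows]
    scale = (iface_high - iface_low) / (hdx_high - hdx_low)
    return [replace(r, hdx_normalized=scale * r.hdx_raw) for r in rows]


def combine_scores(
    rows: Sequence[ScoreRow], weight: float = DEFAULT_HDX_WEIGHT
) -> list[ScoreRow]:
    """Fill ``hdx_weighted``, ``combined`` and ``rank`` (1 = best).

    Ranking is ascending by combined score; ties are broken by model_id so
    the ordering is reproducible across platforms.
    """
    for r in rows:
        if not math.isfinite(r.hdx_normalized):
            raise ScoringError(f"model {r.model_id}: hdx_normalized not filled")
    filled = [
        replace(
            r,
            hdx_weighted=weight * r.hdx_normalized,
            combined=weight * r.hdx_normalized + r.interface_score,
        )
        for r in rows
    ]
    order = sorted(range(len(filled)), key=lambda i: (filled[i].combined, filled[i].model_id))
    ranked = list(filled)
    for rank, i in enumerate(order, start=1):
        ranked[i] = replace(filled[i], rank=rank)
    return ranked


def rescore(
    base_scores: Mapping[str, float],
    hdx_raw: Mapping[str, float],
    weight: float = DEFAULT_HDX_WEIGHT,
    fraction: float = 0.10,
) -> list[ScoreRow]:
    """Full pipeline: pair, normalize, combine, rank."""
    return combine_scores(normalize_hdx_scores(make_rows(base_scores, hdx_raw), fraction), weight)


def select_top_n(rows: Sequence[ScoreRow], n: int = DEFAULT_TOP_N) -> list[ScoreRow]:
    """The n best-ranked rows (all rows, with a note, if the ensemble is short)."""
    ranked = sorted(rows, key=lambda r: r.rank)
    if any(r.rank == 0 for r in rows):
        raise ScoringError("rows are not ranked; run combine_scores first")
    if len(ranked) < n:
        logger.info("ensemble has only %d models; returning all of them", len(ranked))
    return ranked[:n]


def rows_to_frame(rows: Sequence[ScoreRow]) -> pd.DataFrame:
    from .model_io import SCORE_COLUMNS

    return pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in SCORE_COLUMNS} for r in rows], columns=SCORE_COLUMNS
    )


def weight_sweep(
    base_scores: Mapping[str, float],
    hdx_raw: Mapping[str, float],
    irmsd_by_model: Mapping[str, float],
    weights: Sequence[float] | None = None,
    top_n: int = DEFAULT_TOP_N,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Scan the HDX weight and report top-n mean iRMSD and enrichment per weight.

    The default grid runs 0.5 to 15.0 in 0.5 steps. Useful for judging, on a
    synthetic ensemble, how sensitive selection quality is to the weight.
    """
    from .evaluation import enrichment

    if weights is None:
        weights = np.arange(0.5, 15.0 + 0.25, 0.5)
    normalized = normalize_hdx_scores(make_rows(base_scores, hdx_raw), fraction)
    records = []
    for w in weights:
        ranked = combine_scores(normalized, weight=float(w))
        top = select_top_n(ranked, top_n)
        mean_irmsd = float(np.mean([irmsd_by_model[r.model_id] for r in top]))
        scores = {r.model_id: r.combined for r in ranked}
        enr = enrichment(scores, irmsd_by_model)
        records.append(
            {
                "weight": float(w),
                "top_n_mean_irmsd": mean_irmsd,
                "enrichment": enr.enrichment,
            }
        )
    return pd.DataFrame.from_records(records)
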