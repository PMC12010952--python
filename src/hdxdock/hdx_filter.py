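"""Classification of HDX-interacting peptides from deuterium-uptake time courses.

A peptide is called interacting (significantly protected on binding) when

* at least one exposure time shows a protection difference
  diff = unbound_mean - bound_mean of at least ``diff_min`` (0.5 Da) AND at
  least ``sd_mult`` (3.0) pooled standard deviations, where the pooled SD
  combines both states in quadrature, AND
* the cumulative signed difference over all exposure times exceeds
  ``cum_min`` (1.1 Da).

Protection is positive by convention; deprotection (negative differences)
never contributes to flagging and can cancel protection in the cumulative
sum, since that sum runs over signed differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_DIFF_MIN = 0.5  # Da
DEFAULT_SD_MULT = 3.0
DEFAULT_CUM_MIN = 1.1  # Da


class UptakeError(ValueError):
    pass


@dataclass(frozen=True)
class UptakeRecord:
    """Bound/unbound deuterium uptake of one peptide across exposure times."""

    label: str
    chain_id: str
    start: int
    end: int
    timepoints: tuple[float, ...]  # seconds, strictly increasing
    unbound_mean: tuple[float, ...]  # Da
    bound_mean: tuple[float, ...]
    unbound_sd: tuple[float, ...]
    bound_sd: tuple[float, ...]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        nt = len(self.timepoints)
        for name in ("unbound_mean", "bound_mean", "unbound_sd", "bound_sd"):
            if len(getattr(self, name)) != nt:
                raise UptakeError(
                    f"peptide {self.label}: {name} has {len(getattr(self, name))} "
                    f"entries for {nt} timepoints"
                )
        if any(s < 0 for s in self.unbound_sd + self.bound_sd):
            raise UptakeError(f"peptide {self.label}: negative SD")
        if not all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise UptakeError(f"peptide {self.label}: timepoints not strictly increasing")


@dataclass(frozen=True)
class PeptideCall:
    label: str
    interacting: bool
    diffs: tuple[float, ...]  # unbound - bound per timepoint, Da
    pooled_sds: tuple[float, ...]
    cumulative_diff: float


def flag_interacting_peptides(
    records: Sequence[UptakeRecord],
    diff_min: float = DEFAULT_DIFF_MIN,
    sd_mult: float = DEFAULT_SD_MULT,
    cum_min: float = DEFAULT_CUM_MIN,
) -> list[PeptideCall]:
    """Apply the significance gates to each uptake record.

    The per-timepoint criterion is read as a conjunction (the stricter
    reading): diff >= diff_min Da AND diff >= sd_mult x pooled SD.
    """
    calls = []
    for rec in records:
        diffs = np.asarray(rec.unbound_mean) - np.asarray(rec.bound_mean)
        pooled = np.sqrt(np.asarray(rec.unbound_sd) ** 2 + np.asarray(rec.bound_sd) ** 2)
        timepoint_ok = bool(np.any((diffs >= diff_min) & (diffs >= sd_mult * pooled)))
        cumulative = float(diffs.sum())
        calls.append(
            PeptideCall(
                label=rec.label,
                interacting=timepoint_ok and cumulative > cum_min,
                diffs=tuple(float(d) for d in diffs),
                pooled_sds=tuple(float(s) for s in pooled),
                cumulative_diff=cumulative,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Table I/O (long format: one row per peptide-timepoint)
# ---------------------------------------------------------------------------

UPTAKE_COLUMNS = [
    "label",
    "chain",
    "start",
    "end",
    "time_s",
    "unbound_mean",
    "bound_mean",
    "unbound_sd",
    "bound_sd",
    "n_replicates",
]


def read_uptake_table(path: str | Path) -> list[UptakeRecord]:
    path = Path(path)
    if not path.exists():
        raise UptakeError(f"uptake table not found: {path}")
    with open(path) as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(UPTAKE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise UptakeError(f"uptake table missing columns {sorted(missing)}")
    records = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_s")
        records.append(
            UptakeRecord(
                label=str(label),
                chain_id=str(grp["chain"].iloc[0]),
                start=int(grp["start"].iloc[0]),
                end=int(grp["end"].iloc[0]),
                timepoints=tuple(grp["time_s"].astype(float)),
                unbound_mean=tuple(grp["unbound_mean"].astype(float)),
                bound_mean=tuple(grp["bound_mean"].astype(float)),
                unbound_sd=tuple(grp["unbound_sd"].astype(float)),
                bound_sd=tuple(grp["bound_sd"].astype(float)),
                n_replicates=int(grp["n_replicates"].iloc[0]) if "n_replicates" in grp else 3,
            )
        )
    return records


def write_uptake_table(records: Sequence[UptakeRecord], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for rec in records:
        for i, t in enumerate(rec.timepoints):
            rows.append(
                {
                    "label": rec.label,
                    "chain": rec.chain_id,
                    "start": rec.start,
                    "end": rec.end,
                    "time_s": t,
                    "unbound_mean": rec.unbound_mean[i],
                    "bound_mean": rec.bound_mean[i],
                    "unbound_sd": rec.unbound_sd[i],
                    "bound_sd": rec.bound_sd[i],
                    "n_replicates": rec.n_replicates,
                }
            )
    pd.DataFrame.from_records(rows, columns=UPTAKE_COLUMNS).to_csv(path, sep=sep, index=False)


def calls_to_peptide_yaml(
    records: Sequence[UptakeRecord], calls: Sequence[PeptideCall]
) -> list[dict]:
    """HDXPeptide entries (for the docking config) for the flagged peptides."""
    by_label = {r.label: r for r in records}
    out = []
    for call in calls:
        if not call.interacting:
            continue
        rec = by_label[call.label]
        out.append(
            {"label": rec.label, "chain": rec.chain_id, "start": rec.start, "end": rec.end}
        )
    return out
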