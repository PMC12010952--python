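"""Structure, score-table, and configuration I/O.

Conventions shared by the whole toolkit:

* Residue identity is ``(chain_id, res_seq, icode)`` in author numbering,
  1-based as in the PDB; no renumbering is ever performed, because HDX
  peptide ranges are supplied in antigen author numbering.
* Alternate locations: the blank or ``'A'`` conformer is kept, others are
  dropped, so every model has deterministic single-conformer geometry.
* Waters and heteroatoms are excluded from residue sets; hydrogens are
  parsed but flagged, and all distance computations downstream use heavy
  atoms only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]

SCORE_COLUMNS = [
    "model_id",
    "interface_score",
    "hdx_raw",
    "hdx_normalized",
    "hdx_weighted",
    "combined",
    "rank",
]


class ModelIOError(ValueError):
    """Raised for malformed structures, tables, or configurations."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a docked pose, in author numbering."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    coords: tuple[float, float, float]
    element: str

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ModelIOError(f"non-finite coordinates for atom {self}")
        if not self.element:
            raise ModelIOError(f"empty element for atom {self.atom_name}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    """One docked antibody-antigen pose, partitioned into the two partners."""

    model_id: str
    atoms: list[AtomRecord]
    ab_chains: frozenset[str]
    ag_chains: frozenset[str]

    def __post_init__(self) -> None:
        self.ab_chains = frozenset(self.ab_chains)
        self.ag_chains = frozenset(self.ag_chains)
        if not self.ab_chains or not self.ag_chains:
            raise ModelIOError("ab_chains and ag_chains must both be non-empty")
        if self.ab_chains & self.ag_chains:
            raise ModelIOError(
                f"ab/ag chain sets overlap: {sorted(self.ab_chains & self.ag_chains)}"
            )
        known = self.ab_chains | self.ag_chains
        stray = {a.chain_id for a in self.atoms} - known
        if stray:
            raise ModelIOError(
                f"model {self.model_id}: chains {sorted(stray)} belong to "
                f"neither partner (ab={sorted(self.ab_chains)}, ag={sorted(self.ag_chains)})"
            )
        seen_ca: set[ResidueKey] = set()
        for a in self.atoms:
            if a.atom_name == "CA" and a.element == "C":
                if a.residue_key in seen_ca:
                    raise ModelIOError(
                        f"model {self.model_id}: duplicate CA for residue {a.residue_key}"
                    )
                seen_ca.add(a.residue_key)

    # -- coordinate accessors -------------------------------------------------

    def partner_atoms(self, partner: str) -> list[AtomRecord]:
        chains = self.ab_chains if partner == "ab" else self.ag_chains
        return [a for a in self.atoms if a.chain_id in chains]

    def heavy_atoms(self, chains: Iterable[str] | None = None) -> list[AtomRecord]:
        sel = set(chains) if chains is not None else None
        return [
            a
            for a in self.atoms
            if not a.is_hydrogen and (sel is None or a.chain_id in sel)
        ]

    def ca_map(self, chains: Iterable[str] | None = None) -> dict[ResidueKey, np.ndarray]:
        """Residue -> C-alpha coordinate for the selected chains (heavy CA only)."""
        sel = set(chains) if chains is not None else None
        out: dict[ResidueKey, np.ndarray] = {}
        for a in self.atoms:
            if a.atom_name != "CA" or a.element != "C":
                continue
            if sel is not None and a.chain_id not in sel:
                continue
            out[a.residue_key] = np.asarray(a.coords, dtype=float)
        return out

    def residue_names(self) -> dict[ResidueKey, str]:
        names: dict[ResidueKey, str] = {}
        for a in self.atoms:
            names.setdefault(a.residue_key, a.res_name)
        return names

    def with_atoms(self, atoms: list[AtomRecord], model_id: str | None = None) -> "StructureModel":
        return StructureModel(
            model_id=model_id if model_id is not None else self.model_id,
            atoms=atoms,
            ab_chains=self.ab_chains,
            ag_chains=self.ag_chains,
        )


@dataclass(frozen=True)
class CDRSegment:
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelIOError(
                f"CDR segment on chain {self.chain_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class CDRDefinition:
    """Antibody complementarity-determining regions as residue ranges."""

    segments: tuple[CDRSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ModelIOError("CDR definition must contain at least one segment")

    def contains(self, key: ResidueKey) -> bool:
        chain, seq, _ = key
        return any(
            s.chain_id == chain and s.start <= seq <= s.end for s in self.segments
        )


@dataclass(frozen=True)
class HDXPeptide:
    """An antigen peptide showing significant protection upon antibody binding.

    Residue ranges are inclusive on both ends, matching how HDX peptide
    spans are quoted (e.g. "peptide 84-95" covers residues 84 through 95).
    """

    label: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelIOError(
                f"HDX peptide {self.label}: start {self.start} > end {self.end}"
            )

    def covers(self, key: ResidueKey) -> bool:
        chain, seq, _ = key
        return chain == self.chain_id and self.start <= seq <= self.end


# RestraintSpec lives here so DockingConfig can carry it without a circular
# import; the restraints module re-exports it.
@dataclass(frozen=True)
class RestraintSpec:
    """Distance-restraint stringency: threshold d (Angstrom), minimum residue
    count k, and whether prolines on the peptide are excluded (they carry no
    exchangeable backbone amide, hence no HDX signal)."""

    d: float = 10.0
    k: int = 1
    exclude_proline: bool = True

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ModelIOError(f"restraint threshold d must be positive, got {self.d}")
        if self.k < 1:
            raise ModelIOError(f"restraint residue count k must be >= 1, got {self.k}")


@dataclass
class DockingConfig:
    """Everything a docking run needs besides the coordinates."""

    ab_chains: frozenset[str]
    ag_chains: frozenset[str]
    cdrs: CDRDefinition
    hdx_peptides: list[HDXPeptide] = field(default_factory=list)
    restraint_spec: RestraintSpec = field(default_factory=RestraintSpec)
    hdx_weight: float = 4.5
    allostery_threshold: float = 0.75
    top_n: int = 10

    def __post_init__(self) -> None:
        self.ab_chains = frozenset(self.ab_chains)
        self.ag_chains = frozenset(self.ag_chains)
        if self.ab_chains & self.ag_chains:
            raise ModelIOError("ab_chains and ag_chains must be disjoint")
        for seg in self.cdrs.segments:
            if seg.chain_id not in self.ab_chains:
                raise ModelIOError(
                    f"CDR segment on chain {seg.chain_id} which is not an antibody chain"
                )
        for pep in self.hdx_peptides:
            if pep.chain_id not in self.ag_chains:
                raise ModelIOError(
                    f"HDX peptide {pep.label} on chain {pep.chain_id} "
                    "which is not an antigen chain"
                )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "DOD", "WAT"}


def read_pdb_models(
    path: str | Path,
    ab_chains: Iterable[str],
    ag_chains: Iterable[str],
    strict: bool = False,
) -> list[StructureModel]:
    """Read a (possibly multi-MODEL) PDB file into one StructureModel per model.

    Models containing a chain outside the declared partition, or missing one
    of the declared partners, are rejected with a logged diagnostic rather
    than silently truncated. With ``strict=True`` the first rejection raises.
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"PDB file not found: {path}")
    ab = frozenset(ab_chains)
    ag = frozenset(ag_chains)
    structure = gemmi.read_pdb(str(path))
    out: list[StructureModel] = []
    for gm in structure:
        model_id = str(gm.num)
        atoms: list[AtomRecord] = []
        for chain in gm:
            for res in chain:
                if res.het_flag != "A" or res.name in _WATER_NAMES:
                    continue  # waters / heteroatoms excluded from residue sets
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue  # keep the first conformer only
                    atoms.append(
                        AtomRecord(
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            icode=(res.seqid.icode or "").strip(),
                            res_name=res.name,
                            atom_name=atom.name,
                            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                            element=atom.element.name,
                        )
                    )
        try:
            model = StructureModel(model_id=model_id, atoms=atoms, ab_chains=ab, ag_chains=ag)
            chains_present = {a.chain_id for a in atoms}
            missing = (ab | ag) - chains_present
            if missing:
                raise ModelIOError(
                    f"model {model_id}: declared chains {sorted(missing)} absent"
                )
        except ModelIOError as exc:
            if strict:
                raise
            logger.warning("rejecting model from %s: %s", path.name, exc)
            continue
        out.append(model)
    if not out:
        raise ModelIOError(f"no acceptable models in {path}")
    return out


def write_pdb_models(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write models as a multi-MODEL PDB file (coordinates kept to 3 decimals)."""
    structure = gemmi.Structure()
    structure.name = "hdxdock"
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(i)
        chains: dict[str, gemmi.Chain] = {}
        current: tuple[str, ResidueKey] | None = None
        for a in model.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
            chain = chains[a.chain_id]
            key = (a.chain_id, a.residue_key)
            if current != key:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
                res.het_flag = "A"
                chain.add_residue(res)
                current = key
            res = chain[len(chain) - 1]
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            res.add_atom(atom)
        for chain in chains.values():
            gm.add_chain(chain)
        structure.add_model(gm)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Docking configuration
# ---------------------------------------------------------------------------


def load_docking_config(path: str | Path) -> DockingConfig:
    """Load a JSON/YAML docking configuration, materializing defaults."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(raw, dict):
        raise ModelIOError(f"config root must be a mapping, got {type(raw).__name__}")
    return docking_config_from_dict(raw)


def docking_config_from_dict(raw: Mapping) -> DockingConfig:
    try:
        ab = raw["ab_chains"]
        ag = raw["ag_chains"]
        cdr_raw = raw["cdrs"]
    except KeyError as exc:
        raise ModelIOError(f"config missing required key: {exc}") from exc
    segments = tuple(
        CDRSegment(chain_id=str(s["chain"]), start=int(s["start"]), end=int(s["end"]))
        for s in cdr_raw
    )
    peptides = [
        HDXPeptide(
            label=str(p.get("label", f"pep{i + 1}")),
            chain_id=str(p["chain"]),
            start=int(p["start"]),
            end=int(p["end"]),
        )
        for i, p in enumerate(raw.get("hdx_peptides", []))
    ]
    restraint_raw = raw.get("restraint", {})
    spec = RestraintSpec(
        d=float(restraint_raw.get("d", 10.0)),
        k=int(restraint_raw.get("k", 1)),
        exclude_proline=bool(restraint_raw.get("exclude_proline", True)),
    )
    return DockingConfig(
        ab_chains=frozenset(str(c) for c in ab),
        ag_chains=frozenset(str(c) for c in ag),
        cdrs=CDRDefinition(segments=segments),
        hdx_peptides=peptides,
        restraint_spec=spec,
        hdx_weight=float(raw.get("hdx_weight", 4.5)),
        allostery_threshold=float(raw.get("allostery_threshold", 0.75)),
        top_n=int(raw.get("top_n", 10)),
    )


def docking_config_to_dict(config: DockingConfig) -> dict:
    return {
        "ab_chains": sorted(config.ab_chains),
        "ag_chains": sorted(config.ag_chains),
        "cdrs": [
            {"chain": s.chain_id, "start": s.start, "end": s.end}
            for s in config.cdrs.segments
        ],
        "hdx_peptides": [
            {"label": p.label, "chain": p.chain_id, "start": p.start, "end": p.end}
            for p in config.hdx_peptides
        ],
        "restraint": {
            "d": config.restraint_spec.d,
            "k": config.restraint_spec.k,
            "exclude_proline": config.restraint_spec.exclude_proline,
        },
        "hdx_weight": config.hdx_weight,
        "allostery_threshold": config.allostery_threshold,
        "top_n": config.top_n,
    }


def save_docking_config(config: DockingConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(docking_config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a per-model base interface-score table (REU; lower is better).

    Accepts TSV or CSV with at least a model-id column and a score column
    (named ``model_id`` / ``interface_score``, or the first two columns).
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"score table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "model_id" in df.columns:
        ids = df["model_id"]
    else:
        ids = df.iloc[:, 0]
    if "interface_score" in df.columns:
        scores = df["interface_score"]
    elif "score" in df.columns:
        scores = df["score"]
    else:
        scores = df.iloc[:, 1]
    ids = ids.astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ModelIOError(f"duplicate model_id in {path}: {dup.iloc[0]!r}")
    values = pd.to_numeric(scores, errors="coerce")
    bad = ids[~np.isfinite(values)]
    if not bad.empty:
        raise ModelIOError(f"non-numeric or non-finite score for model {bad.iloc[0]!r}")
    return dict(zip(ids, values.astype(float)))


def write_score_table(rows: Sequence, path: str | Path, sep: str = "\t") -> None:
    """Write ScoreRow records to a delimited table with a fixed column order."""
    records = []
    for r in rows:
        records.append({c: getattr(r, c) for c in SCORE_COLUMNS})
    df = pd.DataFrame.from_records(records, columns=SCORE_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def read_score_rows(path: str | Path) -> pd.DataFrame:
    """Read back a full ScoreRow table written by :func:`write_score_table`."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"score table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ModelIOError(f"score table {path} missing columns {sorted(missing)}")
    df["model_id"] = df["model_id"].astype(str)
    return df
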