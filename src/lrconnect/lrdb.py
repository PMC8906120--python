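"""Ligand-receptor ground-truth reference tables.

A connectome is built by mapping per-cluster expression against a table of
known ligand->receptor signaling mechanisms (e.g. the FANTOM5 pair list).
Each mechanism carries a single signaling-family designation used for
network decomposition; pairs without one are labeled ``unassigned``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_CANONICAL_COLUMNS = ["mechanism_id", "ligand", "receptor", "family", "mode"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EmptyDatabaseError(ValueError):
    """No valid ligand-receptor pairs remain."""


def make_mechanism_id(ligand: str, receptor: str) -> str:
    """Unique key for a ligand->receptor mechanism."""
    return f"{ligand}|{receptor}"


@dataclass(frozen=True)
class LRPair:
    """One ligand->receptor signaling mechanism.

    A gene may appear as a ligand in one pair and a receptor in another; a
    single ligand may hit multiple receptors and vice-versa. Exactly one
    family designation per mechanism.
    """

    ligand: str
    receptor: str
    family: str = UNASSIGNED
    mode: str | None = None

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty strings")

    @property
    def mechanism_id(self) -> str:
        return make_mechanism_id(self.ligand, self.receptor)


@dataclass
class LRDatabase:
    """Ordered collection of unique ligand-receptor pairs with family index."""

    pairs: list[LRPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.mechanism_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mechanism_id in database")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ligand_set(self) -> set[str]:
        return {p.ligand for p in self.pairs}

    @property
    def receptor_set(self) -> set[str]:
        return {p.receptor for p in self.pairs}

    @property
    def mechanism_ids(self) -> list[str]:
        return [p.mechanism_id for p in self.pairs]

    @property
    def families(self) -> set[str]:
        return {p.family for p in self.pairs}

    @property
    def family_index(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p in self.pairs:
            out.setdefault(p.family, set()).add(p.mechanism_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Canonical table with columns mechanism_id, ligand, receptor, family, mode."""
        return pd.DataFrame(
            {
                "mechanism_id": [p.mechanism_id for p in self.pairs],
                "ligand": [p.ligand for p in self.pairs],
                "receptor": [p.receptor for p in self.pairs],
                "family": [p.family for p in self.pairs],
                "mode": [p.mode for p in self.pairs],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_lr_database(
    path: str | Path,
    ligand_column: str = "ligand",
    receptor_column: str = "receptor",
    family_column: str | None = "family",
    mode_column: str | None = "mode",
    sep: str | None = None,
    case_fold: bool = False,
) -> LRDatabase:
    """Load a ligand-receptor reference table from CSV/TSV.

    Duplicate (ligand, receptor) rows collapse to the first occurrence;
    row order of first occurrence is preserved. Gene symbols are matched
    case-sensitively by default; ``case_fold=True`` upper-cases symbols,
    useful when applying a human (upper-case) list to mouse (title-case)
    data.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If a named column is absent from the header.
    EmptyDatabaseError
        If no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ligand-receptor table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = [ligand_column, receptor_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}; found {list(df.columns)}")
    if family_column is not None and family_column not in df.columns:
        family_column = None
    if mode_column is not None and mode_column not in df.columns:
        mode_column = None

    pairs: list[LRPair] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        lig = row[ligand_column]
        rec = row[receptor_column]
        if pd.isna(lig) or pd.isna(rec) or not str(lig) or not str(rec):
            continue
        lig, rec = str(lig).strip(), str(rec).strip()
        if case_fold:
            lig, rec = lig.upper(), rec.upper()
        key = make_mechanism_id(lig, rec)
        if key in seen:
            continue
        seen.add(key)
        fam = UNASSIGNED
        if family_column is not None and pd.notna(row[family_column]) and str(row[family_column]).strip():
            fam = str(row[family_column]).strip()
        mode = None
        if mode_column is not None and pd.notna(row[mode_column]) and str(row[mode_column]).strip():
            mode = str(row[mode_column]).strip()
        pairs.append(LRPair(ligand=lig, receptor=rec, family=fam, mode=mode))
    if not pairs:
        raise EmptyDatabaseError(f"no valid ligand-receptor rows in {path}")
    return LRDatabase(pairs=pairs)


def subset_by_family(db: LRDatabase, families: set[str]) -> LRDatabase:
    """Pairs whose family is in ``families``; unknown names yield empty subsets."""
    if not families:
        raise ValueError("families must be non-empty")
    return LRDatabase(pairs=[p for p in db.pairs if p.family in families])


def restrict_to_genes(db: LRDatabase, measured_genes: set[str]) -> LRDatabase:
    """Keep only pairs with both ligand and receptor among measured genes."""
    if not measured_genes:
        raise ValueError("measured_genes must be non-empty")
    measured = set(measured_genes)
    kept, dropped = [], []
    for p in db.pairs:
        (kept if p.ligand in measured and p.receptor in measured else dropped).append(p)
    if dropped:
        logger.warning(
            "restrict_to_genes: dropped %d/%d pairs not fully measured: %s",
            len(dropped),
            len(db),
            ", ".join(p.mechanism_id for p in dropped[:20]),
        )
    if not kept:
        logger.warning("restrict_to_genes: no pairs remain")
    return LRDatabase(pairs=kept)


def bundled_example_database() -> LRDatabase:
    """Small packaged example table of well-known pairs, for tests and demos."""
    with resources.as_file(resources.files("lrconnect.data") / "example_lr_pairs.csv") as p:
        return load_lr_database(p)
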