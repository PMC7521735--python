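"""Core domain types and TSV readers/writers.

The unit of comparison throughout the package is the *bioset*: a
statistically filtered list of differentially expressed genes from one
two-group comparison, each carrying a signed **linear** fold change
(−2 means two-fold down; values in (−1, 1) are never stored).  Biosets
live on a *gene universe* — the set of genes measurable on the source
platform — which supplies the ``N`` of every hypergeometric computation
downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GeneUniverse",
    "Bioset",
    "CompendiumAnnotation",
    "BiosetFormatError",
    "EmptyBiosetError",
    "IncomparablePlatformsError",
    "normalize_gene_id",
    "to_linear_fold",
    "read_bioset",
    "write_bioset",
    "read_universe",
    "write_universe",
    "read_annotations",
    "write_annotations",
    "restrict_to_common_universe",
]


class BiosetFormatError(ValueError):
    """A bioset file is missing required columns or is malformed."""


class EmptyBiosetError(ValueError):
    """A bioset has no records left after filtering; scoring is undefined."""


class IncomparablePlatformsError(ValueError):
    """Two biosets share no measurable genes."""


def normalize_gene_id(gene_id: str) -> str:
    """Upper-case and strip a gene identifier for cross-platform matching."""
    return str(gene_id).strip().upper()


def to_linear_fold(fc: float) -> float:
    """Re-express a fold change on the signed linear convention.

    Ratios in (0, 1) become −1/ratio, so a halving is stored as −2.0.
    Values already outside (−1, 1) pass through unchanged.
    """
    if fc == 0 or not math.isfinite(fc):
        raise ValueError(f"fold change must be finite and non-zero, got {fc}")
    if -1.0 < fc < 1.0:
        return -1.0 / fc
    return float(fc)


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a bioset: identifier, signed linear fold change, optional p."""

    gene_id: str
    fold_change: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_id", normalize_gene_id(self.gene_id))
        object.__setattr__(self, "fold_change", to_linear_fold(self.fold_change))
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    @property
    def direction(self) -> int:
        return 1 if self.fold_change > 0 else -1


@dataclass(frozen=True)
class GeneUniverse:
    """The set of genes measurable on a platform; its size is the
    hypergeometric ``N``."""

    gene_ids: frozenset[str]

    def __init__(self, gene_ids: Iterable[str]) -> None:
        ids = frozenset(normalize_gene_id(g) for g in gene_ids)
        if len(ids) < 2:
            raise ValueError("a gene universe needs at least 2 genes")
        object.__setattr__(self, "gene_ids", ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return normalize_gene_id(gene_id) in self.gene_ids

    def intersection(self, other: "GeneUniverse") -> "GeneUniverse":
        common = self.gene_ids & other.gene_ids
        if len(common) < 2:
            raise IncomparablePlatformsError(
                f"platforms share {len(common)} gene(s); need at least 2"
            )
        return GeneUniverse(common)


@dataclass
class Bioset:
    """A filtered differential-expression gene list on a platform.

    Records are unique by ``gene_id`` and every gene belongs to
    ``platform``.  Iteration order is insertion order; rank order (by
    descending |fold change|) is computed where needed, not stored.
    """

    bioset_id: str
    records: list[GeneRecord]
    platform: GeneUniverse

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in bioset")
            if rec.gene_id not in self.platform:
                raise ValueError(
                    f"gene {rec.gene_id!r} not in the bioset's platform universe"
                )
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def fold_changes(self) -> dict[str, float]:
        return {r.gene_id: r.fold_change for r in self.records}

    def up_genes(self) -> set[str]:
        return {r.gene_id for r in self.records if r.fold_change > 0}

    def down_genes(self) -> set[str]:
        return {r.gene_id for r in self.records if r.fold_change < 0}

    def ranked_gene_ids(self) -> list[str]:
        """Gene ids by descending |fold change|; ties broken lexicographically."""
        return [
            r.gene_id
            for r in sorted(self.records, key=lambda r: (-abs(r.fold_change), r.gene_id))
        ]

    def flipped(self) -> "Bioset":
        """The same bioset with every fold-change sign inverted."""
        return Bioset(
            bioset_id=f"{self.bioset_id}:flipped",
            records=[
                GeneRecord(r.gene_id, -r.fold_change, r.p_value) for r in self.records
            ],
            platform=self.platform,
        )

    def restricted(self, universe: GeneUniverse, bioset_id: str | None = None) -> "Bioset":
        kept = [r for r in self.records if r.gene_id in universe]
        return Bioset(bioset_id or self.bioset_id, kept, universe)


@dataclass(frozen=True)
class CompendiumAnnotation:
    """Experimental metadata for one bioset in the screening compendium."""

    bioset_id: str
    perturbant: str
    cell_type: str = ""
    dose: float | None = None
    dose_unit: str = ""
    time_h: float | None = None
    study: str = ""

    def __post_init__(self) -> None:
        if not self.perturbant:
            raise ValueError("perturbant must be non-empty")


# ---------------------------------------------------------------------------
# I/O.  All files are plain UTF-8 TSV; '#' lines are comments.
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps fold changes bit-exact across write/read cycles
    return pd.read_csv(
        path, sep="\t", comment="#", dtype={"gene_id": str},
        float_precision="round_trip",
    )


def read_bioset(path: str | Path, universe: GeneUniverse, bioset_id: str | None = None) -> Bioset:
    """Load a bioset TSV (``gene_id<TAB>fold_change[<TAB>p_value]``).

    Identifiers are case-normalized; duplicate genes keep the record with
    the largest |fold change|; genes absent from *universe* are dropped
    with a logged count.  Raises :class:`BiosetFormatError` on missing
    columns and :class:`EmptyBiosetError` if nothing survives.
    """
    path = Path(path)
    df = _read_tsv(path)
    missing = {"gene_id", "fold_change"} - set(df.columns)
    if missing:
        raise BiosetFormatError(f"{path}: missing column(s) {sorted(missing)}")

    has_p = "p_value" in df.columns
    best: dict[str, GeneRecord] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        gid = normalize_gene_id(row.gene_id)
        if gid not in universe:
            n_dropped += 1
            continue
        p = float(row.p_value) if has_p and pd.notna(row.p_value) else None
        rec = GeneRecord(gid, float(row.fold_change), p)
        prev = best.get(gid)
        if prev is None or abs(rec.fold_change) > abs(prev.fold_change):
            best[gid] = rec
    if n_dropped:
        logger.warning("%s: dropped %d gene(s) outside the universe", path, n_dropped)
    if not best:
        raise EmptyBiosetError(f"{path}: no genes left after universe filtering")
    return Bioset(bioset_id or path.stem, list(best.values()), universe)


def write_bioset(bioset: Bioset, path: str | Path) -> None:
    """Write a bioset TSV; fold changes are written with repr-roundtrip precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfold_change\tp_value\n")
        for r in bioset.records:
            p = "" if r.p_value is None else repr(r.p_value)
            fh.write(f"{r.gene_id}\t{r.fold_change!r}\t{p}\n")


def read_universe(path: str | Path) -> GeneUniverse:
    """Load a gene universe: one identifier per line."""
    with open(path, encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return GeneUniverse(ids)


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(universe.gene_ids):
            fh.write(gid + "\n")


_ANN_COLUMNS = ["bioset_id", "perturbant", "cell_type", "dose", "dose_unit", "time_h", "study"]


def read_annotations(path: str | Path) -> list[CompendiumAnnotation]:
    """Load a compendium annotation TSV (bioset_id, perturbant, cell_type,
    dose, dose_unit, time_h, study)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"bioset_id", "perturbant"} - set(df.columns)
    if missing:
        raise BiosetFormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        out.append(
            CompendiumAnnotation(
                bioset_id=str(row["bioset_id"]),
                perturbant=str(row["perturbant"]),
                cell_type=str(row.get("cell_type", "") or ""),
                dose=float(row["dose"]) if pd.notna(row.get("dose")) else None,
                dose_unit=str(row.get("dose_unit", "") or ""),
                time_h=float(row["time_h"]) if pd.notna(row.get("time_h")) else None,
                study=str(row.get("study", "") or ""),
            )
        )
    ids = [a.bioset_id for a in out]
    if len(ids) != len(set(ids)):
        raise BiosetFormatError(f"{path}: duplicate bioset_id entries")
    return out


def write_annotations(annotations: Sequence[CompendiumAnnotation], path: str | Path) -> None:
    rows = [
        {
            "bioset_id": a.bioset_id,
            "perturbant": a.perturbant,
            "cell_type": a.cell_type,
            "dose": a.dose,
            "dose_unit": a.dose_unit,
            "time_h": a.time_h,
            "study": a.study,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def restrict_to_common_universe(a: Bioset, b: Bioset) -> tuple[Bioset, Bioset, GeneUniverse]:
    """Restrict two biosets to the intersection of their platforms.

    Cross-platform comparisons are meaningful only on the genes both
    platforms measure; the intersection size becomes the shared ``N``.
    Raises :class:`IncomparablePlatformsError` when the platforms are
    (effectively) disjoint.
    """
    common = a.platform.intersection(b.platform)
    return a.restricted(common), b.restricted(common), common
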