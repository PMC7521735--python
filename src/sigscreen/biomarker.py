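"""Directed biomarker construction from activation and knockdown biosets.

A biomarker is a short, directed gene signature whose coordinated
up/down expression pattern indicates activation of a transcription
factor.  It is distilled from a panel of *activation* biosets
(chemical activators plus genetic activation, e.g. knockdown of a
repressor) and one *genetic-dependence* bioset in which the factor
itself was knocked down, through three successive filters:

1. **directional consistency** — the gene moves the same way in every
   activation bioset where it is differentially expressed, and appears
   in at least a majority of the panel (4 or more of 7 by default);
2. **genetic dependence** — the gene appears in the factor-knockdown
   bioset with the *opposite* sign (mere absence is not enough, so a
   canonical target missing from the knockdown profile is excluded);
3. **effect size** — its mean |linear fold change| over the activation
   biosets where it is differentially expressed is at least 1.5.

Each filter is a pure contraction of the candidate set, so the final
signature is the intersection of the three and its size is monotone
non-increasing in every threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import Bioset, normalize_gene_id

__all__ = [
    "BiomarkerGene",
    "Biomarker",
    "BiomarkerParams",
    "EmptyBiomarkerError",
    "directional_consistency_filter",
    "genetic_filter",
    "effect_size_filter",
    "build_biomarker",
    "read_biomarker",
    "write_biomarker",
]


class EmptyBiomarkerError(ValueError):
    """No gene survived all three filters; downstream scoring is undefined."""


@dataclass(frozen=True)
class BiomarkerGene:
    gene_id: str
    direction: int  # +1 up under activation, -1 down
    mean_fc: float  # signed linear fold change, sign == direction
    support: int  # number of activation biosets where differentially expressed

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.mean_fc != 0 and (self.mean_fc > 0) != (self.direction > 0):
            raise ValueError("sign of mean_fc must match direction")


@dataclass
class Biomarker:
    """A directed gene signature with provenance of its source biosets."""

    genes: list[BiomarkerGene]
    provenance: list[str]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in biomarker")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def up_genes(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.direction > 0}

    def down_genes(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.direction < 0}

    def fold_changes(self) -> dict[str, float]:
        return {g.gene_id: g.mean_fc for g in self.genes}

    def ranked_gene_ids(self) -> list[str]:
        return [
            g.gene_id
            for g in sorted(self.genes, key=lambda g: (-abs(g.mean_fc), g.gene_id))
        ]


@dataclass(frozen=True)
class BiomarkerParams:
    min_support: int | None = None  # default: majority of the activation panel
    min_mean_fc: float = 1.5

    def __post_init__(self) -> None:
        if self.min_mean_fc <= 1:
            raise ValueError("min_mean_fc is a linear fold and must exceed 1")


def _default_min_support(n_biosets: int) -> int:
    # majority: ceil((n+1)/2) -> 4 of 7
    return math.ceil((n_biosets + 1) / 2)


def directional_consistency_filter(
    activation_biosets: Sequence[Bioset], min_support: int | None = None
) -> list[BiomarkerGene]:
    """Keep genes with a single consistent sign across the activation panel
    and presence in at least ``min_support`` biosets."""
    if not activation_biosets:
        raise ValueError("need at least one activation bioset")
    n = len(activation_biosets)
    if min_support is None:
        min_support = _default_min_support(n)
    if not 1 <= min_support <= n:
        raise ValueError(f"min_support must lie in [1, {n}]")

    fcs: dict[str, list[float]] = {}
    for bs in activation_biosets:
        for rec in bs:
            fcs.setdefault(rec.gene_id, []).append(rec.fold_change)

    out: list[BiomarkerGene] = []
    for gene_id in sorted(fcs):
        values = fcs[gene_id]
        signs = {1 if v > 0 else -1 for v in values}
        if len(signs) != 1 or len(values) < min_support:
            continue
        direction = signs.pop()
        mean_abs = sum(abs(v) for v in values) / len(values)
        out.append(BiomarkerGene(gene_id, direction, direction * mean_abs, len(values)))
    return out


def genetic_filter(
    candidates: Sequence[BiomarkerGene], knockdown_bioset: Bioset
) -> list[BiomarkerGene]:
    """Keep candidates regulated in the opposite direction by factor knockdown.

    Presence with the opposite sign is required; a candidate absent from
    the knockdown bioset is removed.
    """
    if len(knockdown_bioset) == 0:
        raise ValueError("knockdown bioset is empty")
    kd = knockdown_bioset.fold_changes()
    kept = []
    for cand in candidates:
        fc = kd.get(cand.gene_id)
        if fc is not None and (fc > 0) != (cand.direction > 0):
            kept.append(cand)
    return kept


def effect_size_filter(
    candidates: Sequence[BiomarkerGene],
    activation_biosets: Sequence[Bioset],
    min_mean_fc: float = 1.5,
    provenance: Sequence[str] = (),
) -> Biomarker:
    """Keep candidates whose mean |linear fc| over the activation biosets
    where they are differentially expressed is >= ``min_mean_fc`` (inclusive)."""
    if min_mean_fc <= 1:
        raise ValueError("min_mean_fc is a linear fold and must exceed 1")
    maps = [bs.fold_changes() for bs in activation_biosets]
    kept = []
    for cand in candidates:
        values = [abs(m[cand.gene_id]) for m in maps if cand.gene_id in m]
        if not values:
            continue
        mean_abs = sum(values) / len(values)
        if mean_abs >= min_mean_fc:
            kept.append(replace(cand, mean_fc=cand.direction * mean_abs))
    return Biomarker(kept, list(provenance))


def build_biomarker(
    activation_biosets: Sequence[Bioset],
    knockdown_bioset: Bioset,
    params: BiomarkerParams = BiomarkerParams(),
) -> Biomarker:
    """Compose the three filters in order and record provenance.

    Raises :class:`EmptyBiomarkerError` if no gene survives.
    """
    candidates = directional_consistency_filter(activation_biosets, params.min_support)
    candidates = genetic_filter(candidates, knockdown_bioset)
    provenance = [bs.bioset_id for bs in activation_biosets] + [knockdown_bioset.bioset_id]
    biomarker = effect_size_filter(
        candidates, activation_biosets, params.min_mean_fc, provenance
    )
    if len(biomarker) == 0:
        raise EmptyBiomarkerError("no gene passed all three biomarker filters")
    return biomarker


def read_biomarker(path: str | Path) -> Biomarker:
    """Load a biomarker TSV (gene_id, direction, mean_fc, support).

    A plain two-column (gene_id, fold_change) signature — e.g. a short
    hand-picked gene list — is also accepted; direction is inferred from
    the sign and support defaults to 1.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "direction" in df.columns:
        genes = [
            BiomarkerGene(
                normalize_gene_id(r["gene_id"]),
                int(r["direction"]),
                float(r["mean_fc"]),
                int(r.get("support", 1)),
            )
            for r in df.to_dict("records")
        ]
    else:
        fc_col = "fold_change" if "fold_change" in df.columns else "mean_fc"
        if fc_col not in df.columns:
            raise ValueError(f"{path}: needs direction/mean_fc or fold_change columns")
        genes = [
            BiomarkerGene(
                normalize_gene_id(r["gene_id"]),
                1 if float(r[fc_col]) > 0 else -1,
                float(r[fc_col]),
                1,
            )
            for r in df.to_dict("records")
        ]
    return Biomarker(genes, provenance=[str(path)])


def write_biomarker(biomarker: Biomarker, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tdirection\tmean_fc\tsupport\n")
        for g in biomarker.genes:
            fh.write(f"{g.gene_id}\t{g.direction:+d}\t{g.mean_fc!r}\t{g.support}\n")
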