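"""Synthetic fixtures with known ground truth for every pipeline stage.

All generators are deterministic given ``SimulationConfig.seed``; each
consumes an independent substream derived from the seed by a fixed
offset, so outputs do not depend on call order.

What is emulated (and what is not): two-group log2-normal expression
matrices with an embedded directed signature; activation-bioset panels
with per-bioset signature dropout and background noise genes; a
screening compendium of activator / suppressor / null chemicals with
dose-scaled effects; a toy genome with promoter-proximal binding peaks
and planted motif instances; and a per-cell reporter assay with
logistic concentration–response.  Probe-level artifacts, batch effects
and platform-specific normalization are deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarker import Biomarker
from .chip import PWM, Peak, PeakSet, TssRecord, TssTable
from .core import Bioset, CompendiumAnnotation, GeneRecord, GeneUniverse
from .deg import CONTROL, TREATED, ExpressionMatrix

__all__ = [
    "ChemicalSpec",
    "SimulationConfig",
    "GroundTruth",
    "GenomicFixtures",
    "default_compendium_spec",
    "simulate_expression",
    "simulate_bioset_panel",
    "simulate_compendium",
    "simulate_genomic_fixtures",
    "simulate_reporter_cells",
    "null_false_activation_rate",
]

# fixed substream offsets: module outputs are independent of call order
_STREAM_GENES = 0
_STREAM_EXPRESSION = 1
_STREAM_PANEL = 2
_STREAM_COMPENDIUM = 3
_STREAM_GENOMIC = 4
_STREAM_REPORTER = 5
_STREAM_NULLS = 6


@dataclass(frozen=True)
class ChemicalSpec:
    label: Literal["activator", "suppressor", "null"]
    n_biosets: int = 4
    effect_scale: float = 1.0


def default_compendium_spec() -> dict[str, ChemicalSpec]:
    """Three activators, two suppressors and ten inert chemicals, four
    biosets each — small enough to screen in seconds, structured enough
    for enrichment and trend analyses."""
    spec: dict[str, ChemicalSpec] = {}
    for i in range(3):
        spec[f"activator_{i + 1}"] = ChemicalSpec("activator")
    for i in range(2):
        spec[f"suppressor_{i + 1}"] = ChemicalSpec("suppressor")
    for i in range(10):
        spec[f"null_{i + 1}"] = ChemicalSpec("null")
    return spec


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all generators.

    ``signature_fc`` is the linear fold change of embedded signature
    genes; ``dropout_prob`` the per-bioset probability that a signature
    gene fails to respond in an activation bioset; ``within_group_sd``
    the per-sample log2 noise of expression matrices.
    """

    seed: int = 0
    n_genes: int = 2000
    n_signature: int = 100
    n_activation_biosets: int = 7
    signature_fc: float = 2.0
    dropout_prob: float = 0.2
    noise_genes_per_bioset: int = 150
    within_group_sd: float = 0.25
    n_replicates: int = 3
    compendium: Mapping[str, ChemicalSpec] = field(default_factory=default_compendium_spec)

    def __post_init__(self) -> None:
        if not 0 < self.n_signature < self.n_genes:
            raise ValueError("need 0 < n_signature < n_genes")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.signature_fc <= 1:
            raise ValueError("signature_fc is a linear fold and must exceed 1")

    def rng(self, stream: int, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, index])


@dataclass
class GroundTruth:
    """What the generator embedded, for parameter-recovery checks."""

    signature: dict[str, int] = field(default_factory=dict)  # gene -> ±1
    chemical_labels: dict[str, str] = field(default_factory=dict)
    bioset_labels: dict[str, str] = field(default_factory=dict)
    planted_motifs: list[dict] = field(default_factory=list)
    bound_genes: list[str] = field(default_factory=list)
    reporter_crossings: dict[str, float | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _gene_structure(config: SimulationConfig):
    """Baseline log2 means, signature membership and directions.

    Signature genes are drawn from genes expressed above the 30th
    percentile of baseline intensity: a factor's target battery is
    measurably expressed, and this keeps the embedded truth from being
    masked by the low-expression filter of the DEG step.
    """
    rng = config.rng(_STREAM_GENES)
    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(8.0, 1.5, config.n_genes)
    eligible = np.flatnonzero(baseline > np.percentile(baseline, 30.0))
    sig_idx = rng.choice(eligible, size=config.n_signature, replace=False)
    directions = rng.choice([1, -1], size=config.n_signature)
    signature = {genes[i]: int(d) for i, d in zip(sig_idx, directions)}
    return genes, baseline, signature


def simulate_expression(
    config: SimulationConfig,
    condition: Literal["activator", "knockdown", "null"] = "activator",
    index: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-group expression matrix with the signature embedded.

    Activator: treated samples shift signature genes by
    ``direction * log2(signature_fc)``, each gene's shift dropped with
    probability ``dropout_prob``.  Knockdown: the opposite shift with
    full penetrance (a hard genetic perturbation).  Null: no shift.
    ``index`` selects an independent replicate matrix.
    """
    if condition not in ("activator", "knockdown", "null"):
        raise ValueError(f"unknown condition {condition!r}")
    genes, baseline, signature = _gene_structure(config)
    rng = config.rng(_STREAM_EXPRESSION, index * 3 + {"activator": 0, "knockdown": 1, "null": 2}[condition])

    n_rep = config.n_replicates
    shift = np.zeros(config.n_genes)
    if condition != "null":
        sign = 1.0 if condition == "activator" else -1.0
        for i, g in enumerate(genes):
            d = signature.get(g)
            if d is None:
                continue
            if condition == "activator" and rng.random() < config.dropout_prob:
                continue
            shift[i] = sign * d * np.log2(config.signature_fc)

    noise = rng.normal(0.0, config.within_group_sd, (config.n_genes, 2 * n_rep))
    values = baseline[:, None] + noise
    values[:, n_rep:] += shift[:, None]

    samples = [f"ctrl_{i}" for i in range(n_rep)] + [f"trt_{i}" for i in range(n_rep)]
    groups = {s: CONTROL for s in samples[:n_rep]} | {s: TREATED for s in samples[n_rep:]}
    matrix = ExpressionMatrix(genes, samples, groups, values)
    truth = GroundTruth(signature=signature)
    return matrix, truth


def _noise_records(
    rng: np.random.Generator,
    genes: Sequence[str],
    exclude: set[str],
    n: int,
) -> list[GeneRecord]:
    pool = [g for g in genes if g not in exclude]
    chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    records = []
    for idx in chosen:
        sign = 1 if rng.random() < 0.5 else -1
        magnitude = 1.2 * 2.0 ** abs(rng.normal(0.0, 0.5))
        records.append(GeneRecord(pool[idx], sign * magnitude))
    return records


def simulate_bioset_panel(
    config: SimulationConfig,
) -> tuple[list[Bioset], Bioset, GroundTruth]:
    """Activation-bioset panel plus factor-knockdown bioset, at the bioset
    level: signature genes appear concordantly with per-bioset dropout;
    the knockdown bioset carries every signature gene with inverted sign;
    noise genes pad each bioset with random directions."""
    genes, _, signature = _gene_structure(config)
    universe = GeneUniverse(genes)
    rng = config.rng(_STREAM_PANEL)
    sig_set = set(signature)

    def signature_records(flip: bool, dropout: float) -> list[GeneRecord]:
        records = []
        for g in sorted(signature):
            if dropout > 0 and rng.random() < dropout:
                continue
            d = signature[g] * (-1 if flip else 1)
            magnitude = config.signature_fc * 2.0 ** rng.normal(0.0, 0.15)
            records.append(GeneRecord(g, d * magnitude))
        return records

    panel = []
    for b in range(config.n_activation_biosets):
        records = signature_records(flip=False, dropout=config.dropout_prob)
        records += _noise_records(rng, genes, sig_set, config.noise_genes_per_bioset)
        panel.append(Bioset(f"activation_{b + 1}", records, universe))

    kd_records = signature_records(flip=True, dropout=0.0)
    kd_records += _noise_records(rng, genes, sig_set, config.noise_genes_per_bioset)
    knockdown = Bioset("factor_knockdown", kd_records, universe)
    return panel, knockdown, GroundTruth(signature=signature)


_DOSE_GRID = (1.0, 3.16, 10.0, 31.6, 100.0, 316.0)


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[dict[str, Bioset], list[CompendiumAnnotation], GroundTruth]:
    """Annotated screening compendium per ``config.compendium``.

    Activator biosets perturb the signature concordantly with a
    dose-scaled fraction of responding genes (stronger at higher dose,
    for trend analyses); suppressors are the mirror image; null
    chemicals contribute noise-only biosets of comparable size.
    """
    genes, _, signature = _gene_structure(config)
    universe = GeneUniverse(genes)
    rng = config.rng(_STREAM_COMPENDIUM)
    sig_set = set(signature)

    biosets: dict[str, Bioset] = {}
    annotations: list[CompendiumAnnotation] = []
    truth = GroundTruth(signature=signature)

    for chemical in sorted(config.compendium):
        spec = config.compendium[chemical]
        truth.chemical_labels[chemical] = spec.label
        n = spec.n_biosets
        for b in range(n):
            bioset_id = f"{chemical}_bs{b + 1}"
            dose = _DOSE_GRID[b % len(_DOSE_GRID)]
            records: list[GeneRecord] = []
            if spec.label in ("activator", "suppressor"):
                # response fraction grows with dose rank within the chemical
                frac = min(1.0, spec.effect_scale * (0.4 + 0.6 * (b + 1) / n))
                flip = -1 if spec.label == "suppressor" else 1
                for g in sorted(signature):
                    if rng.random() < frac:
                        magnitude = config.signature_fc * 2.0 ** rng.normal(0.0, 0.15)
                        records.append(GeneRecord(g, flip * signature[g] * magnitude))
                records += _noise_records(rng, genes, sig_set, config.noise_genes_per_bioset)
            else:
                records += _noise_records(
                    rng, genes, set(), config.n_signature + config.noise_genes_per_bioset
                )
            biosets[bioset_id] = Bioset(bioset_id, records, universe)
            annotations.append(
                CompendiumAnnotation(
                    bioset_id=bioset_id,
                    perturbant=chemical,
                    cell_type="synthetic",
                    dose=dose,
                    dose_unit="uM",
                    time_h=24.0,
                    study="SIM",
                )
            )
            truth.bioset_labels[bioset_id] = spec.label
    return biosets, annotations, truth


# ---------------------------------------------------------------------------
# genomic fixtures
# ---------------------------------------------------------------------------

# ARE-like 9-bp motif (TGACTCAGC core) as a strongly peaked count matrix
_ARE_CONSENSUS = "TGACTCAGC"
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _are_counts() -> np.ndarray:
    counts = np.ones((4, len(_ARE_CONSENSUS)))
    for j, base in enumerate(_ARE_CONSENSUS):
        counts[_BASE_INDEX[base], j] = 97.0
    return counts


@dataclass
class GenomicFixtures:
    genome: dict[str, str]
    peaks: PeakSet
    tss: TssTable
    pwm: PWM
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _motif_free_seq(rng: np.random.Generator, length: int, pwm: PWM, threshold: float) -> str:
    """Background sequence with no PWM window at or above the threshold, so
    the absence of a planted motif really means absence of any match."""
    from .chip import pwm_relatedness

    for _ in range(200):
        seq = _random_seq(rng, length)
        if pwm_relatedness(seq, pwm)[0] < threshold:
            return seq
    raise RuntimeError("could not draw a motif-free background sequence")


def simulate_genomic_fixtures(
    config: SimulationConfig,
    n_genes: int = 30,
    n_bound: int = 10,
    n_planted: int = 6,
    spacing: int = 22_000,
    peak_width: int = 200,
    min_relatedness: float = 0.8,
) -> GenomicFixtures:
    """Toy genome, TSS table, promoter-proximal peaks and an ARE-like PWM.

    ``n_bound`` of the first ``n_genes`` signature-universe genes receive
    one peak within 10 kb of their TSS; ``n_planted`` of those peaks get
    the motif consensus planted at a recorded offset, the rest carry
    motif-free background.  Peaks and TSSs are split over two chromosomes,
    with TSSs spaced further apart than the association window plus the
    peak-placement range so a peak can only annotate the gene it was
    placed for.
    """
    rng = config.rng(_STREAM_GENOMIC)
    pwm = PWM.from_counts(_are_counts())
    genes = _gene_ids(config.n_genes)[:n_genes]
    chroms = ["chr1", "chr2"]
    chrom_length = spacing * (n_genes // 2 + 1)

    tss_records = []
    for i, g in enumerate(genes):
        chrom = chroms[i % 2]
        pos = spacing * (i // 2 + 1) + int(rng.integers(0, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_records.append(TssRecord(g, chrom, pos, strand))
    tss = TssTable(tss_records)

    bound = sorted(rng.choice(n_genes, size=n_bound, replace=False).tolist())
    truth = GroundTruth(bound_genes=[genes[i] for i in bound])

    genome = {c: list(_random_seq(rng, chrom_length)) for c in chroms}
    peaks = []
    for rank, gi in enumerate(bound):
        rec = tss_records[gi]
        offset_from_tss = int(rng.integers(-9_000, 9_000 - peak_width))
        start = max(0, min(chrom_length - peak_width, rec.tss_position - 1 + offset_from_tss))
        peak = Peak(rec.chrom, start, start + peak_width)
        background = _motif_free_seq(rng, peak_width, pwm, min_relatedness)
        if rank < n_planted:
            plant_at = int(rng.integers(0, peak_width - len(pwm)))
            strand = "+" if rng.random() < 0.5 else "-"
            motif = _ARE_CONSENSUS if strand == "+" else _revcomp(_ARE_CONSENSUS)
            background = (
                background[:plant_at] + motif + background[plant_at + len(pwm):]
            )
            truth.planted_motifs.append(
                {"chrom": peak.chrom, "start": peak.start, "end": peak.end,
                 "offset": plant_at, "strand": strand}
            )
        genome[rec.chrom][start : start + peak_width] = list(background)
        peaks.append(peak)

    genome_str = {c: "".join(s) for c, s in genome.items()}
    return GenomicFixtures(genome_str, PeakSet(peaks), tss, pwm, truth)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# reporter assay
# ---------------------------------------------------------------------------

_REPORTER_CONCS = tuple(np.round(np.logspace(-1, np.log10(200), 10), 4))


@dataclass(frozen=True)
class ReporterChemicalSpec:
    """Logistic concentration–response in the probability that a cell
    switches to the induced (GFP-high) state; ``crossing`` is the
    concentration (µM) where the expected GFP-positive fraction reaches
    0.1, or None for an inert chemical."""

    crossing: float | None
    p_max: float = 0.6
    steepness: float = 2.0
    cytotoxic: bool = False


def _logistic_fraction(conc: np.ndarray, spec: ReporterChemicalSpec, baseline: float) -> np.ndarray:
    if spec.crossing is None:
        return np.full_like(conc, baseline, dtype=float)
    # place the midpoint so that baseline + (1-baseline)*p crosses 0.1 at `crossing`
    p_at_crossing = (0.1 - baseline) / (1.0 - baseline)
    shift = np.log(spec.p_max / p_at_crossing - 1.0) / spec.steepness
    x0 = np.log10(spec.crossing) + shift
    p = spec.p_max / (1.0 + np.exp(-spec.steepness * (np.log10(conc) - x0)))
    return baseline + (1.0 - baseline) * p


# fraction of background cells above the Q3 + 0.25*IQR gate for the
# shifted-exponential background below (X = c - Exp(1)):
# P(X > Q3 + 0.25*IQR) = 1 - exp(-(ln(4/3) - 0.25*ln 3)) ~ 1.3%
_BACKGROUND_POSITIVE = float(1.0 - np.exp(-(np.log(4.0 / 3.0) - 0.25 * np.log(3.0))))


def simulate_reporter_cells(
    config: SimulationConfig,
    chemicals: Mapping[str, ReporterChemicalSpec] | None = None,
    n_cells: int = 400,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell reporter table plus ground-truth crossing concentrations.

    Background (vehicle-like) cells have left-skewed log intensities
    (a bright-bounded autofluorescence floor), so only ~1.3% of them
    clear the vehicle-derived GFP gate; induced cells sit well above it.
    PI positivity of a cytotoxic chemical rises with concentration.
    """
    if chemicals is None:
        chemicals = {
            "responder_a": ReporterChemicalSpec(crossing=10.0),
            "responder_b": ReporterChemicalSpec(crossing=1.0),
            "inert": ReporterChemicalSpec(crossing=None),
            "cytotoxic": ReporterChemicalSpec(crossing=30.0, cytotoxic=True),
        }
    rng = config.rng(_STREAM_REPORTER)
    rows: list[dict] = []
    truth = GroundTruth()

    def background_log_intensity(n: int) -> np.ndarray:
        return 4.0 - rng.exponential(1.0, n)

    def induced_log_intensity(n: int) -> np.ndarray:
        return rng.normal(6.5, 0.4, n)

    for plate in range(n_replicates):
        veh = np.exp(background_log_intensity(n_cells))
        for cell, inten in enumerate(veh):
            rows.append(
                dict(plate=plate + 1, well="veh", condition="vehicle",
                     concentration_uM=0.0, cell_id=cell, gfp_intensity=float(inten),
                     pi_positive=int(rng.random() < 0.02))
            )

    concs = np.asarray(_REPORTER_CONCS)
    for chemical in sorted(chemicals):
        spec = chemicals[chemical]
        truth.reporter_crossings[chemical] = spec.crossing
        fractions = _logistic_fraction(concs, spec, _BACKGROUND_POSITIVE)
        for plate in range(n_replicates):
            for ci, conc in enumerate(concs):
                p_induced = 0.0 if spec.crossing is None else float(
                    (fractions[ci] - _BACKGROUND_POSITIVE) / (1.0 - _BACKGROUND_POSITIVE)
                )
                induced = rng.random(n_cells) < p_induced
                log_int = background_log_intensity(n_cells)
                log_int[induced] = induced_log_intensity(int(induced.sum()))
                pi_rate = 0.02
                if spec.cytotoxic:
                    pi_rate = 0.02 + 0.5 * conc / concs.max()
                for cell in range(n_cells):
                    rows.append(
                        dict(plate=plate + 1, well=f"{chemical}_{ci}", condition=chemical,
                             concentration_uM=float(conc), cell_id=cell,
                             gfp_intensity=float(np.exp(log_int[cell])),
                             pi_positive=int(rng.random() < pi_rate))
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_false_activation_rate(
    biomarker: Biomarker,
    universe: GeneUniverse,
    n_replicates: int = 10_000,
    target_size: int = 200,
    threshold: float = 4.0,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> float:
    """Fraction of uniformly random target biosets scoring |value| >= threshold.

    Each replicate draws ``target_size`` genes uniformly from the universe
    with random signs and scores them against the biomarker — the
    compendium's null hypothesis of no association.
    """
    from .fisher import running_min_p

    rng = (config or SimulationConfig(seed=seed)).rng(_STREAM_NULLS)
    genes = sorted(universe.gene_ids)
    N = len(universe)
    fcs = biomarker.fold_changes()
    ranked = [g for g in biomarker.ranked_gene_ids() if g in universe]
    q_up = [g for g in ranked if fcs[g] > 0]
    q_down = [g for g in ranked if fcs[g] < 0]

    n_extreme = 0
    for _ in range(n_replicates):
        idx = rng.choice(N, size=target_size, replace=False)
        signs = rng.random(target_size) < 0.5
        t_up = {genes[i] for i, s in zip(idx, signs) if s}
        t_down = {genes[i] for i, s in zip(idx, signs) if not s}
        s_pos = -np.log10(running_min_p(q_up, t_up, N)) - np.log10(
            running_min_p(q_down, t_down, N)
        )
        s_neg = -np.log10(running_min_p(q_up, t_down, N)) - np.log10(
            running_min_p(q_down, t_up, N)
        )
        if abs(s_pos - s_neg) >= threshold:
            n_extreme += 1
    return n_extreme / n_replicates
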