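"""Peak-to-promoter annotation and ARE motif matching.

Binding peaks (BED, 0-based half-open) are associated with genes whose
transcription start site (1-based) lies within a symmetric window —
10 kb by default, boundary inclusive, both strands ("bi-directional"
promoters).  Enrichment of a gene signature among the bound genes is a
one-sided Fisher exact test on the measurable-gene universe.  ARE
(antioxidant response element) instances inside peaks are detected by
scanning a position weight matrix over both strands and reporting
positions whose *relatedness* — the min–max normalized PWM score
(S − S_min)/(S_max − S_min) ∈ [0, 1] — reaches a threshold, 0.8 by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakSet",
    "TssRecord",
    "TssTable",
    "PWM",
    "MotifHit",
    "read_bed",
    "read_tss_table",
    "read_pwm",
    "annotate_peaks_to_genes",
    "binding_enrichment",
    "pwm_relatedness",
    "scan_ares",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Peak:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class PeakSet:
    intervals: list[Peak]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def chromosomes(self) -> set[str]:
        return {p.chrom for p in self.intervals}


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss_position: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss_position < 1:
            raise ValueError("tss_position is 1-based and must be >= 1")


@dataclass
class TssTable:
    records: list[TssRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def chromosomes(self) -> set[str]:
        return {r.chrom for r in self.records}


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3(+score in column 5) into a PeakSet."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score"][: _n_bed_cols(path)],
    )
    peaks = []
    for row in df.itertuples(index=False):
        score = float(row.score) if hasattr(row, "score") and pd.notna(row.score) else None
        peaks.append(Peak(str(row.chrom), int(row.start), int(row.end), score))
    return PeakSet(peaks)


def _n_bed_cols(path: str | Path) -> int:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 5)
    return 3


def read_tss_table(path: str | Path) -> TssTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "chrom", "tss_position", "strand"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    return TssTable(
        [
            TssRecord(str(r.gene_id).strip().upper(), str(r.chrom), int(r.tss_position), str(r.strand))
            for r in df.itertuples(index=False)
        ]
    )


def annotate_peaks_to_genes(
    peaks: PeakSet, tss: TssTable, window: int = 10_000
) -> dict[str, list[Peak]]:
    """Map gene -> peaks overlapping [tss − window, tss + window] (1-based,
    inclusive at both edges; strand-agnostic).

    Chromosomes present in only one of the two inputs are reported with a
    warning, since a naming mismatch (chr1 vs 1) silently empties the map.
    """
    only_peaks = peaks.chromosomes() - tss.chromosomes()
    only_tss = tss.chromosomes() - peaks.chromosomes()
    if only_peaks or only_tss:
        logger.warning(
            "chromosome naming mismatch: %d chrom(s) only in peaks, %d only in TSS table",
            len(only_peaks), len(only_tss),
        )

    # interval tree per chromosome over peak coordinates, 1-based inclusive
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        # 0-based half-open [start, end) covers 1-based bases start+1 .. end
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start + 1, p.end + 1, p)

    out: dict[str, list[Peak]] = {}
    for rec in tss:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        lo = max(1, rec.tss_position - window)
        hi = rec.tss_position + window
        hits = tree.overlap(lo, hi + 1)  # +1: tree is half-open, window inclusive
        if hits:
            found = sorted({iv.data for iv in hits}, key=lambda p: (p.chrom, p.start, p.end))
            out.setdefault(rec.gene_id, [])
            for p in found:
                if p not in out[rec.gene_id]:
                    out[rec.gene_id].append(p)
    return out


def binding_enrichment(
    biomarker_genes: Iterable[str], bound_genes: Iterable[str], universe_size: int
) -> dict[str, float]:
    """Fractions bound in the signature vs the background, with a one-sided
    Fisher exact p-value for over-representation."""
    bm = set(biomarker_genes)
    bound = set(bound_genes)
    if not bm:
        raise ValueError("empty biomarker gene set")
    if universe_size < len(bm | bound):
        raise ValueError("universe smaller than the union of gene sets")
    k = len(bm & bound)
    table = [
        [k, len(bm) - k],
        [len(bound) - k, universe_size - len(bm) - (len(bound) - k)],
    ]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return {
        "fraction_biomarker": k / len(bm),
        "fraction_background": len(bound) / universe_size,
        "n_bound_biomarker": k,
        "p_value": p,
    }


class PWM:
    """Position weight matrix: 4 × L weights in A, C, G, T row order.

    Counts can be converted to log-odds against a uniform background
    with a pseudocount; ``min_score``/``max_score`` are the attainable
    extremes used by the relatedness normalization.  An ``N`` in the
    sequence scores as the column minimum (most unfavourable base).
    """

    def __init__(self, matrix: np.ndarray | Sequence[Sequence[float]]):
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM must be 4 x L with L >= 1, got shape {m.shape}")
        self.matrix = m
        self._col_min = m.min(axis=0)
        self._col_max = m.max(axis=0)
        self.min_score = float(self._col_min.sum())
        self.max_score = float(self._col_max.sum())
        if not self.max_score > self.min_score:
            raise ValueError("degenerate PWM: max attainable score equals min")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray | Sequence[Sequence[float]],
                    pseudocount: float = 0.25) -> "PWM":
        """Log-odds PWM from a 4 × L count matrix, uniform background."""
        c = np.asarray(counts, dtype=float) + pseudocount
        freqs = c / c.sum(axis=0, keepdims=True)
        return cls(np.log2(freqs / 0.25))

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def score(self, window: str) -> float:
        """Raw score of a single window of length L (N scores as column min)."""
        L = len(self)
        if len(window) != L:
            raise ValueError(f"window length {len(window)} != motif length {L}")
        s = 0.0
        for j, base in enumerate(window.upper()):
            idx = _BASE_INDEX.get(base)
            s += self.matrix[idx, j] if idx is not None else self._col_min[j]
        return s

    def relatedness(self, window: str) -> float:
        return (self.score(window) - self.min_score) / (self.max_score - self.min_score)


def read_pwm(path: str | Path, as_counts: bool = False, pseudocount: float = 0.25) -> PWM:
    """Read a 4-row tab-separated matrix (rows A, C, G, T; JASPAR-like row
    labels in a first column are accepted).  With ``as_counts`` the matrix
    is converted to log-odds with ``pseudocount``."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            fields = line.replace("[", " ").replace("]", " ").split()
            if fields and fields[0].upper() in _BASES:
                fields = fields[1:]
            rows.append([float(f) for f in fields])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 matrix rows (A, C, G, T), got {len(rows)}")
    m = np.asarray(rows, dtype=float)
    return PWM.from_counts(m, pseudocount) if as_counts else PWM(m)


@dataclass(frozen=True)
class MotifHit:
    """A PWM match inside a peak; ``offset`` is 0-based from the peak start
    on the forward genomic strand (leftmost base of the matched window)."""

    peak: Peak
    offset: int
    strand: str
    relatedness: float


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pwm_relatedness(sequence_window: str, pwm: PWM) -> tuple[float, int, str]:
    """Best min–max-normalized PWM score over all offsets and both strands.

    Returns ``(relatedness, offset, strand)`` where offset is 0-based on
    the forward sequence (leftmost base of the matched window).
    """
    seq = sequence_window.upper()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {L}")
    best = (-1.0, 0, "+")
    rc = _revcomp(seq)
    n = len(seq)
    for off in range(n - L + 1):
        r = pwm.relatedness(seq[off : off + L])
        if r > best[0]:
            best = (r, off, "+")
    for off_rc in range(n - L + 1):
        r = pwm.relatedness(rc[off_rc : off_rc + L])
        # mirror the reverse-complement offset back onto forward coordinates
        off_fwd = n - L - off_rc
        if r > best[0]:
            best = (r, off_fwd, "-")
    return best


def scan_ares(
    peaks: PeakSet,
    genome: Mapping[str, object],
    pwm: PWM,
    min_relatedness: float = 0.8,
) -> dict[Peak, list[MotifHit]]:
    """All motif positions with relatedness >= ``min_relatedness`` in each peak.

    ``genome`` is any chrom -> sequence mapping; a ``pyfaidx.Fasta`` works
    directly.  Peaks outside the genome bounds are skipped with a warning.
    """
    out: dict[Peak, list[MotifHit]] = {}
    L = len(pwm)
    for peak in peaks:
        try:
            seq = str(genome[peak.chrom][peak.start : peak.end]).upper()
        except (KeyError, IndexError):
            logger.warning("peak %s:%d-%d outside genome; skipped",
                           peak.chrom, peak.start, peak.end)
            continue
        if len(seq) < max(L, peak.end - peak.start):
            logger.warning("peak %s:%d-%d truncated by genome end; skipped",
                           peak.chrom, peak.start, peak.end)
            continue
        hits: list[MotifHit] = []
        rc = _revcomp(seq)
        n = len(seq)
        for off in range(n - L + 1):
            r = pwm.relatedness(seq[off : off + L])
            if r >= min_relatedness:
                hits.append(MotifHit(peak, off, "+", r))
        for off_rc in range(n - L + 1):
            r = pwm.relatedness(rc[off_rc : off_rc + L])
            if r >= min_relatedness:
                hits.append(MotifHit(peak, n - L - off_rc, "-", r))
        if hits:
            hits.sort(key=lambda h: (h.offset, h.strand))
            out[peak] = hits
    return out
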