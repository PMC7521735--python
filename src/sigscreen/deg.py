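"""Two-group differential expression: expression matrix -> bioset.

Emulates the statistical filter used by large curated expression
compendia: per-gene Welch (or Student) t-test at p < 0.05 with no
multiple-test correction, a linear fold-change cutoff of ±1.2, and
removal of genes whose mean intensity sits in the lower 20th percentile
of both groups.  Input intensities are assumed already log2-transformed
and normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Bioset, GeneRecord, GeneUniverse, to_linear_fold

__all__ = [
    "ExpressionMatrix",
    "DegParams",
    "InsufficientReplicatesError",
    "welch_p",
    "derive_bioset",
    "read_expression_matrix",
]

CONTROL = "control"
TREATED = "treated"


class InsufficientReplicatesError(ValueError):
    """A group has fewer than 2 samples; the t-test is undefined."""


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 intensities with a two-group design.

    ``values`` has one row per gene (order matching ``genes``) and one
    column per sample (order matching ``samples``); ``groups`` maps each
    sample to ``"control"`` or ``"treated"``.
    """

    genes: list[str]
    samples: list[str]
    groups: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        bad = {g for g in self.groups.values()} - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups.get(s) == group]
        return self.values[:, idx]

    def universe(self) -> GeneUniverse:
        return GeneUniverse(self.genes)


@dataclass(frozen=True)
class DegParams:
    """Thresholds of the differential-expression filter."""

    p_cutoff: float = 0.05
    fc_cutoff: float = 1.2
    low_expression_percentile: float = 20.0
    test: Literal["welch", "student"] = "welch"

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff is a linear fold and must exceed 1")
        if not 0 <= self.low_expression_percentile < 100:
            raise ValueError("low_expression_percentile must lie in [0, 100)")


def welch_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided p-value of Welch's unequal-variance t-test.

    Degenerate case: both groups constant with equal means gives p = 1
    by convention (no evidence of a difference).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientReplicatesError("need >= 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def _student_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def derive_bioset(
    matrix: ExpressionMatrix,
    params: DegParams = DegParams(),
    bioset_id: str = "derived",
) -> Bioset:
    """Apply the t-test / fold-change / low-expression filter.

    A gene enters the bioset iff its two-sided test p-value is below
    ``p_cutoff``, its |linear fold change| (2^(mean treated − mean
    control)) is at least ``fc_cutoff``, and its mean intensity is NOT in
    the lower ``low_expression_percentile`` of the per-group gene-mean
    distribution in *both* groups (inclusive boundary).  The result may
    legitimately be empty (returned as a zero-record bioset).
    """
    ctrl = matrix.group_columns(CONTROL)
    trt = matrix.group_columns(TREATED)
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 samples per group, got control={ctrl.shape[1]} "
            f"treated={trt.shape[1]}"
        )

    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2_fc = mean_t - mean_c

    # per-gene p-values; vectorized Welch/Student via scipy on the full matrix
    equal_var = params.test == "student"
    res = stats.ttest_ind(trt, ctrl, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: nan from scipy -> convention p=1 if equal means
    degenerate = np.isnan(pvals)
    if degenerate.any():
        pvals[degenerate] = np.where(np.isclose(log2_fc[degenerate], 0.0), 1.0, 0.0)

    # low-expression mask: mean intensity <= the group's own percentile in
    # BOTH groups (inclusive); percentile 0 disables the filter entirely
    if params.low_expression_percentile > 0:
        q_c = np.percentile(mean_c, params.low_expression_percentile)
        q_t = np.percentile(mean_t, params.low_expression_percentile)
        low_both = (mean_c <= q_c) & (mean_t <= q_t)
    else:
        low_both = np.zeros_like(mean_c, dtype=bool)

    keep = (
        (pvals < params.p_cutoff)
        & (2.0 ** np.abs(log2_fc) >= params.fc_cutoff)
        & ~low_both
    )

    universe = matrix.universe()
    records = [
        GeneRecord(matrix.genes[i], to_linear_fold(2.0 ** log2_fc[i]), float(pvals[i]))
        for i in np.flatnonzero(keep)
    ]
    # an empty bioset is a legitimate null result here; scoring layers reject it
    return Bioset(bioset_id, records, universe)


def read_expression_matrix(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Load a genes-in-rows TSV matrix plus a (sample_id, group) design TSV."""
    df = pd.read_csv(matrix_path, sep="\t", comment="#")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    samples = [c for c in df.columns[1:]]
    design = pd.read_csv(design_path, sep="\t", comment="#")
    if not {"sample_id", "group"} <= set(design.columns):
        raise ValueError(f"{design_path}: needs columns sample_id, group")
    groups = dict(zip(design["sample_id"].astype(str), design["group"].astype(str)))
    return ExpressionMatrix(genes, samples, groups, df[samples].to_numpy(float))
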