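"""Compendium-wide screening: activity calls, chemical enrichment,
confusion metrics, and dose/time trend fits.

Every bioset in an annotated compendium is scored against the biomarker
with the signed running-Fisher test; a score ≥ +4 calls the bioset
*active* (factor activated), ≤ −4 *suppressed*, anything between
*inactive*.  Chemical-level analyses then aggregate the per-bioset
calls in the two ways used in practice: the max-score rule (a chemical
is active if any of its biosets is) and a one-sided Fisher exact
enrichment of each chemical in the active fraction of the whole
compendium, Benjamini–Hochberg corrected across the chemicals tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fisher import SignedScore

__all__ = [
    "ActivityCall",
    "ConfusionCounts",
    "EnrichmentRow",
    "ACTIVATION_THRESHOLD",
    "classify",
    "chemical_max_call",
    "confusion_metrics",
    "chemical_enrichment",
    "bh_adjust",
    "trend_fit",
]

ACTIVATION_THRESHOLD = 4.0

Label = Literal["active", "suppressed", "inactive"]


@dataclass(frozen=True)
class ActivityCall:
    label: Label
    score: float


def _score_value(score: SignedScore | float) -> float:
    return float(score)


def classify(score: SignedScore | float, threshold: float = ACTIVATION_THRESHOLD) -> ActivityCall:
    """Three-way call: active (score >= threshold, inclusive), suppressed
    (score <= -threshold), else inactive."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = _score_value(score)
    if v >= threshold:
        label: Label = "active"
    elif v <= -threshold:
        label = "suppressed"
    else:
        label = "inactive"
    return ActivityCall(label, v)


def chemical_max_call(
    scores: Sequence[SignedScore | float],
    threshold: float = ACTIVATION_THRESHOLD,
    mode: Literal["active", "suppressed"] = "active",
) -> ActivityCall:
    """Chemical-level call from the extreme score across its biosets.

    Activation mode takes the maximum score regardless of dose or time —
    a chemical with one strongly suppressive and one mildly positive
    bioset is still called from the positive side.  Suppression mode is
    the mirror image and uses the minimum.
    """
    if not scores:
        raise ValueError("no scores supplied for chemical")
    values = [_score_value(s) for s in scores]
    if mode == "active":
        extreme = max(values)
        label: Label = "active" if extreme >= threshold else "inactive"
    else:
        extreme = min(values)
        label = "suppressed" if extreme <= -threshold else "inactive"
    return ActivityCall(label, extreme)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("all confusion counts are zero")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy.

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN);
    PPV = TP/(TP+FP); NPV = TN/(TN+FN);
    balanced accuracy = (sensitivity + specificity)/2.
    A metric with a zero denominator is reported as ``None``.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(c.TP, c.TP + c.FN)
    spec = ratio(c.TN, c.FP + c.TN)
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(c.TP, c.TP + c.FP),
        "npv": ratio(c.TN, c.TN + c.FN),
        "balanced_accuracy": bal,
    }


@dataclass(frozen=True)
class EnrichmentRow:
    perturbant: str
    total: int
    active: int
    inactive: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if self.active + self.inactive != self.total:
            raise ValueError("active + inactive must equal total")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def chemical_enrichment(
    calls: Mapping[str, Sequence[ActivityCall]] | pd.DataFrame,
    min_biosets: int = 3,
    mode: Literal["active", "suppressed"] = "active",
    threshold: float = ACTIVATION_THRESHOLD,
) -> list[EnrichmentRow]:
    """Per-chemical one-sided Fisher exact enrichment in the called fraction.

    ``calls`` maps perturbant -> its biosets' :class:`ActivityCall`s (or a
    DataFrame with ``perturbant`` and ``score`` columns, classified here).
    Each chemical with at least ``min_biosets`` biosets is tested on the
    2×2 table [chemical & called, chemical & not-called; others called,
    others not-called] against the *whole* compendium background
    (including the chemical's own biosets).  BH adjustment spans exactly
    the chemicals tested; rows are sorted by adjusted then raw p.
    """
    if isinstance(calls, pd.DataFrame):
        grouped: dict[str, list[ActivityCall]] = {}
        for perturbant, sub in calls.groupby("perturbant"):
            grouped[str(perturbant)] = [classify(s, threshold) for s in sub["score"]]
        calls = grouped

    def hit(c: ActivityCall) -> bool:
        return c.label == mode

    total_all = sum(len(v) for v in calls.values())
    hits_all = sum(sum(hit(c) for c in v) for v in calls.values())

    tested: list[tuple[str, int, int]] = []
    for perturbant in sorted(calls):
        group = calls[perturbant]
        if len(group) >= min_biosets:
            tested.append((perturbant, len(group), sum(hit(c) for c in group)))
    if not tested:
        return []

    p_raws = []
    for _, n_total, n_hit in tested:
        table = [
            [n_hit, n_total - n_hit],
            [hits_all - n_hit, (total_all - hits_all) - (n_total - n_hit)],
        ]
        p_raws.append(float(stats.fisher_exact(table, alternative="greater")[1]))
    p_adjs = bh_adjust(p_raws)

    rows = [
        EnrichmentRow(perturbant, n_total, n_hit, n_total - n_hit, p_raw, p_adj)
        for (perturbant, n_total, n_hit), p_raw, p_adj in zip(tested, p_raws, p_adjs)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.p_raw, r.perturbant))
    return rows


def trend_fit(x: Sequence[float], scores: Sequence[SignedScore | float]) -> dict[str, float]:
    """Ordinary least-squares line of score against dose or time.

    Returns slope, intercept and R².  Constant response is reported as
    R² = 0 (no trend); constant ``x`` is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray([_score_value(s) for s in scores], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; trend undefined")
    if np.var(y) == 0:
        slope, intercept = 0.0, float(y.mean())
        return {"slope": slope, "intercept": intercept, "r_squared": 0.0}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }
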