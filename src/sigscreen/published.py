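"""Reference inputs from the published oxidative-stress biomarker screen.

These are *inputs* to worked examples — printed classification counts
and screen designations — not results of this package.  Everything
derived from them (sensitivity, enrichment p-values, fractions) is
computed at run time by the corresponding module functions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import ConfusionCounts

__all__ = [
    "HTS_CONFUSION",
    "HTS_CONFUSION_RECLASSIFIED",
    "HTS_AGREEMENT",
    "CHIP_BINDING",
    "TOBACCO_SMOKE_ENRICHMENT",
    "load_reporter_designations",
    "reporter_confusion",
]

# HepG2/hepatocyte test set against the two HTS reporter assays:
# 13 true-positive and 42 true-negative biosets, 3 false positives,
# 1 false negative.
HTS_CONFUSION = ConfusionCounts(TP=13, FP=3, TN=42, FN=1)

# the same test set after reclassifying two false positives (weakly active
# in earlier literature) as true positives
HTS_CONFUSION_RECLASSIFIED = ConfusionCounts(TP=15, FP=1, TN=42, FN=1)

# chemical-level agreement between biomarker max-score calls and the HTS
# assays: 17 shared actives + 48 shared inactives among 90 chemicals
HTS_AGREEMENT = {"agreeing_active": 17, "agreeing_inactive": 48, "total": 90}

# promoter-proximal (10 kb) binding: 38 of 143 biomarker genes bound vs
# 3553 of ~26,000 transcribed genes
CHIP_BINDING = {
    "biomarker_bound": 38,
    "biomarker_total": 143,
    "background_bound": 3553,
    "universe": 26_000,
}

# the enrichment worked example: 239 tobacco-smoke biosets of which 84
# scored active, against 1429 active of 45,163 compendium biosets
TOBACCO_SMOKE_ENRICHMENT = {
    "chemical_total": 239,
    "chemical_active": 84,
    "compendium_total": 45_163,
    "compendium_active": 1_429,
}


def load_reporter_designations() -> pd.DataFrame:
    """The 30-chemical SRXN1-GFP confirmation screen designation table."""
    ref = resources.files("sigscreen.data") / "reporter_screen_designations.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def reporter_confusion(designations: pd.DataFrame | None = None) -> ConfusionCounts:
    """Count the TP/FP/TN/FN designations of the confirmation screen."""
    df = load_reporter_designations() if designations is None else designations
    counts = df["designation"].value_counts()
    return ConfusionCounts(
        TP=int(counts.get("TP", 0)),
        FP=int(counts.get("FP", 0)),
        TN=int(counts.get("TN", 0)),
        FN=int(counts.get("FN", 0)),
    )
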