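"""Reproduce the published accuracy and enrichment arithmetic.

The printed classification counts of the HTS test set, the reporter
confirmation screen designations and the promoter-binding counts are
inputs; everything below them is recomputed by the package.
"""

from sigscreen import binding_enrichment, confusion_metrics
from sigscreen.published import (
    CHIP_BINDING,
    HTS_CONFUSION,
    HTS_CONFUSION_RECLASSIFIED,
    reporter_confusion,
)

m = confusion_metrics(HTS_CONFUSION)
print("HTS test set (TP=13, FP=3, TN=42, FN=1):")
for k, v in m.items():
    print(f"  {k}: {v:.0%}")

m2 = confusion_metrics(HTS_CONFUSION_RECLASSIFIED)
print(f"after reclassifying two false positives: balanced accuracy "
      f"{m2['balanced_accuracy']:.0%}")

counts = reporter_confusion()
m3 = confusion_metrics(counts)
print(f"\nreporter confirmation screen (TP={counts.TP}, FP={counts.FP}, "
      f"TN={counts.TN}, FN={counts.FN}):")
print(f"  sensitivity {m3['sensitivity']:.2f}, specificity {m3['specificity']:.2f}, "
      f"balanced accuracy {m3['balanced_accuracy']:.2f}")

bm = {f"b{i}" for i in range(CHIP_BINDING["biomarker_total"])}
bound = {f"b{i}" for i in range(CHIP_BINDING["biomarker_bound"])} | {
    f"x{i}" for i in range(CHIP_BINDING["background_bound"] - CHIP_BINDING["biomarker_bound"])
}
res = binding_enrichment(bm, bound, CHIP_BINDING["universe"])
print(f"\npromoter binding: {res['fraction_biomarker']:.1%} of biomarker genes vs "
      f"{res['fraction_background']:.1%} background, Fisher p = {res['p_value']:.1e}")
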