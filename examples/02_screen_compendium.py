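"""Screen a synthetic compendium for chemicals that modulate the factor.

Scores every annotated bioset against the biomarker with the signed
running-Fisher test (signed -log10 p; >= +4 called active, <= -4
suppressed), makes chemical-level max-score calls, and runs the
Fisher-exact / Benjamini-Hochberg enrichment over chemicals.
"""

import numpy as np

from sigscreen import (
    SimulationConfig,
    build_biomarker,
    chemical_enrichment,
    chemical_max_call,
    classify,
    signed_score,
    simulate_bioset_panel,
    simulate_compendium,
    trend_fit,
)

config = SimulationConfig(seed=0)
activation, knockdown, _ = simulate_bioset_panel(config)
biomarker = build_biomarker(activation, knockdown)
universe = activation[0].platform

biosets, annotations, truth = simulate_compendium(config)
scores: dict[str, list[float]] = {}
doses: dict[str, list[float]] = {}
for ann in annotations:
    s = signed_score(biomarker, biosets[ann.bioset_id], universe)
    scores.setdefault(ann.perturbant, []).append(s.value)
    doses.setdefault(ann.perturbant, []).append(ann.dose)

print("chemical-level max-score calls (truth in parentheses):")
for chem in sorted(scores):
    call = chemical_max_call(scores[chem])
    supp = chemical_max_call(scores[chem], mode="suppressed")
    label = call.label if call.label == "active" else supp.label
    print(f"  {chem:14s} max score {max(scores[chem]):8.2f} -> {label:10s}"
          f" ({truth.chemical_labels[chem]})")

calls = {c: [classify(v) for v in vs] for c, vs in scores.items()}
print("\nchemicals enriched among active biosets (BH-adjusted p < 0.05):")
for row in chemical_enrichment(calls, min_biosets=3):
    if row.p_adj < 0.05:
        print(f"  {row.perturbant:14s} {row.active}/{row.total} active,"
              f" p_adj = {row.p_adj:.2e}")

chem = "activator_1"
fit = trend_fit(np.log10(doses[chem]), scores[chem])
print(f"\ndose trend for {chem}: slope {fit['slope']:.1f} per log10 uM,"
      f" R^2 = {fit['r_squared']:.2f}")
# Activators score far above +4 with dose-increasing strength, suppressors
# mirror them below -4, and inert chemicals stay inside the +/-4 band.
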