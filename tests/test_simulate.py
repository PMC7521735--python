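"""Generators: determinism, embedded ground truth, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from sigscreen import (
    DegParams,
    SimulationConfig,
    annotate_peaks_to_genes,
    chemical_max_call,
    derive_bioset,
    scan_ares,
    signed_score,
    simulate_bioset_panel,
    simulate_compendium,
    simulate_expression,
    simulate_genomic_fixtures,
    simulate_reporter_cells,
)
from sigscreen.deg import TREATED, CONTROL


class TestDeterminism:
    def test_panel_reproducible_and_order_independent(self):
        cfg = SimulationConfig(seed=42)
        a1, kd1, t1 = simulate_bioset_panel(cfg)
        # interleave another generator call: substreams must not interact
        simulate_compendium(cfg)
        a2, kd2, t2 = simulate_bioset_panel(cfg)
        assert t1.signature == t2.signature
        assert [b.fold_changes() for b in a1] == [b.fold_changes() for b in a2]
        assert kd1.fold_changes() == kd2.fold_changes()

    def test_different_seeds_differ(self):
        a1, _, _ = simulate_bioset_panel(SimulationConfig(seed=1))
        a2, _, _ = simulate_bioset_panel(SimulationConfig(seed=2))
        assert a1[0].fold_changes() != a2[0].fold_changes()

    def test_reporter_cells_reproducible(self):
        c1, _ = simulate_reporter_cells(SimulationConfig(seed=3), n_cells=20)
        c2, _ = simulate_reporter_cells(SimulationConfig(seed=3), n_cells=20)
        pd.testing.assert_frame_equal(c1, c2)


class TestSimulateExpression:
    def test_knockdown_inverts_signature_sign(self):
        cfg = SimulationConfig(seed=7)
        m_act, truth = simulate_expression(cfg, "activator")
        m_kd, _ = simulate_expression(cfg, "knockdown")
        bs_kd = derive_bioset(m_kd, bioset_id="kd")
        fcs = bs_kd.fold_changes()
        detected = [g for g in truth.signature if g in fcs]
        assert len(detected) > 0.7 * len(truth.signature)
        flipped = sum((fcs[g] > 0) != (truth.signature[g] > 0) for g in detected)
        assert flipped == len(detected)  # every detected signature gene inverted

    def test_null_condition_type_one_rate(self):
        # Student's test is exact for the generator's iid normal groups, so
        # its null pass rate equals p_cutoff within Monte-Carlo error; the
        # default Welch variant is conservative at n=3 and can only be lower.
        cfg = SimulationConfig(seed=8, n_genes=4000)
        m, truth = simulate_expression(cfg, "null")
        se = np.sqrt(0.05 * 0.95 / cfg.n_genes)
        rate_s = len(derive_bioset(
            m, DegParams(fc_cutoff=1.0000001, low_expression_percentile=0, test="student")
        )) / cfg.n_genes
        assert abs(rate_s - 0.05) < 3 * se
        rate_w = len(derive_bioset(
            m, DegParams(fc_cutoff=1.0000001, low_expression_percentile=0)
        )) / cfg.n_genes
        assert rate_w <= 0.05 + 3 * se

    def test_activator_detection_matches_independent_power_oracle(self):
        """Non-dropped signature genes pass the DEG filter at the rate an
        independent Welch-power simulation predicts for the generator's
        effect size and noise."""
        cfg = SimulationConfig(seed=9)
        detected = []
        n_embedded = 0
        for index in range(5):
            m, truth = simulate_expression(cfg, "activator", index=index)
            bs = derive_bioset(m, bioset_id=f"a{index}")
            fcs = bs.fold_changes()
            # count over embedded genes whose shift was actually applied
            ctrl, trt = m.group_columns(CONTROL), m.group_columns(TREATED)
            diff = trt.mean(1) - ctrl.mean(1)
            gi = {g: i for i, g in enumerate(m.genes)}
            for g, d in truth.signature.items():
                if abs(diff[gi[g]]) > 0.5 * np.log2(cfg.signature_fc):  # shift applied
                    n_embedded += 1
                    detected.append(g in fcs and (fcs[g] > 0) == (d > 0))
        observed = np.mean(detected)

        rng = np.random.default_rng(123)
        n = 40_000
        from scipy import stats
        x = rng.normal(0, cfg.within_group_sd, (n, cfg.n_replicates))
        y = rng.normal(np.log2(cfg.signature_fc), cfg.within_group_sd, (n, cfg.n_replicates))
        p = stats.ttest_ind(y, x, axis=1, equal_var=False).pvalue
        oracle_power = np.mean((p < 0.05) & (np.abs(y.mean(1) - x.mean(1)) >= np.log2(1.2)))

        se = np.sqrt(oracle_power * (1 - oracle_power) / n_embedded)
        assert observed == pytest.approx(oracle_power, abs=4 * se + 0.02)


@pytest.fixture(scope="module")
def screened(biomarker, universe, sim_config):
    biosets, annotations, truth = simulate_compendium(sim_config)
    scores = {}
    for ann in annotations:
        s = signed_score(biomarker, biosets[ann.bioset_id], universe)
        scores.setdefault(ann.perturbant, []).append(s.value)
    return scores, truth


class TestCompendium:
    def test_activators_called_active(self, screened):
        scores, truth = screened
        for chem, label in truth.chemical_labels.items():
            if label == "activator":
                assert chemical_max_call(scores[chem]).label == "active"

    def test_suppressors_mirror_activators(self, screened):
        scores, truth = screened
        for chem, label in truth.chemical_labels.items():
            if label == "suppressor":
                assert chemical_max_call(scores[chem], mode="suppressed").label == "suppressed"
                assert min(scores[chem]) <= -4

    def test_null_chemicals_stay_below_threshold(self, screened):
        scores, truth = screened
        null_scores = [s for chem, label in truth.chemical_labels.items()
                       if label == "null" for s in scores[chem]]
        assert all(abs(s) < 4 for s in null_scores)

    def test_dose_scaled_effects_give_positive_trend(self, screened, sim_config):
        scores, truth = screened
        from sigscreen import trend_fit
        chem = next(c for c, l in truth.chemical_labels.items() if l == "activator")
        doses = [1.0, 3.16, 10.0, 31.6][: len(scores[chem])]
        fit = trend_fit(np.log10(doses), scores[chem])
        assert fit["slope"] > 0


@pytest.fixture(scope="module")
def fixtures(sim_config):
    return simulate_genomic_fixtures(sim_config)


class TestGenomicFixtures:
    def test_bound_genes_recovered_exactly(self, fixtures):
        assoc = annotate_peaks_to_genes(fixtures.peaks, fixtures.tss)
        assert sorted(assoc) == sorted(fixtures.truth.bound_genes)

    def test_planted_motifs_found_at_full_relatedness(self, fixtures):
        hits = scan_ares(fixtures.peaks, fixtures.genome, fixtures.pwm)
        by_peak = {(p.chrom, p.start): h for p, h in hits.items()}
        for planted in fixtures.truth.planted_motifs:
            found = by_peak[(planted["chrom"], planted["start"])]
            exact = [(h.offset, h.strand) for h in found if h.relatedness == 1.0]
            assert (planted["offset"], planted["strand"]) in exact

    def test_unplanted_peaks_have_no_hits(self, fixtures):
        hits = scan_ares(fixtures.peaks, fixtures.genome, fixtures.pwm)
        planted_starts = {(p["chrom"], p["start"]) for p in fixtures.truth.planted_motifs}
        for peak in fixtures.peaks:
            if (peak.chrom, peak.start) not in planted_starts:
                assert peak not in hits


@pytest.fixture(scope="module")
def cells(sim_config):
    return simulate_reporter_cells(sim_config, n_cells=150)


class TestReporterCells:
    def test_inert_chemical_response_stays_flat(self, cells):
        df, truth = cells
        from sigscreen import wells_from_cell_table
        from sigscreen.reporter import condition_response
        wells = wells_from_cell_table(df)
        inert = next(c for c, x in truth.reporter_crossings.items() if x is None)
        _, fracs = condition_response(wells, inert)
        assert max(fracs) < 0.1

    def test_cytotoxic_pi_fraction_rises_with_concentration(self, cells):
        df, _ = cells
        cyto = df[df.condition == "cytotoxic"]
        rates = cyto.groupby("concentration_uM")["pi_positive"].mean()
        assert rates.loc[rates.index.max()] > rates.loc[rates.index.min()] + 0.2
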