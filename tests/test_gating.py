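"""Threshold hierarchy, absolute counting, and the two-stage learned gater."""

import numpy as np
import pytest

from cytoharm import (EventMatrix, ThresholdGater, TwoStageGateClassifier,
                      absolute_count, gate_events, population_stats)
from cytoharm.exceptions import GatingError, ThresholdError
from cytoharm.gating import cohort_row, scatter_level
from cytoharm.panels import PANEL1, PANEL2, SCATTER_TEMPLATES
from cytoharm.synthetic import draw_true_sample

@pytest.fixture(scope="module")
def true_sample(clean_cfg):
    return draw_true_sample(clean_cfg, "gating-sample", "healthy")


class TestThresholdGating:
    def test_frequencies_recover_ground_truth(self, clean_cfg, true_sample):
        em, truth = true_sample
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        stats = population_stats(em, labels, PANEL1.populations,
                                 beads_per_volume=clean_cfg.beads_per_ul)
        for pop, frac in truth.fractions.items():
            got = stats.loc[pop, "freq_of_leukocytes"]
            assert got == pytest.approx(100 * frac, abs=1.0), pop

    def test_t_cell_predicate(self):
        fm, fs, sm, ss = SCATTER_TEMPLATES["lymphocytes"]
        row = {"FSC": 10 ** fm, "SSC": 10 ** sm, "CD3": 2e4, "CD4": 100,
               "CD8": 90, "CD19": 80, "CD56": 120, "CD16": 100,
               "CD14": 110, "CD15": 95}
        em = EventMatrix(np.array([[row[c] for c in
                                    PANEL1.channel_map.canonical_order]]),
                         list(PANEL1.channel_map.canonical_order))
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        assert labels[0] == "T cells"

    def test_all_debris_input_gives_zeros_with_flags(self, rng):
        n = 500
        cols = [10 ** rng.normal(3.0, 0.1, n), 10 ** rng.normal(3.0, 0.1, n)]
        cols += [10 ** rng.normal(1.5, 0.2, n) for _ in range(8)]
        em = EventMatrix(np.column_stack(cols),
                         list(PANEL1.channel_map.canonical_order))
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        stats = population_stats(em, labels, PANEL1.populations)
        leaves = [p.name for p in PANEL1.populations
                  if p.parent not in (None, "all", "leukocytes")]
        for pop in leaves:
            assert stats.loc[pop, "n_events"] == 0
            assert stats.loc[pop, "low_count"]

    def test_deterministic_and_permutation_equivariant(self, rng,
                                                       true_sample):
        em, _ = true_sample
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        assert np.array_equal(
            labels, gate_events(em, PANEL1.populations, PANEL1.thresholds))
        perm = rng.permutation(em.n_events)
        shuffled = em.with_values(em.values[perm])
        assert np.array_equal(
            gate_events(shuffled, PANEL1.populations, PANEL1.thresholds),
            labels[perm])

    def test_missing_threshold_is_an_error(self, true_sample):
        em, _ = true_sample
        partial = {"CD3": 1e3}
        with pytest.raises(ThresholdError):
            gate_events(em, PANEL1.populations, partial)

    def test_panel2_populations_gated(self, clean_cfg):
        cfg = type(clean_cfg)(seed=13, panel_id="panel2",
                              daily_drift_sd=0.0, with_spillover=False,
                              events_per_sample=30_000)
        em, truth = draw_true_sample(cfg, "p2", "healthy")
        labels = gate_events(em, PANEL2.populations, PANEL2.thresholds)
        stats = population_stats(em, labels, PANEL2.populations)
        for pop in ("basophils", "pDC", "mDC1", "mDC2"):
            got = stats.loc[pop, "freq_of_leukocytes"]
            assert got == pytest.approx(100 * truth.fractions[pop],
                                        abs=0.5), pop


class TestAbsoluteCount:
    def test_formula(self):
        assert absolute_count(5000, 1000, 100.0) == pytest.approx(500.0)
        assert absolute_count(0, 1000, 100.0) == 0.0

    def test_zero_beads_is_acquisition_failure(self):
        with pytest.raises(GatingError):
            absolute_count(5000, 0, 100.0)

    def test_concentration_recovered_within_3_se(self, clean_cfg,
                                                 true_sample):
        em, truth = true_sample
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        n_beads = int((labels == "beads").sum())
        leuk = np.isin(labels, ["debris", "beads", "all"], invert=True)
        est = absolute_count(int(leuk.sum()), n_beads,
                             clean_cfg.beads_per_ul)
        se = truth.concentration / np.sqrt(n_beads)
        assert abs(est - truth.concentration) < 3 * se


class TestTwoStageModel:
    def test_self_consistency_with_threshold_gating(self, true_sample):
        em, _ = true_sample
        em.meta["instrument_id"] = "I1"
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        model = TwoStageGateClassifier(PANEL1.populations).fit([em],
                                                               [labels])
        pred = model.predict(em)
        assert (pred == labels).mean() >= 0.99

    def test_instrument_specific_scatter_stage_beats_pooled(self,
                                                            true_sample):
        """2x scatter gain between instruments: per-instrument stage-1
        models handle it; one pooled scatter model does worse."""
        em, truth = true_sample
        em1 = em.copy()
        em1.meta["instrument_id"] = "A"
        em2 = em.copy()
        em2.meta["instrument_id"] = "B"
        for ch in ("FSC", "SSC"):
            em2.values[:, em2.channel_names.index(ch)] *= 2.0
        y = truth.labels

        per_inst = TwoStageGateClassifier(PANEL1.populations).fit(
            [em1, em2], [y, y])
        acc1 = (per_inst.predict(em1) == y).mean()
        acc2 = (per_inst.predict(em2) == y).mean()
        assert acc1 >= 0.95 and acc2 >= 0.95

        pooled_a, pooled_b = em1.copy(), em2.copy()
        pooled_b.meta["instrument_id"] = "A"      # hide the instrument
        pooled = TwoStageGateClassifier(PANEL1.populations).fit(
            [pooled_a, pooled_b], [y, y])
        acc_pooled = min((pooled.predict(pooled_a) == y).mean(),
                         (pooled.predict(pooled_b) == y).mean())
        assert acc_pooled < min(acc1, acc2)

    def test_unseen_instrument_falls_back_with_warning(self, true_sample):
        em, _ = true_sample
        em.meta["instrument_id"] = "I1"
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        fallback = ThresholdGater(PANEL1.populations,
                                  PANEL1.thresholds).fit()
        model = TwoStageGateClassifier(PANEL1.populations,
                                       fallback=fallback).fit([em],
                                                              [labels])
        other = em.copy()
        other.meta["instrument_id"] = "UNSEEN"
        with pytest.warns(UserWarning, match="UNSEEN"):
            pred = model.predict(other)
        assert np.array_equal(pred, labels)

    def test_missing_marker_column_is_an_error(self, true_sample):
        em, _ = true_sample
        em.meta["instrument_id"] = "I1"
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        model = TwoStageGateClassifier(PANEL1.populations).fit([em],
                                                               [labels])
        crippled = EventMatrix(em.values[:, :-1], em.channel_names[:-1],
                               dict(em.meta))
        with pytest.raises(GatingError):
            model.predict(crippled)

    def test_scatter_level_mapping(self):
        lv = scatter_level(PANEL1.populations)
        assert lv["CD4 T cells"] == "lymphocytes"
        assert lv["neutrophils"] == "granulocytes"
        assert lv["debris"] == "debris"
        assert lv["beads"] == "beads"


class TestCohortRow:
    def test_feature_naming_and_content(self, clean_cfg, true_sample):
        em, _ = true_sample
        labels = gate_events(em, PANEL1.populations, PANEL1.thresholds)
        row = cohort_row(em, labels, PANEL1.populations,
                         clean_cfg.beads_per_ul)
        assert "freq|T cells" in row and "mfi|T cells|CD3" in row
        assert "count|B cells" in row
        assert row["mfi|T cells|CD3"] > 5e3          # CD3-bright population
        assert not any(k.startswith("mfi|lymphocytes") for k in row.index)
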