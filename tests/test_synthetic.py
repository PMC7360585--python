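"""Generator contracts: determinism, ground-truth consistency, recovery."""

import numpy as np
import pytest

from cytoharm import detect_peaks, fit_affine, read_fcs
from cytoharm.synthetic import (SimulationConfig, day_drift,
                                draw_true_sample, instrument_gains,
                                lot_effects, simulate_beads,
                                simulate_cohort)

from conftest import D0


class TestDeterminism:
    def test_same_seed_bit_identical(self, clean_cfg):
        a = simulate_beads(clean_cfg, "INST02", D0)
        b = simulate_beads(clean_cfg, "INST02", D0)
        assert np.array_equal(a.values, b.values)
        s1, t1 = draw_true_sample(clean_cfg, "x", "healthy")
        s2, t2 = draw_true_sample(clean_cfg, "x", "healthy")
        assert np.array_equal(s1.values, s2.values)
        assert np.array_equal(t1.labels, t2.labels)

    def test_different_seed_differs(self, clean_cfg):
        other = type(clean_cfg)(seed=99, daily_drift_sd=0.0,
                                with_spillover=False)
        assert not np.array_equal(
            simulate_beads(clean_cfg, "INST02", D0).values,
            simulate_beads(other, "INST02", D0).values)

    def test_frozen_parameters_are_stable(self, clean_cfg):
        assert instrument_gains(clean_cfg, "INST03") == \
            instrument_gains(clean_cfg, "INST03")
        assert lot_effects(clean_cfg, "lot2") == \
            lot_effects(clean_cfg, "lot2")
        assert day_drift(clean_cfg, "INST03", D0) == \
            day_drift(clean_cfg, "INST03", D0)


class TestBeadScaling:
    def test_gain_scales_detected_peaks_exactly(self, clean_cfg, unity):
        base = detect_peaks(simulate_beads(clean_cfg, "INST01", D0,
                                           gain=unity, drift=1.0))
        g = {m: 1.12 for m in clean_cfg.panel.markers}
        scaled = detect_peaks(simulate_beads(clean_cfg, "INST01", D0,
                                             gain=g, drift=1.0))
        for ch in base.channels:
            assert np.allclose(scaled.peaks[ch], 1.12 * base.peaks[ch],
                               rtol=1e-9)

    def test_fitted_alpha_inverts_gain(self, clean_cfg, unity,
                                       reference_peaks):
        gains = instrument_gains(clean_cfg, "INST02")
        obs = detect_peaks(simulate_beads(clean_cfg, "INST02", D0,
                                          gain=gains, drift=1.0))
        t = fit_affine(obs, reference_peaks)
        for ch, g in gains.items():
            assert t.alpha[ch] == pytest.approx(1 / g, rel=0.02)


class TestSampleStructure:
    def test_frequency_estimates_concentrate(self):
        def total_error(n):
            cfg = SimulationConfig(seed=17, events_per_sample=n,
                                   daily_drift_sd=0.0, with_spillover=False)
            _, truth = draw_true_sample(cfg, "conc", "healthy")
            w = cfg.population_weights()
            return sum(abs(truth.fractions[p] - w[p]) for p in w)

        assert total_error(40_000) < total_error(1_000)

    def test_disease_effect_shifts_cd19_only(self, clean_cfg):
        em_h, t_h = draw_true_sample(clean_cfg, "pair", "healthy")
        em_d, t_d = draw_true_sample(clean_cfg, "pair", "disease")
        b_h = em_h.column("CD19")[t_h.labels == "B cells"]
        b_d = em_d.column("CD19")[t_d.labels == "B cells"]
        ratio = np.median(b_d) / np.median(b_h)
        assert ratio == pytest.approx(1.5, rel=0.1)
        t_h3 = em_h.column("CD3")[t_h.labels == "CD4 T cells"]
        t_d3 = em_d.column("CD3")[t_d.labels == "CD4 T cells"]
        assert np.median(t_d3) / np.median(t_h3) == pytest.approx(1.0,
                                                                  rel=0.05)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory):
    cfg = SimulationConfig.small(seed=23, n_centers=11,
                                 n_samples_per_center=2,
                                 events_per_sample=600,
                                 bead_events_per_peak=60)
    out = tmp_path_factory.mktemp("cohort")
    meta, truth = simulate_cohort(cfg, out)
    return cfg, out, meta, truth


class TestCohortTree:
    def test_all_instruments_present(self, cohort):
        _, _, meta, _ = cohort
        assert meta["instrument_id"].nunique() == 11

    def test_layout_and_vendor_dialects(self, cohort):
        cfg, out, meta, _ = cohort
        assert (out / "reference_peaks.csv").exists()
        assert (out / "schedule.json").exists()
        assert (out / "ground_truth.json").exists()
        lmd = [p for p in meta["path"] if p.endswith(".lmd")]
        fcs = [p for p in meta["path"] if p.endswith(".fcs")]
        assert lmd and fcs                      # both vendors emitted
        em = read_fcs(out / lmd[0])
        assert em.meta["vendor"] == "BC"
        assert "FL1 INT" in em.channel_names

    def test_rerun_identical_ground_truth(self, cohort, tmp_path):
        cfg, out, _, truth = cohort
        _, truth2 = simulate_cohort(cfg, tmp_path / "again")
        assert truth2.gains == truth.gains
        assert truth2.lot_effects == truth.lot_effects
        s1 = {k: v.fractions for k, v in truth.samples.items()}
        s2 = {k: v.fractions for k, v in truth2.samples.items()}
        assert s1 == s2
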