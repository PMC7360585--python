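"""Batch/center ratio-of-medians corrections and their exact invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cytoharm import (BatchMFICorrector, CenterMFICorrector,
                      apply_coefficients, assign_batches,
                      batch_coefficients, center_coefficients)
from cytoharm.exceptions import (BatchAssignmentError, CorrectionError,
                                 PipelineOrderError)

MFI_COLS = ["mfi|T cells|CD3", "mfi|B cells|CD19", "mfi|NK cells|CD56"]
OTHER_COLS = ["freq|T cells", "count|T cells"]


def make_table(rng, n_instruments=2, batches=("lot1:e0",), n_per=20,
               inst_gain=None, batch_effect=None, groups=None, sigma=0.1):
    """Cohort table with log-normal MFIs and known multiplicative effects."""
    rows = []
    day = 0
    for i in range(n_instruments):
        inst = f"I{i + 1}"
        g = 1.0 if inst_gain is None else inst_gain[inst]
        for bi, batch in enumerate(batches):
            e = 1.0 if batch_effect is None else batch_effect[batch]
            for k in range(n_per):
                day += 1
                group = (groups[rng.integers(len(groups))]
                         if groups else "healthy")
                row = {"sample_id": f"{inst}_{batch}_{k}",
                       "instrument_id": inst, "center_id": inst,
                       "acquisition_date": dt.date(2015, 1, 1)
                       + dt.timedelta(days=bi * 400 + k),
                       "batch_id": batch, "group": group,
                       "panel_id": "panel1"}
                for j, col in enumerate(MFI_COLS):
                    base = 10 ** rng.normal(3.5 + 0.2 * j, sigma)
                    if group == "disease" and "CD19" in col:
                        base *= 1.5
                    row[col] = base * g * e
                row["freq|T cells"] = rng.uniform(20, 40)
                row["count|T cells"] = rng.uniform(800, 1500)
                rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["corrections"] = []
    return table


class TestAssignBatches:
    LOTS = [("lot1", dt.date(2015, 1, 1), dt.date(2015, 5, 1)),
            ("lot2", dt.date(2015, 5, 1), dt.date(2015, 9, 1)),
            ("lot3", dt.date(2015, 9, 1), dt.date(2016, 1, 1))]

    def test_single_lot_no_recalibration(self):
        out = assign_batches([dt.date(2015, 2, d) for d in (1, 10, 20)],
                             [self.LOTS[0]])
        assert out == ["lot1:e0"] * 3

    def test_boundary_belongs_to_starting_period(self):
        out = assign_batches([dt.date(2015, 5, 1)], self.LOTS,
                             calib_dates=[dt.date(2015, 5, 1)])
        assert out == ["lot2:e1"]      # new lot and new epoch open that day

    def test_lot_times_epoch_combinations(self):
        calib = [dt.date(2015, m, 15) for m in (2, 4, 6, 8, 10, 11, 12)]
        dates = [dt.date(2015, m, 20) for m in range(1, 13)]
        out = assign_batches(dates, self.LOTS, calib)
        lots = {b.split(":")[0] for b in out}
        epochs = {b.split(":")[1] for b in out}
        assert lots == {"lot1", "lot2", "lot3"}
        assert len(epochs) == 8        # 7 recalibrations -> 8 epochs

    def test_date_outside_periods_names_sample(self):
        with pytest.raises(BatchAssignmentError, match="sample 1"):
            assign_batches([dt.date(2015, 2, 1), dt.date(2020, 1, 1)],
                           self.LOTS)


class TestBatchCorrection:
    def test_single_batch_all_coefficients_one(self, rng):
        table = make_table(rng)
        coeffs = batch_coefficients(table)
        assert np.allclose(coeffs.table.to_numpy(), 1.0)

    def test_coefficient_arithmetic(self):
        # batch1 median 1000, batch2 median 800 -> coeff 1.25
        rows = []
        for b, m in (("lot1:e0", 1000.0), ("lot2:e0", 800.0)):
            for k, v in enumerate([m - 10, m, m + 10]):
                rows.append({"sample_id": f"{b}{k}", "instrument_id": "I1",
                             "acquisition_date": dt.date(2015, 1, 1)
                             if b == "lot1:e0" else dt.date(2015, 6, 1),
                             "batch_id": b, "mfi|T cells|CD3": v})
        table = pd.DataFrame(rows)
        coeffs = batch_coefficients(table)
        assert coeffs.table.loc[("I1", "lot2:e0"),
                                "mfi|T cells|CD3"] == pytest.approx(1.25)

    def test_recovers_inverse_lot_effects(self, rng):
        effects = {"lot1:e0": 1.0, "lot2:e0": 0.8, "lot3:e0": 1.3}
        table = make_table(rng, n_instruments=1, batches=list(effects),
                           n_per=50, batch_effect=effects, sigma=0.04)
        coeffs = batch_coefficients(table).table
        for batch, eff in effects.items():
            got = coeffs.loc[("I1", batch)].to_numpy()
            assert np.allclose(got, 1 / eff, rtol=0.05)

    def test_exact_median_alignment_and_idempotence(self, rng):
        effects = {"lot1:e0": 1.0, "lot2:e0": 0.8}
        table = make_table(rng, n_instruments=2, batches=list(effects),
                           n_per=11, batch_effect=effects)
        corr = BatchMFICorrector().fit(table)
        out = corr.transform(table)
        for (inst, col), sub in (
                (key, grp) for key in
                [(i, c) for i in out["instrument_id"].unique()
                 for c in MFI_COLS]
                for grp in [out[out["instrument_id"] == key[0]]]):
            med = sub.groupby("batch_id")[col].median()
            assert np.allclose(med.to_numpy(), med.iloc[0], rtol=1e-12)
        again = batch_coefficients(out).table
        assert np.allclose(again.to_numpy(), 1.0, rtol=1e-12)

    def test_frequencies_and_counts_bit_identical(self, rng):
        effects = {"lot1:e0": 1.0, "lot2:e0": 0.8}
        table = make_table(rng, batches=list(effects),
                           batch_effect=effects)
        out = BatchMFICorrector().fit(table).transform(table)
        for col in OTHER_COLS:
            assert np.array_equal(table[col].to_numpy(),
                                  out[col].to_numpy())


class TestCenterCorrection:
    def test_uniform_2x_gain_gives_half_coefficient(self, rng):
        table = make_table(rng, n_instruments=2, n_per=30,
                           inst_gain={"I1": 1.0, "I2": 2.0})
        coeffs = center_coefficients(table, "I1",
                                     require_batch_corrected=False).table
        assert np.allclose(coeffs.loc["I1"].to_numpy(), 1.0)
        assert np.allclose(coeffs.loc["I2"].to_numpy(), 0.5, rtol=0.1)

    def test_eleven_instruments_align_exactly(self, rng):
        gains = {f"I{i + 1}": g for i, g in
                 enumerate(rng.uniform(0.7, 1.4, 11))}
        gains["I1"] = 1.0
        table = make_table(rng, n_instruments=11, n_per=9, inst_gain=gains)
        corr = CenterMFICorrector("I1", require_batch_corrected=False)
        out = corr.fit(table).transform(table)
        for col in MFI_COLS:
            med = out.groupby("instrument_id")[col].median()
            assert np.allclose(med.to_numpy(), med["I1"], rtol=1e-12)

    def test_center_before_batch_refused(self, rng):
        table = make_table(rng)
        with pytest.raises(PipelineOrderError):
            CenterMFICorrector("I1").fit(table)

    def test_disease_ratio_invariant_under_corrections(self, rng):
        """Multiplicative corrections cancel out of group-median ratios.

        Each correction applies one multiplier per cell of its grouping
        (instrument x batch for step 5, instrument for step 6), so the
        disease/healthy median ratio is exactly invariant within every such
        cell, and the biological signal (a 1.5x CD19 shift) survives the
        whole pipeline.
        """
        effects = {"lot1:e0": 1.0, "lot2:e0": 0.8}
        table = make_table(rng, n_instruments=2, batches=list(effects),
                           n_per=40, batch_effect=effects,
                           inst_gain={"I1": 1.0, "I2": 1.6},
                           groups=("healthy", "disease"))

        def ratios(t, keys):
            out = {}
            for key, sub in t.groupby(keys):
                a = sub[sub["group"] == "disease"]["mfi|B cells|CD19"]
                b = sub[sub["group"] == "healthy"]["mfi|B cells|CD19"]
                out[key] = a.median() / b.median()
            return out

        batch = BatchMFICorrector().fit(table)
        t1 = batch.transform(table)
        cell_keys = ["instrument_id", "batch_id"]
        before = ratios(table, cell_keys)
        after_batch = ratios(t1, cell_keys)
        for key in before:
            assert after_batch[key] == pytest.approx(before[key],
                                                     rel=1e-12)

        center = CenterMFICorrector("I1").fit(t1)
        t2 = center.transform(t1)
        per_inst_before = ratios(t1, ["instrument_id"])
        per_inst_after = ratios(t2, ["instrument_id"])
        for inst in per_inst_before:
            assert per_inst_after[inst] == pytest.approx(
                per_inst_before[inst], rel=1e-12)
            assert per_inst_after[inst] > 1.2   # biology survives

    def test_group_imbalance_warns(self, rng):
        table = make_table(rng, n_instruments=2, n_per=40)
        table.loc[table["instrument_id"] == "I1", "group"] = "healthy"
        table.loc[table["instrument_id"] == "I2", "group"] = "disease"
        table.loc[table.index[:2], "group"] = "disease"
        table.loc[table.index[-2:], "group"] = "healthy"
        with pytest.warns(UserWarning, match="composition"):
            CenterMFICorrector("I1",
                               require_batch_corrected=False).fit(table)


class TestApplyCoefficients:
    def test_identity_and_simple_scaling(self, rng):
        table = make_table(rng, n_instruments=1, n_per=5)
        coeffs = batch_coefficients(table)
        out = apply_coefficients(table, coeffs)
        pd.testing.assert_frame_equal(out.drop(columns=[]), table,
                                      check_dtype=False)
        coeffs.table.loc[:, "mfi|T cells|CD3"] = 1.25
        out2 = apply_coefficients(table, coeffs)
        assert np.allclose(out2["mfi|T cells|CD3"],
                           table["mfi|T cells|CD3"] * 1.25)

    def test_unmapped_row_is_an_error(self, rng):
        table = make_table(rng, n_instruments=1)
        coeffs = batch_coefficients(table)
        table.loc[table.index[0], "batch_id"] = "lotX:e9"
        with pytest.raises(CorrectionError):
            apply_coefficients(table, coeffs)

    def test_non_positive_median_rejected(self, rng):
        table = make_table(rng, n_instruments=1)
        table.loc[:, "mfi|T cells|CD3"] = -5.0
        with pytest.raises(CorrectionError):
            batch_coefficients(table)
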