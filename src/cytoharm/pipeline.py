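"""End-to-end orchestration of the six-step harmonization workflow.

Stage order is fixed — normalize -> compensate -> gate -> batch-correct ->
center-correct — and per-file failures are collected and reported without
aborting the cohort: a mislabelled or missing file costs that sample, not
the study.

Inputs are a study tree as produced by :func:`cytoharm.synthetic.simulate_cohort`
(or assembled by hand to the same layout): ``beads/`` acquisitions,
``samples/`` FCS/LMD files, ``reference_peaks.csv`` frozen targets,
``metadata.csv`` and optionally ``schedule.json`` (lot periods and
recalibration dates; without it the whole study is one batch).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bead_qc import BeadPeakDetector, PeakSet, qc_deviation
from .compensation import SpilloverCompensator, spillover_from_meta
from .exceptions import CytoharmError
from .fcs_io import read_fcs, standardize_channels, write_table
from .gating import ThresholdGater, cohort_row
from .metrics import center_effect_pca, median_equality_test
from .mfi_correction import (BatchMFICorrector, CenterMFICorrector,
                             assign_batches)
from .normalization import AffineNormalizer
from .panels import get_panel


@dataclass
class PipelineResult:
    table_raw: pd.DataFrame
    table_batch_corrected: pd.DataFrame | None
    table_corrected: pd.DataFrame | None
    transforms: dict
    qc: dict
    failures: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def _load_schedule(root: Path):
    path = root / "schedule.json"
    if not path.exists():
        return None
    raw = json.loads(path.read_text())
    return {
        "lot_periods": [(lot, _dt.date.fromisoformat(s),
                         _dt.date.fromisoformat(e))
                        for lot, s, e in raw["lot_periods"]],
        "calibration_dates": [_dt.date.fromisoformat(d)
                              for d in raw.get("calibration_dates", [])],
        "reference_instrument": raw.get("reference_instrument"),
        "beads_per_ul": raw.get("beads_per_ul"),
    }


def run_pipeline(input_dir, output_dir=None, panel_id: str = "panel1",
                 reference_instrument: str | None = None,
                 date_fallback_days: int = 0,
                 gate_model=None) -> PipelineResult:
    """Run steps 2-6 on a study tree; returns tables, QC and diagnostics.

    Parameters
    ----------
    input_dir : path
        Study tree (see module docstring).
    output_dir : path, optional
        Where to write normalized tables, coefficients and reports; nothing
        is written when omitted.
    date_fallback_days : int, default 0
        A sample acquired on a day without a bead file may use a bead
        transform up to this many days away; 0 means exact-day matching and
        such samples fail (and are reported, not fatal).
    gate_model : optional
        A fitted :class:`~cytoharm.gating.TwoStageGateClassifier`; default
        is the threshold rule hierarchy.
    """
    root = Path(input_dir)
    panel = get_panel(panel_id)
    meta = pd.read_csv(root / "metadata.csv")
    meta["acquisition_date"] = pd.to_datetime(meta["acquisition_date"]).dt.date
    reference = PeakSet.from_csv(root / "reference_peaks.csv",
                                 is_reference=True)
    schedule = _load_schedule(root)
    failures: list[dict] = []

    # --- step 2a: bead peaks and per-(instrument, day) transforms ---------
    transforms: dict[tuple, AffineNormalizer] = {}
    qc: dict[tuple, object] = {}
    detector = BeadPeakDetector()
    for bead_path in sorted((root / "beads").glob("*")):
        try:
            em = standardize_channels(read_fcs(bead_path), panel.channel_map)
            peaks = detector.fit(em).peaks_
            key = (em.meta.get("instrument_id"),
                   em.meta.get("acquisition_date"))
            qc[key] = qc_deviation(peaks, reference)
            norm = AffineNormalizer().fit(peaks, reference)
            transforms[key] = norm
        except CytoharmError as exc:
            failures.append({"file": str(bead_path), "stage": "bead_qc",
                             "error": str(exc)})

    def _find_transform(inst, date):
        if (inst, date) in transforms:
            return transforms[(inst, date)]
        for delta in range(1, date_fallback_days + 1):
            for d in (date - _dt.timedelta(days=delta),
                      date + _dt.timedelta(days=delta)):
                if (inst, d) in transforms:
                    return transforms[(inst, d)]
        raise CytoharmError(
            f"no bead transform for instrument {inst} on {date} "
            f"(fallback {date_fallback_days} day(s))")

    # --- steps 2b-4: normalize, compensate, gate each sample ---------------
    gater = ThresholdGater(panel.populations, panel.thresholds).fit()
    rows = []
    for rec in meta.to_dict("records"):
        path = root / rec["path"]
        try:
            em = standardize_channels(read_fcs(path), panel.channel_map)
            norm = _find_transform(rec["instrument_id"],
                                   rec["acquisition_date"])
            em = norm.transform(em)
            spill = spillover_from_meta(em)
            if spill is not None:
                em = SpilloverCompensator(spill).fit(em).transform(em)
            labels = (gate_model.predict(em) if gate_model is not None
                      else gater.predict(em))
            feats = cohort_row(em, labels, panel.populations,
                               beads_per_volume=rec.get("beads_per_ul"))
            row = {k: rec.get(k) for k in
                   ("sample_id", "center_id", "instrument_id",
                    "acquisition_date", "group", "panel_id")}
            row.update(feats.to_dict())
            rows.append(row)
        except CytoharmError as exc:
            failures.append({"file": str(path), "stage": "sample",
                             "error": str(exc)})

    if not rows:
        raise CytoharmError("every sample failed; nothing to correct")
    table = pd.DataFrame(rows)
    table.attrs["corrections"] = []

    # --- step 5 prerequisite: batch assignment -----------------------------
    if schedule is not None:
        table["batch_id"] = assign_batches(table["acquisition_date"],
                                           schedule["lot_periods"],
                                           schedule["calibration_dates"])
    else:
        table["batch_id"] = "lot1:e0"
    if reference_instrument is None and schedule is not None:
        reference_instrument = schedule.get("reference_instrument")
    if reference_instrument is None:
        reference_instrument = sorted(table["instrument_id"].unique())[0]

    # --- steps 5-6: the two ratio-of-medians corrections --------------------
    batch = BatchMFICorrector().fit(table)
    table_b = batch.transform(table)
    center = CenterMFICorrector(reference_instrument).fit(table_b)
    table_c = center.transform(table_b)

    # --- diagnostics --------------------------------------------------------
    metrics: dict = {}
    by_inst = table["instrument_id"].value_counts()
    if len(by_inst) >= 2 and by_inst.min() >= 3:
        metrics["separability_mfi_raw"] = center_effect_pca(
            table, "mfi").separability
        metrics["separability_mfi_corrected"] = center_effect_pca(
            table_c, "mfi").separability
        metrics["separability_freq"] = center_effect_pca(
            table, "freq").separability
        metrics["median_p_raw"] = median_equality_test(table).to_dict()
        metrics["median_p_corrected"] = median_equality_test(
            table_c).to_dict()

    result = PipelineResult(table, table_b, table_c, transforms, qc,
                            failures, metrics)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(table, out / "cohort_raw.csv")
        write_table(table_c, out / "cohort_corrected.csv")
        batch.coefficients_.to_csv(out / "batch_coefficients.csv")
        center.coefficients_.to_csv(out / "center_coefficients.csv")
        pd.DataFrame(failures).to_csv(out / "failures.csv", index=False)
        qc_rows = [{"instrument_id": k[0], "date": k[1],
                    "worst_deviation_pct": r.worst(), "passed": r.passed}
                   for k, r in qc.items()]
        pd.DataFrame(qc_rows).to_csv(out / "qc_report.csv", index=False)
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=1, default=str))
    return result
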