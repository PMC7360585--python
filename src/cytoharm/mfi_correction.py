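"""Ratio-of-medians MFI corrections: antibody batch, then instrument.

Both corrections act on the extracted cohort feature table, never on event
data. They exploit a single property — the median is multiplicative,
``median(c * x) = c * median(x)`` — so aligning medians by a multiplicative
coefficient is *exact*, idempotent, and cancels out of any within-instrument
ratio of group medians. That last point is what "corrects the instrument,
preserves the biology" means operationally: a disease-vs-healthy median
ratio inside one instrument is bit-for-bit invariant under both steps.

Step 5 (batch): dried-antibody production lots (and instrument recalibration
epochs) shift MFIs within an instrument. For each instrument, every marker's
per-batch median is aligned onto the instrument's earliest batch:
``coeff(batch) = median(first batch) / median(batch)``.

Step 6 (center): residual optical-bench differences shift MFIs between
instruments. Every marker's per-instrument median is aligned onto a chosen
reference instrument the same way. This assumes each center saw the same mix
of subjects; a chi-square heterogeneity check warns when the group
composition differs materially across centers, since the correction is
biased otherwise.

Coefficients are computed per (population, marker) column — lot effects are
antibody-specific, and each MFI column belongs to one population of record.
Frequencies and absolute counts pass through both corrections untouched.
"""

from __future__ import annotations

import datetime as _dt
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (BatchAssignmentError, CorrectionError,
                         PipelineOrderError)


def mfi_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("mfi|")]


# ---------------------------------------------------------------------------
# batch assignment
# ---------------------------------------------------------------------------

def assign_batches(dates, lot_periods, calib_dates=()) -> list[str]:
    """Batch id = (antibody lot, calibration epoch) for each acquisition date.

    ``lot_periods`` is a list of (lot_id, start, end) with half-open
    [start, end) date intervals covering the study; ``calib_dates`` are the
    recalibration dates, each opening a new epoch (a date on the boundary
    belongs to the period starting that day). A date outside every lot
    period is an error naming the offending sample index.
    """
    calib = sorted(calib_dates)
    out = []
    for i, d in enumerate(dates):
        if isinstance(d, str):
            d = _dt.date.fromisoformat(d)
        lot = None
        for lot_id, start, end in lot_periods:
            if start <= d < end:
                lot = lot_id
                break
        if lot is None:
            raise BatchAssignmentError(
                f"sample {i}: acquisition date {d} outside every lot period")
        epoch = sum(1 for c in calib if c <= d)
        out.append(f"{lot}:e{epoch}")
    return out


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

class CorrectionCoefficients:
    """Multiplicative per-column coefficients keyed by batch or instrument.

    ``table`` rows are keys ((instrument, batch) tuples or instrument ids);
    columns are the ``mfi|population|marker`` feature names. The reference
    key's coefficients are exactly 1.
    """

    def __init__(self, scope: str, table: pd.DataFrame, reference_key):
        if scope not in ("batch", "center"):
            raise CorrectionError(f"unknown scope {scope!r}")
        vals = table.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.any(vals[finite] <= 0):
            raise CorrectionError("coefficients must be > 0")
        self.scope = scope
        self.table = table
        self.reference_key = reference_key

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="key")


def _column_medians(sub: pd.DataFrame, cols) -> pd.Series:
    med = sub[cols].median(skipna=True)
    bad = med[med <= 0]
    if len(bad):
        raise CorrectionError(
            f"non-positive median for {list(bad.index)}; MFIs must be > 0 "
            "before correction")
    return med


class BatchMFICorrector(BaseEstimator, TransformerMixin):
    """Align per-batch MFI medians onto each instrument's first batch.

    fit() learns ``coefficients_`` from a cohort table (one row per sample
    with ``instrument_id``, ``batch_id``, ``acquisition_date`` and
    ``mfi|...`` columns); transform() multiplies each sample's MFIs by its
    (instrument, batch) coefficient. ``statistic="mean"`` is available for
    sensitivity analysis, at the cost of the exact-alignment property.
    """

    def __init__(self, statistic: str = "median"):
        self.statistic = statistic

    def _stat(self, sub, cols):
        if self.statistic == "median":
            return _column_medians(sub, cols)
        med = sub[cols].mean(skipna=True)
        if (med <= 0).any():
            raise CorrectionError("non-positive batch mean")
        return med

    def fit(self, table: pd.DataFrame, y=None):
        cols = mfi_columns(table)
        rows = {}
        first_batches = {}
        for inst, sub in table.groupby("instrument_id", sort=True):
            if sub["batch_id"].isna().any():
                raise CorrectionError(f"instrument {inst}: missing batch_id")
            first = sub.loc[sub["acquisition_date"].idxmin(), "batch_id"]
            first_batches[inst] = first
            ref_med = self._stat(sub[sub["batch_id"] == first], cols)
            for batch, bsub in sub.groupby("batch_id", sort=True):
                if len(bsub) == 0:
                    raise CorrectionError(f"empty batch {batch}")
                if batch == first:
                    rows[(inst, batch)] = pd.Series(1.0, index=cols)
                else:
                    rows[(inst, batch)] = ref_med / self._stat(bsub, cols)
        coef = pd.DataFrame(rows).T
        coef.index = pd.MultiIndex.from_tuples(coef.index,
                                               names=["instrument_id",
                                                      "batch_id"])
        self.coefficients_ = CorrectionCoefficients("batch", coef,
                                                    first_batches)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        coef = self.coefficients_.table
        cols = [c for c in coef.columns if c in table.columns]
        out = table.copy()
        for i in out.index:
            key = (out.at[i, "instrument_id"], out.at[i, "batch_id"])
            if key not in coef.index:
                raise CorrectionError(
                    f"no batch coefficient for sample {out.at[i, 'sample_id']}"
                    f" with key {key}")
            out.loc[i, cols] = out.loc[i, cols].to_numpy(dtype=float) \
                * coef.loc[key, cols].to_numpy(dtype=float)
        out.attrs["corrections"] = list(table.attrs.get("corrections", [])) \
            + ["batch"]
        return out


class CenterMFICorrector(BaseEstimator, TransformerMixin):
    """Align per-instrument MFI medians onto a reference instrument.

    Refuses to fit a table that has not been batch-corrected (the pipeline
    order is fixed: batch first, then center), unless
    ``require_batch_corrected=False``.
    """

    def __init__(self, reference_instrument=None, statistic: str = "median",
                 require_batch_corrected: bool = True,
                 heterogeneity_alpha: float = 0.01):
        self.reference_instrument = reference_instrument
        self.statistic = statistic
        self.require_batch_corrected = require_batch_corrected
        self.heterogeneity_alpha = heterogeneity_alpha

    def _stat(self, sub, cols):
        if self.statistic == "median":
            return _column_medians(sub, cols)
        return sub[cols].mean(skipna=True)

    def _check_group_mix(self, table):
        # step 6 assumes all centers saw the same variety of subjects
        if "group" not in table.columns or table["group"].isna().all():
            return
        ct = pd.crosstab(table["instrument_id"], table["group"])
        if ct.shape[0] < 2 or ct.shape[1] < 2 or (ct.to_numpy() == 0).any():
            return
        _, p, _, _ = _st.chi2_contingency(ct)
        if p < self.heterogeneity_alpha:
            warnings.warn(
                "disease-group composition differs across instruments "
                f"(chi-square p={p:.2g}); the inter-instrument median "
                "correction may be biased", stacklevel=2)

    def fit(self, table: pd.DataFrame, y=None):
        if (self.require_batch_corrected
                and "batch" not in table.attrs.get("corrections", [])):
            raise PipelineOrderError(
                "center correction requires a batch-corrected table; run "
                "the batch correction first (or pass "
                "require_batch_corrected=False)")
        self._check_group_mix(table)
        cols = mfi_columns(table)
        instruments = sorted(table["instrument_id"].unique())
        ref = self.reference_instrument or instruments[0]
        if ref not in instruments:
            raise CorrectionError(f"reference instrument {ref!r} has no "
                                  "samples")
        ref_med = self._stat(table[table["instrument_id"] == ref], cols)
        rows = {}
        for inst in instruments:
            if inst == ref:
                rows[inst] = pd.Series(1.0, index=cols)
            else:
                sub = table[table["instrument_id"] == inst]
                if len(sub) == 0:
                    raise CorrectionError(f"instrument {inst}: no samples")
                rows[inst] = ref_med / self._stat(sub, cols)
        self.coefficients_ = CorrectionCoefficients(
            "center", pd.DataFrame(rows).T, ref)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        coef = self.coefficients_.table
        cols = [c for c in coef.columns if c in table.columns]
        out = table.copy()
        for i in out.index:
            key = out.at[i, "instrument_id"]
            if key not in coef.index:
                raise CorrectionError(f"no center coefficient for instrument "
                                      f"{key!r}")
            out.loc[i, cols] = out.loc[i, cols].to_numpy(dtype=float) \
                * coef.loc[key, cols].to_numpy(dtype=float)
        out.attrs["corrections"] = list(table.attrs.get("corrections", [])) \
            + ["center"]
        return out


# ---------------------------------------------------------------------------
# functional wrappers (spec surface)
# ---------------------------------------------------------------------------

def batch_coefficients(table: pd.DataFrame,
                       instrument=None) -> CorrectionCoefficients:
    """Per-(instrument, batch) coefficients; optionally one instrument only."""
    if instrument is not None:
        table = table[table["instrument_id"] == instrument]
        if len(table) == 0:
            raise CorrectionError(f"no samples for instrument {instrument!r}")
    return BatchMFICorrector().fit(table).coefficients_


def center_coefficients(table: pd.DataFrame, reference_instrument,
                        require_batch_corrected: bool = True
                        ) -> CorrectionCoefficients:
    corr = CenterMFICorrector(
        reference_instrument,
        require_batch_corrected=require_batch_corrected)
    return corr.fit(table).coefficients_


def apply_coefficients(table: pd.DataFrame,
                       coeffs: CorrectionCoefficients) -> pd.DataFrame:
    """Multiply each sample's MFI columns by its coefficient row."""
    if coeffs.scope == "batch":
        corr = BatchMFICorrector()
    else:
        corr = CenterMFICorrector()
    corr.coefficients_ = coeffs
    return corr.transform(table)
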