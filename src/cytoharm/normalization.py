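"""Per-channel affine normalization onto the reference bead scale.

Each instrument-day's 8-peak bead acquisition is regressed onto the frozen
reference peaks: per channel, (weighted) least squares finds the (alpha,
beta) minimizing sum_k w_k (alpha * obs_k + beta - ref_k)^2 over the eight
rank-matched peak pairs; the default weights w_k = 1/ref_k^2 make the fit
minimize *relative* residuals, the natural objective when the error being
corrected is a multiplicative gain. Applying ``x -> alpha * x + beta`` to that day's sample events
then puts every instrument, every day, on one common intensity scale — which
is what lets a single set of gating thresholds and one pooled analysis work
across centers.

The regression direction is observed -> reference so the fitted transform can
be applied directly to event data. A fit with alpha <= 0 or R^2 below 0.99
signals a corrupted bead run and is rejected rather than silently accepted.
Scatter channels are left untouched (identity) by default: forward/side
scatter is not bead-calibrated.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bead_qc import PeakSet
from .exceptions import AffineFitError, CytoharmError
from .fcs_io import EventMatrix


@dataclass
class AffineTransform:
    """channel -> (alpha, beta) plus fit diagnostics and provenance."""

    alpha: dict[str, float]
    beta: dict[str, float]
    r2: dict[str, float] = field(default_factory=dict)
    max_residual_pct: dict[str, float] = field(default_factory=dict)
    instrument_id: str | None = None
    date: _dt.date | None = None

    @property
    def channels(self) -> list[str]:
        return list(self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alpha, "beta": self.beta,
            "r2": {c: self.r2.get(c, np.nan) for c in self.alpha},
            "max_residual_pct": {c: self.max_residual_pct.get(c, np.nan)
                                 for c in self.alpha},
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="channel")

    @classmethod
    def from_csv(cls, path, **kw) -> "AffineTransform":
        df = pd.read_csv(path, index_col=0)
        return cls(alpha=df["alpha"].to_dict(), beta=df["beta"].to_dict(),
                   r2=df["r2"].to_dict(), **kw)

    @classmethod
    def identity(cls, channels) -> "AffineTransform":
        return cls({c: 1.0 for c in channels}, {c: 0.0 for c in channels},
                   {c: 1.0 for c in channels})


class AffineNormalizer(BaseEstimator, TransformerMixin):
    """Fit bead-peak OLS transforms and apply them to event data.

    Parameters
    ----------
    r2_min : float, default 0.99
        Minimum per-channel R^2; below this the bead run is rejected.
    weighting : {"inverse_squared", "inverse", "none"}
        Weights for the peak pairs. Bead peaks span ~3 decades, and a gain
        miscalibration is a *relative* error, so the default minimizes
        relative residuals (weights 1/ref^2): with unweighted absolute
        least squares the Poisson-scale noise of the brightest peaks lets
        the intercept wander by more than the dimmest peak's entire MFI.
        "none" gives plain OLS for sensitivity analysis.
    transform_scatter : bool, default False
        Whether FSC/SSC are also transformed (needs scatter channels in the
        bead peaks, which standard rainbow targets do not provide).

    Attributes
    ----------
    transform_ : AffineTransform
        Per-channel (alpha, beta) with R^2 and max residual (% of ref).
    """

    def __init__(self, r2_min=0.99, weighting="inverse_squared",
                 transform_scatter=False):
        self.r2_min = r2_min
        self.weighting = weighting
        self.transform_scatter = transform_scatter

    def _weights(self, y: np.ndarray) -> np.ndarray:
        if self.weighting == "none":
            return np.ones_like(y)
        if self.weighting == "inverse":
            return 1.0 / y
        if self.weighting == "inverse_squared":
            return 1.0 / y ** 2
        raise CytoharmError(f"unknown weighting {self.weighting!r}")

    def fit(self, observed: PeakSet, reference: PeakSet):
        if set(observed.channels) != set(reference.channels):
            raise CytoharmError(
                f"channel mismatch: {sorted(observed.channels)} vs "
                f"{sorted(reference.channels)}")
        if observed.n_peaks != reference.n_peaks:
            raise CytoharmError("peak-count mismatch")
        alpha, beta, r2, maxres = {}, {}, {}, {}
        for ch in reference.channels:
            x = observed.peaks[ch]
            y = reference.peaks[ch]
            w = self._weights(y)
            sw = w.sum()
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            sxx = (w * (x - xm) ** 2).sum()
            sxy = (w * (x - xm) * (y - ym)).sum()
            a = sxy / sxx
            b = ym - a * xm
            fitted = a * x + b
            ss_res = (w * (y - fitted) ** 2).sum()
            ss_tot = (w * (y - ym) ** 2).sum()
            r2c = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            if a <= 0 or r2c < self.r2_min:
                raise AffineFitError(
                    f"channel {ch!r}: invalid bead fit "
                    f"(alpha={a:.4g}, R^2={r2c:.5f}); corrupted bead run?")
            alpha[ch], beta[ch], r2[ch] = float(a), float(b), float(r2c)
            maxres[ch] = float(100.0 * np.abs(y - fitted).max() / y.max())
        self.transform_ = AffineTransform(
            alpha, beta, r2, maxres,
            instrument_id=observed.instrument_id, date=observed.date)
        return self

    def transform(self, em: EventMatrix) -> EventMatrix:
        return apply_affine(em, self.transform_,
                            transform_scatter=self.transform_scatter)


def fit_affine(observed: PeakSet, reference: PeakSet,
               **kw) -> AffineTransform:
    """OLS (alpha, beta) per channel mapping observed peaks onto reference."""
    return AffineNormalizer(**kw).fit(observed, reference).transform_


def apply_affine(em: EventMatrix, t: AffineTransform,
                 transform_scatter: bool = False) -> EventMatrix:
    """Apply ``x -> alpha x + beta`` to every fluorescence channel.

    Scatter channels pass through unless ``transform_scatter``. Negative
    corrected values (possible when beta < 0) are kept, not clipped:
    downstream statistics are means and medians, and clipping would bias
    them. Event count and order are unchanged.
    """
    values = em.values.copy()
    for j, ch in enumerate(em.channel_names):
        if ch in ("FSC", "SSC") and not transform_scatter:
            continue
        if ch not in t.alpha:
            raise CytoharmError(f"no affine transform for channel {ch!r}")
        values[:, j] = t.alpha[ch] * values[:, j] + t.beta[ch]
    out = em.with_values(values)
    out.meta["normalized"] = True
    return out
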