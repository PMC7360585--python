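"""Rainbow 8-peak bead extraction and daily QC.

Rainbow calibration beads contain eight discrete dye levels; a daily bead
acquisition therefore shows eight well-separated log-normal peaks on every
fluorescence detector. Per channel this module debris-filters the events,
clusters the remaining intensities on the log10 scale, and reports each
peak's MFI (arithmetic mean of the *linear* intensities of the cluster's
members, ascending). Daily drift is quantified against the instrument's
frozen internal reference: every peak of every fluorochrome must deviate
by less than 5% for the run to pass.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .exceptions import CytoharmError, PeakDetectionError
from .fcs_io import EventMatrix

QC_DEVIATION_LIMIT = 5.0  # percent; the pass/fail rule for daily bead runs


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Ordered peak MFIs per fluorescence channel (linear scale, ascending)."""

    peaks: dict[str, np.ndarray]
    n_events_used: dict[str, int] = field(default_factory=dict)
    is_reference: bool = False
    instrument_id: str | None = None
    date: _dt.date | None = None

    def __post_init__(self):
        for ch, p in self.peaks.items():
            p = np.asarray(p, dtype=float)
            if np.any(p <= 0):
                raise CytoharmError(f"non-positive peak MFI in {ch!r}")
            if np.any(np.diff(p) <= 0):
                raise CytoharmError(f"peaks not strictly increasing in {ch!r}")
            self.peaks[ch] = p

    @property
    def channels(self) -> list[str]:
        return list(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(next(iter(self.peaks.values())))

    def scaled(self, factors: dict[str, float]) -> "PeakSet":
        return PeakSet({ch: p * factors.get(ch, 1.0)
                        for ch, p in self.peaks.items()},
                       dict(self.n_events_used), self.is_reference,
                       self.instrument_id, self.date)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({ch: p for ch, p in self.peaks.items()},
                            index=[f"peak{i + 1}"
                                   for i in range(self.n_peaks)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="peak")

    @classmethod
    def from_csv(cls, path, **kw) -> "PeakSet":
        df = pd.read_csv(path, index_col=0)
        return cls({ch: df[ch].to_numpy(dtype=float) for ch in df.columns},
                   **kw)


@dataclass
class QCReport:
    """Per-peak percent deviation from reference, and the overall verdict."""

    deviations: pd.DataFrame      # rows = peaks, columns = channels, in %
    passed: bool
    limit: float = QC_DEVIATION_LIMIT

    def worst(self) -> float:
        return float(self.deviations.to_numpy().max())


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

class BeadPeakDetector(BaseEstimator):
    """Extract the 8 bead-peak MFIs per fluorescence channel.

    Events are first debris-gated on scatter (debris sits low on FSC), then
    each fluorescence channel is clustered with 1-D k-means on log10
    intensity. K-means is a deliberate choice: the peaks are well-separated
    log-normal modes, so quantile-spaced initialization plus a few seeded
    restarts is deterministic in practice and dependency-free. A channel
    whose clusters are not all populated (>= ``min_occupancy`` of events) and
    cleanly separated (>= ``min_separation`` decades between consecutive
    peak means) fails with a :class:`PeakDetectionError`.

    Parameters
    ----------
    n_peaks : int, default 8
    statistic : "mean" or "median"
        Peak MFI statistic on the linear scale; the arithmetic mean matches
        how bead targets are conventionally reported.
    debris_fsc_quantile : float, default 0.02
        Events below this FSC quantile are dropped, in addition to the
        fixed low-scatter ``debris_box`` (FSC max, SSC max).
    """

    MIN_EVENTS_PER_PEAK = 50

    def __init__(self, n_peaks=8, statistic="mean", n_restarts=10,
                 random_state=0, min_occupancy=0.01, min_separation=0.15,
                 debris_fsc_quantile=0.02, debris_box=(10 ** 3.55, 10 ** 3.55),
                 debris_warn_fraction=0.5):
        self.n_peaks = n_peaks
        self.statistic = statistic
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.min_occupancy = min_occupancy
        self.min_separation = min_separation
        self.debris_fsc_quantile = debris_fsc_quantile
        self.debris_box = debris_box
        self.debris_warn_fraction = debris_warn_fraction

    # -- internals ----------------------------------------------------------

    def _debris_mask(self, em: EventMatrix) -> np.ndarray:
        """True for events to keep."""
        fsc = em.column("FSC")
        keep = fsc >= np.quantile(fsc, self.debris_fsc_quantile)
        if self.debris_box is not None and "SSC" in em.channel_names:
            fmax, smax = self.debris_box
            keep &= ~((fsc < fmax) & (em.column("SSC") < smax))
        return keep

    def _cluster_channel(self, ch: str, x: np.ndarray) -> np.ndarray:
        k = self.n_peaks
        logx = np.log10(np.clip(x, 1e-6, None)).reshape(-1, 1)
        qs = (np.arange(k) + 0.5) / k
        init = np.quantile(logx, qs).reshape(-1, 1)
        best = KMeans(n_clusters=k, init=init, n_init=1).fit(logx)
        if self.n_restarts > 1:
            alt = KMeans(n_clusters=k, n_init=self.n_restarts - 1,
                         random_state=self.random_state).fit(logx)
            if alt.inertia_ < best.inertia_:
                best = alt
        lab = best.labels_
        counts = np.bincount(lab, minlength=k)
        if counts.min() < max(1, self.min_occupancy * len(x)):
            raise PeakDetectionError(
                f"channel {ch!r}: only {int((counts >= max(1, self.min_occupancy * len(x))).sum())} of "
                f"{k} peak clusters are populated")
        stat = np.mean if self.statistic == "mean" else np.median
        mfis = np.array([stat(x[lab == j]) for j in range(k)])
        order = np.argsort(mfis)
        mfis = mfis[order]
        log_means = np.array([logx[lab == j].mean() for j in range(k)])[order]
        if np.any(np.diff(log_means) < self.min_separation):
            raise PeakDetectionError(
                f"channel {ch!r}: fewer than {k} resolvable peaks "
                "(adjacent cluster means too close)")
        return mfis

    # -- estimator API ------------------------------------------------------

    def fit(self, em: EventMatrix, y=None):
        if em.n_events < self.MIN_EVENTS_PER_PEAK * self.n_peaks:
            raise PeakDetectionError(
                f"bead file has {em.n_events} events; need at least "
                f"{self.MIN_EVENTS_PER_PEAK * self.n_peaks}")
        keep = self._debris_mask(em)
        self.debris_fraction_ = 1.0 - keep.mean()
        self.debris_contaminated_ = (self.debris_fraction_
                                     > self.debris_warn_fraction)
        fluo = [c for c in em.channel_names if c not in ("FSC", "SSC")]
        peaks = {}
        used = {}
        for ch in fluo:
            x = em.column(ch)[keep]
            peaks[ch] = self._cluster_channel(ch, x)
            used[ch] = int(keep.sum())
        self.peaks_ = PeakSet(peaks, used,
                              instrument_id=em.meta.get("instrument_id"),
                              date=em.meta.get("acquisition_date"))
        return self


def detect_peaks(em: EventMatrix, n_peaks: int = 8, **kw) -> PeakSet:
    """Functional wrapper around :class:`BeadPeakDetector`."""
    return BeadPeakDetector(n_peaks=n_peaks, **kw).fit(em).peaks_


# ---------------------------------------------------------------------------
# QC deviation
# ---------------------------------------------------------------------------

def qc_deviation(obs: PeakSet, ref: PeakSet,
                 limit: float = QC_DEVIATION_LIMIT) -> QCReport:
    """Percent deviation of observed peak MFIs from the internal reference.

    Peaks are matched by rank (ascending), never by nearest value: gain
    drift preserves peak order, so rank matching is robust to the very
    shifts the QC is meant to catch. Pass iff every deviation < ``limit``.
    """
    if set(obs.channels) != set(ref.channels):
        raise CytoharmError(
            f"channel mismatch: observed {sorted(obs.channels)} vs "
            f"reference {sorted(ref.channels)}")
    if obs.n_peaks != ref.n_peaks:
        raise CytoharmError("peak-count mismatch between observed and "
                            "reference")
    dev = {}
    for ch in ref.channels:
        dev[ch] = 100.0 * np.abs(obs.peaks[ch] - ref.peaks[ch]) / ref.peaks[ch]
    frame = pd.DataFrame(dev, index=[f"peak{i + 1}"
                                     for i in range(ref.n_peaks)])
    return QCReport(frame, bool((frame.to_numpy() < limit).all()), limit)
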