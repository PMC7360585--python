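"""Harmonization diagnostics: CVs, PCA center-effect score, median tests.

The coefficient of variation (100 * SD / mean, sample SD) is the workhorse
quality metric throughout the workflow. The PCA diagnostic mirrors the usual
before/after picture of a multicenter harmonization: project the cohort
feature table (frequencies or MFIs) onto its first two principal components
and score how much of the variance in that plane separates centers. The
median-equality check uses Kruskal–Wallis across instruments — the quantity
the corrections align is a median, so a rank test on it is the natural
convention (the choice of test is ours, and documented as such).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .exceptions import CytoharmError
from .mfi_correction import mfi_columns


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise CytoharmError("cv needs at least 2 values")
    m = x.mean()
    if m <= 0:
        raise CytoharmError("cv undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x PCs, center_id column kept
    explained_variance_ratio: np.ndarray
    separability: float               # between-center variance share, PC1-2
    dropped_features: list


def center_effect_pca(table: pd.DataFrame, feature_set: str = "mfi",
                      n_components: int = 2) -> PCAResult:
    """PCA of z-scored cohort features with a center-separability score.

    feature_set selects ``mfi|...`` or ``freq|...`` columns. Features are
    z-scored, decomposed by SVD, and each component's sign is fixed so its
    largest-magnitude loading is positive (determinism up to that rule).
    Constant features are dropped with a warning. The separability score is
    the between-center share of total variance of the first ``n_components``
    scores: 0 when centers overlap completely, approaching 1 when the plane
    is pure center effect.
    """
    if feature_set in ("mfi", "MFIs"):
        cols = mfi_columns(table)
    elif feature_set in ("freq", "frequencies"):
        cols = [c for c in table.columns if c.startswith("freq|")]
    else:
        raise CytoharmError(f"unknown feature set {feature_set!r}")
    centers = table["instrument_id"] if "instrument_id" in table.columns \
        else table["center_id"]
    counts = centers.value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise CytoharmError("need >= 2 centers with >= 3 samples each")

    x = table[cols].to_numpy(dtype=float)
    keep = np.ones(len(cols), dtype=bool)
    for j in range(len(cols)):
        col = x[:, j]
        if not np.isfinite(col).all() or np.nanstd(col) < 1e-12:
            keep[j] = False
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant/non-finite "
                      f"feature(s): {dropped[:5]}...", stacklevel=2)
    x = x[:, keep]
    if x.shape[1] == 0:
        raise CytoharmError("no usable features")

    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    evr = (s ** 2) / (s ** 2).sum()

    k = min(n_components, scores.shape[1])
    sk = scores[:, :k]
    total = (sk ** 2).sum()
    between = 0.0
    for c in counts.index:
        grp = sk[(centers == c).to_numpy()]
        between += len(grp) * (grp.mean(axis=0) ** 2).sum()
    sep = float(between / total) if total > 0 else 0.0

    ncols = min(max(k, 2), scores.shape[1])
    sdf = pd.DataFrame(scores[:, :ncols],
                       columns=[f"PC{j + 1}" for j in range(ncols)],
                       index=table.index)
    sdf.insert(0, "center", centers.to_numpy())
    return PCAResult(sdf, evr, sep, dropped)


def median_equality_test(table: pd.DataFrame, markers=None,
                         min_per_group: int = 3) -> pd.Series:
    """Kruskal–Wallis p-value per MFI column across instruments.

    Columns without >= 2 instruments of >= ``min_per_group`` samples are
    returned as NaN (not computed) rather than raising.
    """
    cols = markers if markers is not None else mfi_columns(table)
    out = {}
    for col in cols:
        groups = []
        for _, sub in table.groupby("instrument_id"):
            vals = sub[col].dropna().to_numpy(dtype=float)
            if len(vals) >= min_per_group:
                groups.append(vals)
        if len(groups) < 2:
            out[col] = np.nan
            continue
        try:
            out[col] = float(_st.kruskal(*groups).pvalue)
        except ValueError:   # all values identical
            out[col] = 1.0
    return pd.Series(out, name="kruskal_p")
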