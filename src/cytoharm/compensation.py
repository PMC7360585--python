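"""Spillover compensation and a residual-spill diagnostic.

A fluorochrome's emission bleeds into neighbouring detectors. With the
row-vector convention, ``observed = true @ S`` where the spillover matrix S
has unit diagonal and entry (i, j) = fraction of channel-i signal measured in
channel j; compensation is ``compensated = observed @ inv(S)``.

The study workflow verifies and, where needed, adjusts matrices by eye. Here
adjustment stays an explicit, logged config override (no automatic matrix
re-estimation — that would hide provenance), and :func:`residual_spill`
quantifies what an operator judges visually: the slope of the secondary
channel's median against the primary's between bright and dim events. A
well-compensated file has slope ~ 0; an under-compensated one keeps a
positive slope roughly equal to the missing spill fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CompensationError
from .fcs_io import EventMatrix


@dataclass
class SpilloverMatrix:
    """Square spillover matrix with its channel order.

    Invariants enforced at construction: unit diagonal, off-diagonal in
    [0, 1), condition number below ``max_condition``.
    """

    matrix: np.ndarray
    channels: list[str]
    max_condition: float = 1e6

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise CompensationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} channels")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise CompensationError("spillover diagonal must be 1")
        off = self.matrix[~np.eye(n, dtype=bool)]
        if np.any((off < 0) | (off >= 1)):
            raise CompensationError("off-diagonal spillover must be in [0,1)")
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise CompensationError(
                f"spillover matrix ill-conditioned (cond={cond:.3g})")

    @classmethod
    def identity(cls, channels) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), list(channels))

    def with_overrides(self, overrides: dict) -> "SpilloverMatrix":
        """Explicit (source, target) -> value entry overrides, logged by CLI."""
        m = self.matrix.copy()
        idx = {c: i for i, c in enumerate(self.channels)}
        for (src, dst), v in overrides.items():
            m[idx[src], idx[dst]] = v
        return SpilloverMatrix(m, list(self.channels), self.max_condition)

    def to_keyword(self) -> str:
        """Serialize in the FCS $SPILLOVER convention."""
        vals = ",".join(f"{v:.6g}" for v in self.matrix.ravel())
        return f"{len(self.channels)},{','.join(self.channels)},{vals}"

    @classmethod
    def from_keyword(cls, text: str) -> "SpilloverMatrix":
        parts = [p.strip() for p in text.split(",")]
        n = int(parts[0])
        channels = parts[1:1 + n]
        vals = np.array([float(v) for v in parts[1 + n:1 + n + n * n]])
        if vals.size != n * n:
            raise CompensationError("malformed $SPILLOVER keyword")
        return cls(vals.reshape(n, n), channels)


def spillover_from_meta(em: EventMatrix) -> SpilloverMatrix | None:
    """Spillover stored in the file's $SPILLOVER/$COMP keyword, if any."""
    kw = em.meta.get("keywords", {})
    text = kw.get("$SPILLOVER") or kw.get("$COMP")
    return SpilloverMatrix.from_keyword(text) if text else None


class SpilloverCompensator:
    """Apply ``observed @ inv(S)`` to the fluorescence channels.

    If ``spillover`` is None, :meth:`fit` resolves it from the event
    matrix's own $SPILLOVER keyword (keyword takes precedence over config
    by convention — it travels with the file).
    """

    def __init__(self, spillover: SpilloverMatrix | None = None):
        self.spillover = spillover

    def get_params(self, deep=True):
        return {"spillover": self.spillover}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, em: EventMatrix | None = None, y=None):
        s = self.spillover
        if s is None and em is not None:
            s = spillover_from_meta(em)
        if s is None:
            raise CompensationError(
                "no spillover matrix: none configured and the file carries "
                "no $SPILLOVER keyword")
        self.spillover_ = s
        self.inverse_ = np.linalg.inv(s.matrix)
        return self

    def transform(self, em: EventMatrix) -> EventMatrix:
        if not hasattr(self, "spillover_"):
            self.fit(em)
        s = self.spillover_
        idx = []
        for ch in s.channels:
            if ch not in em.channel_names:
                raise CompensationError(
                    f"spillover channel {ch!r} missing from event matrix")
            idx.append(em.channel_names.index(ch))
        values = em.values.copy()
        values[:, idx] = values[:, idx] @ self.inverse_
        out = em.with_values(values)
        out.meta["compensated"] = True
        return out


def apply_compensation(em: EventMatrix,
                       s: SpilloverMatrix | None = None) -> EventMatrix:
    """Compensate; S from argument or the file's $SPILLOVER keyword."""
    return SpilloverCompensator(s).fit(em).transform(em)


def residual_spill(em: EventMatrix, primary: str, secondary: str,
                   positives: np.ndarray, min_positives: int = 50):
    """Residual-spill slope between bright and dim groups.

    ``positives`` masks events bright in the primary channel; the remaining
    events form the dim group. Returns

        slope = (median_sec_bright - median_sec_dim)
                / (median_pri_bright - median_pri_dim)

    or None (inconclusive, not an error) when fewer than ``min_positives``
    bright events are available. |slope| near 0 indicates adequate
    compensation; an under-compensation of 5 points leaves slope ~ +0.05.
    """
    positives = np.asarray(positives, dtype=bool)
    if positives.sum() < min_positives or (~positives).sum() < min_positives:
        return None
    pri = em.column(primary)
    sec = em.column(secondary)
    dp = np.median(pri[positives]) - np.median(pri[~positives])
    ds = np.median(sec[positives]) - np.median(sec[~positives])
    if dp <= 0:
        return None
    return float(ds / dp)
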