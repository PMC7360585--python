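"""Scaled replications of the workflow's validation experiments.

Three self-contained experiments quantify how well bead-anchored affine
normalization removes instrument gain effects:

1. :func:`bead_normalization_cv` — deliberately mis-set detector gains by
   10-15% per channel (the software analogue of detuning PMT voltages),
   re-acquire the 8-peak beads, normalize, and report the worst CV between
   each reference peak MFI and its corrected counterpart.
2. :func:`sample_normalization_cv` — propagate the same perturbation to a
   stained sample (identical cell-level draws), normalize with bead-derived
   transforms, gate both versions, and report the worst CV over matched
   population-marker MFI pairs.
3. :func:`multi_instrument_cv` — render one identical sample through many
   instruments with gains in [0.8, 1.25], normalize each against the common
   reference targets, and report the worst inter-instrument CV of any
   population-marker MFI.

Each experiment isolates normalization: no antibody-lot effects, spillover,
or day drift are simulated, so the residual CV measures peak-estimation
noise plus affine-fit error only.
"""

from __future__ import annotations

import datetime as _dt
import numpy as np

from .bead_qc import detect_peaks
from .gating import ThresholdGater, cohort_row
from .metrics import cv
from .normalization import AffineNormalizer
from .synthetic import SimulationConfig, draw_true_sample, render_sample, \
    simulate_beads

_D0 = _dt.date(2015, 1, 1)
_D1 = _dt.date(2015, 1, 2)


def _clean_config(seed: int, **kw) -> SimulationConfig:
    base = dict(seed=seed, daily_drift_sd=0.0, with_spillover=False,
                residual_center_effect_range=(1.0, 1.0),
                sample_debris_fraction=0.03)
    base.update(kw)
    return SimulationConfig(**base)


def _unity(cfg):
    return {m: 1.0 for m in cfg.panel.markers}


def _pair_cv(a: float, b: float) -> float:
    return cv([a, b])


def bead_normalization_cv(seed: int = 0,
                          gain_range: tuple = (1.10, 1.15)) -> float:
    """Worst CV between reference and gain-perturbed-then-corrected peaks.

    ~500 events per peak; per-channel gain factors drawn uniformly in
    ``gain_range``. Returns the maximum CV (%) over all channels and peaks.
    """
    cfg = _clean_config(seed)
    ref_em = simulate_beads(cfg, "INST01", _D0, gain=_unity(cfg), drift=1.0)
    ref_peaks = detect_peaks(ref_em)

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 101])
    gains = {m: float(rng.uniform(*gain_range)) for m in cfg.panel.markers}
    pert_em = simulate_beads(cfg, "INST01", _D1, gain=gains, drift=1.0)
    norm = AffineNormalizer().fit(detect_peaks(pert_em), ref_peaks)
    corr_peaks = detect_peaks(norm.transform(pert_em))

    worst = 0.0
    for ch in ref_peaks.channels:
        for r, c in zip(ref_peaks.peaks[ch], corr_peaks.peaks[ch]):
            worst = max(worst, _pair_cv(r, c))
    return worst


def sample_normalization_cv(seed: int = 0,
                            gain_range: tuple = (1.10, 1.15),
                            events: int = 10_000) -> float:
    """Worst CV between unperturbed and corrected population marker MFIs.

    One stained sample is drawn once and rendered twice: untouched, and
    through a 10-15% per-channel gain perturbation. The perturbed version
    is normalized with transforms fitted on matching perturbed bead data;
    both are threshold-gated and every (population, marker) MFI pair is
    compared. Returns the maximum CV (%).
    """
    cfg = _clean_config(seed, events_per_sample=events)
    panel = cfg.panel
    true_em, _ = draw_true_sample(cfg, f"t2-{seed}", "healthy")

    unity = _unity(cfg)
    base = render_sample(cfg, true_em, "INST01", _D0, gain=unity, drift=1.0,
                         lot=unity, residual=unity, with_spillover=False)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 202])
    gains = {m: float(rng.uniform(*gain_range)) for m in panel.markers}
    pert = render_sample(cfg, true_em, "INST01", _D0, gain=gains, drift=1.0,
                         lot=unity, residual=unity, with_spillover=False)

    ref_peaks = detect_peaks(simulate_beads(cfg, "INST01", _D0,
                                            gain=unity, drift=1.0))
    pert_beads = simulate_beads(cfg, "INST01", _D1, gain=gains, drift=1.0)
    norm = AffineNormalizer().fit(detect_peaks(pert_beads), ref_peaks)
    corrected = norm.transform(pert)

    gater = ThresholdGater(panel.populations, panel.thresholds).fit()
    row_base = cohort_row(base, gater.predict(base), panel.populations)
    row_corr = cohort_row(corrected, gater.predict(corrected),
                          panel.populations)

    worst = 0.0
    for col in row_base.index:
        if not col.startswith("mfi|"):
            continue
        a, b = row_base[col], row_corr[col]
        if np.isfinite(a) and np.isfinite(b):
            worst = max(worst, _pair_cv(a, b))
    return worst


def multi_instrument_cv(seed: int = 0, n_instruments: int = 11,
                        gain_range: tuple = (0.8, 1.25),
                        events: int = 10_000) -> float:
    """Worst inter-instrument CV of population marker MFIs after
    normalization.

    One identical underlying sample (shared cell-level draws) is rendered
    through ``n_instruments`` instruments whose per-channel gains are drawn
    in ``gain_range``; each instrument is normalized to the common
    reference targets via its own simulated bead file, then gated. Returns
    the maximum CV (%) of any (population, marker) MFI across instruments.
    """
    cfg = _clean_config(seed, events_per_sample=events,
                        n_centers=n_instruments)
    panel = cfg.panel
    true_em, _ = draw_true_sample(cfg, f"t3-{seed}", "healthy")
    unity = _unity(cfg)
    ref_peaks = detect_peaks(simulate_beads(cfg, "REF", _D0,
                                            gain=unity, drift=1.0))
    gater = ThresholdGater(panel.populations, panel.thresholds).fit()

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 303])
    rows = []
    for i in range(n_instruments):
        inst = f"INST{i + 1:02d}"
        gains = {m: float(rng.uniform(*gain_range)) for m in panel.markers}
        date = _D0 + _dt.timedelta(days=i + 1)
        em = render_sample(cfg, true_em, inst, date, gain=gains, drift=1.0,
                           lot=unity, residual=unity, with_spillover=False)
        beads = simulate_beads(cfg, inst, date, gain=gains, drift=1.0)
        norm = AffineNormalizer().fit(detect_peaks(beads), ref_peaks)
        em = norm.transform(em)
        rows.append(cohort_row(em, gater.predict(em), panel.populations))

    worst = 0.0
    for col in rows[0].index:
        if not col.startswith("mfi|"):
            continue
        vals = np.array([r[col] for r in rows], dtype=float)
        if np.isfinite(vals).all():
            worst = max(worst, cv(vals))
    return worst
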