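"""Synthetic bead files and multi-center stained cohorts with ground truth.

The generator emulates the structure of a prospective multicenter
immunophenotyping study at desk scale: several centers, each with one
cytometer whose per-channel detector gains differ from the reference
instrument; daily 8-peak rainbow bead acquisitions tracking each
instrument-day's gain; stained samples drawn from a log-normal population
mixture (log-normal marker distributions are the standard model for
cytometry intensities); dried-antibody lots whose changeovers shift marker
MFIs multiplicatively; instrument recalibration dates splitting lots into
batches; counting beads spiked at known concentration; and a configurable
disease effect (a CD19 MFI shift in one group by default) whose persistence
through the corrections is the biology-preservation check.

Every stochastic draw is keyed off ``cfg.seed`` plus stable string keys, so
identical configs reproduce identical cohorts bit for bit.

The rendering chain for a cell event, per fluorescence channel::

    true (reference scale) -> x lot effect -> spillover -> x gain x day drift

Bead events skip the lot effect (no antibodies) and spillover (the reference
peak template is defined as-measured), so bead-fitted affine transforms
recover exactly the gain-and-drift factor that contaminates samples:
fitted alpha ~ 1/(gain * drift).
"""

from __future__ import annotations

import datetime as _dt
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bead_qc import PeakSet
from .exceptions import CytoharmError
from .fcs_io import EventMatrix, write_fcs, write_lmd
from .panels import SCATTER_TEMPLATES, get_panel


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-scale knobs; defaults emulate the full study at reduced depth.

    Eleven centers/instruments, three antibody lots, seven recalibration
    epochs over a four-year inclusion window. Event depth (~10^4 per
    sample) and cohort width (tens of samples per center) are desk-scale
    stand-ins for the real cohort.
    """

    seed: int = 0
    panel_id: str = "panel1"
    n_centers: int = 11
    n_samples_per_center: int = 24
    events_per_sample: int = 10_000
    bead_events_per_peak: int = 500
    bead_debris_fraction: float = 0.05
    sample_debris_fraction: float = 0.03
    study_start: _dt.date = _dt.date(2014, 12, 1)
    study_end: _dt.date = _dt.date(2018, 12, 1)
    n_lots: int = 3
    n_recalibrations: int = 7
    fluor_gain_range: tuple = (0.8, 1.25)
    scatter_gain_range: tuple = (1.0, 1.0)
    daily_drift_sd: float = 0.02          # log-scale SD of day-to-day gain
    #: optical-bench/fluorochrome interaction per (instrument, marker):
    #: multiplies sample marker signal but not bead signal, so it survives
    #: bead normalization and is what the MFI corrections must remove
    residual_center_effect_range: tuple = (0.85, 1.18)
    lot_effect_range: tuple = (0.75, 1.3)
    groups: tuple = ("healthy", "disease")
    group_mix: tuple = (0.5, 0.5)
    #: group -> [(population, marker, fold-change), ...]
    disease_effects: dict = field(default_factory=lambda: {
        "disease": [("B cells", "CD19", 1.5)]})
    beads_per_ul: float = 1000.0
    cells_per_ul: tuple = (6000.0, 800.0)  # mean, SD of true concentration
    with_spillover: bool = True
    bead_peak_log10: tuple = (1.3, 4.8)    # span of the 8 log-spaced peaks
    bead_sigma_log10: float = 0.04
    reference_gain_one: bool = True        # first instrument is the reference

    @classmethod
    def small(cls, **kw) -> "SimulationConfig":
        """Desk-test preset: 3 centers x 12 samples, 1 simulated year."""
        base = dict(n_centers=3, n_samples_per_center=12,
                    events_per_sample=4000, bead_events_per_peak=300,
                    study_start=_dt.date(2015, 1, 1),
                    study_end=_dt.date(2015, 12, 31),
                    n_recalibrations=2)
        base.update(kw)
        return cls(**base)

    def validate(self):
        weights = self.population_weights()
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise CytoharmError("population mixture weights must sum to 1")
        if min(self.fluor_gain_range) <= 0 or min(self.scatter_gain_range) <= 0:
            raise CytoharmError("gains must be positive")
        if self.study_end <= self.study_start:
            raise CytoharmError("study_end must be after study_start")

    # -- derived structure --------------------------------------------------

    @property
    def panel(self):
        return get_panel(self.panel_id)

    def population_weights(self) -> dict:
        pops = self.panel.templates["populations"]
        return {name: t["weight"] for name, t in pops.items()}

    def instruments(self) -> list[str]:
        return [f"INST{i + 1:02d}" for i in range(self.n_centers)]

    def centers(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_centers)]

    def vendor_of(self, instrument: str) -> str:
        # alternate vendors across centers so both dialects are exercised
        try:
            i = self.instruments().index(instrument)
        except ValueError:
            return "BC"
        return "BC" if i % 2 == 0 else "BD"

    def lot_periods(self) -> list[tuple]:
        total = (self.study_end - self.study_start).days + 1
        bounds = [self.study_start + _dt.timedelta(days=round(total * k
                                                              / self.n_lots))
                  for k in range(self.n_lots + 1)]
        bounds[-1] = self.study_end + _dt.timedelta(days=1)
        return [(f"lot{k + 1}", bounds[k], bounds[k + 1])
                for k in range(self.n_lots)]

    def calibration_dates(self) -> list[_dt.date]:
        total = (self.study_end - self.study_start).days
        return [self.study_start
                + _dt.timedelta(days=round(total * (k + 1)
                                           / (self.n_recalibrations + 1)))
                for k in range(self.n_recalibrations)]


def _rng(seed: int, *keys) -> np.random.Generator:
    tail = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tail])


# ---------------------------------------------------------------------------
# ground-truth parameters
# ---------------------------------------------------------------------------

def instrument_gains(cfg: SimulationConfig, instrument: str) -> dict:
    """Per-fluorescence-channel base gain of one instrument (frozen)."""
    markers = cfg.panel.markers
    if cfg.reference_gain_one and instrument == cfg.instruments()[0]:
        return {m: 1.0 for m in markers}
    rng = _rng(cfg.seed, "gain", instrument)
    lo, hi = cfg.fluor_gain_range
    return {m: float(rng.uniform(lo, hi)) for m in markers}


def instrument_scatter_gain(cfg: SimulationConfig, instrument: str) -> float:
    if cfg.scatter_gain_range == (1.0, 1.0):
        return 1.0
    if cfg.reference_gain_one and instrument == cfg.instruments()[0]:
        return 1.0
    rng = _rng(cfg.seed, "scatter-gain", instrument)
    return float(rng.uniform(*cfg.scatter_gain_range))


def residual_center_effects(cfg: SimulationConfig, instrument: str) -> dict:
    """Marker-specific optical-bench factor of one instrument.

    Rainbow beads and antibody-stained cells do not share fluorochrome
    spectra exactly, so part of an instrument's response is invisible to
    bead calibration; this factor models that residue. Reference
    instrument = 1.
    """
    markers = cfg.panel.markers
    if (cfg.residual_center_effect_range == (1.0, 1.0)
            or (cfg.reference_gain_one
                and instrument == cfg.instruments()[0])):
        return {m: 1.0 for m in markers}
    rng = _rng(cfg.seed, "residual", instrument)
    lo, hi = cfg.residual_center_effect_range
    return {m: float(rng.uniform(lo, hi)) for m in markers}


def day_drift(cfg: SimulationConfig, instrument: str, date: _dt.date) -> float:
    """Multiplicative day-to-day drift shared by that day's beads and samples."""
    if cfg.daily_drift_sd <= 0:
        return 1.0
    rng = _rng(cfg.seed, "drift", instrument, date.isoformat())
    return float(np.exp(rng.normal(0.0, cfg.daily_drift_sd)))


def lot_effects(cfg: SimulationConfig, lot_id: str) -> dict:
    """Per-marker multiplicative staining effect of one antibody lot."""
    markers = cfg.panel.markers
    if lot_id == "lot1":
        return {m: 1.0 for m in markers}
    rng = _rng(cfg.seed, "lot", lot_id)
    lo, hi = cfg.lot_effect_range
    return {m: float(rng.uniform(lo, hi)) for m in markers}


def lot_of_date(cfg: SimulationConfig, date: _dt.date) -> str:
    for lot_id, start, end in cfg.lot_periods():
        if start <= date < end:
            return lot_id
    raise CytoharmError(f"date {date} outside the study period")


def bead_peak_template(cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.bead_peak_log10
    return np.linspace(lo, hi, 8)


def reference_peaks(cfg: SimulationConfig) -> PeakSet:
    """Theoretical reference targets: the mean of each log-normal peak."""
    locs = bead_peak_template(cfg)
    s = cfg.bead_sigma_log10 * np.log(10.0)
    means = 10.0 ** locs * np.exp(s ** 2 / 2.0)
    return PeakSet({m: means.copy() for m in cfg.panel.markers},
                   is_reference=True)


# ---------------------------------------------------------------------------
# bead acquisitions
# ---------------------------------------------------------------------------

def simulate_beads(cfg: SimulationConfig, instrument: str, date: _dt.date,
                   gain: dict | None = None, drift: float | None = None
                   ) -> EventMatrix:
    """One rainbow 8-peak bead acquisition on one instrument-day.

    Eight log-normal clusters per fluorescence channel (every bead is bright
    on every detector at its dye level) scaled by the instrument's current
    gain, plus a low-scatter debris cluster.
    """
    cfg.validate()
    panel = cfg.panel
    markers = panel.markers
    gain = gain if gain is not None else instrument_gains(cfg, instrument)
    drift = drift if drift is not None else day_drift(cfg, instrument, date)
    rng = _rng(cfg.seed, "beads", instrument, date.isoformat())

    locs = bead_peak_template(cfg)
    n_per = cfg.bead_events_per_peak
    n_beads = 8 * n_per
    n_debris = int(round(cfg.bead_debris_fraction * n_beads
                         / max(1e-9, 1 - cfg.bead_debris_fraction)))

    peak_idx = np.repeat(np.arange(8), n_per)
    cols = {}
    # beads sit in one tight mid-scatter cluster
    cols["FSC"] = 10 ** rng.normal(4.6, 0.03, n_beads)
    cols["SSC"] = 10 ** rng.normal(4.4, 0.03, n_beads)
    for m in markers:
        log_i = rng.normal(locs[peak_idx], cfg.bead_sigma_log10)
        cols[m] = 10 ** log_i * gain[m] * drift

    if n_debris:
        dfm, dfs, dsm, dss = SCATTER_TEMPLATES["debris"]
        cols["FSC"] = np.concatenate([cols["FSC"],
                                      10 ** rng.normal(dfm, dfs, n_debris)])
        cols["SSC"] = np.concatenate([cols["SSC"],
                                      10 ** rng.normal(dsm, dss, n_debris)])
        for m in markers:
            deb = 10 ** rng.normal(1.5, 0.2, n_debris) * gain[m] * drift
            cols[m] = np.concatenate([cols[m], deb])

    names = ["FSC", "SSC", *markers]
    values = np.column_stack([cols[c] for c in names])
    meta = {"instrument_id": instrument, "acquisition_date": date,
            "panel_id": "beads", "vendor": cfg.vendor_of(instrument)}
    return EventMatrix(values, names, meta)


# ---------------------------------------------------------------------------
# stained samples
# ---------------------------------------------------------------------------

@dataclass
class SampleTruth:
    sample_id: str
    group: str
    fractions: dict
    concentration: float
    n_cell_events: int
    n_bead_events: int
    labels: np.ndarray | None = None


def draw_true_sample(cfg: SimulationConfig, sample_id: str, group: str
                     ) -> tuple[EventMatrix, SampleTruth]:
    """Cell-level draws on the reference scale, before any instrument effect.

    Returns the true event matrix (cells + debris + counting beads) and the
    per-sample ground truth. Rendering the same true sample through several
    instruments shares these draws.
    """
    cfg.validate()
    panel = cfg.panel
    markers = panel.markers
    tpl = panel.templates
    rng = _rng(cfg.seed, "sample", sample_id)

    pop_names = list(tpl["populations"])
    weights = np.array([tpl["populations"][p]["weight"] for p in pop_names])
    w_full = np.append(weights * (1 - cfg.sample_debris_fraction),
                       cfg.sample_debris_fraction)
    counts = rng.multinomial(cfg.events_per_sample, w_full)

    effects = {(p, m): f for (p, m, f)
               in cfg.disease_effects.get(group, [])}

    blocks, labels = [], []
    sigma = tpl["sigma_log10"]
    base = tpl["baseline_log10"]
    for name, n in zip(pop_names + ["debris"], counts):
        if n == 0:
            continue
        if name == "debris":
            fm, fs, sm, ss = SCATTER_TEMPLATES["debris"]
            mk_locs = {m: 1.5 for m in markers}
            mk_sigma = 0.2
        else:
            t = tpl["populations"][name]
            fm, fs, sm, ss = SCATTER_TEMPLATES[t["scatter"]]
            mk_locs = {m: t["markers"].get(m, base) for m in markers}
            for m in markers:
                if (name, m) in effects:
                    mk_locs[m] += np.log10(effects[(name, m)])
            mk_sigma = sigma
        cols = [10 ** rng.normal(fm, fs, n), 10 ** rng.normal(sm, ss, n)]
        for m in markers:
            cols.append(10 ** rng.normal(mk_locs[m], mk_sigma, n))
        blocks.append(np.column_stack(cols))
        labels.extend([name] * n)

    n_cells = int(counts[:-1].sum())
    conc = float(np.clip(rng.normal(*cfg.cells_per_ul), 500.0, None))
    n_beads = int(rng.poisson(n_cells * cfg.beads_per_ul / conc))
    if n_beads:
        fm, fs, sm, ss = SCATTER_TEMPLATES["beads"]
        cols = [10 ** rng.normal(fm, fs, n_beads),
                10 ** rng.normal(sm, ss, n_beads)]
        for m in markers:
            cols.append(10 ** rng.normal(4.6, 0.05, n_beads))
        blocks.append(np.column_stack(cols))
        labels.extend(["beads"] * n_beads)

    values = np.vstack(blocks)
    labels = np.array(labels, dtype=object)
    # shuffle so event order carries no information
    perm = rng.permutation(len(labels))
    values, labels = values[perm], labels[perm]

    fractions = {p: c / max(1, n_cells)
                 for p, c in zip(pop_names, counts[:-1])}
    truth = SampleTruth(sample_id, group, fractions, conc, n_cells,
                        n_beads, labels)
    em = EventMatrix(values, ["FSC", "SSC", *markers],
                     {"sample_id": sample_id, "group": group,
                      "panel_id": cfg.panel_id})
    return em, truth


def render_sample(cfg: SimulationConfig, true_em: EventMatrix,
                  instrument: str, date: _dt.date,
                  gain: dict | None = None, drift: float | None = None,
                  lot: dict | None = None, residual: dict | None = None,
                  with_spillover: bool | None = None) -> EventMatrix:
    """Pass a true sample through one instrument on one day.

    Marker channels: x lot effect x residual fluorochrome-response factor
    (both act on emitted signal, before the optics mix it), then spillover,
    then x (gain x day drift). Scatter channels: x scatter gain only.
    """
    panel = cfg.panel
    markers = list(panel.markers)
    gain = gain if gain is not None else instrument_gains(cfg, instrument)
    drift = drift if drift is not None else day_drift(cfg, instrument, date)
    lot = lot if lot is not None else lot_effects(cfg, lot_of_date(cfg, date))
    if residual is None:
        residual = residual_center_effects(cfg, instrument)
    spill = cfg.with_spillover if with_spillover is None else with_spillover

    values = true_em.values.copy()
    midx = [true_em.channel_names.index(m) for m in markers]
    fluo = values[:, midx] * np.array([lot[m] * residual[m]
                                       for m in markers])
    if spill:
        fluo = fluo @ panel.spillover
    fluo = fluo * np.array([gain[m] * drift for m in markers])
    values[:, midx] = fluo
    sg = instrument_scatter_gain(cfg, instrument)
    for ch in ("FSC", "SSC"):
        values[:, true_em.channel_names.index(ch)] *= sg

    meta = dict(true_em.meta)
    meta.update({"instrument_id": instrument,
                 "center_id": f"C{cfg.instruments().index(instrument) + 1:02d}",
                 "acquisition_date": date,
                 "vendor": cfg.vendor_of(instrument)})
    if spill:
        from .compensation import SpilloverMatrix
        meta.setdefault("keywords", {})["$SPILLOVER"] = SpilloverMatrix(
            panel.spillover, markers).to_keyword()
    return EventMatrix(values, list(true_em.channel_names), meta)


def simulate_sample(cfg: SimulationConfig, instrument: str, date: _dt.date,
                    group: str, sample_id: str | None = None
                    ) -> tuple[EventMatrix, SampleTruth]:
    """Draw and render one stained sample (convenience composition)."""
    sid = sample_id or f"{instrument}_{date.isoformat()}_{group}"
    true_em, truth = draw_true_sample(cfg, sid, group)
    return render_sample(cfg, true_em, instrument, date), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    gains: dict
    scatter_gains: dict
    lot_effects: dict
    samples: dict                      # sample_id -> SampleTruth (no labels)
    residual_center_effects: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "gains": self.gains,
            "scatter_gains": self.scatter_gains,
            "lot_effects": self.lot_effects,
            "residual_center_effects": self.residual_center_effects,
            "samples": {k: {kk: vv for kk, vv in asdict(v).items()
                            if kk != "labels"}
                        for k, v in self.samples.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _vendor_channel_names(panel, vendor: str) -> list[str]:
    markers = panel.markers
    if vendor == "BC":
        return ["FS INT", "SS INT"] + [f"FL{i + 1} INT"
                                       for i in range(len(markers))]
    dyes = {"panel1": ["FITC-A", "PE-A", "PerCP-Cy5-5-A", "PE-Cy7-A",
                       "APC-A", "APC-H7-A", "V450-A", "V500-A"],
            "panel2": ["FITC-A", "PE-A", "PerCP-Cy5-5-A", "PE-Cy7-A",
                       "APC-A", "APC-H7-A"]}[panel.panel_id]
    return ["FSC-A", "SSC-A"] + dyes[:len(markers)]


def _write_vendor_file(cfg, em: EventMatrix, path: Path) -> Path:
    """Write with vendor-dialect channel names; LMD for BC, FCS for BD."""
    vendor = em.meta.get("vendor", "BD")
    dialect = _vendor_channel_names(cfg.panel, vendor)
    em_out = EventMatrix(em.values, dialect, dict(em.meta))
    if vendor == "BC":
        path = path.with_suffix(".lmd")
        head = EventMatrix(em.values[:min(200, em.n_events)], dialect,
                           dict(em.meta))
        write_lmd([head, em_out], path)
    else:
        path = path.with_suffix(".fcs")
        write_fcs(em_out, path)
    return path


def simulate_cohort(cfg: SimulationConfig, out_dir
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a full synthetic study tree the CLI pipeline can consume.

    Layout: ``beads/`` (one acquisition per instrument-day),
    ``samples/`` (LMD for Beckman-style centers, FCS for BD-style),
    ``reference_peaks.csv`` (frozen calibration targets measured on the
    reference instrument at gain 1), ``metadata.csv`` and
    ``ground_truth.json``.
    """
    from .bead_qc import detect_peaks

    cfg.validate()
    out = Path(out_dir)
    (out / "beads").mkdir(parents=True, exist_ok=True)
    (out / "samples").mkdir(parents=True, exist_ok=True)

    instruments = cfg.instruments()
    total_days = (cfg.study_end - cfg.study_start).days
    truth = GroundTruth(
        gains={i: instrument_gains(cfg, i) for i in instruments},
        scatter_gains={i: instrument_scatter_gain(cfg, i)
                       for i in instruments},
        lot_effects={lot: lot_effects(cfg, lot)
                     for lot, _, _ in cfg.lot_periods()},
        residual_center_effects={i: residual_center_effects(cfg, i)
                                 for i in instruments},
        samples={},
    )

    # frozen calibration reference: gain-1, drift-1 bead run at study start
    ref_instrument = instruments[0]
    unity = {m: 1.0 for m in cfg.panel.markers}
    calib = simulate_beads(cfg, ref_instrument, cfg.study_start,
                           gain=unity, drift=1.0)
    ref_peaks = detect_peaks(calib)
    ref_peaks.is_reference = True
    ref_peaks.to_csv(out / "reference_peaks.csv")

    rows = []
    n = cfg.n_samples_per_center
    for ci, inst in enumerate(instruments):
        grp_rng = _rng(cfg.seed, "groups", inst)
        groups = grp_rng.choice(list(cfg.groups), size=n,
                                p=list(cfg.group_mix))
        dates = [cfg.study_start
                 + _dt.timedelta(days=round(total_days * (k + 0.5) / n))
                 for k in range(n)]
        for k, (date, group) in enumerate(zip(dates, groups)):
            sid = f"{inst}_S{k + 1:03d}"
            em, struth = simulate_sample(cfg, inst, date, str(group), sid)
            path = _write_vendor_file(cfg, em,
                                      out / "samples" / sid)
            struth.labels = None        # labels stay in-memory only
            truth.samples[sid] = struth
            rows.append({"sample_id": sid, "center_id": em.meta["center_id"],
                         "instrument_id": inst, "acquisition_date": date,
                         "group": str(group), "panel_id": cfg.panel_id,
                         "beads_per_ul": cfg.beads_per_ul,
                         "path": str(path.relative_to(out))})
        for date in sorted({d for d in dates}):
            bem = simulate_beads(cfg, inst, date)
            bpath = _write_vendor_file(cfg, bem,
                                       out / "beads"
                                       / f"{inst}_{date.isoformat()}")
    meta = pd.DataFrame(rows)
    meta.to_csv(out / "metadata.csv", index=False)
    truth.to_json(out / "ground_truth.json")
    schedule = {
        "lot_periods": [(lot, s.isoformat(), e.isoformat())
                        for lot, s, e in cfg.lot_periods()],
        "calibration_dates": [d.isoformat()
                              for d in cfg.calibration_dates()],
        "reference_instrument": ref_instrument,
        "beads_per_ul": cfg.beads_per_ul,
    }
    (out / "schedule.json").write_text(json.dumps(schedule, indent=1))
    return meta, truth
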