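"""Hierarchical gating, population statistics and absolute counting.

Two gating routes are provided:

* :class:`ThresholdGater` — a fully specified rule hierarchy: every population
  is a conjunction of per-marker conditions relative to configured cutoffs on
  the normalized reference scale. Deterministic, and the ground truth for
  evaluating the learned route.
* :class:`TwoStageGateClassifier` — a supervised mimic of manual gating with
  the two-step architecture used for multi-instrument studies: a first,
  instrument-specific classifier on forward/side scatter (scatter signals
  differ strongly across cytometers and are not normalized), then a shared,
  instrument-agnostic classifier on the marker channels.

Absolute counts come from counting beads spiked at a known concentration:
``cells/uL = (cell events / bead events) * beads per uL``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier

from .exceptions import GatingError, ThresholdError
from .fcs_io import EventMatrix

ROOT = "all"


# ---------------------------------------------------------------------------
# population definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One per-marker clause of a population predicate.

    op is one of ``'+'`` (>= threshold), ``'-'`` (< threshold), ``'high'``
    (>= the marker's ``"<marker>:high"`` cutoff), ``'low'`` (< that cutoff),
    or ``'between'`` with explicit numeric ``bounds`` (lo inclusive, hi
    exclusive; ``None`` = unbounded).
    """

    marker: str
    op: str
    bounds: tuple | None = None

    def mask(self, x: np.ndarray, thresholds: dict) -> np.ndarray:
        if self.op == "between":
            lo, hi = self.bounds
            m = np.ones(x.shape, dtype=bool)
            if lo is not None:
                m &= x >= lo
            if hi is not None:
                m &= x < hi
            return m
        key = self.marker if self.op in "+-" else f"{self.marker}:high"
        if thresholds is None or key not in thresholds:
            raise ThresholdError(f"no threshold configured for {key!r}")
        thr = thresholds[key]
        if self.op in ("+", "high"):
            return x >= thr
        return x < thr


@dataclass(frozen=True)
class PopulationDef:
    """A node of the gating hierarchy: name, parent, predicate conjunction."""

    name: str
    parent: str | None
    conditions: tuple
    record_markers: tuple = ()
    panel_id: str | None = None


def build_tree(defs) -> tuple[dict, dict]:
    """Return (children, parent) maps; validates a single acyclic root."""
    parent = {}
    children: dict[str, list] = {}
    roots = []
    for d in defs:
        if d.name in parent or (d.parent is None and d.name in roots):
            raise GatingError(f"duplicate population {d.name!r}")
        if d.parent is None:
            roots.append(d.name)
            parent[d.name] = None
        else:
            parent[d.name] = d.parent
            children.setdefault(d.parent, []).append(d)
    if len(roots) != 1:
        raise GatingError(f"expected exactly one root population, got {roots}")
    for d in defs:
        seen, node = set(), d.name
        while node is not None:
            if node in seen:
                raise GatingError(f"cycle in population tree at {node!r}")
            seen.add(node)
            node = parent.get(node)
            if node is not None and node not in parent:
                raise GatingError(f"unknown parent {node!r}")
    return children, parent


def ancestry(defs) -> dict[str, list]:
    """name -> [name, parent, ..., root] chains."""
    _, parent = build_tree(defs)
    chains = {}
    for name in parent:
        chain, node = [], name
        while node is not None:
            chain.append(node)
            node = parent[node]
        chains[name] = chain
    return chains


# ---------------------------------------------------------------------------
# threshold gating
# ---------------------------------------------------------------------------

def gate_events(em: EventMatrix, defs, thresholds: dict | None = None
                ) -> np.ndarray:
    """Assign every event the deepest population label it satisfies.

    Children are evaluated in definition order; an event matching several
    siblings goes to the first (a documented, deterministic tie-break —
    well-formed hierarchies have disjoint siblings). Events matching no child
    keep their parent's label.
    """
    children, parent = build_tree(defs)
    root = next(n for n, p in parent.items() if p is None)
    n = em.n_events
    labels = np.full(n, root, dtype=object)
    cols = {}

    def col(marker):
        if marker not in cols:
            cols[marker] = em.column(marker)
        return cols[marker]

    def descend(pop_name, member_mask):
        taken = np.zeros(n, dtype=bool)
        for child in children.get(pop_name, []):
            m = member_mask & ~taken
            for cond in child.conditions:
                if not m.any():
                    break
                m = m & cond.mask(col(cond.marker), thresholds)
            labels[m] = child.name
            taken |= m
            descend(child.name, m)

    descend(root, np.ones(n, dtype=bool))
    return labels


class ThresholdGater(BaseEstimator):
    """Rule-hierarchy gater (sklearn-style; ``fit`` only validates config)."""

    def __init__(self, defs=None, thresholds=None):
        self.defs = defs
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        if self.defs is None:
            raise GatingError("no population definitions configured")
        build_tree(self.defs)
        self.tree_validated_ = True
        return self

    def predict(self, em: EventMatrix) -> np.ndarray:
        if not getattr(self, "tree_validated_", False):
            self.fit()
        return gate_events(em, self.defs, self.thresholds)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def absolute_count(population_events: int, bead_events: int,
                   beads_per_volume: float) -> float:
    """Cells/uL from counting-bead ratio.

    count = (population events / bead events) * beads-per-uL. Zero bead
    events means the spike-in failed and the acquisition is unusable.
    """
    if bead_events < 1:
        raise GatingError("zero counting-bead events: acquisition failure")
    if beads_per_volume <= 0:
        raise GatingError("beads_per_volume must be > 0")
    return population_events / bead_events * beads_per_volume


LOW_COUNT_MIN = 10  # below this many events, MFIs are flagged unreliable


def population_stats(em: EventMatrix, labels: np.ndarray, defs,
                     beads_per_volume: float | None = None,
                     leukocyte_root: str = "leukocytes",
                     bead_population: str = "beads") -> pd.DataFrame:
    """Per-population frequencies, absolute counts and marker MFIs.

    Counts are *subtree* counts (a parent includes its children). Frequencies
    are reported both as % of the parent population and as % of leukocytes.
    MFI is the arithmetic mean on the linear scale over subtree members, NaN
    (with ``low_count`` flagged) when fewer than ``LOW_COUNT_MIN`` events.
    """
    chains = ancestry(defs)
    _, parent = build_tree(defs)
    subtree = {name: 0 for name in parent}
    lab_counts = pd.Series(labels).value_counts()
    for name, cnt in lab_counts.items():
        for anc in chains[name]:
            subtree[anc] += int(cnt)
    n_leuk = subtree.get(leukocyte_root, 0)
    n_beads = subtree.get(bead_population, 0)

    in_subtree = {name: np.isin(labels, [n for n in chains
                                         if name in chains[n]])
                  for name in parent}

    rows = []
    for d in defs:
        if d.parent is None:
            continue
        n_pop = subtree[d.name]
        n_par = subtree[d.parent]
        under_leuk = leukocyte_root in chains[d.name]
        row = {
            "population": d.name,
            "parent": d.parent,
            "n_events": n_pop,
            "freq_of_parent": 100.0 * n_pop / n_par if n_par else 0.0,
            "freq_of_leukocytes": (100.0 * n_pop / n_leuk
                                   if (under_leuk and n_leuk) else np.nan),
            "low_count": n_pop < LOW_COUNT_MIN,
        }
        if beads_per_volume is not None and under_leuk:
            row["absolute_count"] = (
                absolute_count(n_pop, n_beads, beads_per_volume)
                if n_beads else np.nan)
        for m in d.record_markers:
            if n_pop >= LOW_COUNT_MIN:
                row[f"mfi_{m}"] = float(em.column(m)[in_subtree[d.name]].mean())
            else:
                row[f"mfi_{m}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


def cohort_row(em: EventMatrix, labels: np.ndarray, defs,
               beads_per_volume: float | None = None,
               leukocyte_root: str = "leukocytes") -> pd.Series:
    """Flatten per-sample population stats into one cohort-table row.

    Feature naming: ``freq|<pop>`` (% of leukocytes), ``count|<pop>``
    (cells/uL), ``mfi|<pop>|<marker>``.
    """
    stats = population_stats(em, labels, defs, beads_per_volume,
                             leukocyte_root=leukocyte_root)
    chains = ancestry(defs)
    record_of = {d.name: d.record_markers for d in defs}
    feats = {}
    for pop, row in stats.iterrows():
        chain = chains[pop]
        if leukocyte_root not in chain or pop == leukocyte_root:
            continue
        if chain[1] == leukocyte_root:   # scatter classes: frequency only
            feats[f"freq|{pop}"] = row["freq_of_leukocytes"]
            continue
        feats[f"freq|{pop}"] = row["freq_of_leukocytes"]
        if "absolute_count" in row and not pd.isna(row.get("absolute_count",
                                                           np.nan)):
            feats[f"count|{pop}"] = row["absolute_count"]
        for m in record_of[pop]:
            feats[f"mfi|{pop}|{m}"] = row.get(f"mfi_{m}", np.nan)
    return pd.Series(feats)


# ---------------------------------------------------------------------------
# supervised two-stage model
# ---------------------------------------------------------------------------

def scatter_level(defs, leukocyte_root: str = "leukocytes") -> dict[str, str]:
    """Map every population to its scatter-level class.

    Scatter classes are the children of the leukocyte root plus the root's
    siblings (debris, beads); everything deeper maps to its scatter ancestor.
    """
    chains = ancestry(defs)
    out = {}
    for name, chain in chains.items():
        if leukocyte_root in chain:
            i = chain.index(leukocyte_root)
            out[name] = chain[i - 1] if i > 0 else leukocyte_root
        else:
            out[name] = chain[-2] if len(chain) > 1 else chain[-1]
    return out


class TwoStageGateClassifier(BaseEstimator, ClassifierMixin):
    """Supervised gating automaton with an instrument-specific scatter step.

    Stage 1 fits one classifier per instrument on (FSC, SSC) predicting the
    scatter-level class; stage 2 fits a single shared classifier on the
    fluorescence markers (plus the stage-1 class as an ordinal feature)
    predicting the final population. Predictions are forced to respect the
    population tree: a stage-2 label inconsistent with the stage-1 scatter
    class is demoted to the scatter class itself.

    Parameters
    ----------
    defs : sequence of PopulationDef
        The population hierarchy the labels live in.
    base_classifier : sklearn classifier, optional
        Cloned for each stage; default is a decision tree with a fixed seed.
    fallback : ThresholdGater, optional
        Used (with a warning) for instruments unseen during training.
    """

    def __init__(self, defs=None, base_classifier=None, fallback=None,
                 random_state=0):
        self.defs = defs
        self.base_classifier = base_classifier
        self.fallback = fallback
        self.random_state = random_state

    def _base(self):
        if self.base_classifier is not None:
            return clone(self.base_classifier)
        return DecisionTreeClassifier(random_state=self.random_state,
                                      min_samples_leaf=5)

    @staticmethod
    def _scatter_features(em: EventMatrix) -> np.ndarray:
        x = np.column_stack([em.column("FSC"), em.column("SSC")])
        return np.log10(np.clip(x, 1.0, None))

    def _marker_features(self, em: EventMatrix) -> np.ndarray:
        missing = [m for m in self.marker_channels_
                   if m not in em.channel_names]
        if missing:
            raise GatingError(f"marker channel(s) missing from event "
                              f"matrix: {missing}")
        cols = [em.column(m) for m in self.marker_channels_]
        return np.arcsinh(np.column_stack(cols) / 150.0)

    def fit(self, X, y):
        """Fit from labelled samples.

        X : list of EventMatrix; y : list of per-event label arrays
        (e.g. produced by manual gating or :class:`ThresholdGater`).
        """
        if self.defs is None:
            raise GatingError("population definitions are required")
        self.scatter_of_ = scatter_level(self.defs)
        self.marker_channels_ = [c for c in X[0].channel_names
                                 if c not in ("FSC", "SSC")]
        by_instrument: dict[str, list] = {}
        for em, lab in zip(X, y):
            inst = em.meta.get("instrument_id", "?")
            by_instrument.setdefault(inst, []).append((em, np.asarray(lab)))

        self.stage1_ = {}
        for inst, pairs in by_instrument.items():
            xs = np.vstack([self._scatter_features(em) for em, _ in pairs])
            ys = np.concatenate([[self.scatter_of_[l] for l in lab]
                                 for _, lab in pairs])
            self.stage1_[inst] = self._base().fit(xs, ys)

        self.scatter_classes_ = sorted(set(self.scatter_of_.values()))
        code = {c: i for i, c in enumerate(self.scatter_classes_)}
        self._scatter_code_ = code
        xs2, ys2 = [], []
        for em, lab in ((em, lab) for pairs in by_instrument.values()
                        for em, lab in pairs):
            mk = self._marker_features(em)
            sc = np.array([code[self.scatter_of_[l]] for l in lab],
                          dtype=float)
            xs2.append(np.column_stack([mk, sc]))
            ys2.append(lab)
        self.stage2_ = self._base().fit(np.vstack(xs2), np.concatenate(ys2))
        return self

    def predict(self, em: EventMatrix) -> np.ndarray:
        inst = em.meta.get("instrument_id", "?")
        if inst not in self.stage1_:
            if self.fallback is None:
                raise GatingError(
                    f"instrument {inst!r} unseen during training and no "
                    "fallback threshold gater configured")
            warnings.warn(f"instrument {inst!r} unseen during training; "
                          "falling back to threshold gating", stacklevel=2)
            return self.fallback.predict(em)
        scatter = self.stage1_[inst].predict(self._scatter_features(em))
        sc = np.array([self._scatter_code_[s] for s in scatter], dtype=float)
        x2 = np.column_stack([self._marker_features(em), sc])
        labels = self.stage2_.predict(x2).astype(object)
        # enforce tree consistency with the instrument-specific stage
        bad = np.array([self.scatter_of_[l] for l in labels]) != scatter
        labels[bad] = scatter[bad]
        return labels


def train_gate_model(samples, labels, defs, fallback=None,
                     random_state=0) -> TwoStageGateClassifier:
    """Convenience wrapper: fit a :class:`TwoStageGateClassifier`."""
    model = TwoStageGateClassifier(defs=defs, fallback=fallback,
                                   random_state=random_state)
    return model.fit(samples, labels)


def predict_gates(em: EventMatrix, model: TwoStageGateClassifier
                  ) -> np.ndarray:
    return model.predict(em)
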