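# Methods

This note documents the models, conventions and numerical choices behind
`cytoharm`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Data model

All computation happens on **linear-scale** intensities. Log-amplified
integer channels (`$PnE = "d,f"`) are linearized at read time as
`f · 10^(d·v/R)`; log/arcsinh transforms exist only inside the supervised
gater's feature map and for display. Beckman LMD containers hold two
concatenated datasets (an FCS 2.0 segment and an FCS 3.0 segment); the last
segment is returned by default because it carries the full-resolution data.
All byte offsets within a segment, including `$NEXTDATA`, are interpreted
relative to that segment's start. Channel names are mapped to canonical
marker names per panel (both `FL1 INT`-style and `FITC-A`-style dialects)
and columns re-ordered to the panel's canonical order, so matrices from
different vendors are column-compatible; an unmapped detector is an error
listing all offenders, never a silent drop.

## Bead peaks

Rainbow 8-peak beads produce eight well-separated log-normal modes per
fluorescence channel. After a debris gate (events below the 2nd FSC
percentile, or inside a fixed low-scatter box), each channel is clustered
by 1-D k-means on log₁₀ intensity with quantile-spaced initialization plus
nine seeded random restarts. K-means on a *shifted* log axis has identical
distances, so a pure gain change moves every cluster rigidly: detected
peaks scale exactly with the gain, which the tests assert to 1e-9. A
channel fails (rather than returning wrong peaks) when any cluster holds
< 1 % of events or two cluster means sit closer than 0.15 decades — the
signature of fewer than eight resolvable modes. The peak statistic is the
arithmetic mean of linear intensities (median available by configuration).
Peaks are matched to reference by rank, never by nearest value, because
gain drift preserves order. The daily QC rule is: every peak of every
fluorochrome within 5 % of the instrument's internal reference.

## Affine normalization

Per channel, the transform `corrected = α·observed + β` is fitted by
weighted least squares over the eight rank-matched (observed, reference)
peak pairs, in the observed→reference direction so it can be applied
directly to sample events.

**Weighting.** The default weights are `1/ref²`, i.e. relative least
squares. The peaks span ~3.5 decades; with unweighted absolute least
squares, the sampling noise of the brightest peaks (SE ≈ 0.4 % of ~6·10⁴ at
500 events/peak) moves the fitted intercept by more than the dimmest peak's
entire MFI, so the dim end of the scale is destroyed even though the fit
"looks" excellent. Since the error being corrected is a multiplicative gain,
a relative-residual objective is the natural choice; measured on the
synthetic beads it leaves worst-case pair CVs of ~1.3 % vs ~3 % for `1/ref`
weights and catastrophic values for unweighted. `weighting="none"` and
`"inverse"` remain available for sensitivity analysis.

Fits with `α ≤ 0` or `R² < 0.99` raise — a corrupted bead run must surface,
not silently pass. Scatter channels are not bead-calibrated and map to
identity. Negative corrected values (possible when `β < 0`) are kept:
downstream statistics are means and medians and clipping would bias them.
The transform fitted from a day's beads applies to that day's samples on
that instrument; date matching is exact with a configurable ±N-day fallback
(default 0 — a day without beads fails those samples, visibly).

## Compensation

Row-vector convention: `observed = true · S`, `compensated = observed ·
S⁻¹`, spillover matrix validated (unit diagonal, off-diagonal in [0, 1),
condition number below 10⁶). The matrix comes from the file's `$SPILLOVER`
keyword when present, else from configuration; adjustments are explicit,
logged entry overrides — no automatic re-estimation, which would hide
provenance. The `residual_spill` diagnostic quantifies what an operator
judges by eye: the slope of secondary-channel medians against
primary-channel medians between bright and dim event groups; |slope| ≈ 0
indicates adequate compensation and an under-compensation of five points
leaves slope ≈ +0.05. Its flagging threshold is a repository convention,
not an established standard. Fewer than 50 bright events is "inconclusive",
not an error.

## Gating

The threshold hierarchy is fully declarative: each population is a
conjunction of per-marker conditions (`+`/`−` against a cutoff, `high`/`low`
against a second cutoff, or explicit bounds), organized as a tree under
scatter classes (lymphocytes / monocytes / granulocytes, plus debris and
counting beads on forward scatter). Cutoffs live on the **normalized**
reference scale — normalization is precisely what makes one threshold set
valid on every instrument. Events get the deepest label whose predicate
chain they satisfy; among overlapping siblings the first in definition
order wins (a deterministic tie-break; well-formed panels have disjoint
siblings). MFIs are arithmetic means on the linear scale, computed after
normalization *and* compensation, over each population's subtree, and only
for that population's markers of record (the antibodies that define it).
Populations with fewer than 10 events report NaN MFIs with a low-count
flag. Frequencies are reported both as %-of-parent and %-of-leukocytes; the
cohort table stores %-of-leukocytes.

The supervised gater mimics the two-step automaton architecture used for
multi-instrument studies: stage 1 is one classifier per instrument on
(log₁₀ FSC, log₁₀ SSC) predicting the scatter class — scatter is never
normalized, so this step must be instrument-specific — and stage 2 is a
single shared classifier on arcsinh-scaled markers plus the stage-1 class,
predicting the final population. Decision trees with a fixed seed are the
default family (fast, deterministic, and the boundaries really are
axis-aligned); any sklearn classifier can be substituted. Predictions are
forced to respect the tree: a stage-2 label inconsistent with the stage-1
scatter class is demoted to the scatter class. Unseen instruments fall back
to threshold gating with a warning. The lineage-exclusion cocktail of the
dendritic-cell panel is modelled as a single dump channel ("Lin").

## MFI corrections

Both corrections act on the extracted cohort table, never on event data,
and rely on one fact: `median(c·x) = c·median(x)`, so ratio-of-medians
coefficients align medians **exactly** (to float rounding), are idempotent,
and cancel out of any ratio of group medians within a correction cell.
Batch correction aligns each (instrument, batch) onto the instrument's
earliest batch; batches are (antibody lot × recalibration epoch) with
half-open date intervals, a boundary date belonging to the period starting
that day. Center correction aligns each instrument onto a designated
reference instrument and refuses to run before batch correction (the
pipeline order is fixed). Coefficients are per (population, marker) column,
not pooled per channel: lot effects are antibody-specific and each MFI
column belongs to one population of record. "MFI of all samples" is
computed as the median across samples (the quantity the procedure aligns);
mean is available for sensitivity analysis at the cost of exactness. The
center step assumes every center saw the same mix of subjects; a chi-square
check on the instrument × group contingency table warns (α = 0.01) when
composition differs materially, since the correction is biased otherwise.
Frequencies and absolute counts pass through both steps bit-identically.

Note one refinement of the "biology preserved" statement: the batch step
applies one multiplier per (instrument, batch), so a disease/healthy median
ratio is exactly invariant *within each batch*; pooled across batches it
can move when the group mix differs between batches. The center step is
exactly invariant per instrument.

## Diagnostics

CV is `100 · sample SD / mean` (scale-invariant; requires n ≥ 2 and a
positive mean). The center-effect score z-scores the chosen feature block
(MFIs or frequencies), decomposes by SVD with signs fixed so each
component's largest-magnitude loading is positive, and reports the
between-center share of variance of the first two PC scores — 0 for fully
overlapping centers, →1 for a pure center effect; constant features are
dropped with a warning. Median equality across instruments is tested per
MFI column with Kruskal–Wallis: the aligned statistic is a median, so a
rank test is the natural convention; the choice of test is this package's,
as none is prescribed by the procedure itself. Columns lacking ≥ 2
instruments with ≥ 3 samples return NaN rather than failing.

## Synthetic data generator

The generator emulates the structure of a multi-year, multi-center study
at desk scale. Defaults: 11 centers (one instrument each, alternating
Beckman/BD file dialects), 24 samples per center over a 4-year window,
10⁴ events per sample, 500 events per bead peak, 3 antibody lots and 7
recalibration dates. The desk-test preset (`SimulationConfig.small()`)
shrinks this to 3 centers × 12 samples × 4,000 events so the full pipeline
runs in seconds; these sizes are the package's chosen test scale, and the
statistical claims scale as √n.

Marker intensities are log-normal (the standard model for cytometry
fluorescence), with population templates (mixture weight, per-marker log₁₀
location, σ = 0.12) placed ≥ 1 decade from the gating cutoffs. The
rendering chain per fluorescence channel is:

```
true (reference scale)
  × lot effect (per lot × marker, drawn in [0.75, 1.3], lot 1 ≡ 1)
  × residual fluorochrome response (per instrument × marker,
      drawn in [0.85, 1.18], reference instrument ≡ 1)
  → spillover mixing (adjacent-channel 8 %/3 %)
  × instrument gain (per channel, [0.8, 1.25]) × daily drift (lognormal σ 0.02)
```

Bead events skip the lot and residual factors (calibration particles carry
no antibodies and define the as-measured reference scale) and spillover, so
bead-fitted transforms recover exactly the gain × drift factor — fitted
α ≈ 1/(g·drift) to < 2 % — while the lot and residual factors survive
normalization and are what steps 5–6 must remove. The residual factor
models the documented phenomenon that part of an optical bench's response
is antibody/fluorochrome-specific and hence invisible to bead calibration;
without it, bead normalization alone would abolish all center effects and
steps 5–6 would have nothing to do. A disease group carries a 1.5× CD19
shift on B cells (configurable), giving the biology-preservation checks a
known signal. Counting beads are spiked at 1,000 beads/µL against a true
concentration drawn around 6,000 cells/µL; debris (3 % of sample events,
5 % of bead events) sits low on scatter. Every draw is keyed off
`(seed, purpose, instrument, date)`, so identical configs reproduce
identical cohorts bit for bit.

**What passing tests show — and don't.** The generator realizes exactly the
error model the corrections assume: multiplicative, population-independent
channel effects and log-normal populations separated cleanly from their
cutoffs. Real data add autofluorescence, doublets, spectral ringing,
non-multiplicative saturation, gating ambiguity near boundaries, and
center-specific subject mixes; success here demonstrates the algebra and
the implementation, not robustness to those factors. The real cohort's
published dispersion values depend on clinical data this package does not
ship and are deliberately not reproduced.

## Validation experiments

`cytoharm.validation` packages three end-to-end experiments (also run by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`):

1. detune per-channel gains by 10–15 % (the software analogue of
   mis-setting PMT voltages), re-acquire beads, normalize, and measure the
   worst CV between reference and corrected peak MFIs — bound 2.5 %;
2. propagate the same detuning to a stained sample (identical cell-level
   draws), normalize with bead-fitted transforms, gate both versions, and
   measure the worst CV over matched population-marker MFI pairs — bound
   5 %;
3. render one sample through 11 instruments with gains in [0.8, 1.25],
   normalize each to the common reference, and measure the worst
   inter-instrument MFI CV — bound 5 %.

These isolate the normalization step (no lot effects, spillover or drift),
so the residual CV is peak-estimation noise plus affine-fit error;
measured values sit well under 1.5 %.

## Known limitations

No spline/quantile normalization (affine only, by design); no automated
spillover estimation from single-stain controls; no doublet exclusion
beyond scatter boxes; LMD support covers the dual-dataset layout this
package writes and the common Beckman convention of segment-relative
offsets, not every historical vendor quirk; the supervised gater is a
deliberately modest stand-in for production automatons and inherits the
threshold hierarchy's labels rather than human gating.
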