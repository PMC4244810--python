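# Methods

This note records the models, conventions and numerical choices behind
`microlapse`, and what the synthetic experiments do and do not establish
about real microscope data.

## Experimental geometry and units

The pipeline assumes the standard agar-sandwich time-lapse setup: cells
immobilized between a coverslip and agar, imaged at a pre-programmed grid
of positions (default 7×7 = 49) in two channels, brightfield and
propidium iodide (PI) fluorescence. Time zero is the moment the agar is
added; frame times are hours since then, strictly increasing, first
frame at 0. All sizes are integer pixel counts ("pixel" is the unit —
no physical calibration is assumed), coordinates are 0-based (row, col),
growth rates are in ln pixels per hour, and CFU quantities use log10.
The acquisition interval is a free parameter (default Δt = 1 h) because
it is an instrument setting, not a biological constant.

## Growth model

Microcolony area follows the Baranyi–Roberts primary model in natural
log space (see README for the equations), with the curvature parameter
fixed at m = 1 — the common fitting-software default; nothing in the
data here motivates freeing it. λ = h0/μmax is exposed alongside h0.
The closed form is written entirely in log-sum-exp terms
(`logaddexp`, guarded `log(expm1)`) so that large μmax·t and large h0
(long lags) cannot overflow, and t = 0 is pinned to return y0 exactly.

Two properties are worth noting because they are easy to get wrong:

* the Baranyi lag is *soft*: at t = λ the curve already sits near
  2·A0 (for large h0, y(λ) − y0 → ln 2). "No growth during lag" is only
  true through mid-lag. Tests assert the correct behaviour.
* with h0 = 0 the adjustment function collapses to A(t) = t and the
  model reduces to the logistic-in-log form; with ymax → ∞ as well it is
  pure exponential growth. Both limits are tested.

### Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective, tight tolerances) on ln areas, with fully deterministic
initialization: μmax from the steepest 3-point sliding-window slope, y0
from the first observation, ymax from the maximum + 0.5, h0 from a
tangent-intersection lag guess times the initial μmax. Bounds: y0 within
±2 of the first observation, ymax in [max − 0.5, max + 15], μmax in
[1e−4, 10], h0 in [0, 300]. A fit is **non-fittable** when the series is
shorter than 5 points, flat, non-convergent, has RMSE above 0.5 ln px,
or μmax ≤ 0.01 ln px/h (indistinguishable from zero); such series are
counted and reported, never silently dropped. Standard errors come from
the linearized covariance (Jᵀ J)⁻¹·s², with the lag SE by the delta
method; on noisy synthetic series the ±2 SE intervals cover the truth
for ≳ 90% of fits. Merge-censored series are fitted on their uncensored
prefix.

## Segmentation

Cells are dark on a light field. The background level is estimated from
the 90th intensity percentile (not the median: mature colonies can cover
more than half of a late frame), the image is inverted to "depth below
background", and Otsu's threshold is applied. Otsu needs a substantial
dark class, so if the resulting foreground is not significantly darker
than the background (median separation < 6 robust SDs), the threshold
falls back to background median + 6 robust SDs — this handles
time-zero frames where a handful of ~30 px cells occupy 0.1% of the
field, and leaves truly blank frames empty (with a warning, never an
exception). Components are 8-connected; objects below 5 px are removed
by area filtering, which leaves all surviving object pixels untouched —
on noise-free synthetic frames measured areas equal truth-mask counts
*exactly*, and that exactness is a regression test.

Holes are never filled before counting: `area` is the raw foreground
pixel count, so the interior holes of rough colonies are excluded from
biomass by construction. `filled_area` additionally counts enclosed
background, computed by full-frame hole filling per label (bbox-cropped
filling misses pockets that touch the bounding box edge). PI positivity
of an object is `mean PI > background median + k·MAD·1.4826` with
k = 6, chosen over Otsu because a healthy field may contain no PI signal
at all.

## Tracking and censoring

Colonies under agar do not move; linking is therefore maximal pixel
overlap between consecutive frames (deterministic tie-breaks: lowest
label, then lowest founder id). Founder ids are assigned by (row, col)
centroid order at frame 0, so two runs of the same data agree. When one
current-frame component overlaps two or more lineages, those colonies
have merged: every involved lineage is censored at that frame and its
series ends one frame earlier. Censored lineages remain in the tracker
as *ghosts* — they emit no further areas but keep claiming their pixels,
so a third colony that later collides with an already-merged blob is
itself censored rather than silently absorbing it. Censoring is
per-lineage (the stricter experiment-wide stop is recoverable as the
minimum censoring frame), and areas observed before a merge are
bit-identical to what a merge-free control yields — also a regression
test.

A founder is classified **dividing** when its maximum observed area
ratio reaches 4.0× (≈ two doublings). This threshold separates genuine
growers from "elongaters" — cells that lengthen 2–3× without ever
dividing — which the simulator caps at 2.0× area. Cells that elongate
up to 6× before their first division are a known edge case: if such a
cell then stalls, the threshold can misclassify it. PI positivity at
time zero is an orthogonal flag; by default those founders stay in the
survival denominator (configurable), since the denominator is defined
as all cells present at time zero.

## Population statistics

Microscope survival is 100·N_dividing/N_total(t0); CFU survival is
100·CFU_treatment/CFU_control; log reduction is the log10 difference
(the two log conventions — natural log for growth, log10 for CFU — are
deliberate and kept separate). Medians and IQRs of λ and μmax are taken
over *fittable* fits of dividing founders only, mirroring the
fitted/non-fittable bookkeeping; conditions with fewer than 10 fittable
curves are flagged low-n rather than suppressed (a condition where only
four cells divide still gets a summary). The λ–μmax association uses
Spearman rank correlation with a permutation p-value because post-stress
distributions are heavily skewed.

### Dead-cell spatial test

The claim "dead cells are scattered randomly within the colony" (vs the
nutrient-depletion alternative that they concentrate at the center) is
formalized as a Monte-Carlo test. Each PI-positive cell gets a
normalized radial coordinate r̂ ∈ (0, 1]: the fraction of colony pixels
at least as deep as it under the Euclidean distance transform (≈ 0 at
the colony's deepest interior, 1 at the boundary), which is
distribution-free over irregular, holed colony shapes. The statistic is
the mean r̂²; the null is B uniform placements over the colony's
foreground pixels, and the two-sided p-value is
(1 + #{|T_b − E| ≥ |T_obs − E|})/(B + 1) with E the exact uniform
expectation. Per-colony results are always reported; across colonies
they are pooled by Fisher's combination. Calibration (type-I ≈ 0.05)
and power (> 0.9 against center bias of strength 3 with 10 deaths per
colony) are verified by simulation.

One subtlety: in a full time-lapse, a cell that dies at 40 h is placed
within the colony as it exists at 40 h; by the final frame the colony
has grown past it, so even "uniform at time of death" placements sit
interior-ward of the final boundary. The pooled test can therefore
report mild center-concentration on end-to-end runs. This is a property
of the experiment, not a miscalibration — against placements uniform
over the *tested* mask the test holds its nominal level.

## The synthetic microscope

The simulator defines the study conditions under which the pipeline is
validated: 49 fields of 512×512 8-bit pixels; founders per field
truncated-Poisson (mean 6, max 14), giving ~300 total in 200–500;
collision-free placement with 25 px minimum separation and a 20 px
margin; hourly frames to 48 h. Per-cell physiology: lag a shifted
log-normal (untreated: 1 + LN(median 3 h, CV 0.35); stressed preset:
2 + LN(median 20 h, CV 0.6)), μmax a truncated normal (untreated
0.45 ± 0.07; stressed 0.30 ± 0.10 ln px/h), plateau ymax = 10.34 ln px
so the fastest colonies reach ≈ 3.1×10⁴ pixels by 35 h. Untreated
grower fraction 0.95 (survival just under 100%); stressed preset 0.40.
Non-growers split 40/60 into elongaters (area cap U(1.1, 2.0), below
the 4× dividing threshold by construction) and inert cells; ~30% of
non-growers eventually stain PI-positive — most membrane-compromised
physiology is *not* PI-visible, which is the regime of interest.
Growth truth uses the same Baranyi form the fitter assumes — deliberate,
so parameter recovery is a well-posed test — with an optional Gompertz
(`model_mismatch`) mode for robustness experiments.

Rendering is a blob model, not an agent simulation: each founder owns a
deterministic pixel fill order — first a fixed-width rod elongating
2–3× (rarely up to 6×) along its axis, then lateral expansion in order
of geodesic distance from the rod (isotropic for S-type; directionally
modulated by random low-order harmonics for R-type). The mask at time t
is exactly the first N(t) pixels of that order with N(t) the rounded
closed-form area, so truth masks are nested in time, their pixel counts
match the growth curve exactly, and — because geodesic ordering grows a
single connected region and routes around the excluded hole disks of
R-type colonies — every mask is one component. Intensities (background
200 ± 8, cells 60, PI-positive 150 on a ≈ 5 ± 2 background, 8-bit) are
declared conventions, not estimates of any instrument. Single-cell
texture inside colonies, phase-contrast optics and 3-D colony doming
are out of scope; consequently, passing tests demonstrate correctness
of the measurement pipeline under the stated noise model, not
robustness to real optical artifacts (defocus, illumination gradients,
debris), which would need real data.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; one root seed fans out to
stage seeds via `numpy.random.SeedSequence` with fixed keys, so
identical (parameters, seed) reproduce every artifact bit-for-bit.
Experiments are simulated and analyzed one position at a time, so
memory stays flat in grid size. The validation suite uses two full
49-position experiments (~300 founders each, 49 hourly frames, ~2 min
each on one CPU), 50-series fit-recovery batches, a 128-point
parameter grid for the ODE cross-check, and 200/50-colony batches for
spatial-test calibration/power — sizes chosen so the complete
validation runs in a few minutes while keeping binomial/Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

* Overlap linking assumes immobile colonies; motile or drifting cells
  would need a different tracker.
* The 4× dividing threshold is a heuristic operationalization of
  "divided"; extreme pre-division elongation followed by stalling can
  fool it.
* Cells whose lag exceeds the observation horizon are counted as
  non-dividing — microscope survival is defined relative to the
  observation window, exactly as plate counts are relative to their
  incubation time.
* Area is a 2-D proxy; once colonies dome into 3-D, pixel area
  under-measures biomass. The simulator does not emulate this regime.
* Fisher pooling of discrete Monte-Carlo p-values is slightly
  anti-conservative; per-colony p-values are reported alongside the
  pooled value for this reason.
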