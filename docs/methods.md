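# Methods

## The scoring model

A beat is a 12 × T matrix of lead voltages (mV) on a uniform grid (default
1 kHz, 450 ms window; times in ms, 0-based samples, half-open windows). The
intrinsic morphology match score of a beat against a frozen intrinsic
template is the arithmetic mean of the 12 per-lead Pearson coefficients
inside the independent scoring interval (ISI), times 100, rounded half-up
to an integer percent. The per-lead combination rule is not dictated by
anything deeper than symmetry: all 12 leads enter equally, and the printed
scores are integers, hence the final rounding. Negative global scores are
kept at full value for descriptive statistics and clamped to 0 only for
display, mirroring how a mapping system would plot them.

Alignment: the beat is shifted so that its detected QRS onset coincides
with the template's reference offset (the template's detected onset). QRS
onset/offset detection operates on the cross-lead RMS signal with a
5%-of-peak threshold, three robustness guards (threshold floored at 1.6×
the median RMS when baseline noise would dominate, a crossing must open a
run of ≥ 5 above-threshold samples, and the crossing time is refined to
sub-sample precision by linear interpolation unless the edge is
discontinuous), and the alignment itself is applied at fractional-sample
resolution by linear interpolation. Without the sub-sample step the ±1 ms
quantization error couples with genuine morphology differences and roughly
quintuples the low tail of the selective-capture score distribution —
an artifact of the grid, not of the signals. A manual shift on top of the
automatic alignment is available (`shift_search` tries every
integer-sample manual shift in ±max and returns the total shift of the
best match; ties prefer the smallest manual displacement, negative first).

Zero-variance leads have no defined correlation; they contribute 0 and are
flagged as degenerate rather than silently dropped.

Local activation time is `LAT = detected QRS onset − (stimulus time +
capture tolerance)` with a 40 ms default tolerance: a paced beat must begin
within 40 ms of the stimulus to count as captured (LAT ≤ 0). Non-captured
and atrial-capture beats — intrinsic-timed escape beats and
atrially-conducted beats, both starting long after the stimulus — have
LAT > 0 and are excluded before statistics *regardless of their score*;
such beats match the template almost perfectly, which is exactly why the
timing filter, not the score, has to remove them.

The ISI defaults to the operator's procedure: lines enclosing the template
QRS with a 10 ms margin on each side ([−10, QRSd + 10) ms relative to
onset). A fixed interval can be supplied instead. The enclosing choice also
makes the score scale-free with respect to the patient's QRS duration; a
fixed 120 ms window re-introduces a dependence on the QRSd draw through
tail clipping.

## The synthetic cohorts

No beat-level recordings are deposited, so the analysis runs on a
generator built to the study's printed distributions. Each source
morphology is a sum of three Gaussian wavelets (Q/R/S deflections) with a
duration scale chosen so that the measured 5%-threshold QRS duration
equals the requested value; the conduction-system (intrinsic) and
RV-myocardial sources project onto the 12 leads through separate weight
vectors. The myocardial weight variant differs between the two pacing
tools (His lead vs. roving catheter), carrying the source-dependent RVP
score level: with ~10 of 12 concordant leads the His-lead RVP median sits
near 48%, with ~8 concordant leads the catheter's near 23%.

A cohort emulates one representative patient: the first intrinsic beat is
the template donor, and every other beat re-generates the donor's wavelet
parameters with small within-patient jitter (relative QRSd wobble,
morphology jitter, onset jitter, additive noise). Between-patient spread
(QRSd 101 ± 11 ms intrinsic, 124 ± 14 ms nonselective-paced) lives in the
donor-level draws, so the single-call constructors still reproduce the
population moments while cohort score quartiles stay stable across seeds.
This is a deliberate simplification — the published cohorts pool ~13
patients with per-patient templates, so the pooled between-patient
variance of the score distributions is under-represented here; medians are
faithful, extreme ranges slightly narrower than printed.

Paced classes:

* **S-HBP** — stimulus-to-QRS latency ~28 ms (isoelectric interval),
  morphology = donor shape plus a *residual dissimilarity* component: the
  shape's time derivative, tapered after onset, Gram–Schmidt-
  orthogonalized against the shape over the scoring window, normalized to
  the shape's RMS, added with random sign and weight `w`. Because the
  component is orthogonal, the windowed correlation is analytically
  `(1−w)/√((1−w)²+w²)` — the mixing weight here parametrizes subtle
  capture-related morphology change (autonomic and contact variation,
  minute activation-timing shifts), not literal myocardial capture, which
  selective His capture by definition lacks. The calibrated weight
  distribution (Beta(4.5, 1.6) on [0.12, 0.30]) puts the cohort at median
  93–95% with a hard floor near 89%.
* **NS-HBP** — fused capture: QRS onset at the stimulus. The site-level
  widening (~23 ms, scaled to the patient's QRSd) splits into a
  pseudodelta onset delay (~1/3) and a terminal slur (~2/3); the
  pseudodelta ramp and terminal slur are explicit waveform components
  whose prominence floors at half the configured amplitude, so onset
  detection lands at the stimulus for every fused beat. The myocardial
  admixture is orthogonalized like the selective component (weight
  Beta(4, 4) on [0.08, 0.18]). Result: median 84%, IQR ≈ 83–86, support
  ≈ 75–91.
* **RVP** — pure myocardial projection (w = 1) for most beats, plus a
  partial-His-capture *fusion shoulder* (w down to ~0.6, Beta(1.1, 0.32)
  on [0.58, 1]): near-threshold stimulation intermittently co-captures the
  His bundle, producing occasional high-scoring RV-paced beats. The
  shoulder reproduces the printed RVP upper range (max ≈ 76–79) and is
  what anchors the lower classification cutoff: without RV-paced beats in
  the 70–78% band the optimum-threshold search has no reason to stop near
  78 and drifts to the bottom of the nonselective tail. Per-beat
  myocardial lead-weight jitter (pacing-site variation across the septum)
  supplies the wide spread, including occasional negative scores.
* **NO_CAPTURE / ATRIAL_CAPTURE** — intrinsic-morphology beats starting
  60–180 ms (escape) or 80–200 ms (PR-conducted, with a small altered
  P deflection) after the stimulus; both therefore score near 100% and
  both are LAT-positive.

Noise is 6 µV RMS per lead (8 µV for the catheter preset) — clinical
mapping-system surface channels are heavily filtered. Larger values let
the *template's own frozen noise* bias each cohort's scores in a
template-specific direction, which has no clinical counterpart at these
signal-to-noise ratios.

The two presets (`his_lead`, `catheter`) are study conditions: their
mixing distributions, jitters and weight variants were calibrated once
against this package's own scoring engine so that cohort score quartiles
match the published per-class summaries, and then frozen. They are not
user dials; `BeatGenConfig` exposes the physical knobs for new scenarios.

## Statistics

Scores divided by 100 are modelled as beta-distributed. The fit maximizes
the beta log-likelihood in log-shape coordinates (L-BFGS-B with analytic
gradient) from a method-of-moments start; values are clamped into
[ε, 1−ε] first (default ε = 1e−4, and an all-identical sample is refused
as degenerate). *Accuracy* is the mode of the fitted distribution —
interior `(α−1)/(α+β−2)` when both shapes exceed 1, boundary 0/1
otherwise, 0.5 by convention in the flat case — and *precision* is the
interval between the 2.25th and 97.5th percentiles, implemented exactly as
printed (the asymmetric 2.25 is preserved; a symmetric 2.5 variant is one
argument away). 95% CIs come from a parametric bootstrap: each replicate
redraws n values from Beta(α̂, β̂), refits with the same optimizer, and
the 2.5th/97.5th percentiles across replicates bound each statistic; one
seed governs all replicates, and more than 5% replicate failures abort
with diagnostics.

When the pipeline fits *integer* percent scores, it clamps at ε = 0.005 —
half the rounding resolution, since a recorded 100% stands for anything in
[99.5, 100]. With the generic ε = 1e−4 the ~38% of intrinsic beats at
exactly 100 drag the MLE J-shaped (β̂ < 1) and the mode to the boundary;
the rounding-aware clamp yields an interior fit (accuracy ≈ 99.4%,
precision ≈ 96.2–99.9% on the default cohort).

The optimum cutoff pair maximizes the generalized Youden objective
`J = P(RVP < c_low) + P(c_low ≤ NS < c_high) + P(S ≥ c_high)` over all
pairs of midpoints between adjacent distinct observed scores (the
objective separates in c_low and c_high, so the search is linear-time with
an O(n²) fallback when the separate optima cross). Ties are broken by the
larger minimum per-class correct fraction, then the reported cutoff is the
midpoint of the optimal plateau — the full run of equally-optimal
adjacent candidate intervals — so perfectly separated classes yield the
midpoint of the empty gap. Classification uses ≥ at both cutoffs: a score
exactly at a cutoff takes the higher class.

Diagnostic metrics are one-vs-rest sensitivity/specificity/PPV/NPV with
exact Clopper–Pearson 95% CIs; a ratio with a zero denominator is reported
as NaN, never as 0. Group comparisons use the two-sided Mann–Whitney test:
exact enumeration when both groups have ≤ 20 observations and no ties, the
tie-corrected normal approximation otherwise.

The rule-based surrogate for the conventional (electrophysiologist)
classification uses the features the criteria name: an isoelectric
stimulus-to-QRS latency (> 10 ms) with unchanged QRS duration (±10 ms)
reads as selective capture; a fused beat (latency ≤ 10 ms) is nonselective
when the last 60 ms of its QRS, offset-aligned, still correlates with the
intrinsic template at ≥ 0.5 (late activation via the conduction system),
and RV-paced otherwise. On the default His-lead cohort it agrees with
generator ground truth for ~97% of captured paced beats; ground truth for
all reported statistics is nevertheless the generator label, with the rule
as a cross-check.

## Problem sizes and determinism

The default cohorts use the published class counts (871 captured paced
beats + 354 intrinsic per tool); the test suite shares one such cohort per
session and scales bootstrap checks to 100–200 replicates, while the
analysis drivers use the full 1000. Every random choice flows through an
explicit seed (cohort seed, bootstrap seed = cohort seed + 1 unless set),
and rerunning any pipeline configuration reproduces its outputs
byte-for-byte.

## Known limitations

* One template donor per cohort: between-patient variance is
  under-represented (see above); per-patient sub-cohorts with per-patient
  templates would be the faithful extension.
* No P/T-wave realism beyond the small altered-P deflection of
  atrial-capture beats; no arrhythmia, no bundle-branch-block morphologies
  (outside the intended narrow-QRS population).
* The fusion mixing weight is an abstraction: for selective capture it
  encodes residual dissimilarity, not anatomy, and its calibrated
  distributions inherit any bias in the published summary tables.
* QRS-duration measurement (5% RMS threshold) is one of several plausible
  conventions; absolute durations shift by a few ms under alternatives,
  relative comparisons do not.
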