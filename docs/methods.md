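# Methods

## The measurement problem

Cells confined to ring-shaped adhesive microlanes (radius *R* = 50 µm, lane
width ≈ 20 µm, surrounded by cell-repellent PLL-PEG) migrate
quasi-one-dimensionally and alternate between two modes: directionally
persistent *runs* and localized, diffusive *rests*. `ringmig` turns
nucleus-centroid tracks from such assays into a small set of motility
parameters — the run speed `v_run`, the persistence times `tau_run` and
`tau_rest`, and two barrier-interaction probabilities — and bundles them
into a five-parameter "migratory fingerprint" for comparing cell lines or
drug treatments.

All analysis happens on the arc-length coordinate. After a least-squares
circle fit locates the ring center, each frame is expressed in polar
coordinates and the signed tangential velocity per frame interval is
`v_i = R (phi_{i+1} - phi_i) / dt` (µm/h, counterclockwise positive). When
the assay's design radius is known it replaces the fitted radius in this
conversion; the fitted radius is the fallback. Radial motion is ignored
throughout — in a 20-µm lane it is bounded and carries no information about
the run/rest process.

## State segmentation

Segmentation is a two-step procedure on the velocity series.

**Change-point detection** uses iterative (binary-segmentation) CUSUM
analysis. Within a candidate segment, the partial sums
`S_k = sum_{i<=k}(v_i - vbar)` peak where the mean velocity changes. A
split is accepted when the decision statistic exceeds the `(1 - alpha)`
quantile of the same statistic under random permutations of the segment
(Monte Carlo p-value `(1 + #{perm >= obs})/(B + 1)`, `B = 1000`,
`alpha = 0.05`), and the procedure recurses until nothing is significant or
segments reach the minimum length (3 velocity samples = 30 min at 10-min
frames). Two decision statistics are available:

* `scan` (default): the maximum of (a) the variance-standardized
  single-split statistic `|S_k| / sqrt(k(n-k)/n)`, whose argmax coincides
  with the least-squares split point, and (b) a windowed scan over
  partial-sum increments with windows up to 12 samples (2 h), standardized
  the same way. Both terms are in noise-SD units, so one permutation test
  calibrates the pair. The scan term exists because a plain single-change
  statistic is nearly blind to a brief state embedded in a long segment —
  in synthetic data it silently absorbed ~18 % of rest states and inflated
  `tau_run` by a quarter. When the winning statistic is a window, both
  window edges are inserted and the recursion continues in all three
  pieces.
* `range` (config option): the classical CUSUM range `max S - min S` with
  the argmax-|S| candidate, kept for comparison with the simplest version
  of the procedure.

**Classification** assigns each inter-change-point segment `run` or `rest`
by the log-log slope `alpha` of its time-averaged MSD along the lane
(positions `d_arc = R * phi`): ballistic runs have `alpha ≈ 2`, diffusive
rests `alpha ≈ 1`; the cut is the midpoint `alpha_threshold = 1.5`. MSD
lags extend to a quarter of the segment length but always to at least 5
lags (or all available on shorter segments) — on 4–7-frame windows the
quarter-lag rule left a 2-point fit whose slope misread one in five rest
windows as ballistic. Segments shorter than 8 samples still carry too
little MSD information, so after the long segments are classified their
labels are re-derived from the velocity bimodality: the run speed scale
`v_scale` is the median |state-mean velocity| of the long run segments of
the same track, and a short segment is a run iff its |mean velocity|
exceeds `v_scale / 2`. This extends the same idea the merge rule for
sub-classifiable slivers uses (velocity proximity) with a scale calibrated
per track. Sub-3-sample pieces are merged into the neighbor with the
nearest mean velocity, and adjacent pairs of sub-6-sample pieces left by
over-splitting are fused before classification.

Adjacent same-label segments are merged, with one deliberate exception:
two run segments with opposite velocity sign stay distinct. Runs are
directional states; a zero-crossing between them is a reorientation event
even when the intervening rest was too brief to resolve at the frame rate.
Without this rule, a missed 10–20-min rest could fuse a clockwise and a
counterclockwise run into a single fictitious multi-hour "run" with mean
velocity near zero, corrupting both the run-duration tail and `v_run`.
Consequently labels alternate *except* at run-direction reversals.

## Motility parameters

`v_run` is the mean over run states of the absolute within-state mean
tangential velocity, with its SEM across states; because each state mean
telescopes to net displacement over duration, it is robust to frame-wise
position noise. `v_mean` averages |v_i| over whole tracks and then across
cells; it includes rest periods and is therefore systematically smaller
than `v_run`.

Persistence times come from the empirical survival function
`S(t) = P(T > t)` of state durations. To keep finite observation windows
from biasing the estimate, only states that start at least 20 h before
their track's end are used, and the fit window ends at 20 h. `log S` is fit
by unweighted ordinary least squares at the observed duration values in
the window — above 5 h for runs, above 2.5 h for rests, where the decay is
clearly exponential — and `tau = -1/slope` with a 99 % confidence interval
mapped from the slope's. Two caveats are documented rather than patched:
the OLS interval treats the survival points as independent although a
survival curve is strongly autocorrelated, so it describes the fit, not
the full sampling variability of `tau`; and states shorter than ~2 frames
are unresolvable at 10-min sampling, which merges their flanking states
and leaves a small (~+5 %) upward bias on the fitted persistence times.

## Barrier statistics

A PEGylated gap of width `d_gap` interrupts the lane. An *encounter* opens
when the nucleus enters the zone within 50 µm of the barrier (measured from
the gap edge; a center-referenced option exists because the definition is
ambiguous in practice) and closes at the first frame outside; exit on the
entry side is a reversal, on the far side a transit, and a track ending
inside the zone leaves the encounter censored (excluded from counts). A
track that starts inside the zone has no observed entry side, so frames
before its first exit are skipped. Per-width turning/transit probabilities
carry exact Clopper–Pearson 95 % intervals.

The transit probability is modeled as
`P_trans(d_gap) = (1 - P_turn(0)) * exp(-d_gap / mu_trans)`. The decay
length is fit by one-parameter weighted least squares with the intercept
fixed at `1 - P_turn(0)` and inverse binomial-variance weights (a shrunken
proportion `(k + 1/2)/(n + 1)` keeps weights finite at empirical 0 or 1);
the 95 % CI comes from the fit covariance. `P_turn(0)` is the mean
spontaneous turning probability over 8 equally spaced virtual 50-µm
regions on barrier-free rings — equal spacing is the reproducible stand-in
for "arbitrary" placement — with a pooled Clopper–Pearson interval.

Invasion depths (maximal penetration of the lamellipodium into the PEG
area, measured independently in a blind-alley geometry) are summarized by
fitting `log S_inv` linearly over every unique depth below the largest one,
giving `S_inv(d) = s0 * exp(-d / mu_inv)`.

The run/rest occupancy profile bins all cell-frames by arc distance to the
gap edge and reports the run fraction per bin; rest accumulation in the
first bins is the signature of barrier-induced depolarization.

## The synthetic-data generator

The generator is phenomenological by design: it produces exactly the
statistical structure the analysis assumes, so every stage can be validated
against ground truth. Defaults are the reference MDA-MB-436 conditions.

| parameter | default | meaning |
|---|---|---|
| `tau_run`, `tau_rest` | 13.6 h, 6.5 h | exponential dwell means |
| `v_run` | 30.2 µm/h | run speed (constant within a run) |
| `v_run_sigma` | 0 µm/h | optional per-run speed spread (realism knob) |
| `rest_diffusion` | 20 µm²/h | rest-state diffusion coefficient |
| `rest_confinement` | 10 µm | reflecting-tether half-length of rest motion |
| `pos_noise_sigma` | 1 µm | frame-wise Gaussian jitter on (x, y) |
| `p_direction_flip` | 0.5 | probability a new run reverses direction |
| `radius`, `dt`, `duration` | 50 µm, 1/6 h, 48 h | assay geometry and acquisition |

Rest motion is confined diffusion on the arc (reflecting tether), chosen so
the rest MSD slope is ≈ 1 at sub-hour lags and saturates beyond; the
position jitter mimics nucleus-centroid wobble. Dwell times are
exponential, but state switches are snapped to the frame grid: the emitted
positions then contain no partially-mixed frame intervals and the
ground-truth segments are exact frame tilings. The rounding perturbs the
dwell distribution by at most ~`dt/(2 tau)` ≈ 1 % in Kolmogorov distance —
far below detectability at the tested sample sizes — and removes an
artifact in which sub-frame switch phases dilute every state's mean
velocity by an amount (~0.4 µm/h) no frame-level estimator could recover.
One global seed drives a splittable per-track stream (`SeedSequence.spawn`),
so adding tracks never perturbs existing ones and equal seeds give
bit-identical output.

Barrier encounters are resolved atomically: once a running cell enters the
zone heading for the gap, its approach, decision and retreat-or-crossing
are scripted, and dwell clocks are suspended inside the zone. The decision
at the gap edge is either a direct Bernoulli draw from
`(1 - P_turn0) exp(-d_gap / mu_trans)` or, under the invasion mechanism, a
drawn invasion depth compared against the gap width — which makes the link
between `mu_inv` and `mu_trans` an exact identity in the generator. After a
reversal the cell rests at the gap edge (tether on the entry side) and then
runs away, matching the observed depolarization-and-repolarization
sequence. Invasion depths are sampled by inverse CDF from the truncated
law on [2, 30] µm, with the leftover probability as point masses at the
bounds (every cell penetrates at least 2 µm; none deeper than 30 µm).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: cell-to-cell and within-run speed
variability (unless `v_run_sigma` is raised, which makes slow runs
statistically indistinguishable from rest diffusion), non-exponential dwell
structure, gradual depolarization at barriers (switches are instantaneous),
division/death, and any radial dynamics. Rest-state motion within the
encounter zone can occasionally dip a resting cell across the zone
boundary, creating a small number of analysis-level encounters the
scripted model did not intend (~3 % effect on the fitted decay length,
well inside its CI).

## Numerical and design notes

* Permutation tests use the `(1+m)/(B+1)` p-value, keeping the per-test
  level at or just below `alpha` under exchangeability; detection is
  exactly invariant under sign flip and translation of the velocity series.
* The circle fit is the algebraic (Kåsa) linear least-squares fit,
  validated in tests against a full geometric (nonlinear) fit; at 1-µm
  noise on a 50-µm ring the two agree to well under 0.5 µm.
* A local least-squares boundary-refinement pass was evaluated and
  rejected: with the rest state ~2× noisier than the run state, the
  pairwise LS split is biased and measurably worsened recovery.
* Survival curves are step functions evaluated at observed durations;
  `S(0) = 1` and monotonicity are asserted on every curve.
* Degenerate inputs raise typed errors (collinear circle fits, zero-radius
  frames, all-censored survival input, non-decaying tails, degenerate
  invasion depths); short velocity series return an empty change-point set
  with a warning.
* On 600-track ensembles at the default conditions the pipeline recovers
  `tau_run` within ~4 %, `tau_rest` within ~12 %, and `v_run` within
  ~0.5 µm/h; the residual positive bias on the persistence times is the
  sub-resolution-state merging discussed above. Problem sizes used in the
  acceptance checks (600 tracks for parameter recovery, 300 encounters per
  gap width, 500 invasion depths) were chosen so Monte Carlo scatter is
  small against the stated tolerances.
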