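# Methods

This note documents the models, numerical choices and known limits of
each stage of the pipeline. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic stimuli

The original study stimuli (virtual-reality movies of a train in a
landscape) are not distributable, so `stimuli` renders parametric 2D
stand-ins that preserve the *motion structure* of the five conditions:

| condition | background | object |
|---|---|---|
| Offboard | static | translates (pure object-motion) |
| Onboard | global coherent flow | none (pure self-motion) |
| Joint | global coherent flow | fixed screen position |
| Disjoint | global coherent flow | translates independently |
| Static | 4 held frames (0.75 s each) | — |

The background is Gaussian-filtered white noise (σ = 2 px, wrap-around
boundaries) scaled to [0, 255]; filtering in wrap mode makes integer
`np.roll` shifts *bit-exact*, so the dense ground-truth flow attached
to every rendered movie is exact rather than approximate. The object
is an independent texture draw with the same amplitude and correlation
statistics as the background: with equal statistics, the MAD cost of
matching a mixed object/background block is on a single scale and the
block is claimed by whichever surface covers more of it. Occlusion and
disocclusion pixels are assigned the object displacement in the ground
truth — a simple, testable convention.

Default trial-generator conditions (60 trials, 15 per motion
condition): background speeds Onboard 3, Joint 4, Disjoint 5 px/frame
pair (±1 px per-trial jitter), Offboard object speed 2 px/frame pair.
These programmed speeds encode the ordering of motion energy measured
on the original movies — most in Disjoint, least in Offboard, Joint
above Onboard — which the tests require the *estimates* to reproduce.
Frames default to 128 × 128 px (the full-scale option is 640 × 480,
matching the study's video geometry; small frames keep the suite fast
while leaving 64 macroblocks per frame, enough that single-block
quantisation cannot dominate the movie summaries). Object trajectories
run horizontally inside a macroblock-aligned band, and headings avoid
the ±180° discontinuity of the linear orientation convention (below);
Disjoint flow is vertical so object and background orientations are
maximally distinct without wrapping.

What the generator does **not** emulate: perspective (expanding or
curvilinear) flow, depth structure, photometric noise, occlusion by
scene geometry, and sub-pixel motion. Passing tests therefore show
that the measurement chain is correct for piecewise-translational
scenes, not that the matcher is accurate on arbitrary natural video.

## Block matching

Frames are tessellated into N × N macroblocks (N = 16; partial border
blocks are dropped, so 640 × 480 frames give 30 × 40 = 1,200 blocks).
For each consecutive frame pair, each block's displacement within
±p px (p = 7) minimises the mean absolute difference

MAD = (1/N²) Σᵢⱼ |Cᵢⱼ − Rᵢⱼ|,

where pixel pairs with |Cᵢⱼ − Rᵢⱼ| ≤ ZMT (the zero-motion threshold)
contribute zero to the sum while the divisor stays N². ZMT is
estimated as the 95th percentile of absolute frame-to-frame
differences over a user-identified still region; for the noiseless
synthetic movies it is 0 and plays no role.

Two search strategies share one candidate-evaluation core:

* `full_search` scans the whole (2p+1)² window — the oracle.
* `arps_ds` evaluates the adaptive rood pattern (centre, four arms of
  length max(|pred|, 1), the predicted vector), then iterates
  large-diamond steps re-centred on the running best until the centre
  wins, then one small-diamond refinement.

Ties are broken deterministically: lower cost, then smaller Euclidean
displacement, then row-major order. Candidate displacement handling at
frame borders is configurable: `wrap` (default) indexes the reference
toroidally — exact for the periodic synthetic textures and required
for border blocks of a globally translated frame to have a valid
optimum at all — while `clip` restricts candidates to stay inside the
frame, the right choice for real footage.

Field estimation walks blocks left-to-right, top-to-bottom with the
left neighbour's vector as prediction (the classic spatial-coherence
assumption). Three pragmatic seeding choices stabilise the greedy
search without touching the per-block algorithm: the first block of
each row predicts from the block above; each block also evaluates the
above-neighbour's vector and its own vector from the previous frame
pair as extra initial candidates (coherence in space extends to time);
and the top-left block of each pair — the root of the prediction chain
— is matched exhaustively (one exhaustive block per frame pair, ≈2% of
the work at 64 blocks), so a poor initial guess cannot propagate.

**QoM** is the mean vector amplitude over blocks and frame pairs (with
equal-sized blocks the block mean equals the pixel mean). **SoM** is,
per frame pair, the standard deviation of orientations
atan2(dy, dx) ∈ (−180°, 180°] over blocks with nonzero amplitude,
averaged over pairs; pairs with no moving block are excluded, and a
movie with no motion at all reports SoM = 0 with an `all_zero` flag.
The SD is linear, not circular, so orientations near ±180° are
wrap-sensitive — a known property of the convention, which the
stimulus generator simply avoids.

**Known limitation.** A block containing comparable shares of two
surfaces has a bimodal cost landscape, and the greedy ARPS+DS descent
occasionally settles in the wrong basin where exhaustive search does
not (observed in roughly 1% of generated trials, always at the single
object-bearing block of Disjoint movies). Per-movie QoM error stays
below 0.1 px in all observed cases; per-movie SoM error can then
exceed the usual ≤5° by a few degrees for that movie. Condition-level
means, which is what the GLM consumes, are unaffected. The exhaustive
strategy never shows the effect and `arps_ds` never achieves a lower
cost than it (this bound is asserted over thousands of random
instances).

A documented discrepancy: at the stated 640 × 480 / 16 px geometry the
tessellation yields 1,200 blocks, not the 1,350 sometimes quoted for
this configuration; the implementation follows the arithmetic.

## Scan design

One scan = 75 non-target trials (15 per condition) + 5 one-back
targets, 3 s each, intertrial interval 0, a 10 s fixation block after
every 10 trials: 320 s, i.e. 160 volumes at TR = 2 s. Exact
first-order counterbalance is impossible for 75 trials (74 real
transitions over 25 ordered pairs), so the sequence is the node walk
of an Eulerian circuit on the complete 5-node digraph with self-loops
and 3 parallel edges per arc: every ordered pair occurs 3 times except
the single wrapped pair (2), giving imbalance ≤ 1 — the closest
realisable reading. Targets are exact duplicates of their predecessor
(the "same movie twice" one-back event), inserted with ≥ 12 trials
between them (≈ once per minute), and are excluded from the balance
since they are post-hoc duplications. Events files follow the BIDS
events TSV convention.

## GLM

Regressor order (15 task regressors): movement, movement×QoM,
movement×SoM, Offboard, Onboard, Joint, Disjoint, Static,
Offboard×OMS, Onboard×SMS, Joint×OMS, Joint×SMS, Disjoint×OMS,
Disjoint×SMS, responses. The movement regressor spans every non-Static
trial; SMS/OMS modulate the conditions in which the corresponding
sensation exists (no modulators for Static). Events are delta sticks
on a 0.1 s microtime grid convolved with the canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions,
undershoot ratio 6, 32 s kernel, unit peak — peaking at 5.0 s) and
sampled at volume times. Modulator values are mean-centred within
scan before multiplication, and every modulated regressor is serially
residualised against all regressors listed before it, so each carries
only variance unexplained by earlier terms. Fixation is deliberately
unmodelled and forms the implicit baseline.

The full model is **rank deficient by construction**: the movement
event train is exactly the sum of the four motion-condition trains.
This mirrors the original modelling environment, which silently uses a
pseudoinverse. Here the contract is explicit: `fit_glm_ar1` rejects
rank-deficient designs by default (naming the collinear regressors via
pivoted QR), and `rank_policy="pinv"` selects the deterministic
minimum-norm solution — under which all modulator betas, the response
beta and every between-condition difference are unique and estimable,
which covers every downstream statistic. Recovery simulations use the
identifiable variant with the redundant movement regressor omitted.

Fitting: each series is grand-mean scaled to 100 (so betas are percent
signal change at regressor peak); drift is removed by projecting out
the discrete-cosine basis of all components with period above 128 s
(constant included) — note a projection filter attenuates only
components in its basis, so an off-basis slow cosine (e.g. period
256 s in a 320 s scan) is damped but not annihilated; a single AR(1)
coefficient per scan is estimated from the pooled lag-1
autocorrelation of the OLS residuals and both sides are whitened with
the AR(1) square-root-inverse transform before refitting.

The raw residual autocorrelation is biased toward zero because the
residual-forming projection absorbs autocorrelated noise (with this
design, white noise residuals show ≈ −0.12 at lag 1). The estimator
therefore moment-matches: with R the residual projector and C(ρ) the
AR(1) correlation matrix, the expected ratio tr(L R C R)/tr(R C R) is
inverted for ρ by bisection; Toeplitz structure reduces each
evaluation to a polynomial in ρ via precomputed diagonal sums. At the
study's scan length this recovers ρ = 0.4 with bias < 0.01, where the
uncorrected ratio returns ≈ 0.24. Consistently, whitened-residual
autocorrelation is judged against the white-noise projection benchmark
rather than against zero.

## BOLD simulation

Y = 100 + centred(X·β) + centred(drift) + AR(1) noise, one column per
region; β in PSC units, drift as the slowest scan cosines (exactly
what the high-pass filter targets), stationary AR(1) noise with
marginal SD `noise_sd` (default 1 = 1% of baseline, a typical ROI
noise level at 3 T). Multi-subject simulations draw subject betas
from a normal distribution around group means. The rating generator
produces 0–10 visual-analog SMS/OMS scores with the behavioural
pattern programmed in (Onboard strongest self-motion sensation,
Static near floor, object-motion sensation flat across object-moving
conditions; between-subject SD 1).

## Regional statistics

The regional unit of analysis is a subjects × conditions table of PSC
values restricted to the four motion conditions (Static is plotted but
never analysed). The repeated-measures one-way ANOVA partitions sums
of squares into condition, unit and residual; F = MS_cond/MS_resid
with df (k−1, (k−1)(n−1)) — (3, 42) for 15 matched trial sets,
(3, 39) for 14 subjects. An all-constant table reports F = 0, p = 1.
The repeated-measure unit for the QoM/SoM ANOVA is the matched trial
set (the df-consistent reading); for behavioural and regional ANOVAs
it is the subject, with hemispheres averaged beforehand.

Duncan's multiple range test sorts the means and tests spans
widest-first: a span of r means is significant when its range exceeds
q(1−(1−α)^(r−1), r, df₂)·√(MS_resid/n), with studentized-range
quantiles from numerical integration (`scipy.stats.studentized_range`,
cross-checked against Monte-Carlo draws in the tests); no pair inside
a non-significant span is ever declared significant (step-down
protection). α defaults to .05 and is configurable. For k = 2 the
protection level is α and the test reduces to an unprotected LSD
comparison.

Modulator loadings are tested against zero with one-sample t-tests at
the Bonferroni level α/N over N regions; a zero-variance nonzero-mean
cell is reported as significant with infinite t and a `degenerate`
flag. The flow-parsing index is the mean Joint − Onboard difference
with a paired t-test; a region is flow-parsing-capable when the index
is positive and significant. Profile classification uses the Duncan
decisions: Onboard > Offboard → self-preferring, Offboard > Onboard →
object-preferring, neither but Disjoint above both pure conditions →
complex-preferring, otherwise unclassified.

## Problem sizes

Default test and acceptance workloads: 128 × 128 movies of 6 frames,
15 trials per condition; 160-volume scans at TR 2 s; 200 replicate
scans for GLM recovery; 2,000 null tables for the ANOVA size check.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping a full run in tens of seconds.
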