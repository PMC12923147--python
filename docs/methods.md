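# Methods

This note documents the quantities courtmetrics computes, the generative
model behind its synthetic data, and the numerical and design choices that
were genuinely open.

## Court frame and grid

Coordinates are court centimetres with the origin at one corner: x runs
along the endline (0–1500 cm), y along the sideline (0–1100 cm). Frames are
0-based at 20 fps (`t = frame × 0.05 s`); a trial is at most 302 frames
(the 15-s play limit plus the starting frame). Raw pixel data are mapped to
this frame by a projective (homography) transform estimated from ≥ 4
non-collinear point correspondences with the normalized direct linear
transform (scikit-image); calibration residuals are reported in cm and the
matrix is normalized to `H[2,2] = 1`.

The occupancy grid divides the endline into 15 and the sideline into 10
intervals — 150 cells of 100 cm × 110 cm. A cell of roughly one metre
matches the space a player needs for an action (dribble, shot, screen), so
cell transitions reflect tactically meaningful relocation rather than
postural jitter. Cells are half-open `[k·w, (k+1)·w)` with the final cell
closed; ids are 1-based, row-major from the origin corner.

**Out-of-bounds handling.** Players do step over lines, and measurement
noise pushes boundary positions out by a few cm. Such frames are clamped to
the nearest boundary cell and counted (with a logged warning) rather than
dropped: entropy compares trials of differing lengths through normalized
occupancies, and silently dropping frames would bias *p* for trials played
near the lines.

## Occupancy entropy

Per trial and agent, cell counts are normalized to probabilities and
summarized as `H = −Σ p_i log₂ p_i` bits, with `0·log 0 ≡ 0`. `H` ranges
from 0 (single cell) to log₂ 150 ≈ 7.229 (exactly uniform occupancy). No
smoothing, filtering, or time-windowing is applied to the positions before
gridding — at 20 fps over ≤ 15 s there is too little data to smooth without
distorting the occupancy profile. Entropy is computed for the offensive
roles by default; defensive entropies are available by option. The measure
is marginal (sequence order does not matter): it quantifies *where* a
player's time went, not the transition dynamics.

## Spacing variability (CV)

For the key role O3, the Euclidean distance to each of O1, O2, D1, D2, D3
is computed per frame; a trial yields five records of mean, standard
deviation, and `CV = sd/mean`. The **sample** (n−1) standard deviation is
used — the default of the numeric environments these analyses are usually
run in; at ~160–300 frames per trial the n vs n−1 distinction is far below
reporting precision, but the choice is fixed for reproducibility. A zero
mean distance (agents coincident throughout) is rejected as degenerate. The
simulated random-walk condition is excluded from the CV analysis: its
agents are not play-level interacting and pair spacing has no tactical
meaning there.

## Random-walk null condition

Each agent starts in the cell containing its real initial position (taken
from the matched high-expertise trial) and at every frame moves exactly one
cell up/down/left/right. The boundary rule is uniform choice among the
*feasible* moves (`resample_feasible`), so the agent always moves when it
can — the closest realizable reading of "moves one cell per frame" on a
bounded grid. The alternative (`stay_if_blocked`: draw among all four
directions, stay when blocked) is available for sensitivity analysis; it
only changes behavior within the 44 edge cells. Positions are emitted at
cell centers — entropy depends only on the cell sequence, so the
within-cell position is a reporting convention, not a modeling choice.
Simulated trials mirror the reference condition's (session, trial, role)
structure and frame counts (capped at 301 frames = 15 s), keeping
downstream model designs balanced.

Seeding is hierarchical: a single master seed spawns one child generator
per (session, trial, role) through `numpy.random.SeedSequence`, so an
individual trial can be re-simulated in isolation and the full condition is
byte-reproducible.

## Synthetic experiment generator

The generator emulates the *structure* of a small-sided field experiment —
six agents, 3 sessions × 7 trials per condition, 15-s trials, balanced
layout — with movement regimes ordered by diversity:

* `stationary` — hold a position;
* `scripted_play` — run a waypoint script at constant speed (piecewise
  linear, ~250 cm/s with per-trial lognormal speed jitter and Gaussian
  waypoint jitter), then hold at the final waypoint;
* `play_mixture` — per trial, sample one play from a weighted repertoire
  (hand-off, pick-and-roll, deep-corner run, goal cut, stay-in-place
  templates with hard-coded waypoints);
* `shadow` — defenders track their matched attacker displaced 80 cm toward
  the goal (an arbitrary but fixed guarding distance; only offensive
  entropy is analyzed);
* `random_walk` — the null condition above.

Two noise layers are distinguished. **Measurement noise** is isotropic
Gaussian per frame and axis, parametrized by per-axis mean absolute error
(default 2.390 cm × 1.557 cm, the accuracy scale of bird's-eye video
tracking) converted to a standard deviation via the half-normal relation
`sd = mae·√(π/2)`. **Behavioral wander** is a per-axis Ornstein–Uhlenbeck
displacement around the scripted path (default amplitude 90 cm, correlation
time 2 s in the bundled design; 0 unless enabled) representing the
continuous adjusting and repositioning of live play. Without wander a
scripted trial occupies only the handful of cells on its path and entropies
sit far below what live tracking shows; with it, structured play lands in
the realistic 2.5–3.5-bit range while remaining clearly below the walk's
~6 bits. Paths (including wander) are clipped to the court before
measurement noise is added.

The bundled four-condition design encodes the diversity contrast the
analysis is meant to resolve: a diverse five-play repertoire for the key
role (high expertise), a slightly narrower and sloppier repertoire
(low expertise before coaching), the key role locked to the single coached
deep-corner pattern executed tightly (low expertise after coaching), and
the random walk. What passing tests on these data show is that the pipeline
*detects movement-diversity differences of realistic size under realistic
noise in a balanced repeated-measures design* — not that any particular
real population behaves this way: the generator has no ball, no collision
avoidance, no learning within a session, and defenders who shadow rather
than defend.

A second, outcome-level generator draws per-trial entropies directly from
the linear mixed model below (condition × role cell means, session and
session-within-trial random intercepts, residual; default variances 0.008 /
0.033 / 0.565 on the bits scale) and is used for parameter-recovery and
calibration testing of the statistics module.

## Mixed-model comparison

Outcomes (entropy per role, or CV per pair) are analyzed on a long table
`condition, session, trial, unit, y` with a four-model ladder:

| model | fixed | random intercepts |
|---|---|---|
| `rand_role` | condition | unit |
| `rand_sess` | condition | session, session:trial |
| `basic` | condition | unit, session, session:trial |
| `interactive` | condition × unit | session, session:trial |

Session and trial-within-session labels are treated as shared factor levels
across conditions (3 and 21 levels), matching the balanced repeated-measures
layout. Models are compared sequentially by likelihood-ratio tests on ML
fits, with AIC = −2·logLik + 2·(p + q + 1) per fit; the smallest-AIC model
is selected. The first comparison (`rand_role` vs `rand_sess`) is **not
nested**; when the larger-df model has the lower likelihood its χ² is
reported clamped at 0 with p = 1 and the pair flagged `non_nested` in the
output, rather than silently reinterpreted.

The selected model is refit by REML with treatment coding (default
baselines: the before-coaching condition and role O1 / pair O3–O1).
Estimation is an in-house variance-component engine: the profiled ML or
REML criterion is minimized over the variance components by L-BFGS-B with
analytic gradients (`d(−2ℓ)/dθ_k = tr(P G_k) − u′G_ku`), dense linear
algebra (problem sizes are a few hundred rows), bounds at zero, and
optimizer tolerances of 1e-12 (criterion) / 1e-8 (gradient). A variance at
the boundary is flagged (`boundary`), not fatal. The engine is validated in
the test suite against statsmodels MixedLM (single grouping) and against R
lme4/lmerTest (full model: estimates, SEs, variance components, ML AIC and
Satterthwaite df agree to 1e-4 or better).

**Degrees of freedom.** t and F tests use the Satterthwaite approximation:
for a contrast c, `df = 2φ²/(g′Ag)` with `φ = c′(X′V⁻¹X)⁻¹c`, g its
finite-difference gradient in the variance components, and A twice the
inverse REML-criterion Hessian (Hessian by central differences of the
analytic gradient; one-sided at a zero-variance boundary). Multi-df F tests
pool per-eigencontrast dfs through `E = Σ dᵢ/(dᵢ−2)`, `ddf = 2E/(E−q)`. In
the balanced design this reproduces the familiar between-within values
(e.g. 220 = 252 − 12 − 20 for within-cell contrasts).

**Type III ANOVA.** Effects (condition, unit, interaction) are tested by
Wald F on a sum-to-zero-coded REML refit — the parametrization under which
Type III hypotheses are marginal — with partial
η² = F·df₁/(F·df₁ + df₂).

**Contrasts.** All C(k,2) pairwise condition differences are formed within
each unit level as differences of cell-mean predictions; p-values are
Bonferroni-multiplied by the family size (6 for four conditions, 3 for
three) and capped at 1. If the selected model has no interaction the
contrasts do not depend on the unit; one marginal family is returned with a
warning. The pipeline emits per-unit contrast files only when the
interactive model was selected *and* its interaction is significant at the
configured α, mirroring standard practice of not decomposing an absent
interaction. A stratified permutation test (condition labels permuted
within sessions; exhaustive enumeration when there are ≤ 20 000
arrangements, Monte Carlo otherwise) is provided as a distribution-free
fallback for any single comparison.

## Calibration evidence computed by the suite

The acceptance tests (tests/test_acceptance.py) recompute, at the full
design size of 252 records: pooled 95% CI coverage of the fixed effects
across 500 simulated replicates (required to land in [0.93, 0.97]),
absence of systematic bias (each coefficient's mean estimate within
Monte-Carlo error of truth), uniformity of the Type III interaction p-value
under a null interaction (Kolmogorov–Smirnov across 200 replicates), and
dominance of the random-walk condition's mean entropy over every structured
regime in each of 100 replicates. Family-wise error control of the
Bonferroni contrasts is checked on null data in the unit suite. Monte-Carlo
sizes for the remaining property tests (e.g. 40 replicates for
AIC-selection behavior) were fixed from binomial-error considerations: the
expected selection rate under a null is ≈ 0.81 — AIC accepts a spurious
one-df improvement whenever its χ²₁ exceeds 2, probability ≈ 0.157 — and
thresholds sit three binomial SEs below the expectation.

## Known limitations

* The entropy is occupancy-marginal; two trials with identical cell
  histograms but different visit orders are indistinguishable.
* Grid resolution is a tuning choice: finer grids inflate entropy through
  postural jitter, coarser grids saturate. The 1-m default is motivated
  above but not estimated from data.
* The synthetic generator's realism claims are limited to the ordering and
  scale properties stated; it is not a behavioral model of basketball.
* Satterthwaite df rest on an asymptotic variance of the variance
  components; with only 3 session levels the session-variance information
  is weak, and intercept dfs inherit that uncertainty (as they do in the
  reference R implementations).
* The ladder's first comparison is non-nested; its printed χ² is a
  reporting convention, not a calibrated test.
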