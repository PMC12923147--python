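# courtmetrics

Quantitative analysis of collective movement in small-sided basketball
(3-on-3) from multi-agent tracking data. The package is aimed at researchers
in sports science, cognitive science and collective-behavior analysis who
want to quantify **how hard an offense is to anticipate** and compare that
quantity across experimental conditions (e.g. expertise levels, before/after
coaching, simulated baselines).

## What it computes

**Occupancy entropy.** The half-court (15 m along the endline x 11 m along
the sideline) is partitioned into a grid of 15 x 10 = 150 cells of roughly
1 m side. For each trial and player, the per-frame (20 fps) cell occupancies
are normalized into a probability vector *p* and summarized by the Shannon
entropy

&nbsp;&nbsp;&nbsp;&nbsp;H = −Σᵢ pᵢ log₂ pᵢ&nbsp;&nbsp;&nbsp;&nbsp;(bits, 0 ≤ H ≤ log₂ 150 ≈ 7.23)

H = 0 for a player who never leaves one cell; high H means time spread over
many cells — movement that is costly for a defender to predict.

**Spacing variability (CV).** For the key offensive role (O3, the player who
intervenes in and adjusts the two-man game), the frame-wise Euclidean
distance to each of the five other players is reduced to a coefficient of
variation CV = sd(d)/mean(d) per trial — near 0 for rigid spacing, large
when the key player alternates between tight two-man actions (hand-off, pick
and roll) and deep spacing (corner runs).

**Random-walk null.** A simulated condition in which each agent starts in
the grid cell of a real initial position and moves one cell per frame in a
uniformly random feasible cardinal direction. Its entropy is the practical
ceiling against which structured play is judged.

**Mixed-model comparison.** Per-trial outcomes are compared across
conditions with a ladder of linear mixed models (random intercepts for
role/pair, session, and trial nested in session; fixed condition and
condition x role effects), selected by sequential likelihood-ratio tests and
AIC, followed by a Type III ANOVA with partial η² and Bonferroni-adjusted
pairwise condition contrasts within each role. Estimation is REML (ML for
the likelihood-ratio tests) with Satterthwaite denominator degrees of
freedom, matching the conventions of the R mixed-model stack (lme4 /
lmerTest / emmeans), against which the engine is tested.

A synthetic-data module generates full tracking experiments (six agents,
3 sessions x 7 trials per condition, scripted coordination plays, play
mixtures, defender shadowing, realistic ~2.4 cm x ~1.6 cm measurement
noise), so every stage of the pipeline is testable without access to any
particular study's recordings.

## Worked example

```python
import courtmetrics as cm

data = cm.generate_experiment(cm.default_design(seed=42))   # synthetic study
ent = cm.entropy_table(data)                                 # H per trial/role
print(ent.groupby(["condition", "role"])["H_bits"].mean().unstack().round(3))

ladder = cm.fit_ladder(ent, "H_bits", "role")
print(ladder.table[["model", "k", "AIC", "chi2", "df", "p"]].round(3))
print("selected:", ladder.selected)

fit = cm.fit_optimal(ent, "H_bits", "role")                  # REML, treatment coding
contr = cm.pairwise_contrasts(fit)
print(contr[(contr.role == "O3") &
            (contr.comparison == "low_after_tips vs high_expertise")]
      [["role", "comparison", "estimate", "se", "df", "t", "p_adj"]]
      .round(3).to_string(index=False))
```

Output:

```
role                O1     O2     O3
condition
high_expertise   3.407  3.325  3.410
low_after_tips   3.406  3.329  2.483
low_before_tips  3.337  3.443  3.454
random_walk      6.078  5.984  6.043
         model   k      AIC    chi2   df      p
0    rand_role   6  216.826     NaN  NaN    NaN
1    rand_sess   7  226.665   0.000  1.0  1.000
2        basic   8  220.826   7.838  1.0  0.005
3  interactive  15  141.178  93.649  7.0  0.000
selected: interactive
role                       comparison  estimate    se      df      t  p_adj
  O3 low_after_tips vs high_expertise    -0.927 0.095 234.748 -9.725    0.0
```

Reading this: random-walk agents approach the entropy ceiling (~6 bits)
while structured play sits near 3.4 bits; the key role O3 is markedly less
diverse (2.48 bits) in the condition locked to a single coached pattern
than in the diverse-repertoire condition (3.41 bits). The ladder prefers
the interactive model (condition x role fixed effects; smallest AIC), and
the Bonferroni-adjusted contrast confirms the O3 difference (estimate
−0.93 bits, t(234.7) = −9.7, adjusted p < 0.001).

The same analysis runs from the shell:

```bash
courtmetrics synth --seed 42 --out synth.csv
courtmetrics entropy --tracking synth.csv --out entropy.csv
courtmetrics fit --table entropy.csv --outcome entropy --out-dir reports/
courtmetrics run --seed 42 --out results/        # full pipeline + manifest
```

## Layout

```
src/courtmetrics/
  tracking.py     tracking-table I/O, validation, pixel->court homography
  occupancy.py    court grid, occupancy histograms, entropy tables
  distance_cv.py  key-role pair distances and CV records
  random_walk.py  grid random-walk null condition
  synthetic.py    trajectory + outcome-level generators
  lmm.py          REML/ML variance-component engine, Satterthwaite inference
  stats.py        model ladder, Type III ANOVA, contrasts, permutation test
  pipeline.py     one-command orchestration with manifest + config hashing
  cli.py          `courtmetrics` command-line interface
```

See `docs/methods.md` for the statistical model, its assumptions, and the
numerical choices.
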