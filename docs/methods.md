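# Methods

## The model

Serum PSA (ng/ml) is treated as the sum of the contributions of three
tumor-cell compartments: androgen-dependent cells `x1`, reversibly
castration-resistant cells `x2` (arising by adaptation, able to revert to
androgen dependence when therapy is withdrawn), and irreversibly
castration-resistant cells `x3` (arising by mutation, unable to revert).
Two linear systems govern the dynamics.  While hormone therapy is applied,

    dx/dt = W1 x,   W1 lower triangular

(AD cells are suppressed and leak into both resistant compartments); while
it is withheld,

    dx/dt = W0 x,   W0 zero except the diagonal and the (1,2) entry

(reversibly resistant cells flow back to the AD compartment; the
irreversible clone evolves in isolation).  Fitting and simulation use the
Euler discretisation with a fixed step of one day, so the canonical
parameters are the ten structurally nonzero entries of the daily
multiplier matrices `D1`, `D0`, related to the rates entry-wise by
`w_ij = d_ij` off the diagonal and `w_ii = d_ii - 1` on it.  Horizons
stated in weeks or months convert as 1 week = 7 days, 1 month = 30 days
(so 36 months = 1080 days).  Simulated PSA is stored in double precision
and never clipped: divergence is meaningful — it is the model's
representation of relapse.

Pharmacokinetics of the depot injections is deliberately ignored (therapy
is modelled as instantaneously on or off), and there is no stochastic
cell-population or androgen-concentration dynamics.

## Fitting

One patient's data are observation days `t_k`, PSA values `p(t_k)`
(k = 1..K), and the recorded on/off treatment intervals.  The fitted
quantities are the ten daily multipliers plus the three initial
compartments — 13 values.  The cost is

    [ sum_k |p(t_k) - psa_hat(t_k)| + eps2 ] / (K + eps1)  +  penalties

with `eps1 = 1e-9`, `eps2 = 1e-3` guarding the division, `psa_hat` the
simulation under the recorded treatment history, and one-sided penalty
terms `h(z) = 100 (1 - z)` for `z < 0` (else 0) enforcing: non-negative
simulated compartments at the observation days; every multiplier
non-negative; diagonals in [0.8, 1.2] with `d1_33 >= 1` (the irreversible
clone is never suppressed below replacement while on therapy — this is
what lets the model relapse); off-diagonals in [0, 0.1]; column sums in
[0.8, 1.2]; and the relapse-under-continuous-suppression constraints —
total PSA of an all-on simulation from the same initial state at most
2 ng/ml at day 360 and at least 10 ng/ml at day 1800.  Two redundant
penalty terms of the original formulation (the `[0.8, ...]` lower bound on
`d1_33` next to the `>= 1` bound, and off-diagonal lower bounds listed
both collectively and individually) are kept verbatim; they are zero
wherever the binding terms are.

The cost floor is analytic: `cost >= eps2 / (K + eps1)`, with equality
exactly when all resampled residuals and all penalties vanish.

Minimisation uses `scipy.optimize.differential_evolution`
(best/1/bin, mutation 0.7, crossover 0.9, tolerance 1e-8), with the
population given as an explicit array so its size is exact: 60 individuals
for 2000 generations by default, 40 for 600 in the reduced-budget
profile.  The reduced profile was chosen as the smallest budget at which
refits of synthetic series reliably reach the same cost plateau as the
full budget; materially smaller budgets leave parameter sets severalfold
above it, and the resulting half-converged dynamics systematically
misclassify.  The initial population is drawn inside the penalty-feasible
box (the search bounds are slightly wider — diagonals [0.75, 1.25],
off-diagonals [-0.05, 0.15], initial compartments [0, 1.5 x max observed
PSA] — so the penalties, not the box, define feasibility), and the best
member is polished with L-BFGS-B.  The objective evaluates the whole
population at once using batched per-segment 3x3 matrix powers; the
recorded cost, end error, and end state of each fit are recomputed through
the plain day-by-day simulator, which is also the path the data generator
uses, so a zero-residual refit hits the cost floor exactly.

Because 13 parameters against a short noisy series are over-parameterised,
no single fit is trusted.  `fit_ensemble` repeats the fit on B = 100
(default) bootstrap resamples of the observation *time points* (uniform
with replacement, per-replicate seed = master seed + replicate index) over
the first 2.5 treatment cycles (on-off-on-off-on; observations beyond the
end of the third on-interval are dropped).  The absolute PSA error at the
last observation of that window is the acceptance statistic: members with
error above 5 ng/ml are flagged and excluded from scheduling (if no member
passes, the single best member is used, with a logged warning).
Non-convergence (positive penalties at the end of the budget) is reported
as a flag, never an exception.

## Classification

A parameter set is **type (i)** if some mixture `a W1 + (1-a) W0` with
`a` in (0, 1) has all eigenvalue real parts negative: an intermittent
schedule spending about that fraction of time on therapy then contracts
the tumor indefinitely.  Failing that, it is **type (ii)** if some
compartment grows strictly slower off treatment than on it
(`w1_ii > w0_ii`), so off-periods delay the inevitable relapse; otherwise
it is **type (iii)** and continuous suppression is preferable.  The
combination is generally non-symmetric, hence the real-part reading;
negativity is strict (tolerance 0).

The mixture is searched on a fixed 999-point grid (step 0.001).  Because
every combination inherits the model's sparsity (its third column is zero
off the diagonal), the spectrum is the combined `x3` rate plus the two
eigenvalues of the top-left 2x2 block, which the implementation evaluates
in closed form; a dense eigensolver path is kept for cross-checking and
agrees to 1e-12.  `is_type_i` reports the *first* grid mixture that
works; `suppressive_alpha` reports the abscissa-minimising one, which is
the meaningful duty-cycle recommendation for a type-(i) patient (the first
witness sits at the edge of the admissible window with vanishing margin).

Patients are labelled by the most frequent type across their bootstrap
ensemble; ties break toward the higher-numbered (clinically less
favorable) type.  Note one structural asymmetry: the per-member type-(i)
test takes a minimum of a noisily estimated abscissa curve over the grid,
and a minimum of a noisy function is biased downward, so members of
borderline non-suppressible (type-ii) truths lean toward type (i).  The
modal vote absorbs this only when fits are well converged — the origin of
the reduced-profile budget above.

## Scheduling

Post-fit simulations start from each member's simulated state at the end
of its 2.5-cycle fitting window.  Therapy over a 1080-day horizon is
assigned in 168-day (24-week) blocks — seven blocks, the last truncated
to 72 days.  All 2^7 = 128 assignments are enumerated; each is scored by
the **maximum** total PSA at the horizon across accepted members, and the
minimiser is returned (ties toward more on-blocks, then lexicographically
smallest).  Exhaustiveness makes the optimum exact for the given ensemble;
a guard rejects searches beyond 20 blocks.  The mean-dynamics variant
averages the accepted members' multipliers and end states and optimises
that single system; it ignores the ensemble spread and is systematically
over-optimistic, which is exactly the comparison it exists to expose.

Comparison strategies: CAS (all-on) and the conventional intermittent
protocol — stop on the first day the current on-period is at least 40
weeks (280 days) old *and* PSA is below 0.1 ng/ml; resume when PSA reaches
1 ng/ml (both conditions evaluated daily; the stop is a conjunction).
Time-under-control for a patient is the first day the maximum PSA across
accepted members reaches 100 ng/ml, censored at the horizon; cohort curves
are the per-patient empirical fraction still under threshold, compared
with a two-sided log-rank test (the time-to-event test recorded in the
output metadata; any other censoring-aware test could be swapped in).

## Synthetic cohorts

The fitted trial series are privacy-restricted, so the generator emulates
their shape.  Per patient: a ground-truth parameter set is
rejection-sampled uniformly from the feasible box until it classifies as
the requested type and satisfies the relapse-under-continuous-suppression
constraints from its drawn initial state; the conventional
threshold-triggered protocol is simulated to produce the on/off history; K
~ round(N(33.7, 17.1^2)) clamped to [4, 103] observation days are placed
on a jittered regular grid (the real spacing distribution is unpublished);
observations are the simulated PSA times multiplicative log-normal noise
(sigma = 0.1 by default; PSA spans orders of magnitude, so additive noise
would break non-negativity), clipped to the published [0, 220] ng/ml
range.  Clinical-status and Gleason-like labels are sampled conditional on
the true type with the published cross-tabulation rows as probabilities —
a simulation convenience for exercising the contingency machinery, not a
claim about the real cohort.

Generation uses the *trial* protocol — therapy stopped below 4 ng/ml
after the minimum on-period and resumed at 10 ng/ml — rather than the
0.1/1.0 thresholds of the simulated conventional-IAS comparison strategy.
The distinction matters: under a 0.1 ng/ml stop threshold any resistant
clone must remain below 0.1 ng/ml through three successive nadirs for 2.5
cycles to exist, which pushes every type-distinguishing feature below the
measurement noise and makes ground-truth recovery impossible in principle.
The source trials' patients were treated (and measured) at the 4/10 scale,
where resistant-clone kinetics are visible.

Realism constraints narrow the uniform box, chosen once on clinical
grounds: AD cells decline on-treatment (`d1_11 <= 0.99`) and regrow
off-treatment (`d0_11 >= 1.005`) — without regrowth the protocol never
resumes and no patient cycles; the irreversible clone starts rare
(`x3(0) <= 0.02` ng/ml), is fed slowly (couplings into `x3` at most 1e-4:
mutation is a rare event), and has months-scale doubling in either phase
(`d1_33` in [1.002, 1.012], `d0_33` in [0.95, 1.02]) — consistent with
PSA at most 2 ng/ml after a year of continuous therapy yet at least
10 ng/ml by year five.  Ground-truth draws must also sit at least a
spectral margin of 3e-3/day from the type boundary: refitted parameter
sets scatter by a few 1e-3/day in spectral abscissa, so boundary draws are
unidentifiable from noisy series and would make recovery rates
meaningless; materially larger margins are themselves incompatible with
completing 2.5 cycles (they force a fast on-treatment-growing clone).
Records span up to five completed on-periods (or 4000 days); at least
half of the observations — and never fewer than 4 — fall inside the
2.5-cycle fitting window, emulating the denser monitoring during actively
managed cycles.  A patient whose simulation does not complete 2.5 cycles
within the span is redrawn with a perturbed seed (bounded retries),
mirroring the analysed cohort, in which every fitted patient reached 2.5
cycles; type-(iii) parameter sets (two patients of 150 in the source
cohort) rarely cycle at all, so cohorts containing them may retain
short-series patients, flagged as such.

What passing tests on these cohorts do **not** show: robustness to real
assay noise structure (detection limits, heteroscedasticity beyond the
log-normal), irregular clinical sampling, protocol deviations, dropout,
or inter-trial heterogeneity — none of which the generator emulates.

## Numerical choices

* Day-0-based indexing; the schedule value at day t advances the state
  from day t to t+1.
* Grid classification step 0.001; strict negativity; closed-form block
  spectrum (exact for the model's sparsity).
* Overflowing candidates during the search (products over hundreds of
  days at multipliers above 1.2) receive a large finite cost (1e100)
  rather than inf/nan, keeping differential evolution well-defined.
* Byte-identical reproducibility: all randomness flows from explicit
  seeds (per-patient seeds spawned from the master seed, per-replicate
  seeds = master + index); JSON is written with sorted keys.
* The problem sizes used by the test suite and the acceptance script —
  20-patient recovery cohorts at B = 20 and a 12-patient end-to-end study
  at B = 10 with the reduced fitting profile — were chosen as the
  smallest runs at which the cohort-level statistics stabilise.

## Known limitations

* The type-(ii)/(iii) diagonal comparison is implemented exactly as
  specified (`w1_ii > w0_ii`); its sign convention is only meaningful
  under the reading that off-periods help when some clone grows slower
  off treatment than on it.
* Patients with very few observations in the fitting window (K near 4)
  produce poorly constrained ensembles; their modal types are close to
  uninformative, as reflected in wide vote splits.
* The mean-dynamics comparison reports horizon PSA and time-under-
  threshold; the published "schedule length" percentages rest on the
  restricted patient data and an undefined length metric, and are not
  reproduced.
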