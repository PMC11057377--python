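# Methods

This note documents the statistical machinery of `dyadcausal`: the models and
procedures, their assumptions, the tunable parameters and their defaults, what
the synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## The causal model and its assumptions

The analysis treats a dyad as a six-variable stochastic process — the
prefrontal triads F3/Fz/F4 of two interacting people, labelled
`L_F3 … F_F4` — and asks which lagged variables X_i(t−ℓ), ℓ = 1..τ,
directly influence each X_j(t).  Causal interpretation of the discovered
graph rests on the usual conditions for constraint-based time-series
discovery: stationarity of each analyzed segment, no missing samples, linear
dependencies (so that vanishing partial correlation implies conditional
independence under Gaussianity), causal sufficiency within the measured
variables, the causal Markov condition and faithfulness.  None of these are
enforced mechanically; stationarity is checked heuristically (below) and the
rest are modelling assumptions the user accepts when interpreting edges as
causal rather than merely predictive.

Contemporaneous (lag-0) links are deliberately excluded: the discovery is
restricted to strictly lagged influences, so instantaneous volume-conduction
or reference artifacts cannot appear as edges.  Self-links (lagged
autodependencies) are tested and reported like any other link but flagged
`is_self`, since their presence mostly reflects the signal's own memory.

## Conditional-independence primitive (ParCorr)

`partial_corr(x, y, Z)` standardizes all variables, regresses x and y on
[1, Z] by least squares and correlates the residuals.  The regress-then-
correlate route is robust to near-collinear conditioning sets; its algebraic
equivalence to the precision-matrix formula ρ_xy·Z = −P_xy/√(P_xx P_yy) is
kept as a test oracle rather than used as the implementation.  Significance
uses t = r√(df/(1−r²)) with df = n_eff − |Z| − 2, two-sided.  |r| is capped
at 1 − 1e−12 before the transform; residual variances below 1e−12 raise a
degenerate-data error instead of returning a meaningless statistic.

## PC condition selection

For each target, all N·τ lagged candidates are screened unconditionally,
then re-tested over iterations q = 1, 2, … conditioned on the q strongest
*other* surviving parents (conditioning sets frozen at iteration start so
results do not depend on within-sweep removal order), removing candidates
with p > α_PC, until q exceeds `max_conds_dim` (default 3) or too few
parents remain.  This is the single-combination (PC₁-style) variant: the
exhaustive subset search of the classical PC algorithm is exponential and
unnecessary here, since the PC step only needs a superset of the true
parents — false-positive control belongs to the MCI + FDR stage.  A
consequence worth knowing: under a full null the PC screen retains spurious
parents at roughly its nominal rate α·N·τ, because conditioning on unrelated
variables barely changes an already-selected statistic.  The test suite
asserts exactly this calibration.

When `pc_alpha` is a list (or `"aic"`, meaning the grid
{0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}), the PC step runs per α and the
α minimizing Σ_j [n·log(RSS_j/n) + 2(k_j+1)] — the Gaussian least-squares
AIC of each target regressed on its selected parents — is chosen, ties
toward the smaller α (sparser graph).

## MCI testing and effective windows

The MCI test of X_i(t−ℓ) → X_j(t) conditions on P(X_j) \ {X_i(t−ℓ)} and on
P(X_i) shifted back by ℓ (standard MCI; `include_source_parents=False`
conditions on the target's parents only).  Shifted source parents reach back
up to 2τ, so all MCI tests share the uniform window t = 2τ..T−1 and
n_eff = T − 2τ; the PC stage, whose conditions reach only τ, uses
n_eff = T − τ.  Using one fixed window per stage keeps every test in a stage
on identical samples, at the cost of a few discarded rows.

All N²·τ MCI p-values (self-links included) form a single
Benjamini–Hochberg family; `bh_fdr` implements the step-up adjustment
q_(i) = min_{j≥i}(p_(j)·m/j) capped at 1 and is cross-checked against
statsmodels in the tests.  Significance is q ≤ α_FDR (default 0.05).

## Choice of the maximum lag τ

`lagged_dependencies` computes unconditional lagged correlations for all
ordered pairs at lags 1..`search_max` (default 20) on a common overlap
window (n_eff = T − search_max).  `choose_tau` returns the smallest lag from
which *every* pair's |correlation| stays below threshold at all later lags —
requiring decay at all later lags prevents oscillating autocorrelations from
truncating τ early — clamped to [τ_min, τ_max] (defaults 1 and 5), falling
back to τ_max with a warning when the table never decays.

The default threshold is the 95% null band of the *maximum* statistic the
rule inspects: the Bonferroni-corrected normal quantile over all
N²·search_max entries, scaled per pair by Bartlett's large-lag variance
factor (1 + r_i r_j)/(1 − r_i r_j), where r_k is channel k's lag-1
autocorrelation.  Both corrections matter: a flat per-comparison band
(2/√n_eff) lies below the noise floor of a maximum over 36 pairs at every
lag, and without the Bartlett factor strongly autocorrelated channels never
decay below any fixed band.  With this default, dyads with lag-1
autocorrelation 0.4 at series length 12,400 select τ = 4–5, and the selected
τ grows with the autocorrelation strength.  τ is chosen once per dataset,
globally over the six variables.

## Stationarity check

Before discovery, each channel's two halves are compared: if the half-mean
difference exceeds 0.5 full-series SDs, or the half-variances differ by more
than 50% of the full variance, a warning names the channel.  Violations warn
rather than abort, since segment-level trend removal is the preprocessing
stage's job and borderline cases are common in real recordings.

## Signal conditioning

Defaults follow ordinary EEG practice for drift-free, lag-faithful series:
zero-phase (forward–backward) 4th-order Butterworth high-pass at 1 Hz —
zero-phase because phase distortion would bias lagged estimates; polyphase
FIR resampling with a Kaiser window (target 100 Hz) to avoid aliasing that
could masquerade as lagged dependence; average reference computed over the
*full* montage before the triad is selected (referencing and selection do
not commute; a regression test pins the order); half-open segment windows
[onset, offset) with 0-based sample indexing.  Artifact removal by ICA is
out of scope: inputs are expected to be artifact-pruned upstream, which the
CLI's `--assume-clean` flag documents.

## Synthetic ground truth

`VARSpec` holds the coefficient tensor A[ℓ][j][i] and per-variable innovation
SDs of x_t = Σ_ℓ A_ℓ x_{t−ℓ} + ε_t with independent Gaussian ε.  Stability
is enforced via the companion-matrix spectral radius (< 1), and generation
discards a 1,000-sample burn-in.  Defaults mirror the emulated study
conditions: 6 variables, series length 12,400 (~124 s at 100 Hz), lag-1
autocorrelation 0.4, couplings at lags 1..5.  Coupling strength 0.15 for
between-brain links is this package's choice of a weak-but-recoverable
effect at that series length (observed MCI ≈ 0.14, comfortably above the
detection floor ≈ 0.03 but far from saturation).

The tap generator emits a leader train (a 7-tap rhythm within a 6 s cycle,
repeated 5 times, starting 1 s into the task) and a follower train delayed by
`reaction_delay` (default 0.16 s, a typical auditory reaction time; the
recovery analyses also use 0.0065 s, the magnitude of a practiced follower)
plus Gaussian jitter (default 0.02 s).  Contamination is planted as double
taps (an extra tap 0.1 s after a genuine one) and stray taps appended beyond
the train end, each preceded by a >2 s silence, so the cleaning rules remove
exactly the planted contaminants.  A ground-truth match list is returned so
the matcher can be scored.

What the generator does *not* emulate: realistic EEG spectra (1/f background,
alpha peaks), nonlinearity, nonstationarity, volume conduction, or artifact
topographies.  Passing tests therefore demonstrate that the estimator
recovers linear lagged structure under its stated assumptions — not that
those assumptions hold in any particular recording.

## Tap cleaning, matching and synchrony

Cleaning: scanning left to right, a tap closer than 0.2 s to the previously
kept tap is removed (the earlier tap of a double is kept — the first contact
is the intended tap); then every tap terminating an inter-tap gap above 2 s
is removed in one non-cascading pass.  The non-cascading rule means cleaning
is idempotent on realistic trains (isolated outlier gaps) but not on
pathological gap structures where a removal merges two long gaps; this is
accepted as the cost of not letting one outlier cascade into deleting
legitimate taps.

Matching: candidate (leader, follower) pairs within ±1 s are accepted
greedily by ascending |time difference|, each tap used at most once, ties to
the earlier tap — on tap-like data this coincides with the assignment
minimizing the total absolute difference, which an exhaustive small-instance
oracle test confirms.  Synchronicity is the signed follower − leader
difference over matched pairs (leader as baseline, late follower positive),
summarized by mean and sample SD.

## Problem sizes in the shipped analyses

The test suite and `scripts/acceptance.py` size their simulations to make
each claim sharp while keeping the whole suite quick on a single CPU: 20
seeds at the full series length 12,400 for structure recovery, 50 (suite) or
20 (script) white-noise systems at T = 2,000 for null calibration, T =
100,000 for the large-sample MCI oracle, 1,000 replicates for type-I
calibration, and 20 seeded tap simulations.  These sizes are the package's
own choices and are trivially adjustable at the call sites.

## Known limitations

- Linear-Gaussian tests only; nonlinear dependence invisible to partial
  correlation will be missed (by design, matching the linearity assumption).
- No contemporaneous links, latent-confounder handling, or bootstrap
  confidence intervals.
- The PC screen's null retention tracks α rather than shrinking below it;
  do not interpret raw parent sets as discoveries — only FDR-corrected MCI
  links.
- n_eff treats samples as exchangeable within the analysis window; strong
  residual autocorrelation beyond the selected parents can make MCI p-values
  mildly anticonservative.
- The stationarity check is a coarse two-half heuristic, not a formal test.
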