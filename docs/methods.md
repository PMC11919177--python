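# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the limits of what the test suite shows.

## Constructs and screening

Seven construct scores per respondent per wave: PHQ-9 total (0–27,
depressive symptoms), GAD-7 total (0–21, anxiety), the three RRS
rumination subscale totals — symptom rumination (12 items), brooding
(5), reflective pondering (5), each item 1–4 — plus the ANIS total
(10 items, 1–5; negative attention bias, "NA") and the short-form ATQ
total (8 items, 1–5; negative automatic thoughts, "NAT"). All scoring
is an unweighted item sum.

Record screening applies, in a fixed order so per-reason counts are
reproducible: unparseable record; failed lie item; any missing item
response; response time under 480 s (strict); age outside 18–24 (or
an explicit age-by-grade table); any construct total with |z| > 3
within the wave; any missing demographic. Each exclusion is charged
to the first reason that fires, so `n_input = n_retained +
Σ exclusions` holds exactly. Two deliberate choices:

* Outlier z-scores use the population SD over *all scoreable records
  in the wave*, not just survivors of the earlier filters. This makes
  the outlier flag independent of the filter order and maximizes the
  reference pool. A small-sample constraint follows from the z-score
  itself: over an n-record pool the largest attainable |z| is
  √(n−1), so the conventional 3.0 threshold cannot fire in very small
  batches — tiny hand-built fixtures must lower `outlier_z`
  explicitly (the packaged five-record fixture uses 1.5).
* "Under 8 minutes" is implemented as `response_time_s < 480`,
  strict.

Waves are matched by an inner join on respondent code (duplicates
within a wave are an error), and descriptive comparisons use paired
t tests across waves and Welch t tests across samples; zero-variance
difference columns are reported with a degenerate flag instead of a
statistic.

## Synthetic data-generating process

Wave-1 latent scores are multivariate normal with precision matrix
`K1` (unit diagonal): the true contemporaneous network is the partial
correlation ρᵢⱼ = −K1ᵢⱼ, known exactly. The default truth plants a
dense positive rumination block (SR–BD 0.38, SR–RP 0.32, BD–RP 0.32),
a strong depression–anxiety edge (0.35), PHQ–SR 0.22, GAD–NAT 0.25
and NA–NAT 0.25; the remaining 14 pairs are exact zeros. Wave 2
follows `X2 = X1 B + E` with autoregressive diagonal 0.4, planted
cross-lags SR→PHQ +0.15, NAT→GAD +0.18, PHQ→GAD +0.12, GAD→NA +0.16,
RP→PHQ −0.12, and residual covariance 0.5·I (chosen to keep wave-2
marginal SDs near 0.85–0.95 given the default B). Latent scores are
on a standardized scale; the networks are fit on correlations, so
absolute scaling is immaterial.

Item responses are `round(clip(loading·z + intercept + noise))` into
each scale's range, with intercepts at the response midpoint and
loadings/noise set so construct totals correlate > 0.8 (in practice
≈ 0.9–0.95) with the latent scores. Validity violations are injected
independently per record at configurable rates (lie failure, one
blanked item, fast completion, blanked demographic, wave-2 dropout),
with a ledger of corrupted codes for round-trip assertions.

What the generator does **not** emulate: skewed/floor-effect item
distributions (responses are symmetric around the midpoint, unlike
real clinical screening data), ordinal-appropriate polychoric
correlation structure, systematic (non-random) attrition, and
construct scores whose population network drifts between waves —
the wave-2 cross-sectional network here is the attenuated implication
of the autoregressive transition, not an independently planted
structure. Passing recovery tests therefore demonstrate correctness
of the estimators under their own model assumptions, not robustness
to the distributional quirks of real questionnaire data.

## Network estimation

Input is the Pearson correlation matrix of the (complete) score
table; polychoric/nonparanormal input is out of scope. The graphical
lasso solves max log det K − tr(SK) − λΣᵢ≠ⱼ|Kᵢⱼ| (diagonal
unpenalized) by block coordinate descent — each column of the working
covariance updated via an inner lasso solved by coordinate descent —
compiled with numba so resampling procedures can re-estimate
thousands of networks cheaply. Convergence is declared when the
maximum change in the working covariance falls below `tol` (default
1e-6); non-convergence raises with diagnostics. λ = 0 returns the
exact inverse. Warm starts carry (W, B) down the penalty path.

The path is 100 log-spaced penalties from λ_max = max off-diagonal
|S| (the empty graph) down to 0.01·λ_max. Model selection minimizes
EBIC = −2ℓ + E ln n + 4γE ln p with γ = 0.5, where ℓ is the
*penalized* estimate's Gaussian log-likelihood (no unpenalized refit
— the simpler, standard convention) and E counts off-diagonal entries
with |Kᵢⱼ| > 1e-8; weights at or below that magnitude are treated as
exact zeros for edge counts. The reported `density` is the fraction
of the p(p−1)/2 possible edges that are nonzero (some applied papers
call this "sparsity"; 19/21 = 0.90, 18/21 = 0.86).

Estimator correctness is checked on two independent routes: a
restarted Nelder–Mead minimizer of the same penalized objective
(with a snap-to-zero polish, since derivative-free search stalls at
the |K|=0 hinges) on p ≤ 3 problems to 1e-6, and
`sklearn.covariance.graphical_lasso` on p = 7 problems.

## Centrality

Strength = Σⱼ|wᵢⱼ|; closeness = reciprocal of the summed Dijkstra
distances with edge length 1/|w| (a node that cannot reach every
other node scores 0); betweenness = Brandes' fractional shortest-path
count over unordered pairs, same distances. Signed weights enter
distances and strength by absolute value. Closeness is reported as
the reciprocal (higher = more central) so the three indices order
nodes consistently. z-scores standardize each index across the p
nodes with the population (n) denominator; constant columns come
back as zeros with a degenerate flag. For directed cross-lagged
networks, incoming/outgoing expected influence are the signed
column/row sums of the coefficient matrix, autoregressive diagonal
excluded by default.

## Bootstrap accuracy and stability

Edge accuracy: B = 1,000 (default) nonparametric bootstrap replicates
re-estimating the full EBIC-glasso network; percentile 2.5/97.5
intervals per edge; failed replicates are dropped and counted.

Case-drop stability: for each drop proportion in {0.05, …, 0.75}
(step 0.05), B = 250 (default) subsamples without replacement;
Spearman correlation (robust to monotone scale change; Pearson
configurable) between subsample and full-sample centralities. The CS
coefficient is the largest drop proportion whose correlation is
≥ 0.7 in ≥ 95% of subsamples *and* whose smaller grid points all
satisfy the same condition — requiring the prefix guards against
non-monotone sampling noise. The grid ceiling is 0.75: a perfectly
stable index cannot score higher, and small/noisy samples should fall
below it. Levels whose subsample would have fewer than p+1 cases are
skipped and cannot carry the CS value.

## Network comparison

Observed statistics come from networks re-estimated per group:
|global strength difference| and the omnibus max |edge difference|,
plus per-edge differences. The null re-estimates both networks per
permutation: independent design permutes pooled group labels; the
paired design swaps each subject's two wave rows with probability
1/2, which respects within-subject dependence and is the default for
two-wave data from the same respondents. p values use the add-one
estimator (never exactly 0); per-edge p values are Holm-adjusted over
all 21 possible edges (none/Bonferroni/BH configurable — with m = 21
comparisons, edge-level discoveries at α = 0.05 need n_perm ≳ 500 so
the attainable minimum adjusted p clears the threshold).

## Cross-lagged panel network

Columns standardized (population SD), then per wave-2 target j:
min (1/2n)‖x2ⱼ − X1β‖² + λ‖β‖₁ over a 100-point per-target λ path
(ratio 1e-3), λ chosen by 10-fold CV with deterministic seeded fold
assignment; CV-minimum rule by default, one-SE rule available. The
lasso's exact zeros are the "elimination of small coefficients"; no
extra threshold is applied by default (configurable). Autoregressive
paths are estimated — omitting a target's own baseline would inflate
its cross-lags — but excluded from IEI/OEI and flagged in the
prediction table. A fixed near-zero penalty recovers the
normal-equations least-squares coefficients (verified entrywise to
0.01 at n = 50,000).

## Pipeline determinism and problem sizes

One master seed spawns per-stage child seeds through
`numpy.random.SeedSequence.spawn` in the fixed stage order, so a
config + seed reproduces every artifact; the summary JSON is
byte-identical across runs (stage timings go to `run.log` only).

Simulation-based checks use problem sizes chosen to make their
statistical claims decisive while keeping the default suite fast on a
single CPU: support recovery and cross-lag recovery at n = 5,000 over
20 seeds; permutation-test calibration at n = 500 with 200
permutations over 200 Monte-Carlo repetitions (the resampling-heavy
runs use a shortened 10–40-point penalty path via `EstimatorConfig` —
a coarser model search, not a different estimator); stability at
n = 5,000 vs n = 60 with 100 subsamples per drop level; the OLS limit
at n = 50,000.

## Known limitations

* Ordinal item sums enter as Pearson correlations; no polychoric or
  nonparanormal option.
* The case-drop CS is reported for one index at a time and the
  default pipeline computes strength only.
* No bootstrapped difference tests between centralities of node
  pairs, no centrality-invariance permutation test, no
  graphical-VAR-style joint contemporaneous-plus-temporal model, and
  two waves only.
* Network figures are not produced; all canonical outputs are
  tabular.
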