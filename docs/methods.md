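# Methods

## Synthetic cohort model

Every subject's regional timeseries follows a latent-factor model. Each
of the K communities has a unit-variance AR(1) latent signal (lag-1
coefficient 0.3); latents of different communities are correlated at
`between_coupling / within_coupling`, so that before noise the expected
Pearson correlation is `within_coupling` inside a community and
`between_coupling` (optionally pair-specific) across communities. Node
signals add i.i.d. Gaussian noise with SD `noise_sd`:

    x_i(t) = sqrt(within) * u_{m(i)}(t) + noise_sd * e_i(t)

The observed correlation is then `within/(within+noise_sd²)` within a
block, scaled down proportionally across blocks. The latent correlation
matrix must be positive semidefinite; couplings that violate this (or
that a planted effect would drive negative) are rejected at
construction.

Defaults emulate a child resting-state cohort: 5 communities over 60
nodes (242 in the full-atlas setting), 196 volumes (200 acquired minus 4
non-steady-state) at TR = 1.76 s, `within = 0.5`, `between = 0.1`,
`noise_sd = 0.8`, giving within-block |r| ≈ 0.44 and between-block
≈ 0.09 — typical magnitudes for absolutized-correlation networks.

SOCS phenotypes are drawn from three latent classes whose fractions are
the `prevalence` parameters: probable OCD (items summing ≥ 6; a 60 %
subtype also scores 'often' somewhere and is counted inside the high-OCS
budget so realized class fractions track their nominal prevalences),
high-OCS-only (exactly one or more 'often' items, sum ≤ 5), and a
zero-inflated background (52 % symptom-free; otherwise items Bernoulli
0.35, capped below the cutoff). With the default prevalences
(probable OCD 6.4 %, high OCS 7.8 %) the generator reproduces the
published cohort's marginals: ~46 % symptom-free controls, whole-sample
SOCS mean ≈ 1.7 (SD ≈ 2.2), probable-OCD mean ≈ 7.2. Exactly one item
goes missing in 2 % of subjects, exercising the weighted-sumscore rule
(sum of 6 × 7/6). Covariates: age ~ N(10.1, 0.6) years, sex Bernoulli
0.492, three-level maternal ethnicity (1.7 % missing), adjusted CBCL
score negative-binomial (dispersion 1.3) with group-dependent means
(13/20/24). Framewise-displacement traces are folded Gaussians with
subject means near 0.12 mm so roughly a tenth of subjects trip the
motion-exclusion rules.

What the generator does **not** emulate: hemodynamics, scanner drift and
physiological noise spectra, spatial (voxel-level) structure, distance-
dependent correlations, or heavy-tailed motion. Passing tests therefore
demonstrate correctness and calibration of the pipeline's statistics
under block-structured correlation data, not robustness to every
property of real fMRI.

## Denoising

"Simultaneous nuisance regression and temporal filtering" is implemented
as one least-squares projection onto [intercept | nuisance | DCT-II
columns at frequencies outside 0.009–0.08 Hz]. A joint projection is
idempotent and cannot re-introduce removed variance, unlike sequential
regression followed by filtering. Rank-deficient designs are handled by
a pseudoinverse (minimum-norm fit). The cosine basis at T = 196, TR =
1.76 s spans k/(2·T·TR) for k = 1…T−1 excluding the pass band.

## Community detection and consensus

`louvain_partition` maximizes the resolution-parametrized weighted
modularity Q(γ) = (1/2W) Σ_ij [w_ij − γ s_i s_j / 2W] δ(m_i, m_j). The
engine is Leiden (RBConfiguration quality, identical to Q(γ)); igraph's
original multilevel Louvain is available via `engine="multilevel"`. Each
pass starts from a seed-shuffled node order and is polished by a
refinement stack: greedy single-node moves to convergence, greedy
community merges, and a Kernighan–Lin sweep (tentative locked moves that
may be individually negative, keeping the best prefix), alternated until
stable; the best of 5 restarts is returned. On random dense 8-node
graphs this attains the exhaustive maximum over all 4,140 partitions in
≈ 98–100 % of cases — the residual misses are graphs whose optimum
differs by a multi-node exchange outside the sweep's reach.

Consensus clustering repeats the partition pass `n_reps = 50` times per
subject matrix (pooled mode; `groupmean` clusters the cohort-mean matrix
instead, used for large-cohort experiments where pooled runs would be
wasteful), builds the node-pair co-assignment matrix, zeroes entries
below τ = 0.5, and re-clusters the thresholded matrix until
co-assignment is binary; the final partition is its connected
components. K is never forced: 5 communities is the expected outcome at
γ = 1.05 on data with the planted structure, and `expect_k` can assert
it loudly.

## Graph measures

Standard weighted definitions: participation coefficient
pc_i = 1 − Σ_m (κ_im/s_i)²; within-module degree Z with the population
(N-denominator) SD and z = 0 for singleton or zero-variance modules;
Onnela clustering on weights normalized by the maximum (node degree
counts nonzero weights; nodes with degree < 2 contribute 0); path length
and efficiency on edge lengths 1/w via Dijkstra, with unreachable pairs
excluded from L and contributing 0 efficiency; small-worldness
σ = (C/C_rand)/(L/L_rand) against nulls that permute the off-diagonal
weight multiset (10 nulls by default; the null generator is injectable).
Per-subject Q is computed against the group consensus partition by
default so values are comparable across subjects; per-subject Louvain is
available.

On dense absolutized-correlation graphs σ typically falls below 1:
weight shuffling spreads strong weights uniformly, which raises null
clustering relative to the modular original. σ is reported as defined;
its interpretation on fully weighted dense graphs differs from sparse
binary small-world analyses.

The thalamic summary averages a nodal metric over each bilateral
subregion pair when both sides share a community and reports the sides
separately otherwise; with 7 shared pairs and the split caudal temporal
pair this yields the 9 node values of the nodal test family.

## Inference

Each outcome is fit by OLS on [predictor | age | sex | ethnicity
dummies (reference: Dutch) | optionally adjusted CBCL]. B, t, and the
two-sided p come from the parametric fit; the standardized β rescales B
by sd(predictor)/sd(outcome); the 95 % CI is a percentile
case-resampling bootstrap (default 10,000 iterations; resamples with a
degenerate predictor are redrawn and counted). The probable-OCD contrast
drops subjects with 0 < SOCS < 6 entirely; the high-OCS contrast
compares children with any 'often' item against those with all items
≤ 1. BH-FDR (q = 0.05) is applied within the 10-test subnetwork family
and within each 9-value thalamic family; the three global tests are
reported unadjusted. Missing ethnicity is filled by seeded draws from
the observed category distribution (or the modal category) — a
deliberate simplification of chained-equation multiple imputation, which
is not this pipeline's contribution; with ~1.7 % missingness the choice
is immaterial to the covariate adjustment.

## Network-based statistics

Edge-wise t-statistics for the group term come from a vectorized OLS over
all upper-triangle edges. Supra-threshold edges (t > 3.0 by default,
one-sided per direction) form components via union-find, sized by edge
count. Significance uses the max-component permutation null (group
labels shuffled with covariates kept attached; default 5,000
permutations) with p = (1 + #{perm ≥ obs})/(n_perm + 1).

The pure edge-count statistic is integer-valued, and its ties between
permutation and observed values make the test conservative (exact level
0.016–0.042 instead of 0.05 across thresholds 2–3 in our null
simulations). Equal-size components are therefore ordered by a bounded
continuous function of their peak supra-threshold t — statistic =
size + (t_max − thresh)/(1 + t_max − thresh) — which preserves the extent
ordering, keeps the permutation test valid, and restores near-exact
calibration (measured FWER ≈ 0.045–0.065 per 400–1000 null replicates).
This is a tie-break refinement of the extent statistic, not an
intensity/mass statistic.

## Validation battery and problem sizes

The standing experiments (`ocsnet.experiments`, run by the test suite,
the acceptance script and the analysis drivers) use these sizes, chosen
to give tight Monte-Carlo bounds at desk scale:

- exhaustive-partition oracle: 50 random 8-node graphs;
- consensus recovery: 20 cohorts × 20 subjects × 60 nodes in the
  high-contrast regime (within 0.9, between 0.05, noise 0.1);
- regression type-I error: 1,000 null simulations at n = 500;
- NBS FWER: 1,000 null replicates (60 subjects, 30 nodes, 500
  permutations);
- planted-effect recovery: 50 cohorts of n = 300 with a 0.3 reduction of
  one pair's between-coupling for a 15 %-prevalence high-OCS group. The
  baseline couplings for this experiment are within 0.7 / between 0.35 /
  noise 1.0 so the reduced pair stays non-negative and the latent
  correlation stays positive definite; the consensus partition uses
  group-mean mode there. Bootstrap CIs are skipped (n_boot = 0) in
  calibration loops where only p-values are consumed; tests that
  exercise the bootstrap use a few hundred resamples rather than the
  analysis default of 10,000.

## Known limitations

- The synthetic generator's block-correlation world is far simpler than
  real fMRI; effect sizes that recover cleanly here may not at matched n
  in real cohorts.
- σ on dense weighted graphs is sensitive to the null model choice; only
  the weight-shuffle null is built in.
- Single-draw ethnicity imputation understates imputation uncertainty
  relative to multiple imputation (immaterial at the simulated
  missingness rate).
- The consensus procedure's repetition count, τ, and pooled-vs-groupmean
  mode are configurable because the original study's exact settings are
  not public; results on clean planted structure are insensitive to
  them.
- Stage outputs are cached only at whole-run granularity (a config
  digest in the manifest); individual expensive stages are rerun via the
  CLI subcommands on files rather than a per-stage content-hash cache.
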