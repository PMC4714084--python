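# Methods

This note documents the models, numerical choices and assumptions behind
`wingmorph`, and what the synthetic-data tests do and do not establish
about real wing data.

## Superimposition

Partial Procrustes fitting: every configuration is translated to the
origin and scaled to unit centroid size; rotations come from the SVD of
the cross-covariance matrix with the determinant sign-corrected, so
reflections are never introduced silently (`allow_reflection` exposes
them for explicit use). Generalized Procrustes analysis iterates
align-to-consensus / re-estimate-consensus, re-normalizing the consensus
to unit size each round, until the root-mean-square change of the
consensus falls below `tol = 1e-10` or `max_iter = 100`; non-convergence
is reported in the result (`converged=False`), not raised, because a
usable alignment still exists.

Left wings are mirrored (x negated) into right-wing orientation before
fitting. This is a package decision: mixed wing sides are common (damaged
right wings), a mirror image cannot be reached by rotation alone, and the
measurement-error analysis treats wing side as a factor under test, which
is only meaningful after the trivial mirror difference is removed.

The default feature space is the untransformed Procrustes coordinates,
flattened to 2k columns, so Euclidean row distances equal Procrustes
residual distances. An orthogonal tangent-space projection at the
consensus is available (`tangent_project(..., project=True)`) but off by
default; at the small shape variances typical of wing data the two differ
negligibly, and downstream distance-based tests are defined on the
untransformed coordinates.

## DAPC and membership probabilities

The classifier is PCA followed by linear discriminant analysis in the
retained-PC space. The pooled within-group covariance (homoscedastic
assumption, divisor n − g) is used for whitening; its eigenvalues are
floored at 1e-10 of the largest to keep the inverse square root stable
when the retained-PC count approaches the sample size. Discriminant axes
are the leading eigenvectors of the whitened between-group scatter; at
most g − 1 are kept. PGMPs are Gaussian posteriors from squared Euclidean
distances to group centroids in this whitened space — equivalent to
classical LDA posteriors with unbiased covariance pooling (this is also
how the tests cross-check them, via a full-space Gaussian-density
oracle). Priors default to group proportions, matching the unbalanced
design; uniform priors are an option.

Cross-validation: stratified 90/10 splits (per-group training counts
rounded to nearest, at least one specimen held out and two kept per group
where the group allows), default 1000 replicates per candidate PC count,
candidate grid {5, 10, 15, …} capped at min(n − g, p). The score is mean
held-out assignment success; ties go to fewer PCs. The same replicate
split streams are reused across grid levels so levels are compared on
identical partitions, and all randomness descends from one seed.
Held-out PGMPs at the chosen level are averaged per specimen over the
replicates in which it was held out. The success criterion (rather than,
say, a probability RMSE) is this package's choice of optimizer target.

On data with no group structure, held-out success fluctuates around 1/g
but is biased slightly below it at small n (leaving specimens out shifts
the training centroids away from them); tests therefore compare against
1/g within three standard errors of the replicate spread rather than
exactly.

## Threshold-gated identification

Assignment requires the best PGMP to *strictly* exceed the threshold;
exact ties on the argmax leave the specimen unassigned. The consistency
rate's denominator is all specimens in the stratum by default, so
discarded specimens lower the rate (`denominator='assigned'` gives the
precision-style alternative). Reference libraries are sex-stratified —
sexual wing dimorphism exceeds the group effects, so pooled-sex models
would confound the two — and queries must declare a matching sex. Queries
are aligned to the *frozen* library consensus by ordinary superimposition
so that library features never change after the library is built;
left-wing queries are auto-reflected.

## PERMANOVA

For Euclidean distances, the PERMANOVA partition equals the classical
multivariate ANOVA partition of the centred feature matrix (Gower's
identity), so sums of squares are computed in feature space —
O(np) per term rather than O(n²) — as cell-mean sums of squares with all
contained coarser terms subtracted (inclusion–exclusion over full factor
sets, which reproduces textbook balanced-design df and SS for crossed,
nested and mixed layouts). Multi-factor designs must be balanced; the
one-way case accepts unequal group sizes. Balanced subsets are drawn with
`balanced_subsample` (without replacement, seeded).

Two denominator policies exist. The default refers every term to the
residual mean square; this matches how the implemented tables are
reported and keeps one-way pseudo-F identical to the classical F.
`denominator='ems'` selects denominators by restricted-model
expected-mean-squares rules — the denominator of a term is the minimal
random term containing it whose extra factors are all random — and flags
quasi-F situations (no unique minimal candidate) with a warning and a
residual-denominator fallback.

p-values come from unrestricted permutation of observation rows, with the
observed statistic counted in numerator and denominator:
p = (#{F* ≥ F} + 1)/(n_perm + 1) ∈ [1/(n_perm+1), 1]. For small samples
(n ≤ 9) `exact=True` enumerates all n! permutations and reports the exact
tail probability. A caveat worth knowing: with unrestricted permutations,
tests of nested nuisance terms (image, scoring) in the presence of a
large specimen-level effect are conservative — their observed mean
squares are small against a permutation distribution dominated by the big
effects, so their p-values crowd toward 1. This is acceptable for the
screening purpose these terms serve (ruling nuisance effects *in* would
still show up); restricted permutation schemes are a known alternative
and out of scope here.

Pairwise comparisons run the two-group one-way test per pair,
t = √pseudo-F, with Benjamini–Hochberg step-up FDR (delegated to
statsmodels) applied across pairs. Pairs with fewer than two replicates
in either group are flagged untestable rather than dropped. Note that
with very few replicates per group the distinct permutations are few and
the attainable p-values coarse (e.g. three per group cannot reach far
below ~0.1 per pair), which the female genotypic-cluster analysis in
`analysis/06` illustrates.

## Synthetic data

The generator emulates the structure the pipeline assumes:

- a wing-like k-point template (elongated rounded outline, unit centroid
  size; no anatomical realism claimed);
- group mean shapes = template + smooth low-frequency displacement fields
  (4 Fourier modes over landmark index, net translation removed) of
  prescribed RMS magnitude, re-normalized to unit size;
- specimen shape = group mean + shared sex displacement field +
  isotropic Gaussian landmark noise, with optional wing-side, image and
  scoring layers for the replicated measurement-error design;
- emission in mm at centroid size ~N(4.0, 0.25²) mm with random rotation
  and translation, left wings mirrored with probability 0.193;
- band areas log-normal around template values with group and sex shifts
  on the log scale (positivity guaranteed).

Default magnitudes (dimensionless shape units): group displacement RMS
0.01, sex effect 0.04, side effect 0, image noise 0.002, scoring noise
0.001, individual landmark noise 0.012. These encode the assumed regime —
group effects small and hard to see in unconstrained ordination, sex
dominant, side null, measurement error negligible. The default cohort is
80/97/50 specimens by species across clusters A, F1, F2, R1, R2 with 163
males and 64 females; per-group sex counts are chosen so every species
keeps at least 31 males and 19 females and every cluster at least 10
males and 3 females — exactly the balanced-subsample sizes the one-way
analyses draw (31/19 per species, 10/3 per cluster), so that every
analysis code path is exercisable on the default cohort.

What passing synthetic tests shows: the pipeline's algebra, calibration
and monotonicity properties are correct, and effects of the assumed kind
are recovered at the assumed magnitudes. What it does not show: that real
wings follow isotropic Gaussian landmark noise (real digitization error
is landmark-specific), that real group differences are smooth
low-frequency fields, or that real PGMP levels match the simulated ones.
Absolute consistency rates on real specimens must be estimated from real
reference data.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use reduced but structurally
faithful sizes chosen as a matter of proportion: 100 cross-validation
replicates per PC level (the CLI default remains 1000), 999 permutations
inside calibration loops and 10⁴ for single reported tables, 500 null
datasets for the type-I-error estimate, and 60-specimen three-group
datasets for classifier calibration. The analysis scripts under
`analysis/` use 200 replicates and 10⁴ permutations.

## Known limitations

- Unbalanced multi-factor designs are rejected rather than Type-II/III
  partitioned; balance is obtained by subsampling.
- Nested-term permutation is unrestricted (see above); no moment-matched
  Monte-Carlo p approximation is provided.
- Only Euclidean distances; no sliding semi-landmarks; 2-D only.
- Landmark and band-area evidence are modelled separately, never fused
  into one score.
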