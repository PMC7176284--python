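# Methods

## Model

Each analysis unit — a single gene's cohort expression, or a cohort's
samples over a panel of genes — is modeled as a Dirichlet-process Gaussian
mixture. The DP prior has concentration `alpha` and a normal-Wishart base
measure; mixing weights come from the truncated stick-breaking
construction (`nu_k ~ Beta(1, alpha)`, `pi_k = nu_k prod_{l<k}(1-nu_l)`,
last break fixed at 1, truncation `k_trunc`). Observations are Gaussian
given their component. Because the DP concentrates mass on few sticks,
the number of *occupied* components is inferred from the data; truncation
only caps it.

Assumptions worth stating: expression is treated as Gaussian on the
log2(TPM+1) scale (reasonable after the log transform for moderately to
highly expressed genes; the mean-expression filter at 1.0 log2(TPM+1)
removes the low-abundance genes where this is worst); samples are
exchangeable; and clusters are interpreted as discrete expression states
(subtypes or tumor-microenvironment compositions).

## Inference

Full-batch mean-field coordinate ascent (CAVI) on the factorized posterior
`q(z) q(nu) q(mu, Lambda)`, with Beta stick factors and normal-Wishart
component factors, iterated until the relative ELBO change falls below
`tol` (default 1e-6) or `max_iter` (default 500). The ELBO is evaluated
once per full pass at a self-consistent state, so the per-restart trace is
non-decreasing up to float noise; the one-component ELBO equals the
closed-form conjugate evidence at convergence, which the tests check
against an independent closed-form oracle.

Local optima are handled three ways:

- **Initialization.** Univariate fits seed K components at evenly spaced
  quantiles of the gene (first restart) or at random data points (later
  restarts). Multivariate fits pit the random-anchor start against a
  deterministic pool of principal-component tail splits (both tails of the
  leading PCs at several split fractions — expression subtypes appear as
  heavy tails along high-variance directions); each candidate gets three
  CAVI passes and the best short-run ELBO start is continued.
- **Merge moves.** Components that drift onto the same mode drain into
  each other only geometrically slowly under plain CAVI, so duplicate
  merges are proposed periodically during the run and at convergence;
  a proposal is kept only if the ELBO after a short relaxation does not
  drop. Delete moves remove components below `delete_weight` (1e-4) under
  the same ELBO guard.
- **Restarts.** `n_restarts` (default 2) independent runs; the highest
  final ELBO wins. Everything is deterministic given (data, prior, config,
  seed); per-gene and per-set child seeds are derived by hashing the master
  seed with the gene/set identifier, so results do not depend on batch
  composition or database order.

Per-gene univariate fits are vectorized across genes (one array program
advances all genes at once, retiring genes as they converge), which is why
a 2,000-gene filter takes seconds rather than an hour.

## Priors

Defaults: `alpha = 1` for univariate fits and the sweep; `alpha = 5` for
clustering over enriched genes; `m0` = empirical mean; `kappa0 = 1`;
`scale0 = 2.0` (prior expected covariance = 2 x identity, a weakly
informative choice on the log2(TPM+1) scale where per-gene variances are
typically 0.5-1.5); `dof0 = d + 2` for dense covariances (making
`E[Sigma] = scale0` exactly) and 3 per dimension for diagonal ones (same
identity, per dimension). Univariate truncation defaults to 10; the
multivariate stages use 5.

## Covariance structure

`covariance_type` selects dense ("full") or diagonal ("diag", the default)
component covariances. This is the package's most consequential design
choice. A dense covariance costs each *occupied* component an evidence
penalty that grows roughly with d^2, because every cluster must re-learn a
d x d matrix against the prior; at gene-panel sizes (d of 30-200 versus
n of 70-300) that penalty provably exceeds the likelihood gain of real
subtype splits, and the variational evidence then prefers a single broad
component no matter how the optimizer is initialized. Diagonal components
keep the penalty linear in d, which restores the detection behavior the
pipeline needs at cohort scale — near-chance detection below effect sizes
of ~0.75-2.0 (depending on %DEG) rising to near-perfect above them — while
still letting every cluster have its own per-gene variances. Dense
covariances remain available and are recommended only when d is small
relative to n (they are also what the closed-form multivariate evidence
test exercises).

The known cost of diagonal components: a strongly co-expressed but
*unimodal* gene set can be fit as a spurious two-cluster mixture that
mimics the correlation. The cohort workflow neutralizes this by running
the sweep on the filter's multimodal genes only (`restrict_to_multimodal`)
— co-expressed unimodal genes are never banked, so such sets lose their
genes and are skipped. The synthetic benchmark runs the sweep unrestricted;
there the artifact is harmless because spurious clusters are uncorrelated
with the injected subtype and score at AUC ~0.5.

## Pipeline statistics

- **Multimodality call (filter).** A gene is banked when its fitted
  mixture keeps >= 2 components of weight >= 0.05. The weight of the
  smallest effective component (the *minimum component probability*) is
  carried forward so downstream screens (defaults 0.10 for the sweep,
  0.20 for enrichment) can require that a signature affects a meaningful
  fraction of patients.
- **Enrichment.** Upper-tail hypergeometric test of the screened
  multimodal genes against each gene set, with the population defined as
  all genes passing the mean-expression filter (the genes eligible to be
  detected — not the whole genome, not only the banked genes). Zero
  overlap returns p = 1 exactly. Benjamini-Hochberg controls the FDR
  across tested sets (default q < 0.01).
- **Scan.** Sweeps the minimum-component-probability threshold, reporting
  genes passing, sets enriched, enriched-set genes and cluster counts; the
  recommended threshold maximizes clusters subject to keeping the
  enriched-gene count below the sample count (ill-conditioned fits
  otherwise), ties resolved toward the larger (more parsimonious)
  threshold.
- **Sweep.** Per-set multivariate fit; a set is multimodal when >= 2
  effective clusters remain and the smallest holds >= `min_prob` mass.
  The over-expressing cluster is the effective cluster whose mean vector
  has the largest L1 norm (ties to the lower index); a sample's score is
  its posterior (training) or predictive (test) probability of that
  cluster. Degenerate or skipped sets score a constant 0.5, i.e. no
  information.
- **Prediction.** New samples are scored with component posterior
  predictive Student-t densities weighted by `w_k * n/(n+alpha)`, plus a
  new-cluster column carrying `alpha/(n+alpha)` times the prior predictive
  — the Chinese-restaurant mass for "none of the fitted clusters". A
  sample whose argmax is the new-cluster column is reported unassigned.
- **Cluster profiling.** Welch (unequal-variance) t-statistics per gene,
  inside versus outside a cluster, over *all* genes (GSEA needs the
  non-differential genes for calibration); zero-variance genes get t = 0.
- **Preranked GSEA.** Weighted Kolmogorov-Smirnov-like running sum: hits
  advance by |score|^p (p = 1 by default) normalized over hits, misses
  retreat by 1/(N - N_hit); the ES is the maximum deviation, taking the
  earliest extremum within 1e-12 when magnitudes tie (possible for p = 0).
  The null permutes gene labels (the only exchangeable unit without
  phenotype replicates); p-values are sign-aware with the +1 correction,
  NES divides by the mean same-sign permuted ES, and q follows the
  standard pooled NES-based FDR estimate. Set sizes outside [5, 500]
  after intersection are skipped.
- **N-of-1.** A new profile is classified by the predictive above, then
  z-scored per gene against its assigned cluster's members (sample sd,
  n-1 denominator; zero-spread genes flagged and excluded) and profiled by
  preranked GSEA on the z-scores — enrichments relative to the sample's
  own subtype rather than the whole cohort.

## Synthetic data

The generator emulates a bulk expression cohort as a multivariate Gaussian
over genes on the log2(TPM+1) scale. Backgrounds come either from a real
cohort (per-gene means plus the centered-data factor, so sampling
reproduces the empirical gene-gene covariance without forming the
rank-deficient genome-scale matrix; 1e-6 x mean-variance diagonal jitter,
skipped for exactly-constant genes) or fully synthetically: means uniform
on [2, 6] (comfortably above the mean filter), per-gene standard
deviations on [0.6, 1.2], and consecutive 25-gene blocks sharing a common
within-block correlation drawn from [0.2, 0.6] — a coarse stand-in for
co-expression modules.

An injected subtype follows the definition "distinct mean and correlation
structure": a random `pct_deg` subset of a chosen gene set is shifted by
`effect_size` background standard deviations, and the whole set-gene block
is redrawn under a random SPD covariance (a scaled A A'/d + 0.1 I product,
diagonal rescaled to the background marginal variances). The subtype
specification (DEG subset, covariance) depends only on the seed while
sample draws also depend on a replicate index, so train/test cohort pairs
share one injected subtype. Values are floored at 0 to stay on the
log2(TPM+1) scale (negligible mass is clipped at the default means). The
multi-subtype generator used for the filter → enrich tests gives each
non-baseline subtype a random sign pattern of shifts and its own random
covariance — subtypes that differ only along one collinear direction are
close to information-theoretically undetectable, which real subtypes are
not.

What the generator does **not** emulate: count-level (negative-binomial)
noise, library-size and batch effects, dropout, non-Gaussian marginals,
and cross-covariance between set genes and the rest of the genome within
subtype samples (the redrawn block is independent of the remaining genes).
Passing tests therefore demonstrate correct behavior of the statistical
machinery under the stated Gaussian model, not robustness to every
artifact of real RNA-seq.

The benchmark generates one train/test pair per (set, effect size, %DEG)
cell, fits each detector on the training cohort, scores the test cohort,
and summarizes per-sample ROC AUC (rank-sum identity, ties counting 1/2)
with set-level bootstrap confidence intervals. Detectors are pluggable
adapters (a callable mapping train/test cohorts and the set genes to test
scores), so external single-sample enrichment tools can be compared
without being re-implemented.

## Numerical choices and problem sizes

Relative-ELBO tolerance 1e-6; merge/delete acceptance slack 1e-9 relative;
diagonal jitter 1e-6 x mean diagonal on Cholesky failure; argmax ties
break to the lower component index; hard training labels argmax over
*effective* components only (near-empty components revert to the broad
prior and would otherwise soak up boundary samples); minimum-component
screens apply a 1e-9 tolerance at the threshold boundary.

The test suite and acceptance script use scaled-down but structurally
faithful problem sizes chosen once: 1-D recovery at n = 300 with adjacent
means 6 sigma apart (3 sigma on either side of each decision boundary —
the separation at which near-perfect assignment is statistically
possible); benchmark cohorts of n = 150 over 1,000-gene backgrounds with
40-gene sets; and end-to-end runs on 2,000-gene, 200-sample cohorts with a
30-gene signature, using a single quantile-anchored restart for the
per-gene filter.

## Known limitations

- Diagonal components trade correlation modeling for detection power; see
  the covariance section for when each structure is appropriate and how
  the multimodal-gene restriction controls the resulting false positives.
- Mixture identifiability degrades below ~2 sigma mode separation; the
  filter's recall falls smoothly with separation rather than abruptly.
- The minimum-component probability is a mixing weight, not a sample
  count; for very small cohorts the distinction matters.
- GSEA's gene-label permutation null ignores inter-gene correlation, as
  all preranked GSEA implementations do; q-values should be read
  comparatively.
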