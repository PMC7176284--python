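# mmsig — multimodal gene-expression signatures

`mmsig` finds **multimodally expressed genes** and **multimodal gene-set
signatures** in tumor expression cohorts, without a matched-normal
reference. Bulk tumor RNA mixes cancer-cell programs with infiltrating
immune and stromal cells, so many genes are expressed at two or more
discrete levels across a cohort; those genes mark expression subtypes
(often tumor-microenvironment states) that standard cohort-wide analyses
blur out. The package is aimed at computational cancer biologists working
with gene-by-sample matrices of log2(TPM+1) expression and MSigDB-style
gene sets.

## The model

Expression of a gene (or a panel of genes) is modeled as a Dirichlet
process mixture of Gaussians, truncated at K components via the
stick-breaking construction:

    nu_k ~ Beta(1, alpha),   pi_k = nu_k * prod_{l<k} (1 - nu_l)
    (mu_k, Lambda_k) ~ NormalWishart(m0, kappa0, W0, dof0)
    z_i | pi ~ Categorical(pi),   x_i | z_i ~ N(mu_{z_i}, Lambda_{z_i}^{-1})

The posterior is approximated by full-batch mean-field coordinate ascent
(variational inference) with interleaved, ELBO-guarded merge and delete
moves, so the number of occupied components is inferred rather than fixed.
Component covariances are diagonal by default (each gene gets its own
variance per cluster; `covariance_type="full"` learns dense covariances for
small panels).

The pipeline stages mirror how the model is used:

| stage | what it does |
|---|---|
| `filtering` | per-gene univariate DP-GMM; banks genes with >= 2 expression clusters |
| `enrich` | hypergeometric over-representation of multimodal genes in gene sets (BH-FDR), minimum-component-probability *scan*, multivariate clustering over enriched genes |
| `sweep` | per-gene-set multivariate DP-GMM screen; flags multimodal sets, labels the over-expressing (largest-L1-mean) cluster, scores samples |
| `profiling` | Welch-t cluster profiling and preranked GSEA; N-of-1 classification and cluster-relative z-scoring of single samples |
| `synthetic` | multivariate-Gaussian cohort generator with injected subtypes, and the ROC/AUC detection benchmark |

## Worked example

`examples/02_enrich_subtypes.py` generates a 2,000-gene, 200-sample cohort
carrying one 3-subtype signature over a 30-gene set, then runs the
filter → enrich → cluster pipeline:

```
filter: 31 multimodal genes (universe 1999)

top enriched sets (population = mean-filtered genes):
set_name  overlap      p_value      q_value
 SET_000       29 6.147763e-64 1.229553e-62
 SET_004        2 7.306363e-02 4.870909e-01
 SET_018        2 7.306363e-02 4.870909e-01

clustering over 29 enriched genes: 3 clusters, ARI vs ground truth = 1.000
cluster posterior fractions (incl. mass reserved for an unseen cluster):
{0: 0.317, 1: 0.32, 2: 0.339, 'new': 0.024}
```

Reading the output: the univariate filter reduced 1,999 eligible genes to
31 multimodal candidates; 29 of them land in the injected set `SET_000`,
which dominates the hypergeometric ranking (q ≈ 1e-62). Clustering the
samples over those 29 genes recovers the three planted subtypes exactly
(adjusted Rand index 1.0), each holding roughly a third of the posterior
mass, with 2.4% reserved for a yet-unseen cluster — the Dirichlet-process
prior's allowance for new subtypes in future samples.

`examples/05_benchmark.py` shows the detection benchmark: the sweep
detector's test-cohort AUC rises from 0.5 (no signal) at effect size 0.25
to ~1.0 at effect size 3.0.

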