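"""Screen a gene-set database for multimodal expression signatures.

Injects an over-expressing subtype into one gene set of a synthetic cohort
and sweeps every set with a multivariate DP-GMM, restricted — as in the
cohort workflow — to the genes the univariate filter called multimodal
(this keeps co-expressed but unimodal sets from producing spurious
clusters). A set is flagged when it splits into >= 2 clusters whose
smallest covers at least 10% of samples; the over-expressing cluster is
the one with the largest L1-norm mean, and each sample is scored by its
probability of belonging to it.
"""

from mmsig.dpmm import FitConfig
from mmsig.filtering import fit_gene_models
from mmsig.sweep import sweep_db
from mmsig.synthetic import (generate_cohort, random_gene_set_db, roc_auc,
                             synthetic_background)

bg = synthetic_background(600, seed=11)
db = random_gene_set_db(bg, 8, 40, seed=11)
cohort = generate_cohort(bg, db["SET_002"], n_total=150,
                         subtype_fraction=0.35, effect_size=2.5,
                         pct_deg=0.25, seed=21, set_name="SET_002")

bank = fit_gene_models(cohort.expr, config=FitConfig(seed=4, n_restarts=1))
print(f"filter banked {len(bank)} multimodal genes\n")

results, table = sweep_db(cohort.expr, db, config=FitConfig(seed=4),
                          min_prob=0.1, restrict_to_multimodal=True,
                          bank=bank)
print(table[["set_name", "n_genes_used", "k_effective", "minor_prob",
             "multimodal"]].to_string(index=False))

hit = next(r for r in results if r.set_name == "SET_002")
auc = roc_auc(hit.sample_scores[cohort.labels.index], cohort.labels)
print(f"\ninjected set SET_002: over-expressing cluster "
      f"{hit.overexpressing_cluster}, per-sample score AUC vs truth = "
      f"{auc:.3f} (1.0 = the subtype is perfectly ranked)")
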