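"""Classify and profile a single new tumor sample (N-of-1 analysis).

Fits a 2-cluster expression model on a cohort, classifies one new sample
into a cluster (with explicit mass reserved for "none of the fitted
clusters"), z-scores the sample against its cluster's members, and runs
preranked GSEA on the z-scores to find the sample's private enrichments.
"""

import numpy as np
import pandas as pd

from mmsig.dpmm import DPPrior, FitConfig, fit
from mmsig.io import ExpressionMatrix, GeneSetDB
from mmsig.profiling import (RankedList, nof1_assign, nof1_zscores,
                             preranked_gsea)

rng = np.random.default_rng(9)
genes = [f"g{i}" for i in range(40)]
# cohort with two expression clusters over the first 10 genes
base = rng.normal(4.0, 1.0, size=(120, 40))
base[60:, :10] += 5.0
X = np.clip(base, 0, None)
model = fit(X, DPPrior(alpha=1.0, k_trunc=4), FitConfig(seed=2),
            gene_ids=genes)
print(f"cohort model: {model.effective_components(0.05)} clusters, "
      f"weights {np.round(model.weights[model.weights >= 0.05], 2)}")

# a new sample from cluster-1-like expression, plus a private up-shift
# on genes g20..g24
sample = pd.Series(np.clip(rng.normal(4.0, 1.0, 40), 0, None), index=genes)
sample[:10] += 5.0
sample[20:25] += 3.0

label, proba = nof1_assign(model, sample)
print(f"new sample assigned to cluster {label} "
      f"(P = {proba[f'cluster_{label}']:.3f}, "
      f"new-cluster mass = {proba['new']:.3f})")

members = ExpressionMatrix(pd.DataFrame(
    X[model.labels == label].T, index=genes,
    columns=[f"m{i}" for i in range((model.labels == label).sum())]))
z, excluded = nof1_zscores(sample, members)
ranking = RankedList.from_scores(z)
db = GeneSetDB.from_mapping({
    "PRIVATE_SIGNATURE": genes[20:25],
    "CLUSTER_SIGNATURE": genes[:10],
    "RANDOM": genes[30:38],
})
gsea = preranked_gsea(ranking, db, n_perm=500, seed=3)
print("\npreranked GSEA on cluster-relative z-scores:")
print(gsea[["set_name", "es", "nes", "p_nominal", "q_value"]]
      .to_string(index=False))
print("\nThe sample's private up-shift (PRIVATE_SIGNATURE) is enriched, "
      "while its cluster-defining genes are not — z-scoring against the "
      "sample's own cluster removes the shared subtype signal.")
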