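"""The *enrich* stage: over-representation of multimodal genes in gene sets,
the minimum-component-probability *scan*, and multivariate clustering of
samples over enriched-set genes.

The hypergeometric test asks whether the multimodal genes (hits) land in a
gene set more often than chance, with the population being all genes that
survived the mean-expression screen — the genes that were eligible to be
detected. Benjamini-Hochberg controls the FDR across the tested sets.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dpmm import DPPrior, FitConfig, MixtureModel, fit
from .filtering import ModelBank
from .io import ExpressionMatrix, GeneSetDB

logger = logging.getLogger(__name__)

__all__ = ["min_prob_filter", "hypergeom_enrich", "enrich_cluster", "scan"]


def min_prob_filter(bank: ModelBank, threshold: float) -> list[str]:
    """Banked genes whose minor component probability is at least ``threshold``.

    Screens out multimodal genes whose smallest expression cluster covers too
    few samples to define a useful subtype.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    # tolerance keeps weights at the boundary (they carry ~1e-16 float noise)
    return [g for g in bank.genes
            if bank.minor_component_probability(g) >= threshold - 1e-9]


def hypergeom_enrich(hits: Sequence[str], universe: Sequence[str],
                     db: GeneSetDB, fdr: float = 0.01) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` in ``db``.

    Each set is intersected with the universe before testing; sets with an
    empty intersection are skipped. An overlap of zero yields p = 1 exactly.

    Returns a table sorted by ascending p with columns ``set_name``,
    ``set_size_in_universe``, ``overlap``, ``overlap_genes``, ``p_value``,
    ``q_value`` (Benjamini-Hochberg) and ``significant`` (q < fdr).
    """
    universe_set = set(universe)
    hit_set = set(hits)
    stray = hit_set - universe_set
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)[:10]}")
    M, n_hits = len(universe_set), len(hit_set)
    rows = []
    for name in db:
        members = set(db[name]) & universe_set
        if not members:
            continue
        overlap_genes = sorted(members & hit_set)
        k = len(overlap_genes)
        p = 1.0 if k == 0 else float(
            hypergeom.sf(k - 1, M, len(members), n_hits))
        rows.append({"set_name": name,
                     "set_size_in_universe": len(members),
                     "overlap": k,
                     "overlap_genes": ",".join(overlap_genes),
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set_name", "set_size_in_universe",
                                        "overlap", "overlap_genes", "p_value"])
    if len(table):
        _, q, _, _ = multipletests(table["p_value"].to_numpy(),
                                   method="fdr_bh")
        table["q_value"] = q
        table["significant"] = table["q_value"] < fdr
        table = table.sort_values(["p_value", "set_name"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["q_value"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def enriched_gene_union(table: pd.DataFrame) -> list[str]:
    """Hit genes belonging to at least one significant set, sorted."""
    genes: set[str] = set()
    for _, row in table[table["significant"]].iterrows():
        if row["overlap_genes"]:
            genes.update(row["overlap_genes"].split(","))
    return sorted(genes)


def enrich_cluster(expr: ExpressionMatrix, enriched_genes: Sequence[str],
                   prior: DPPrior | None = None,
                   config: FitConfig | None = None):
    """Cluster samples with a multivariate DP-GMM over the enriched genes.

    Returns ``(model, assignments, fractions)`` where ``assignments`` is a
    per-sample Series of cluster labels and ``fractions`` maps each effective
    cluster — plus ``"new"`` — to its posterior mass. The cluster fractions
    are the renormalized effective mixing weights scaled by ``n/(n+alpha)``,
    and the new-cluster mass is ``alpha/(n+alpha)``, so they sum to 1.
    """
    enriched_genes = list(enriched_genes)
    if len(enriched_genes) < 2:
        raise ValueError("need at least 2 enriched genes to cluster")
    prior = prior or DPPrior(alpha=5.0, k_trunc=5)
    config = config or FitConfig()
    n = expr.n_samples
    if len(enriched_genes) >= n:
        logger.warning("clustering %d genes with only %d samples; the "
                       "inference may be unstable", len(enriched_genes), n)
    X = expr.samples_by_genes(enriched_genes)
    model = fit(X.to_numpy(dtype=float), prior, config,
                gene_ids=enriched_genes)
    w = model.weights
    eff = np.flatnonzero(w >= config.min_weight)
    alpha = model._pr["alpha"]
    scale = n / (n + alpha)
    w_eff = w[eff] / w[eff].sum()
    fractions = {int(k): float(w_eff[j] * scale) for j, k in enumerate(eff)}
    fractions["new"] = float(alpha / (n + alpha))
    labels = pd.Series(model.labels, index=X.index, name="cluster")
    return model, labels, fractions


def scan(bank: ModelBank, expr: ExpressionMatrix, db: GeneSetDB,
         thresholds: Sequence[float], fdr: float = 0.01,
         prior: DPPrior | None = None,
         config: FitConfig | None = None):
    """Survey minimum-component-probability thresholds.

    For every threshold the routine counts the genes passing the screen, the
    sets enriched at ``q < fdr``, the genes those sets contribute, and the
    clusters found over them. The recommended threshold maximizes the
    cluster count subject to the enriched-gene count staying below the
    sample count (ties resolved toward the larger threshold); if no
    threshold meets the constraint the recommendation is ``None``.

    Returns ``(summary_table, recommended_threshold)``.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    n = expr.n_samples
    rows = []
    for thr in thresholds:
        hits = min_prob_filter(bank, thr)
        table = hypergeom_enrich(hits, bank.universe, db, fdr)
        genes = enriched_gene_union(table)
        n_sets = int(table["significant"].sum()) if len(table) else 0
        if len(genes) >= 2:
            _, labels, _ = enrich_cluster(expr, genes, prior, config)
            n_clusters = int(labels.nunique())
        else:
            n_clusters = 0
        rows.append({"threshold": thr, "n_genes_passing": len(hits),
                     "n_enriched_sets": n_sets,
                     "n_enriched_genes": len(genes),
                     "n_clusters": n_clusters})
    summary = pd.DataFrame(rows)
    ok = summary[summary["n_enriched_genes"] < n]
    ok = ok[ok["n_clusters"] > 0]
    if len(ok):
        best = ok.sort_values(["n_clusters", "threshold"]).iloc[-1]
        recommended = float(best["threshold"])
    else:
        recommended = None
    return summary, recommended
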