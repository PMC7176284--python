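"""The *sweep* stage: screen whole gene sets for multimodal expression.

For every gene set, a multivariate DP-GMM is fit to the samples over the
set's (mean-filtered, optionally multimodal-restricted) genes. A set is
flagged multimodal when at least two effective clusters remain and the
smallest one holds at least the configured minimum component probability.
The over-expressing cluster is the effective cluster whose mean vector has
the largest L1 norm, and each sample's score is its posterior probability of
belonging to that cluster — a single-sample alternative to ssGSEA-style
enrichment scores.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dpmm import DPPrior, FitConfig, MixtureModel, fit
from .filtering import ModelBank, mean_filter
from .io import ExpressionMatrix, GeneSetDB

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "sweep_set", "sweep_db", "jaccard_network",
           "score_samples"]


@dataclass
class SweepResult:
    """Outcome of the multivariate screen on one gene set."""

    set_name: str
    genes_used: list[str] = field(default_factory=list)
    k_effective: int = 0
    minor_prob: float = float("nan")
    assignments: pd.Series | None = None
    overexpressing_cluster: int | None = None
    sample_scores: pd.Series | None = None
    multimodal: bool = False
    skipped_reason: str | None = None
    model: MixtureModel | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


def _overexpressing_cluster(model: MixtureModel, min_weight: float) -> int:
    """Effective cluster with the largest L1-norm mean (ties: lower index)."""
    w = model.weights
    eff = np.flatnonzero(w >= min_weight)
    l1 = np.abs(model.means[eff]).sum(axis=1)
    return int(eff[int(np.argmax(l1))])


def sweep_set(expr: ExpressionMatrix, set_genes, set_name: str = "",
              prior: DPPrior | None = None, config: FitConfig | None = None,
              min_prob: float = 0.1, mean_threshold: float = 1.0,
              restrict_to_multimodal: bool = False,
              bank: ModelBank | None = None) -> SweepResult:
    """Fit a multivariate DP-GMM to one gene set and score the samples."""
    prior = prior or DPPrior(k_trunc=5)
    config = config or FitConfig()
    usable = [g for g in set_genes if g in expr.values.index]
    if mean_threshold is not None:
        keep = set(mean_filter(expr, mean_threshold))
        usable = [g for g in usable if g in keep]
    if restrict_to_multimodal:
        if bank is None:
            raise ValueError("restrict_to_multimodal requires a model bank")
        usable = [g for g in usable if g in bank]
    if len(usable) < 2:
        return SweepResult(set_name=set_name, genes_used=usable,
                           skipped_reason=f"only {len(usable)} usable genes")
    if len(usable) >= expr.n_samples:
        logger.warning("set %s: %d genes with only %d samples; the "
                       "inference may be unstable", set_name, len(usable),
                       expr.n_samples)
    X = expr.samples_by_genes(usable)
    model = fit(X.to_numpy(dtype=float), prior, config, gene_ids=usable)
    w = model.weights
    eff = np.flatnonzero(w >= config.min_weight)
    k_eff = eff.size
    minor = float(w[eff].min())
    over = _overexpressing_cluster(model, config.min_weight)
    scores = pd.Series(model.responsibilities[:, over], index=X.index,
                       name="score")
    labels = pd.Series(model.labels, index=X.index, name="cluster")
    return SweepResult(
        set_name=set_name, genes_used=usable, k_effective=int(k_eff),
        minor_prob=minor, assignments=labels,
        overexpressing_cluster=over, sample_scores=scores,
        multimodal=bool(k_eff >= 2 and minor >= min_prob),
        model=model)


def score_samples(result: SweepResult, expr: ExpressionMatrix) -> pd.Series:
    """Score new samples with a fitted sweep model.

    The score is the predictive probability of the over-expressing cluster.
    Skipped or degenerate results yield a constant score of 0.5 (no signal).
    """
    samples = expr.sample_ids
    if result.skipped or result.model is None or result.k_effective < 2:
        return pd.Series(0.5, index=samples, name="score")
    X = expr.samples_by_genes(result.genes_used)
    _, proba = result.model.predict(X)
    col = f"cluster_{result.overexpressing_cluster}"
    if col not in proba.columns:
        return pd.Series(0.5, index=samples, name="score")
    return pd.Series(proba[col].to_numpy(), index=samples, name="score")


def sweep_db(expr: ExpressionMatrix, db: GeneSetDB,
             prior: DPPrior | None = None, config: FitConfig | None = None,
             min_prob: float = 0.1, mean_threshold: float = 1.0,
             restrict_to_multimodal: bool = False,
             bank: ModelBank | None = None):
    """Run :func:`sweep_set` over a whole database.

    Per-set seeds are derived from the master seed and the set name, so the
    table is reproducible and independent of database ordering. Returns
    ``(results, table)`` where ``table`` has one row per set.
    """
    config = config or FitConfig()
    results: list[SweepResult] = []
    rows = []
    for name in db:
        child = np.random.SeedSequence(
            [int(config.seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        cfg = FitConfig(max_iter=config.max_iter, tol=config.tol,
                        n_restarts=config.n_restarts,
                        min_weight=config.min_weight,
                        delete_weight=config.delete_weight,
                        do_moves=config.do_moves, seed=seed)
        res = sweep_set(expr, db[name], set_name=name, prior=prior,
                        config=cfg, min_prob=min_prob,
                        mean_threshold=mean_threshold,
                        restrict_to_multimodal=restrict_to_multimodal,
                        bank=bank)
        results.append(res)
        over_size = (int((res.assignments == res.overexpressing_cluster).sum())
                     if res.assignments is not None else 0)
        rows.append({"set_name": name, "n_genes_used": len(res.genes_used),
                     "k_effective": res.k_effective,
                     "minor_prob": res.minor_prob,
                     "multimodal": res.multimodal,
                     "overexpressing_cluster_size": over_size,
                     "skipped_reason": res.skipped_reason or ""})
    table = pd.DataFrame(rows, columns=["set_name", "n_genes_used",
                                        "k_effective", "minor_prob",
                                        "multimodal",
                                        "overexpressing_cluster_size",
                                        "skipped_reason"])
    return results, table


def jaccard_network(db: GeneSetDB, edge_threshold: float = 0.0) -> pd.DataFrame:
    """Pairwise Jaccard similarity network over gene sets.

    Returns an edge list (``source``, ``target``, ``jaccard``) for all
    unordered pairs with similarity at least ``edge_threshold``; self-edges
    are excluded.
    """
    names = list(db)
    members = {n: set(db[n]) for n in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            union = members[a] | members[b]
            j = len(members[a] & members[b]) / len(union) if union else 0.0
            if j >= edge_threshold:
                rows.append({"source": a, "target": b, "jaccard": j})
    return pd.DataFrame(rows, columns=["source", "target", "jaccard"])
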