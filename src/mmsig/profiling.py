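"""Cluster profiling and N-of-1 analysis.

Cluster profiling ranks every gene by a Welch t-statistic contrasting
samples inside a cluster against those outside, then runs preranked gene-set
enrichment analysis (GSEA) on the ranking. The N-of-1 routine classifies a
single new tumor profile into a fitted cluster, z-scores its expression
against that cluster's members, and runs preranked GSEA on the z-scores —
so the sample is profiled relative to its own expression subtype rather
than the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dpmm import MixtureModel, predict
from .io import ExpressionMatrix, GeneSetDB

__all__ = ["RankedList", "cluster_tstats", "preranked_gsea", "nof1_assign",
           "nof1_zscores", "enrichment_score"]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending score (most up-regulated first)."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.gene_ids) != scores.size:
            raise ValueError("gene_ids and scores differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if scores.size > 1 and np.any(np.diff(scores) > 0):
            raise ValueError("scores must be sorted descending")

    @classmethod
    def from_scores(cls, scores: pd.Series | dict) -> "RankedList":
        """Build a ranked list from gene -> score, sorting descending.

        Ties are broken by gene identifier for determinism.
        """
        s = pd.Series(scores, dtype=float)
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        return cls(tuple(str(g) for g in order),
                   s.loc[order].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.gene_ids)


def cluster_tstats(expr: ExpressionMatrix, assignments: pd.Series,
                   cluster) -> pd.DataFrame:
    """Welch t-statistic per gene, in-cluster versus out-of-cluster.

    Positive values mean the gene is higher inside the cluster. Genes with
    zero variance in both groups get a statistic of 0. All genes are used:
    GSEA needs the non-differential genes to calibrate enrichment scores.
    """
    assignments = assignments.reindex(expr.sample_ids)
    if assignments.isna().any():
        raise ValueError("assignments missing for some samples")
    inside = assignments == cluster
    if inside.sum() < 2 or (~inside).sum() < 2:
        raise ValueError("need at least 2 samples inside and outside the "
                         "cluster")
    a = expr.values.loc[:, inside.index[inside]].to_numpy(dtype=float)
    b = expr.values.loc[:, inside.index[~inside]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.DataFrame({"gene": expr.gene_ids, "t": t}).set_index("gene")


def _running_es(weights_hit: np.ndarray, is_hit: np.ndarray):
    """Weighted Kolmogorov-Smirnov-like running sum along a ranking.

    ``weights_hit`` holds |score|^p at hit positions (0 at misses). Returns
    (running sum, ES, index of the extremum).
    """
    n = is_hit.size
    n_hit = int(is_hit.sum())
    denom_hit = weights_hit.sum()
    if denom_hit <= 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        weights_hit = is_hit.astype(float)
        denom_hit = float(n_hit)
    p_hit = np.cumsum(weights_hit) / denom_hit
    p_miss = np.cumsum(~is_hit) / float(n - n_hit)
    running = p_hit - p_miss
    # earliest extremum within 1e-12 of the max deviation: magnitude ties
    # (possible with unweighted rational steps) break deterministically
    mag = np.abs(running)
    idx = int(np.argmax(mag >= mag.max() - 1e-12))
    return running, float(running[idx]), idx


def enrichment_score(ranking: RankedList, genes, weight_p: float = 1.0):
    """Enrichment score of one gene set along a ranked list.

    Hits advance the running sum by ``|score|^p`` (normalized by the total
    over hits) and misses retreat it by ``1/(N - N_hit)``; the ES is the
    running sum's maximum deviation from zero. Returns (es, leading_edge).
    """
    members = set(genes)
    is_hit = np.fromiter((g in members for g in ranking.gene_ids),
                         dtype=bool, count=len(ranking))
    if not is_hit.any() or is_hit.all():
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(ranking.scores) ** weight_p * is_hit
    running, es, idx = _running_es(w, is_hit)
    if es >= 0:
        lead = [g for g, h in zip(ranking.gene_ids[: idx + 1], is_hit) if h]
    else:
        lead = [g for g, h in zip(ranking.gene_ids[idx:], is_hit[idx:]) if h]
    return es, lead


def _perm_es(scores: np.ndarray, n_hit: int, weight_p: float, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES values for random gene-label permutations (random hit positions)."""
    n = scores.size
    u = rng.random((n_perm, n))
    hit_idx = np.argpartition(u, n_hit - 1, axis=1)[:, :n_hit]
    H = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(H, hit_idx, True, axis=1)
    w = np.abs(scores) ** weight_p
    hw = H * w
    denom = hw.sum(axis=1, keepdims=True)
    bad = denom[:, 0] <= 0
    if bad.any():
        hw[bad] = H[bad].astype(float)
        denom = hw.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(hw, axis=1) / denom
    p_miss = np.cumsum(~H, axis=1) / float(n - n_hit)
    running = p_hit - p_miss
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def preranked_gsea(ranking: RankedList, db: GeneSetDB,
                   weight_p: float = 1.0, n_perm: int = 1000,
                   seed: int = 0, min_size: int = 5,
                   max_size: int = 500) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    For each set (intersected with the ranking; sets outside
    ``[min_size, max_size]`` skipped) the ES is computed as in
    :func:`enrichment_score`. Nominal p-values compare the ES with permuted
    ES values of the same sign, NES divides the ES by the mean magnitude of
    the same-sign permuted values, and q is the standard NES-based FDR
    estimate pooled across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rank_genes = set(ranking.gene_ids)
    work = []
    for name in db:
        members = set(db[name]) & rank_genes
        if not (min_size <= len(members) <= max_size):
            continue
        if len(members) == len(ranking):
            continue
        work.append((name, members))
    rows = []
    all_perm_nes: list[np.ndarray] = []
    perm_cache: dict[int, np.ndarray] = {}
    for name, members in work:
        es, lead = enrichment_score(ranking, members, weight_p)
        n_hit = len(members)
        if n_hit not in perm_cache:
            # one permutation pool per set size; sizes recur across dbs
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, n_hit]))
            perm_cache[n_hit] = _perm_es(ranking.scores, n_hit, weight_p,
                                         n_perm, rng)
        perm = perm_cache[n_hit]
        same = perm[perm >= 0] if es >= 0 else perm[perm < 0]
        if same.size:
            p_nom = (np.sum(np.abs(same) >= abs(es)) + 1.0) / (same.size + 1.0)
            mean_mag = np.abs(same).mean()
        else:
            p_nom, mean_mag = 1.0 / (n_perm + 1.0), abs(es) or 1.0
        nes = es / mean_mag if mean_mag > 0 else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pos_mean = np.abs(perm[perm >= 0]).mean() if (perm >= 0).any() else 1.0
            neg_mean = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else 1.0
        perm_nes = np.where(perm >= 0, perm / pos_mean, perm / neg_mean)
        all_perm_nes.append(perm_nes)
        rows.append({"set_name": name, "size": n_hit, "es": es, "nes": nes,
                     "p_nominal": p_nom,
                     "leading_edge": ",".join(lead)})
    table = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes",
                                        "p_nominal", "leading_edge"])
    if len(table):
        pooled = np.concatenate(all_perm_nes)
        obs = table["nes"].to_numpy()
        q = np.ones(len(table))
        for i, nes in enumerate(obs):
            if nes >= 0:
                num_pool = pooled[pooled >= 0]
                num = np.mean(num_pool >= nes) if num_pool.size else 0.0
                den = np.mean(obs[obs >= 0] >= nes) if (obs >= 0).any() else 1.0
            else:
                num_pool = pooled[pooled < 0]
                num = np.mean(num_pool <= nes) if num_pool.size else 0.0
                den = np.mean(obs[obs < 0] <= nes) if (obs < 0).any() else 1.0
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        table["q_value"] = q
        table = table.sort_values(["p_nominal", "set_name"],
                                  kind="mergesort").reset_index(drop=True)
        table = table[["set_name", "size", "es", "nes", "p_nominal",
                       "q_value", "leading_edge"]]
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table


def nof1_assign(model: MixtureModel, sample: pd.Series):
    """Classify one new expression profile into a fitted cluster.

    ``sample`` maps gene identifiers to expression values and must cover all
    model genes. Returns ``(label, probabilities)`` where ``label`` is the
    cluster index or -1 when the new-cluster mass dominates, and
    ``probabilities`` is a Series over effective clusters plus ``"new"``.
    """
    missing = [g for g in model.gene_ids if g not in sample.index]
    if missing:
        raise KeyError(f"sample is missing model genes: {missing[:10]}")
    x = sample.loc[model.gene_ids].to_numpy(dtype=float)[None, :]
    labels, proba = predict(model, x)
    return int(labels[0]), proba.iloc[0]


def nof1_zscores(sample: pd.Series, cluster_members: ExpressionMatrix):
    """Per-gene z-scores of a sample relative to its cluster's members.

    Uses the sample standard deviation (n-1 denominator) over the cluster.
    Genes with zero spread in the cluster are flagged and excluded from the
    returned ranking material. Returns ``(zscores, excluded_genes)``.
    """
    if cluster_members.n_samples < 3:
        raise ValueError("cluster must have at least 3 members")
    genes = [g for g in cluster_members.gene_ids if g in sample.index]
    vals = cluster_members.values.loc[genes]
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    ok = ~constant
    z = (sample.loc[genes][ok] - mu[ok]) / sd[ok]
    z.name = "z"
    return z, list(mu.index[constant])
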