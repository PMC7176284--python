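"""Synthetic expression cohorts and the detection benchmark.

Cohorts are drawn from a multivariate Gaussian background over genes (mean
and covariance estimated from a reference cohort, or fully synthetic with
block-structured correlation). An expression subtype is injected as a
random fraction of samples whose differentially expressed genes — a random
``pct_deg`` share of a chosen gene set — are mean-shifted by
``effect_size`` background standard deviations, under a randomly generated
covariance on the set genes. The benchmark fits a detector on a training
cohort, scores an independently generated test cohort, and summarizes
detection as the area under the ROC curve over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import SCALE_LOG, ExpressionMatrix, GeneSetDB
from .sweep import score_samples, sweep_set

logger = logging.getLogger(__name__)

__all__ = ["BackgroundModel", "SyntheticCohort", "estimate_background",
           "synthetic_background", "make_subtype_covariance",
           "generate_cohort", "generate_multimodal_cohort", "roc_auc",
           "run_benchmark", "sweep_adapter", "random_gene_set_db"]

#: relative diagonal jitter added when sampling from an empirical covariance
COV_JITTER = 1e-6


@dataclass
class BackgroundModel:
    """Sampling representation of the background gene-gene covariance.

    ``factor`` is any matrix F with covariance = F'F (a centered-data factor
    for cohort-estimated backgrounds, a Cholesky factor for synthetic ones),
    which permits sampling without forming the possibly rank-deficient
    genome-scale covariance. Genes with zero variance stay exactly constant.
    """

    gene_ids: list[str]
    mean: np.ndarray
    factor: np.ndarray                       # (r, d) with cov = F' F
    source: str = "synthetic"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.factor = np.asarray(self.factor, dtype=float)
        if self.factor.shape[1] != self.mean.size:
            raise ValueError("factor and mean disagree on the gene count")
        if len(self.gene_ids) != self.mean.size:
            raise ValueError("gene_ids and mean disagree in length")

    @property
    def n_genes(self) -> int:
        return self.mean.size

    def variances(self) -> np.ndarray:
        return (self.factor ** 2).sum(axis=0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` samples (n x d), reproducible under the generator."""
        z = rng.standard_normal((n, self.factor.shape[0]))
        X = self.mean[None, :] + z @ self.factor
        var = self.variances()
        jitter_sd = np.sqrt(COV_JITTER * max(float(var.mean()), 0.0))
        live = var > 0
        if jitter_sd > 0 and live.any():
            X[:, live] += jitter_sd * rng.standard_normal((n, int(live.sum())))
        return X


@dataclass
class SyntheticCohort:
    """A generated cohort with its injection ground truth."""

    expr: ExpressionMatrix
    labels: pd.Series                        # 1 = subtype, 0 = background
    injected_set: str
    deg_genes: list[str]
    effect_size: float
    pct_deg: float
    seed: int
    subtype_fraction: float = float("nan")


def estimate_background(expr: ExpressionMatrix) -> BackgroundModel:
    """Estimate the background mean and covariance factor from a cohort.

    The covariance is represented by the centered data matrix divided by
    sqrt(n-1), so sampled cohorts reproduce the cohort's gene-gene
    covariance in expectation even when genes far outnumber samples.
    """
    if expr.n_samples < 20:
        raise ValueError("need at least 20 samples to estimate a background")
    if expr.scale != SCALE_LOG:
        raise ValueError("background estimation expects log2(TPM+1) values")
    X = expr.values.to_numpy(dtype=float).T             # (n, d)
    mean = X.mean(axis=0)
    factor = (X - mean) / np.sqrt(X.shape[0] - 1)
    return BackgroundModel(expr.gene_ids, mean, factor, source="cohort")


def synthetic_background(n_genes: int, seed: int = 0, block_size: int = 25,
                         mean_range: tuple[float, float] = (2.0, 6.0),
                         sd_range: tuple[float, float] = (0.6, 1.2),
                         block_corr_range: tuple[float, float] = (0.2, 0.6),
                         gene_prefix: str = "G") -> BackgroundModel:
    """Fully synthetic background with block-structured gene correlation.

    Genes fall into consecutive blocks of ``block_size`` sharing a common
    within-block correlation; means sit well above the mean-expression
    filter so the whole panel is eligible downstream.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    gene_ids = [f"{gene_prefix}{i:04d}" for i in range(n_genes)]
    mean = rng.uniform(*mean_range, size=n_genes)
    sd = rng.uniform(*sd_range, size=n_genes)
    factor = np.zeros((n_genes, n_genes))
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        b = stop - start
        rho = rng.uniform(*block_corr_range)
        C = np.full((b, b), rho)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        s = sd[start:stop]
        factor[start:stop, start:stop] = (L * s[:, None]).T
    return BackgroundModel(gene_ids, mean, factor, source="synthetic")


def make_subtype_covariance(d: int, target_variances,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random SPD covariance with a prescribed diagonal.

    A random square matrix product A A'/d (plus a small ridge) provides a
    positive-definite correlation skeleton, which is then rescaled so the
    diagonal equals ``target_variances`` exactly.
    """
    if d < 1:
        raise ValueError("d must be at least 1")
    tv = np.broadcast_to(np.asarray(target_variances, dtype=float), (d,))
    if np.any(tv <= 0):
        raise ValueError("target variances must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(int(seed) & 0x7FFFFFFF))
    A = rng.standard_normal((d, d))
    C = A @ A.T / d + 0.1 * np.eye(d)
    s = np.sqrt(tv / np.diag(C))
    return C * np.outer(s, s)


def generate_cohort(background: BackgroundModel, set_genes: Sequence[str],
                    n_total: int, subtype_fraction: float,
                    effect_size: float, pct_deg: float, seed: int = 0,
                    set_name: str = "", replicate: int = 0) -> SyntheticCohort:
    """Inject one expression subtype into a background cohort.

    Subtype samples get their set-gene block redrawn under a random subtype
    covariance (marginal variances kept at background levels), with the DEG
    subset mean-shifted by ``effect_size`` background standard deviations.
    Values are floored at 0 to stay on the log2(TPM+1) scale.

    The subtype *specification* (which genes are DEG, the subtype
    covariance) is determined by ``seed`` alone, while the sample draws also
    depend on ``replicate`` — so cohorts generated with the same seed but
    different replicates share one injected subtype (paired training and
    test data), and different seeds define different subtypes.
    """
    if not 0 < subtype_fraction < 1:
        raise ValueError("subtype_fraction must lie in (0, 1)")
    if not 0 < pct_deg <= 1:
        raise ValueError("pct_deg must lie in (0, 1]")
    idx = {g: i for i, g in enumerate(background.gene_ids)}
    set_in = [g for g in set_genes if g in idx]
    if not set_in:
        raise ValueError("no set genes present in the background")
    n_deg = round(pct_deg * len(set_in))
    if n_deg == 0:
        raise ValueError("pct_deg rounds to an empty DEG subset")
    n_sub = int(round(subtype_fraction * n_total))
    if not 0 < n_sub < n_total:
        raise ValueError("subtype size must be strictly between 0 and n_total")

    spec_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0]))
    deg_genes = sorted(spec_rng.choice(set_in, size=n_deg,
                                       replace=False).tolist())
    set_idx = np.asarray([idx[g] for g in set_in])
    var = np.maximum(background.variances()[set_idx], 1e-8)
    sub_cov = make_subtype_covariance(len(set_in), var, spec_rng)
    L = np.linalg.cholesky(sub_cov + 1e-10 * np.eye(len(set_in)))
    mu_set = background.mean[set_idx].copy()
    deg_mask = np.isin(np.asarray(set_in), deg_genes)
    mu_set[deg_mask] += effect_size * np.sqrt(var[deg_mask])

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 1 + int(replicate)]))
    X = background.sample(n_total, rng)                # (n, d)
    z = rng.standard_normal((n_sub, len(set_in)))
    X[:n_sub, set_idx] = mu_set[None, :] + z @ L.T

    labels = np.zeros(n_total, dtype=int)
    labels[:n_sub] = 1
    order = rng.permutation(n_total)
    X = np.clip(X[order], 0.0, None)
    labels = labels[order]
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    expr = ExpressionMatrix(
        pd.DataFrame(X.T, index=background.gene_ids, columns=sample_ids),
        SCALE_LOG)
    return SyntheticCohort(expr, pd.Series(labels, index=sample_ids,
                                           name="subtype"),
                           set_name, deg_genes, float(effect_size),
                           float(pct_deg), int(seed),
                           subtype_fraction=float(subtype_fraction))


def generate_multimodal_cohort(background: BackgroundModel,
                               signature_genes: Sequence[str],
                               n_total: int, n_subtypes: int = 3,
                               separation: float = 3.0,
                               seed: int = 0) -> SyntheticCohort:
    """Cohort with ``n_subtypes`` expression subtypes on a signature.

    Subtype 0 is the unmodified background; every other subtype shifts each
    signature gene by ``separation`` background standard deviations with a
    random sign per gene and redraws the signature block under its own
    random covariance (marginal variances kept at background levels), so
    subtypes differ in both mean direction and correlation structure — the
    way tumor expression subtypes do. Subtype sizes are near-equal;
    ``labels`` holds the subtype index of each sample.
    """
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    idx = {g: i for i, g in enumerate(background.gene_ids)}
    sig = [g for g in signature_genes if g in idx]
    if len(sig) < 1:
        raise ValueError("no signature genes present in the background")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    sizes = np.full(n_subtypes, n_total // n_subtypes)
    sizes[: n_total % n_subtypes] += 1
    labels = np.repeat(np.arange(n_subtypes), sizes)
    X = background.sample(n_total, rng)
    sig_idx = np.asarray([idx[g] for g in sig])
    var = np.maximum(background.variances()[sig_idx], 1e-8)
    sd = np.sqrt(var)
    mu_sig = background.mean[sig_idx]
    for j in range(1, n_subtypes):
        signs = rng.choice([-1.0, 1.0], size=len(sig))
        mu_j = mu_sig + signs * separation * sd
        cov_j = make_subtype_covariance(len(sig), var, rng)
        L = np.linalg.cholesky(cov_j + 1e-10 * np.eye(len(sig)))
        rows = np.flatnonzero(labels == j)
        z = rng.standard_normal((rows.size, len(sig)))
        X[np.ix_(rows, sig_idx)] = mu_j[None, :] + z @ L.T
    order = rng.permutation(n_total)
    X = np.clip(X[order], 0.0, None)
    labels = labels[order]
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    expr = ExpressionMatrix(
        pd.DataFrame(X.T, index=background.gene_ids, columns=sample_ids),
        SCALE_LOG)
    return SyntheticCohort(expr, pd.Series(labels, index=sample_ids,
                                           name="subtype"),
                           "signature", sig, float(separation), 1.0,
                           int(seed))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum identity (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sweep_adapter(train: SyntheticCohort, test: SyntheticCohort,
                  set_genes: Sequence[str], seed: int) -> pd.Series:
    """Built-in detector: multivariate DP-GMM sweep on the injected set.

    Fits on the training cohort and returns each test sample's predictive
    probability of the over-expressing (largest-L1) cluster.
    """
    from .dpmm import DPPrior, FitConfig

    res = sweep_set(train.expr, set_genes, set_name=train.injected_set,
                    prior=DPPrior(k_trunc=5),
                    config=FitConfig(seed=int(seed) & 0x7FFFFFFF),
                    min_prob=0.1, restrict_to_multimodal=False)
    return score_samples(res, test.expr)


def random_gene_set_db(background: BackgroundModel, n_sets: int,
                       set_size: int, seed: int = 0,
                       prefix: str = "SET") -> GeneSetDB:
    """Random, non-overlapping-by-chance gene sets over background genes."""
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    sets = {}
    for i in range(n_sets):
        genes = rng.choice(background.gene_ids, size=set_size, replace=False)
        sets[f"{prefix}_{i:03d}"] = tuple(genes.tolist())
    return GeneSetDB(sets, {k: "" for k in sets})


def run_benchmark(background: BackgroundModel, db: GeneSetDB,
                  effect_sizes: Sequence[float], pct_degs: Sequence[float],
                  n_total: int = 100,
                  subtype_fraction_range: tuple[float, float] = (0.15, 0.45),
                  method_adapters: Mapping[str, Callable] | None = None,
                  seed: int = 0, n_boot: int = 200):
    """Grid benchmark: train/test cohort pairs per (set, effect size, %DEG).

    For every cell a training and a test cohort are generated with the same
    injection parameters but independent draws; each adapter is fit on the
    training cohort and its test-sample scores are summarized as an AUC.
    Adapter failures leave the cell missing and the run continues.

    Returns ``(grid, summary)``: the per-cell AUC table and per
    (method, effect size, %DEG) means with bootstrap 95% CIs over sets.
    """
    if method_adapters is None:
        method_adapters = {"sweep": sweep_adapter}
    master = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    rng = np.random.default_rng(master)
    rows = []
    for set_name in db:
        for es in effect_sizes:
            for pdeg in pct_degs:
                frac = float(rng.uniform(*subtype_fraction_range))
                seed_pair = int(rng.integers(0, 2**31 - 1))
                seed_fit = int(rng.integers(0, 2**31 - 1))
                train = generate_cohort(background, db[set_name], n_total,
                                        frac, es, pdeg, seed_pair, set_name,
                                        replicate=0)
                test = generate_cohort(background, db[set_name], n_total,
                                       frac, es, pdeg, seed_pair, set_name,
                                       replicate=1)
                for method, adapter in method_adapters.items():
                    try:
                        scores = adapter(train, test, db[set_name], seed_fit)
                        auc = roc_auc(
                            pd.Series(scores).reindex(test.labels.index),
                            test.labels)
                    except Exception as exc:  # noqa: BLE001 - record and go on
                        logger.warning("adapter %s failed on %s (es=%s, "
                                       "pdeg=%s): %s", method, set_name, es,
                                       pdeg, exc)
                        auc = np.nan
                    rows.append({"method": method, "set_name": set_name,
                                 "effect_size": es, "pct_deg": pdeg,
                                 "subtype_fraction": frac, "auc": auc})
    grid = pd.DataFrame(rows)
    summary_rows = []
    boot_rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, 9999]))
    for (method, es, pdeg), sub in grid.groupby(
            ["method", "effect_size", "pct_deg"], sort=True):
        aucs = sub["auc"].dropna().to_numpy()
        if aucs.size == 0:
            summary_rows.append({"method": method, "effect_size": es,
                                 "pct_deg": pdeg, "mean_auc": np.nan,
                                 "ci_low": np.nan, "ci_high": np.nan,
                                 "n_cells": 0})
            continue
        boots = boot_rng.choice(aucs, size=(n_boot, aucs.size),
                                replace=True).mean(axis=1)
        summary_rows.append({"method": method, "effect_size": es,
                             "pct_deg": pdeg,
                             "mean_auc": float(aucs.mean()),
                             "ci_low": float(np.percentile(boots, 2.5)),
                             "ci_high": float(np.percentile(boots, 97.5)),
                             "n_cells": int(aucs.size)})
    return grid, pd.DataFrame(summary_rows)
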