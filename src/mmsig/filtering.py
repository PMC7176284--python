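"""The *filter* stage: find multimodally expressed genes and bank their models.

Each gene passing a mean-expression screen gets its own univariate DP-GMM.
Genes whose fitted mixture keeps two or more components of non-negligible
weight are "multimodal" and their models are stored in a ModelBank that can
later label new samples without refitting. Per-gene fits are independent;
their CAVI updates are vectorized across genes so cohorts of thousands of
genes fit in seconds, and every gene derives its own seed from the master
seed and the gene identifier, so results do not depend on batch composition.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _vb
from .dpmm import DPPrior, FitConfig, MixtureModel
from .io import SCALE_LOG, ExpressionMatrix

logger = logging.getLogger(__name__)

#: weight a component needs at the filter stage to count toward multimodality
FILTER_MIN_WEIGHT = 0.05

__all__ = ["ModelBank", "mean_filter", "fit_gene_models",
           "predict_gene_states", "gene_seed", "FILTER_MIN_WEIGHT"]


def gene_seed(master_seed: int, gene_id: str) -> np.random.SeedSequence:
    """Deterministic per-gene seed derived from the master seed."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(str(gene_id).encode())])


def mean_filter(expr: ExpressionMatrix, threshold: float = 1.0) -> list[str]:
    """Genes whose mean log2(TPM+1) expression is at least ``threshold``.

    Lowly expressed genes have noisy measurements; the conventional cutoff is
    a mean of 1.0 log2(TPM+1). Genes exactly at the boundary are retained and
    the original gene order is preserved.
    """
    if expr.scale != SCALE_LOG:
        raise ValueError("mean_filter expects log2(TPM+1) values")
    means = expr.values.mean(axis=1)
    return list(means.index[means >= threshold])


@dataclass
class ModelBank:
    """Univariate mixture models for the multimodal genes of a cohort."""

    models: dict[str, MixtureModel]
    universe: list[str]
    min_weight: float = FILTER_MIN_WEIGHT
    mean_threshold: float = 1.0
    prior: DPPrior = field(default_factory=lambda: DPPrior(k_trunc=10))
    fit_config: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self):
        stray = set(self.models) - set(self.universe)
        if stray:
            raise ValueError(f"banked genes outside the universe: {sorted(stray)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, gene: str) -> bool:
        return gene in self.models

    def minor_component_probability(self, gene: str) -> float:
        return self.models[gene].minor_component_probability(self.min_weight)

    def summary(self) -> pd.DataFrame:
        """Per-banked-gene table: component count, weights, means, minor prob."""
        rows = []
        for gene, model in self.models.items():
            w = model.weights
            eff = w >= self.min_weight
            rows.append({
                "gene": gene,
                "n_components": int(eff.sum()),
                "weights": ",".join(f"{x:.4g}" for x in w[eff]),
                "means": ",".join(f"{x:.4g}" for x in model.means[eff, 0]),
                "minor_prob": float(w[eff].min()),
            })
        return pd.DataFrame(rows, columns=["gene", "n_components", "weights",
                                           "means", "minor_prob"])

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from dataclasses import asdict
        prior = asdict(self.prior)
        for k, v in prior.items():
            if isinstance(v, np.ndarray):
                prior[k] = v.tolist()
        manifest = {
            "format": "mmsig-bank",
            "version": 1,
            "universe": self.universe,
            "genes": self.genes,
            "min_weight": self.min_weight,
            "mean_threshold": self.mean_threshold,
            "prior": prior,
            "fit_config": asdict(self.fit_config),
            "seed": self.seed,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        models = {g: m.to_dict(include_responsibilities=False)
                  for g, m in self.models.items()}
        with open(directory / "models.json", "w") as fh:
            json.dump(models, fh)

    @classmethod
    def load(cls, directory) -> "ModelBank":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        if manifest.get("format") != "mmsig-bank":
            raise ValueError("not an mmsig model-bank directory")
        with open(directory / "models.json") as fh:
            models_doc = json.load(fh)
        prior_kwargs = dict(manifest["prior"])
        for k in ("m0", "scale0"):
            if isinstance(prior_kwargs.get(k), list):
                prior_kwargs[k] = np.asarray(prior_kwargs[k], dtype=float)
        return cls(
            models={g: MixtureModel.from_dict(doc)
                    for g, doc in models_doc.items()},
            universe=manifest["universe"],
            min_weight=manifest["min_weight"],
            mean_threshold=manifest["mean_threshold"],
            prior=DPPrior(**prior_kwargs),
            fit_config=FitConfig(**manifest["fit_config"]),
            seed=manifest["seed"],
        )


def _finalize_gene(x: np.ndarray, r: np.ndarray, upr: dict) -> dict:
    """Self-consistent single-gene state from responsibilities."""
    post = _vb.uni_mstep(x[None, :], r[None, :, :], upr)
    from scipy.special import logsumexp
    log_rho = _vb.uni_log_rho(x[None, :], post)
    lse = logsumexp(log_rho, axis=2)
    resp = np.exp(log_rho - lse[:, :, None])[0]
    elbo = float(lse.sum(axis=1)[0] + _vb._uni_kl_terms(post, upr)[0])
    sq = {k: np.asarray(v)[0] for k, v in post.items()}
    return {"post": sq, "resp": resp, "elbo": elbo}


def fit_gene_models(expr: ExpressionMatrix,
                    genes: Sequence[str] | None = None,
                    prior: DPPrior | None = None,
                    config: FitConfig | None = None,
                    mean_threshold: float = 1.0,
                    min_weight: float = FILTER_MIN_WEIGHT) -> ModelBank:
    """Fit a univariate DP-GMM per gene and bank the multimodal ones.

    Parameters
    ----------
    expr : cohort expression matrix on the log2(TPM+1) scale.
    genes : genes to fit; defaults to ``mean_filter(expr, mean_threshold)``.
    prior, config : DP-GMM prior and fit controls (univariate defaults).
    min_weight : weight each of >= 2 components must reach for a gene to be
        called multimodal and banked.

    Constant genes are skipped with a log entry and never banked.
    """
    prior = prior or DPPrior(k_trunc=10)
    config = config or FitConfig()
    if genes is None:
        genes = mean_filter(expr, mean_threshold)
    else:
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
    universe = list(genes)
    n = expr.n_samples
    if n < 10:
        logger.warning("fitting gene models with only %d samples", n)
    if not universe:
        return ModelBank({}, [], min_weight, mean_threshold, prior, config,
                         config.seed)

    X = expr.values.loc[universe].to_numpy(dtype=float)     # (G, n)
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        for g in np.asarray(universe)[constant]:
            logger.info("gene %s is constant; skipped", g)
    fit_idx = np.flatnonzero(~constant)
    fit_genes = [universe[i] for i in fit_idx]
    Xf = X[fit_idx]
    G = len(fit_genes)
    models: dict[str, MixtureModel] = {}
    if G:
        K = min(prior.k_trunc, n)
        upr = {
            "alpha": float(prior.alpha),
            "kappa0": float(prior.kappa0),
            "dof0": float(prior.dof0) if prior.dof0 is not None else 3.0,
            "m0": (Xf.mean(axis=1) if prior.m0 is None
                   else np.full(G, float(np.ravel(prior.m0)[0]))),
            "invW0": float(np.ravel(prior.scale0)[0]),
        }
        seeds = [gene_seed(config.seed, g) for g in fit_genes]
        best_r = None
        best_L = np.full(G, -np.inf)
        for restart in range(config.n_restarts):
            rngs = [np.random.default_rng(
                np.random.SeedSequence([*s.entropy, restart]))
                for s in seeds]
            r0 = _vb.init_uni_responsibilities(Xf, K, rngs,
                                               quantile=restart == 0)
            r, L, _, _ = _vb.uni_cavi(Xf, r0, upr, config.max_iter, config.tol)
            if best_r is None:
                best_r, best_L = r, L
            else:
                better = L > best_L
                best_r[better] = r[better]
                best_L[better] = L[better]
        post = _vb.uni_mstep(Xf, best_r, upr)
        for gi, gene in enumerate(fit_genes):
            w = _vb.expected_weights(post["a"][gi], post["b"][gi], K)
            n_eff = int((w >= config.min_weight).sum())
            g_upr = _vb._uni_sub(upr, [gi])
            r_g = best_r[gi]
            if config.do_moves and n_eff >= 2:
                r_g, _, _ = _vb.cleanup_moves(
                    Xf[gi], r_g, g_upr, mode="uni",
                    max_iter=config.max_iter, tol=config.tol,
                    eff_min=config.min_weight,
                    delete_weight=config.delete_weight)
            state = _finalize_gene(Xf[gi], r_g, g_upr)
            sq = state["post"]
            w = _vb.expected_weights(sq["a"], sq["b"], len(sq["kappa"]))
            if int((w >= min_weight).sum()) < 2:
                continue
            resolved = {"alpha": upr["alpha"], "kappa0": upr["kappa0"],
                        "dof0": upr["dof0"],
                        "m0": np.asarray([upr["m0"][gi]]),
                        "invW0": np.asarray([upr["invW0"]])}
            models[gene] = MixtureModel(
                gene_ids=[gene], prior=prior, resolved_prior=resolved,
                config=config, seed=config.seed, n_train=n,
                stick_a=sq["a"], stick_b=sq["b"], kappa=sq["kappa"],
                m=sq["m"][:, None], dof=sq["dof"],
                invW=sq["invW"][:, None],
                responsibilities=state["resp"], elbo=state["elbo"],
                elbo_trace=[state["elbo"]], covariance_type="diag")
    logger.info("banked %d of %d genes as multimodal", len(models),
                len(universe))
    return ModelBank(models, universe, min_weight, mean_threshold, prior,
                     config, config.seed)


def predict_gene_states(bank: ModelBank, new_expr: ExpressionMatrix):
    """Label new samples against every banked gene model.

    Returns
    -------
    labels : DataFrame (samples x banked genes) of component indices
        (-1 = unassigned to any fitted component).
    overexpressed : DataFrame of booleans; True when a sample is assigned to
        the component with the largest mean for that gene.
    """
    missing = [g for g in bank.genes if g not in new_expr.values.index]
    if missing:
        raise KeyError(f"banked genes absent from new samples: {missing[:10]}")
    samples = new_expr.sample_ids
    labels = pd.DataFrame(index=samples, columns=bank.genes, dtype=int)
    over = pd.DataFrame(index=samples, columns=bank.genes, dtype=bool)
    for gene, model in bank.models.items():
        x = new_expr.values.loc[gene].to_numpy(dtype=float)[:, None]
        lab, _ = model.predict(x, min_weight=bank.min_weight)
        w = model.weights
        eff = np.flatnonzero(w >= bank.min_weight)
        top = eff[np.argmax(model.means[eff, 0])]
        labels[gene] = lab
        over[gene] = lab == top
    return labels, over
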