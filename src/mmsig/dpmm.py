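"""Truncated stick-breaking Dirichlet-process Gaussian mixture models.

The model places a Dirichlet-process prior (concentration ``alpha``,
normal-Wishart base measure) over Gaussian mixture components and fits a
truncated stick-breaking representation by full-batch mean-field coordinate
ascent. Components are cleaned up with merge and delete moves that are only
accepted when the evidence lower bound (ELBO) does not decrease, and the fit
is repeated from several random initializations, keeping the restart with
the highest ELBO.

The same machinery covers the univariate case (per-gene expression
distributions) and the multivariate case (samples over a panel of genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_t

from . import _vb

__all__ = [
    "DPPrior",
    "FitConfig",
    "MixtureModel",
    "stick_breaking_weights",
    "fit",
    "compute_elbo",
    "predict",
    "effective_components",
    "minor_component_probability",
]


def stick_breaking_weights(nu: Sequence[float]) -> np.ndarray:
    """Convert stick-break fractions into mixture weights.

    ``pi_k = nu_k * prod_{l<k} (1 - nu_l)``. The final break fraction must be
    1 (the truncation convention), which makes the weights sum to exactly 1.

    Parameters
    ----------
    nu : sequence of float in [0, 1], last entry equal to 1.

    Returns
    -------
    ndarray of nonnegative weights of the same length, summing to 1.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 1 or nu.size == 0:
        raise ValueError("nu must be a non-empty 1-D sequence")
    if np.any(nu < 0.0) or np.any(nu > 1.0):
        raise ValueError("stick-break fractions must lie in [0, 1]")
    if nu[-1] != 1.0:
        raise ValueError("the last break fraction must equal 1 (truncation)")
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - nu[:-1])])
    return nu * remaining


@dataclass(frozen=True)
class DPPrior:
    """Prior for the DP-GMM: concentration plus normal-Wishart centering.

    Parameters
    ----------
    alpha : DP concentration; larger values spread mass over more clusters.
    m0 : prior mean vector. ``None`` uses the empirical data mean.
    kappa0 : scale on the mean's precision (pseudo-observations).
    dof0 : Wishart degrees of freedom; ``None`` uses ``d + 2``, which makes
        the prior expected covariance equal ``scale0`` exactly.
    scale0 : prior expected covariance. A scalar means that multiple of the
        identity; the default 2.0 matches a weakly informative prior on
        log2(TPM+1) data.
    k_trunc : truncation level (maximum number of components).
    covariance_type : "diag" constrains component covariances to be diagonal
        (a product of per-dimension normal-gamma bases), which keeps the
        per-component evidence penalty linear in the number of genes and is
        the default for gene-panel clustering; "full" learns dense
        covariances and suits low-dimensional problems.
    """

    alpha: float = 1.0
    m0: np.ndarray | float | None = None
    kappa0: float = 1.0
    dof0: float | None = None
    scale0: np.ndarray | float = 2.0
    k_trunc: int = 10
    covariance_type: str = "diag"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.k_trunc < 1:
            raise ValueError("k_trunc must be at least 1")
        if self.covariance_type not in ("diag", "full"):
            raise ValueError("covariance_type must be 'diag' or 'full'")

    def resolve(self, X: np.ndarray) -> dict:
        """Materialize engine-ready prior arrays for data ``X`` (n, d)."""
        n, d = X.shape
        diag = self.covariance_type == "diag"
        if self.dof0 is not None:
            dof0 = float(self.dof0)
        else:
            dof0 = 3.0 if diag else float(d + 2)
        if diag and dof0 <= 2:
            raise ValueError("dof0 must exceed 2 per dimension for diagonal "
                             "components")
        if not diag and dof0 < d:
            raise ValueError(f"dof0 must be >= d ({d})")
        if self.m0 is None:
            m0 = X.mean(axis=0)
        else:
            m0 = np.broadcast_to(np.asarray(self.m0, dtype=float), (d,)).copy()
        scale0 = np.asarray(self.scale0, dtype=float)
        if diag:
            if scale0.ndim == 2:
                scale0 = np.diag(scale0)
            invW0 = np.broadcast_to(scale0, (d,)).astype(float).copy()
            if np.any(invW0 <= 0):
                raise ValueError("scale0 must be positive")
        elif scale0.ndim == 0:
            if scale0 <= 0:
                raise ValueError("scalar scale0 must be positive")
            invW0 = float(scale0) * np.eye(d)
        else:
            invW0 = 0.5 * (scale0 + scale0.T)
            if invW0.shape != (d, d):
                raise ValueError("scale0 must be d x d")
            if np.any(np.linalg.eigvalsh(invW0) <= 0):
                raise ValueError("scale0 must be symmetric positive definite")
        return {
            "alpha": float(self.alpha),
            "kappa0": float(self.kappa0),
            "dof0": dof0,
            "m0": m0,
            "invW0": invW0,
        }


@dataclass(frozen=True)
class FitConfig:
    """Controls for the variational fit.

    ``min_weight`` is the default mixing-weight threshold below which a
    component does not count as effective; downstream screens apply their own
    stricter thresholds. ``tol`` is the relative-ELBO convergence threshold.
    """

    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 2
    min_weight: float = 0.01
    delete_weight: float = 1e-4
    do_moves: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        if not 0 < self.min_weight < 0.5:
            raise ValueError("min_weight must lie in (0, 0.5)")


class MixtureModel:
    """A fitted truncated DP-GMM.

    Holds the variational posterior (Beta stick parameters and per-component
    normal-Wishart parameters), per-sample responsibilities, the final ELBO
    and its trace, plus the prior/config/seed needed to reproduce the fit.
    """

    def __init__(self, *, gene_ids, prior: DPPrior, resolved_prior: dict,
                 config: FitConfig, seed: int, n_train: int,
                 stick_a, stick_b, kappa, m, dof, invW,
                 responsibilities, elbo: float, elbo_trace,
                 covariance_type: str = "diag"):
        self.gene_ids = list(gene_ids)
        self.prior = prior
        self._pr = resolved_prior
        self.config = config
        self.seed = int(seed)
        self.n_train = int(n_train)
        self.covariance_type = covariance_type
        self.stick_a = np.asarray(stick_a, dtype=float)
        self.stick_b = np.asarray(stick_b, dtype=float)
        self.kappa = np.asarray(kappa, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.dof = np.asarray(dof, dtype=float)
        # invW is (K, d) for diagonal components, (K, d, d) for full
        self.invW = np.asarray(invW, dtype=float)
        if covariance_type == "diag" and self.invW.ndim != 2:
            raise ValueError("diagonal models store invW as (K, d)")
        if covariance_type == "full" and self.invW.ndim != 3:
            raise ValueError("full models store invW as (K, d, d)")
        self.responsibilities = (None if responsibilities is None
                                 else np.asarray(responsibilities, dtype=float))
        self.elbo = float(elbo)
        self.elbo_trace = list(elbo_trace)

    # -- derived quantities -------------------------------------------------

    @property
    def d(self) -> int:
        return self.m.shape[1]

    @property
    def n_components(self) -> int:
        return self.m.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Expected mixing weights under the stick posterior (sum to 1)."""
        return _vb.expected_weights(self.stick_a, self.stick_b,
                                    self.n_components)

    @property
    def sticks(self) -> np.ndarray:
        """Expected stick-break fractions (last fixed at 1)."""
        if self.n_components == 1:
            return np.ones(1)
        return np.concatenate([self.stick_a / (self.stick_a + self.stick_b),
                               [1.0]])

    @property
    def means(self) -> np.ndarray:
        return self.m

    @property
    def covariances(self) -> np.ndarray:
        """Posterior-expected component covariances, (K, d, d)."""
        if self.covariance_type == "diag":
            denom = np.maximum(self.dof - 2.0, 1e-6)
            var = self.invW / denom[:, None]
            return np.stack([np.diag(v) for v in var])
        denom = np.maximum(self.dof - self.d - 1.0, 1e-6)
        return self.invW / denom[:, None, None]

    @property
    def labels(self) -> np.ndarray:
        """Hard training labels: argmax responsibility over the effective
        components (ties to lower index). Near-empty components revert to
        the broad prior and would otherwise soak up boundary samples."""
        if self.responsibilities is None:
            raise ValueError("model was saved without responsibilities")
        eff = np.flatnonzero(self.weights >= self.config.min_weight)
        if eff.size == 0:
            eff = np.array([int(np.argmax(self.weights))])
        return eff[np.argmax(self.responsibilities[:, eff], axis=1)]

    def effective_components(self, min_weight: float | None = None) -> int:
        return effective_components(self, min_weight
                                    if min_weight is not None
                                    else self.config.min_weight)

    def minor_component_probability(self, min_weight: float | None = None) -> float:
        return minor_component_probability(self, min_weight
                                           if min_weight is not None
                                           else self.config.min_weight)

    def predict(self, Xnew, min_weight: float | None = None):
        return predict(self, Xnew, min_weight=min_weight)

    # -- serialization ------------------------------------------------------

    def to_dict(self, include_responsibilities: bool = True) -> dict:
        pr = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
              for k, v in self._pr.items()}
        prior = asdict(self.prior)
        for k, v in prior.items():
            if isinstance(v, np.ndarray):
                prior[k] = v.tolist()
        doc = {
            "format": "mmsig-model",
            "version": 1,
            "covariance_type": self.covariance_type,
            "gene_ids": self.gene_ids,
            "seed": self.seed,
            "n_train": self.n_train,
            "prior": prior,
            "resolved_prior": pr,
            "config": asdict(self.config),
            "posterior": {
                "stick_a": self.stick_a.tolist(),
                "stick_b": self.stick_b.tolist(),
                "kappa": self.kappa.tolist(),
                "m": self.m.tolist(),
                "dof": self.dof.tolist(),
                "invW": self.invW.tolist(),
            },
            "elbo": self.elbo,
            "elbo_trace": self.elbo_trace,
        }
        if include_responsibilities and self.responsibilities is not None:
            doc["responsibilities"] = self.responsibilities.tolist()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "MixtureModel":
        if doc.get("format") != "mmsig-model":
            raise ValueError("not an mmsig model document")
        prior_kwargs = dict(doc["prior"])
        for k in ("m0", "scale0"):
            if isinstance(prior_kwargs.get(k), list):
                prior_kwargs[k] = np.asarray(prior_kwargs[k], dtype=float)
        pr = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
              for k, v in doc["resolved_prior"].items()}
        post = doc["posterior"]
        return cls(
            gene_ids=doc["gene_ids"],
            prior=DPPrior(**prior_kwargs),
            resolved_prior=pr,
            config=FitConfig(**doc["config"]),
            seed=doc["seed"],
            n_train=doc["n_train"],
            stick_a=post["stick_a"],
            stick_b=post["stick_b"],
            kappa=post["kappa"],
            m=post["m"],
            dof=post["dof"],
            invW=post["invW"],
            responsibilities=doc.get("responsibilities"),
            elbo=doc["elbo"],
            elbo_trace=doc["elbo_trace"],
            covariance_type=doc.get("covariance_type", "diag"),
        )

    def save(self, path, include_responsibilities: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_responsibilities), fh)

    @classmethod
    def load(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_matrix(X, gene_ids):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be an n x d matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if gene_ids is None:
        gene_ids = [f"feature_{i}" for i in range(d)]
    elif len(gene_ids) != d:
        raise ValueError("gene_ids length does not match the feature count")
    return X, list(gene_ids)


def _uni_pr_from(pr: dict) -> dict:
    """Lift a d=1 resolved prior into the batched-univariate layout."""
    return {
        "alpha": pr["alpha"],
        "kappa0": pr["kappa0"],
        "dof0": pr["dof0"],
        "m0": np.asarray([float(np.ravel(pr["m0"])[0])]),
        "invW0": float(np.ravel(pr["invW0"])[0]),
    }


def _finalize_state(X, post, pr, mode: str):
    """Self-consistent (responsibilities, elbo) at the stored posterior."""
    if mode == "uni":
        log_rho = _vb.uni_log_rho(X[None, :, 0], post)
        lse = logsumexp(log_rho, axis=2)
        r = np.exp(log_rho - lse[:, :, None])[0]
        elbo = float(lse.sum(axis=1)[0] + _vb._uni_kl_terms(post, pr)[0])
    elif mode == "diag":
        log_rho = _vb.diag_log_rho(X, post)
        lse = logsumexp(log_rho, axis=1)
        r = np.exp(log_rho - lse[:, None])
        elbo = float(lse.sum()) + _vb._diag_kl_terms(post, pr)
    else:
        log_rho, chols, Elogdet = _vb.multi_log_rho(X, post)
        lse = logsumexp(log_rho, axis=1)
        r = np.exp(log_rho - lse[:, None])
        elbo = float(lse.sum()) + _vb._multi_kl_terms(post, pr, chols, Elogdet)
    return r, elbo


def _squeeze_uni_post(post: dict) -> dict:
    """Drop the leading batch axis from a G=1 univariate posterior."""
    return {k: np.asarray(v)[0] for k, v in post.items()}


def fit(X, prior: DPPrior | None = None, config: FitConfig | None = None,
        gene_ids: Sequence[str] | None = None) -> MixtureModel:
    """Fit a truncated DP-GMM to an ``n x d`` sample-by-feature matrix.

    Runs ``config.n_restarts`` independent initializations, each followed by
    ELBO-guarded merge/delete cleanup, and returns the restart with the
    highest ELBO. Deterministic for fixed data, prior, config and seed.
    """
    prior = prior or DPPrior()
    config = config or FitConfig()
    X, gene_ids = _as_matrix(X, gene_ids)
    n, d = X.shape
    K = min(prior.k_trunc, n)
    pr = prior.resolve(X)
    univariate = d == 1
    mode = prior.covariance_type if not univariate else "uni"
    if univariate:
        upr = _uni_pr_from(pr)

    best = None
    for restart in range(config.n_restarts):
        ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, restart])
        rng = np.random.default_rng(ss)
        trace: list[float] = []
        if univariate:
            x_row = X[:, 0][None, :]
            r0 = _vb.init_uni_responsibilities(x_row, K, [rng],
                                               quantile=restart == 0)
            r, L, post, traces = _vb.uni_cavi(x_row, r0, upr, config.max_iter,
                                              config.tol, record_trace=True)
            trace.extend(traces[0])
            r1, elbo = r[0], float(L[0])
            if config.do_moves:
                r1, elbo, post = _vb.cleanup_moves(
                    X[:, 0], r1, upr, mode="uni",
                    max_iter=config.max_iter, tol=config.tol,
                    eff_min=config.min_weight,
                    delete_weight=config.delete_weight, trace=trace)
            post = _vb.uni_mstep(X[:, 0][None, :], r1[None, :, :], upr)
            resp, elbo = _finalize_state(X, post, upr, mode="uni")
            post_sq = _squeeze_uni_post(post)
            state = {
                "stick_a": post_sq["a"], "stick_b": post_sq["b"],
                "kappa": post_sq["kappa"], "m": post_sq["m"][:, None],
                "dof": post_sq["dof"],
                "invW": post_sq["invW"][:, None],
            }
        else:
            r0 = _vb.init_responsibilities(X, K, rng)
            if restart == 0:
                # deterministic PC-tail candidates compete with the anchors;
                # short triage runs pick the most promising start
                pass_fn = (_vb.multi_pass if mode == "full"
                           else _vb.diag_pass)
                cands = [r0] + _vb.pc_split_inits(X, K)
                scored = []
                for rc in cands:
                    rt = rc
                    Lt = -np.inf
                    for _ in range(3):
                        rt, Lt, _ = pass_fn(X, rt, pr)
                    scored.append((Lt, rt))
                r0 = max(scored, key=lambda t: t[0])[1]
            r1, elbo, post, tr = _vb.multi_cavi(X, r0, pr, config.max_iter,
                                                config.tol, record_trace=True,
                                                mode=mode)
            trace.extend(tr)
            if config.do_moves:
                r1, elbo, post = _vb.cleanup_moves(
                    X, r1, pr, mode=mode,
                    max_iter=config.max_iter, tol=config.tol,
                    eff_min=config.min_weight,
                    delete_weight=config.delete_weight, trace=trace)
            mstep_fn = _vb.multi_mstep if mode == "full" else _vb.diag_mstep
            post = mstep_fn(X, r1, pr)
            resp, elbo = _finalize_state(X, post, pr, mode=mode)
            state = {
                "stick_a": post["a"], "stick_b": post["b"],
                "kappa": post["kappa"], "m": post["m"],
                "dof": post["dof"], "invW": post["invW"],
            }
        trace.append(elbo)
        if best is None or elbo > best[0]:
            best = (elbo, state, resp, trace)

    elbo, state, resp, trace = best
    return MixtureModel(
        gene_ids=gene_ids, prior=prior, resolved_prior=pr, config=config,
        seed=config.seed, n_train=n,
        stick_a=state["stick_a"], stick_b=state["stick_b"],
        kappa=state["kappa"], m=state["m"], dof=state["dof"],
        invW=state["invW"], responsibilities=resp, elbo=elbo,
        elbo_trace=trace,
        covariance_type="diag" if univariate else prior.covariance_type)


def compute_elbo(model: MixtureModel, X) -> float:
    """Evidence lower bound of ``X`` at the model's variational posterior.

    Responsibilities are set to their optimum for the stored parameters. For
    a one-component model this is a lower bound on the closed-form
    normal-Wishart marginal likelihood of ``X``.
    """
    X, _ = _as_matrix(X, None)
    if X.shape[1] != model.d:
        raise ValueError(
            f"dimension mismatch: model has d={model.d}, X has {X.shape[1]}")
    if model.d == 1:
        pr = _uni_pr_from(model._pr)
        invW1 = (model.invW[:, 0] if model.covariance_type == "diag"
                 else model.invW[:, 0, 0])
        post = {
            "a": model.stick_a[None, :], "b": model.stick_b[None, :],
            "kappa": model.kappa[None, :], "m": model.m[:, 0][None, :],
            "dof": model.dof[None, :],
            "invW": invW1[None, :],
            "Nk": None,
        }
        _, elbo = _finalize_state(X, post, pr, mode="uni")
    else:
        post = {"a": model.stick_a, "b": model.stick_b, "kappa": model.kappa,
                "m": model.m, "dof": model.dof, "invW": model.invW,
                "Nk": None}
        _, elbo = _finalize_state(X, post, model._pr,
                                  mode=model.covariance_type)
    return float(elbo)


# ---------------------------------------------------------------------------
# prediction and component summaries
# ---------------------------------------------------------------------------

def effective_components(model: MixtureModel, min_weight: float) -> int:
    """Number of components with mixing weight at least ``min_weight``."""
    if not 0 < min_weight < 0.5:
        raise ValueError("min_weight must lie in (0, 0.5)")
    return int(np.sum(model.weights >= min_weight))


def minor_component_probability(model: MixtureModel,
                                min_weight: float = 0.01) -> float:
    """Mixing weight of the smallest effective component.

    This is the probability of placing a sample in the smallest expression
    cluster, used to screen for signatures that affect a meaningful fraction
    of samples.
    """
    w = model.weights
    eff = w[w >= min_weight]
    if eff.size == 0:
        raise ValueError("model has no effective component at this threshold")
    return float(eff.min())


def _student_t_logpdf(X: np.ndarray, loc: np.ndarray, shape: np.ndarray,
                      df: float) -> np.ndarray:
    return multivariate_t.logpdf(X, loc=loc, shape=shape, df=df)


def predict(model: MixtureModel, Xnew, min_weight: float | None = None):
    """Assign new samples to fitted clusters, with a new-cluster column.

    Each effective component contributes its posterior-predictive Student-t
    density weighted by ``weight_k * n/(n + alpha)``; an extra column carries
    the Chinese-restaurant-style mass ``alpha/(n + alpha)`` times the prior
    predictive density, so samples unlike any training cluster are flagged.

    Parameters
    ----------
    Xnew : ``m x d`` array in the model's feature order, or a DataFrame whose
        columns include the model's ``gene_ids`` (re-ordered by identifier).

    Returns
    -------
    labels : int array of length m; the effective-component index, or -1
        ("unassigned") when the new-cluster column is the argmax.
    proba : DataFrame with one column per effective component
        (``cluster_<k>``) plus ``new``; rows sum to 1.
    """
    import pandas as pd

    if min_weight is None:
        min_weight = model.config.min_weight
    if isinstance(Xnew, pd.DataFrame):
        missing = [g for g in model.gene_ids if g not in Xnew.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        index = Xnew.index
        Xm = Xnew.loc[:, model.gene_ids].to_numpy(dtype=float)
    else:
        Xm = np.asarray(Xnew, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None] if model.d == 1 else Xm[None, :]
        if Xm.size and Xm.shape[1] != model.d:
            raise ValueError(
                f"expected {model.d} features, got {Xm.shape[1]}")
        index = pd.RangeIndex(Xm.shape[0])
    d = model.d
    w = model.weights
    eff = np.flatnonzero(w >= min_weight)
    cols = [f"cluster_{k}" for k in eff] + ["new"]
    if Xm.shape[0] == 0:
        return (np.empty(0, dtype=int),
                pd.DataFrame(np.empty((0, len(cols))), columns=cols))
    if not np.all(np.isfinite(Xm)):
        raise ValueError("Xnew contains non-finite values")

    n, alpha = model.n_train, model._pr["alpha"]
    pr = model._pr
    w_eff = w[eff] / w[eff].sum()
    logp = np.empty((Xm.shape[0], eff.size + 1))
    if model.covariance_type == "diag":
        from scipy.stats import t as student_t
        for j, k in enumerate(eff):
            df_k = model.dof[k]
            scale = np.sqrt(model.invW[k] * (model.kappa[k] + 1.0)
                            / (model.kappa[k] * df_k))
            logp[:, j] = (np.log(w_eff[j]) + np.log(n / (n + alpha))
                          + student_t.logpdf(Xm, df_k, loc=model.m[k],
                                             scale=scale).sum(axis=1))
        df0 = pr["dof0"]
        invW0 = np.broadcast_to(np.asarray(pr["invW0"], dtype=float), (d,))
        scale0 = np.sqrt(invW0 * (pr["kappa0"] + 1.0) / (pr["kappa0"] * df0))
        logp[:, -1] = (np.log(alpha / (n + alpha))
                       + student_t.logpdf(Xm, df0, loc=pr["m0"],
                                          scale=scale0).sum(axis=1))
    else:
        for j, k in enumerate(eff):
            df_k = model.dof[k] - d + 1.0
            shape = model.invW[k] * (model.kappa[k] + 1.0) \
                / (model.kappa[k] * df_k)
            logp[:, j] = (np.log(w_eff[j]) + np.log(n / (n + alpha))
                          + _student_t_logpdf(Xm, model.m[k], shape, df_k))
        df0 = pr["dof0"] - d + 1.0
        shape0 = pr["invW0"] * (pr["kappa0"] + 1.0) / (pr["kappa0"] * df0)
        logp[:, -1] = (np.log(alpha / (n + alpha))
                       + _student_t_logpdf(Xm, pr["m0"], shape0, df0))
    proba = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    arg = np.argmax(proba, axis=1)
    labels = np.where(arg == eff.size, -1, eff[np.minimum(arg, eff.size - 1)])
    return labels.astype(int), pd.DataFrame(proba, columns=cols, index=index)
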