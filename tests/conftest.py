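"""Shared fixtures: small synthetic cohorts, gene-set files, model helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mmsig.dpmm import DPPrior, FitConfig, MixtureModel
from mmsig.io import SCALE_LOG, ExpressionMatrix, GeneSetDB


@pytest.fixture(scope="session")
def background():
    from mmsig.synthetic import synthetic_background

    return synthetic_background(400, seed=7)


@pytest.fixture()
def small_expr():
    """Tiny deterministic 4-gene x 6-sample matrix, log2(TPM+1) scale."""
    rng = np.random.default_rng(0)
    vals = np.abs(rng.normal(3, 1, size=(4, 6)))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(4)],
                     columns=[f"s{i}" for i in range(6)]),
        SCALE_LOG)


@pytest.fixture()
def bimodal_cohort():
    """60-gene cohort: genes g0..g9 bimodal (6-sigma spaced modes, 50/50),
    the rest unimodal; n = 200."""
    rng = np.random.default_rng(41)
    n = 200
    rows = []
    for i in range(60):
        if i < 10:
            lab = rng.random(n) < 0.5
            x = np.where(lab, rng.normal(2.0, 1.0, n), rng.normal(8.0, 1.0, n))
        else:
            x = rng.normal(4.0, 1.0, n)
        rows.append(np.clip(x, 0, None))
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows), index=[f"g{i}" for i in range(60)],
                     columns=[f"s{i}" for i in range(n)]),
        SCALE_LOG)


def model_with_weights(weights, means=None, n_train=100, alpha=1.0,
                       variances=None):
    """Build a univariate MixtureModel with prescribed mixing weights.

    Stick Beta posteriors are chosen so the expected weights equal
    ``weights`` exactly; normal-Wishart posteriors are tight around the
    requested means/variances.
    """
    w = np.asarray(weights, dtype=float)
    K = w.size
    if means is None:
        means = np.arange(K, dtype=float) * 10.0
    means = np.asarray(means, dtype=float)
    if variances is None:
        variances = np.ones(K)
    variances = np.asarray(variances, dtype=float)
    nu = np.empty(K)
    rem = 1.0
    for k in range(K):
        nu[k] = w[k] / rem if rem > 0 else 1.0
        rem -= w[k]
    nu[-1] = 1.0
    conc = 1000.0
    stick_a = np.clip(nu[:-1], 1e-9, 1 - 1e-9) * conc
    stick_b = conc - stick_a
    dof = np.full(K, 200.0)
    invW = variances * (dof - 2.0)
    pr = {"alpha": float(alpha), "kappa0": 1.0, "dof0": 3.0,
          "m0": np.array([float(means.mean())]), "invW0": np.array([2.0])}
    return MixtureModel(
        gene_ids=["g"], prior=DPPrior(alpha=alpha, k_trunc=K),
        resolved_prior=pr, config=FitConfig(), seed=0, n_train=n_train,
        stick_a=stick_a, stick_b=stick_b,
        kappa=np.full(K, 100.0), m=means[:, None], dof=dof,
        invW=invW[:, None], responsibilities=np.full((n_train, K), 1.0 / K),
        elbo=0.0, elbo_trace=[0.0], covariance_type="diag")


@pytest.fixture()
def gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write


@pytest.fixture()
def tiny_db():
    return GeneSetDB.from_mapping({
        "SET_A": ["g0", "g1", "g2"],
        "SET_B": ["g1", "g2", "g3", "g4"],
        "SET_C": ["g9", "g8"],
    })
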