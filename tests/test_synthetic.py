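"""Tests for the synthetic-cohort generator and benchmark harness."""

import numpy as np
import pandas as pd
import pytest

from mmsig.io import ExpressionMatrix, GeneSetDB
from mmsig.synthetic import (BackgroundModel, estimate_background,
                             generate_cohort, generate_multimodal_cohort,
                             make_subtype_covariance, random_gene_set_db,
                             roc_auc, run_benchmark, synthetic_background)


# ---------------------------------------------------------------------------
# background models
# ---------------------------------------------------------------------------

def test_estimate_background_recovers_known_covariance():
    rng = np.random.default_rng(0)
    d = 20
    A = rng.standard_normal((d, d))
    cov_true = A @ A.T / d + 0.5 * np.eye(d)
    mean_true = rng.uniform(2, 5, d)
    X = rng.multivariate_normal(mean_true, cov_true, size=500)
    expr = ExpressionMatrix(pd.DataFrame(
        np.clip(X, 0, None).T, index=[f"g{i}" for i in range(d)],
        columns=[f"s{i}" for i in range(500)]))
    bg = estimate_background(expr)
    # mean recovery within 2 standard errors per gene
    se = np.sqrt(np.diag(cov_true) / 500)
    assert np.all(np.abs(bg.mean - mean_true) < 3 * se + 0.05)
    # sampled cohorts reproduce the covariance within 15% relative error
    # on the well-determined entries
    Y = bg.sample(4000, np.random.default_rng(1))
    cov_emp = np.cov(Y.T)
    big = np.abs(cov_true) > 0.5
    rel = np.abs(cov_emp[big] - cov_true[big]) / np.abs(cov_true[big])
    assert np.median(rel) < 0.15


def test_background_constant_gene_stays_constant():
    bg = BackgroundModel(["a", "b"], np.array([3.0, 5.0]),
                         np.array([[1.0, 0.0]]))
    X = bg.sample(50, np.random.default_rng(0))
    assert np.all(X[:, 1] == 5.0)
    assert X[:, 0].std() > 0.5


def test_background_sampling_reproducible(background):
    X1 = background.sample(10, np.random.default_rng(3))
    X2 = background.sample(10, np.random.default_rng(3))
    np.testing.assert_array_equal(X1, X2)


# ---------------------------------------------------------------------------
# subtype covariance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d", [1, 5, 20, 50])
def test_make_subtype_covariance_spd_with_target_diagonal(d):
    rng = np.random.default_rng(d)
    for seed in range(10):
        tv = rng.uniform(0.5, 2.0, d)
        C = make_subtype_covariance(d, tv, seed)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0
        np.testing.assert_allclose(np.diag(C), tv, atol=1e-9)


def test_make_subtype_covariance_deterministic_and_errors():
    np.testing.assert_array_equal(make_subtype_covariance(4, 1.0, 9),
                                  make_subtype_covariance(4, 1.0, 9))
    with pytest.raises(ValueError):
        make_subtype_covariance(3, [-1.0, 1.0, 1.0], 0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_generate_cohort_bookkeeping(background):
    genes = background.gene_ids[:40]
    cohort = generate_cohort(background, genes, 200, 0.2, 1.0, 0.25, seed=1)
    assert int(cohort.labels.sum()) == 40
    assert len(cohort.deg_genes) == 10
    assert set(cohort.deg_genes) <= set(genes)
    assert cohort.expr.n_samples == 200


def test_generate_cohort_effect_size_realized(background):
    genes = background.gene_ids[:40]
    cohort = generate_cohort(background, genes, 300, 0.5, 3.0, 0.25, seed=2)
    sub = cohort.labels == 1
    idx = {g: i for i, g in enumerate(background.gene_ids)}
    smds = []
    for g in cohort.deg_genes:
        x = cohort.expr.values.loc[g]
        sd = np.sqrt(background.variances()[idx[g]])
        smds.append((x[sub.values].mean() - x[~sub.values].mean()) / sd)
    assert np.mean(smds) == pytest.approx(3.0, abs=0.3)


def test_generate_cohort_null_effect(background):
    genes = background.gene_ids[:40]
    cohort = generate_cohort(background, genes, 400, 0.5, 0.0, 0.25, seed=3)
    sub = cohort.labels == 1
    for g in cohort.deg_genes:
        x = cohort.expr.values.loc[g]
        diff = abs(x[sub.values].mean() - x[~sub.values].mean())
        se = x.std() * np.sqrt(1 / sub.sum() + 1 / (~sub).sum())
        assert diff < 3 * se


def test_generate_cohort_shares_spec_across_replicates(background):
    genes = background.gene_ids[:40]
    a = generate_cohort(background, genes, 100, 0.3, 1.0, 0.25, seed=5,
                        replicate=0)
    b = generate_cohort(background, genes, 100, 0.3, 1.0, 0.25, seed=5,
                        replicate=1)
    assert a.deg_genes == b.deg_genes
    assert not np.array_equal(a.expr.values.to_numpy(),
                              b.expr.values.to_numpy())


def test_generate_cohort_empty_deg_error(background):
    with pytest.raises(ValueError):
        generate_cohort(background, background.gene_ids[:40], 100, 0.3,
                        1.0, 0.001, seed=1)


def test_generate_multimodal_cohort_labels(background):
    cohort = generate_multimodal_cohort(background,
                                        background.gene_ids[:12], 90,
                                        n_subtypes=3, separation=3.0, seed=4)
    counts = cohort.labels.value_counts()
    assert sorted(counts.index) == [0, 1, 2]
    assert counts.max() - counts.min() <= 1


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scores, labels, expected", [
    ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
    ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
    ([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0], 0.75),
])
def test_roc_auc_examples(scores, labels, expected):
    assert roc_auc(scores, labels) == pytest.approx(expected)


def test_roc_auc_single_class_error():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


def test_roc_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.4).astype(int)
    base = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
    assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def test_run_benchmark_deterministic_and_handles_failures(background):
    db = random_gene_set_db(background, 2, 25, seed=3)

    def broken(train, test, genes, seed):
        raise RuntimeError("synthetic failure")

    def oracle(train, test, genes, seed):
        # label-revealing adapter: benchmark wiring check only
        return test.labels.astype(float) + 0.001

    grid, summary = run_benchmark(
        background, db, [1.0], [0.25], n_total=60,
        method_adapters={"oracle": oracle, "broken": broken}, seed=5)
    assert grid[grid["method"] == "broken"]["auc"].isna().all()
    assert (grid[grid["method"] == "oracle"]["auc"] == 1.0).all()
    grid2, _ = run_benchmark(
        background, db, [1.0], [0.25], n_total=60,
        method_adapters={"oracle": oracle, "broken": broken}, seed=5)
    pd.testing.assert_frame_equal(grid, grid2)


def test_run_benchmark_summary_cis_bracket_mean(background):
    db = random_gene_set_db(background, 3, 20, seed=4)

    def noisy(train, test, genes, seed):
        rng = np.random.default_rng(seed)
        return pd.Series(test.labels + rng.normal(0, 0.8, len(test.labels)),
                         index=test.labels.index)

    _, summary = run_benchmark(background, db, [1.0], [0.25], n_total=60,
                               method_adapters={"noisy": noisy}, seed=6)
    row = summary.iloc[0]
    assert row["ci_low"] <= row["mean_auc"] <= row["ci_high"]
    assert row["n_cells"] == 3
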