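"""Tests for hypergeometric enrichment, the scan routine and clustering."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from mmsig.dpmm import DPPrior, FitConfig
from mmsig.enrich import (enrich_cluster, enriched_gene_union,
                          hypergeom_enrich, min_prob_filter, scan)
from mmsig.filtering import ModelBank, fit_gene_models
from mmsig.io import ExpressionMatrix, GeneSetDB

from conftest import model_with_weights


def _bank_from_weights(weight_sets):
    models = {f"g{i}": model_with_weights(w)
              for i, w in enumerate(weight_sets)}
    for i, m in enumerate(models.values()):
        m.gene_ids = [f"g{i}"]
    return ModelBank(models, universe=list(models), min_weight=0.05)


def hypergeom_tail_oracle(M, K, n, k):
    """Exact P(overlap >= k) by direct combinatorial summation."""
    total = comb(M, n)
    return sum(comb(K, j) * comb(M - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


# ---------------------------------------------------------------------------
# min_prob_filter
# ---------------------------------------------------------------------------

def test_min_prob_filter_thresholds():
    bank = _bank_from_weights([[0.8, 0.2], [0.95, 0.05], [0.5, 0.5]])
    assert min_prob_filter(bank, 0.2) == ["g0", "g2"]
    assert min_prob_filter(bank, 0.1) == ["g0", "g2"]
    assert min_prob_filter(bank, 0.49) == ["g2"]
    with pytest.raises(ValueError):
        min_prob_filter(bank, 0.6)


# ---------------------------------------------------------------------------
# hypergeometric test
# ---------------------------------------------------------------------------

def test_hypergeom_exact_example():
    universe = [f"u{i}" for i in range(20)]
    hits = universe[:5]
    db = GeneSetDB.from_mapping({"HITSET": hits})
    table = hypergeom_enrich(hits, universe, db, fdr=0.01)
    assert table.iloc[0]["p_value"] == pytest.approx(1 / 15504, rel=1e-12)


def test_hypergeom_degenerate_sets():
    universe = [f"u{i}" for i in range(12)]
    hits = universe[:4]
    db = GeneSetDB.from_mapping({
        "DISJOINT": universe[6:9],
        "WHOLE": universe,
    })
    table = hypergeom_enrich(hits, universe, db).set_index("set_name")
    assert table.loc["DISJOINT", "p_value"] == 1.0
    assert table.loc["WHOLE", "p_value"] == pytest.approx(1.0)
    assert table.loc["WHOLE", "overlap"] == 4


def test_hypergeom_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for M in (8, 13, 21):
        universe = [f"u{i}" for i in range(M)]
        for _ in range(10):
            n_hits = int(rng.integers(1, M))
            k_set = int(rng.integers(1, M))
            hits = list(rng.choice(universe, n_hits, replace=False))
            members = list(rng.choice(universe, k_set, replace=False))
            db = GeneSetDB.from_mapping({"S": members})
            table = hypergeom_enrich(hits, universe, db)
            k = int(table.iloc[0]["overlap"])
            expected = hypergeom_tail_oracle(M, k_set, n_hits, k) if k else 1.0
            assert table.iloc[0]["p_value"] == pytest.approx(expected,
                                                             abs=1e-12)


def test_hypergeom_hits_must_be_subset():
    with pytest.raises(ValueError):
        hypergeom_enrich(["x"], ["a", "b"], GeneSetDB.from_mapping({"S": ["a"]}))


def test_bh_matches_textbook_step_up():
    """q-values agree with a direct step-up implementation."""
    rng = np.random.default_rng(1)
    universe = [f"u{i}" for i in range(30)]
    hits = universe[:8]
    db = GeneSetDB.from_mapping(
        {f"S{i}": list(rng.choice(universe, 6, replace=False))
         for i in range(12)})
    table = hypergeom_enrich(hits, universe, db, fdr=0.1)
    p = table["p_value"].to_numpy()          # sorted ascending
    m = len(p)
    q_direct = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
    q_direct = np.minimum(q_direct, 1.0)
    np.testing.assert_allclose(table["q_value"].to_numpy(), q_direct,
                               atol=1e-12)
    assert np.all(np.diff(table["q_value"]) >= -1e-12)
    np.testing.assert_array_equal(table["significant"],
                                  table["q_value"] < 0.1)


# ---------------------------------------------------------------------------
# clustering over enriched genes
# ---------------------------------------------------------------------------

def test_enrich_cluster_single_population_one_cluster():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(6)]
    vals = np.clip(rng.normal(4, 1, size=(6, 80)), 0, None)
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes,
                                         columns=[f"s{i}" for i in range(80)]))
    model, labels, fractions = enrich_cluster(expr, genes,
                                              config=FitConfig(seed=1))
    assert labels.nunique() == 1
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_enrich_cluster_fraction_normalization_and_new_mass():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(4)]
    base = rng.normal(3, 1, size=(4, 70))
    base[:, 35:] += 6.0
    expr = ExpressionMatrix(pd.DataFrame(np.clip(base, 0, None), index=genes,
                                         columns=[f"s{i}" for i in range(70)]))
    _, labels, fractions = enrich_cluster(
        expr, genes, DPPrior(alpha=5.0, k_trunc=5), FitConfig(seed=1))
    assert labels.nunique() == 2
    assert fractions["new"] == pytest.approx(5.0 / 75.0)
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_enrich_cluster_needs_two_genes(small_expr):
    with pytest.raises(ValueError):
        enrich_cluster(small_expr, ["g0"])


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scan_setup():
    """Small cohort with a 3-subtype signature over 12 genes in one set."""
    from mmsig.synthetic import (generate_multimodal_cohort,
                                 random_gene_set_db, synthetic_background)

    bg = synthetic_background(120, seed=5)
    db = random_gene_set_db(bg, 6, 12, seed=5)
    cohort = generate_multimodal_cohort(bg, db["SET_000"], 150,
                                        n_subtypes=3, separation=3.0, seed=9)
    bank = fit_gene_models(cohort.expr,
                           config=FitConfig(seed=2, n_restarts=1))
    return cohort, bank, db


def test_scan_counts_monotone_and_recommendation(scan_setup):
    cohort, bank, db = scan_setup
    thresholds = [0.1, 0.2, 0.3]
    summary, recommended = scan(bank, cohort.expr, db, thresholds,
                                fdr=0.01, config=FitConfig(seed=2))
    passing = summary["n_genes_passing"].to_numpy()
    assert np.all(np.diff(passing) <= 0)
    assert recommended is not None
    row = summary[summary["threshold"] == recommended].iloc[0]
    assert row["n_enriched_genes"] < cohort.expr.n_samples
    assert row["n_clusters"] >= 2


def test_scan_single_threshold(scan_setup):
    cohort, bank, db = scan_setup
    summary, recommended = scan(bank, cohort.expr, db, [0.2], fdr=0.01,
                                config=FitConfig(seed=2))
    assert len(summary) == 1
    row = summary.iloc[0]
    ok = (row["n_enriched_genes"] < cohort.expr.n_samples
          and row["n_clusters"] > 0)
    assert (recommended == 0.2) == ok


def test_scan_requires_sorted_thresholds(scan_setup):
    cohort, bank, db = scan_setup
    with pytest.raises(ValueError):
        scan(bank, cohort.expr, db, [0.3, 0.1])


def test_injected_set_attains_top_enrichment(scan_setup):
    cohort, bank, db = scan_setup
    hits = min_prob_filter(bank, 0.2)
    table = hypergeom_enrich(hits, bank.universe, db, fdr=0.01)
    assert table.iloc[0]["set_name"] == "SET_000"
    genes = enriched_gene_union(table)
    assert set(genes) <= set(bank.universe)
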