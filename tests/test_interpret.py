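"""Evaluation metrics, attention summaries, knockout and association tests."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_model

from citrus import SimConfig, simulate_cohort
from citrus.interpret import (
    aggregate_attention,
    alteration_subtype_association,
    attention_report,
    driver_enrichment,
    insilico_knockout,
    multiple_testing,
    spearman_per_tumor,
    subtype_clustering,
    tf_tumortype_association,
)


# -------------------------------------------------------------------- spearman
def bruteforce_spearman(x, y):
    """Rank correlation via explicit average ranks and Pearson on ranks."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return r
    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def test_spearman_limits_and_tied_oracle():
    y = np.array([[1.0, 3.0, 2.0, 5.0, 4.0]])
    rhos, mean = spearman_per_tumor(y, y.copy())
    assert rhos[0] == pytest.approx(1.0) and mean == pytest.approx(1.0)
    rhos, _ = spearman_per_tumor(y, -y)
    assert rhos[0] == pytest.approx(-1.0)

    a = np.array([1.0, 2.0, 2.0, 4.0, 5.0])  # one tie
    b = np.array([2.0, 1.0, 4.0, 4.0, 3.0])
    rhos, _ = spearman_per_tumor(a[None, :], b[None, :])
    assert rhos[0] == pytest.approx(bruteforce_spearman(a, b), abs=1e-12)


def test_spearman_constant_rows_are_excluded_with_warning():
    y = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
    yhat = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    with pytest.warns(UserWarning, match="constant"):
        rhos, mean = spearman_per_tumor(y, yhat)
    assert np.isnan(rhos[1]) and mean == pytest.approx(1.0)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=20), rng.normal(size=20)
    base, _ = spearman_per_tumor(a[None, :], b[None, :])
    warped, _ = spearman_per_tumor(np.exp(3 * a)[None, :], (b ** 3 + 5 * b)[None, :])
    assert warped[0] == pytest.approx(base[0], abs=1e-12)


# ------------------------------------------------------------------- attention
def test_attention_aggregation_matches_manual_sum(small_cohort):
    cohort, prior, _ = small_cohort
    model = make_model(cohort, prior, seed=1)
    sub = cohort.subset(range(3))
    report = attention_report(model, sub)
    summary = aggregate_attention(report, sub)
    manual = report.groupby("gene")["attention"].sum()
    for _, row in summary.iterrows():
        expected = manual.get(row["gene"], 0.0)
        assert row["cumulative_attention"] == pytest.approx(expected)
    absent = summary[summary["n_carriers"] == 0]
    assert (absent["cumulative_attention"] == 0).all()


def test_single_carrier_single_gene_gets_h_attention(tiny_model):
    from citrus.data import Cohort
    cohort = Cohort(
        tumor_ids=["t1"], cancer_types=["x"],
        alteration_genes=tiny_model.alteration_genes,
        alterations=[np.array([2])],
        expression_genes=tiny_model.expression_genes,
        expression=np.zeros((1, 11)),
    )
    report = attention_report(tiny_model, cohort)
    summary = aggregate_attention(report, cohort)
    got = summary.set_index("gene").at["a2", "cumulative_attention"]
    assert got == pytest.approx(tiny_model.config.attention_heads)


def summary_frame(att, drivers):
    genes = [f"g{i}" for i in range(len(att))]
    return (
        pd.DataFrame({"gene": genes, "cumulative_attention": att,
                      "n_carriers": 1, "frequency": 0.1}),
        {g for g, d in zip(genes, drivers) if d},
    )


def test_driver_enrichment_balanced_table_gives_p_one():
    att = [10.0, 10.0, 0.0, 0.0]
    summary, drivers = summary_frame(att, [1, 0, 1, 0])
    table, p = driver_enrichment(summary, drivers, threshold=2.0)
    assert table.tolist() == [[1, 1], [1, 1]]
    assert p == pytest.approx(1.0)


def test_driver_enrichment_extreme_table_matches_enumeration():
    att = [100.0] * 5 + [0.0] * 5
    summary, drivers = summary_frame(att, [1] * 5 + [0] * 5)
    table, p = driver_enrichment(summary, drivers, threshold=2.0)
    assert table.tolist() == [[5, 0], [0, 5]]
    assert p == pytest.approx(2.0 / 252.0, rel=1e-9)  # 2 / C(10,5)


def test_driver_enrichment_null_calibration():
    """With drivers assigned independently of attention, false positives at
    alpha=0.05 stay near (below, by discreteness) the nominal rate."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 400
    for _ in range(reps):
        att = np.where(rng.random(40) < 0.3, 50.0, 0.0)
        drivers = rng.random(40) < 0.25
        summary, dset = summary_frame(att, drivers)
        _, p = driver_enrichment(summary, dset, threshold=2.0)
        hits += p <= 0.05
    assert hits / reps <= 0.07


def test_empty_high_group_warns_p_one():
    summary, drivers = summary_frame([0.0, 0.0], [1, 0])
    with pytest.warns(UserWarning, match="threshold"):
        _, p = driver_enrichment(summary, drivers, threshold=5.0)
    assert p == 1.0


# -------------------------------------------------------------------- knockout
def test_knockout_of_ignored_gene_gives_null_table(small_cohort):
    cohort, prior, _ = small_cohort
    model = make_model(cohort, prior, seed=3)
    gene = max(
        cohort.alteration_genes,
        key=lambda g: len(cohort.carriers(g)),
    )
    # zero gene embeddings: e_t reduces to the cancer-type embedding whatever
    # the alteration set, so deleting the gene is an exact no-op
    model.params["E_gene"][:] = 0.0
    table = insilico_knockout(model, cohort, gene)
    assert np.allclose(table["mean_difference"], 0.0)
    assert (table["p_value"] == 1.0).all()
    assert (table["fdr"] == 1.0).all()


def test_knockout_errors(small_cohort):
    cohort, prior, _ = small_cohort
    model = make_model(cohort, prior, seed=0)
    with pytest.raises(KeyError, match="not in the cohort"):
        insilico_knockout(model, cohort, "NOPE")
    rare = min(cohort.alteration_genes, key=lambda g: len(cohort.carriers(g)))
    n = len(cohort.carriers(rare))
    with pytest.raises(ValueError, match="needs >="):
        insilico_knockout(model, cohort, rare, min_carriers=n + 1)


def test_knockout_recovers_planted_target(small_trained):
    cohort, truth, models = small_trained
    recovered = 0
    for gene in truth.driver_genes:
        table = insilico_knockout(models, cohort, gene)
        best_tf = table.loc[table["fdr"].idxmin(), "tf"]
        sig = set(table.loc[table["fdr"] < 0.05, "tf"])
        if sig & set(truth.driver_effects[gene]) or best_tf in truth.driver_effects[gene]:
            recovered += 1
    assert recovered >= len(truth.driver_genes) - 1


@pytest.fixture(scope="module")
def small_trained(small_cohort):
    from citrus import ModelConfig, TrainConfig, train_ensemble
    from conftest import SMALL_MODEL
    cohort, prior, truth = small_cohort
    trained = train_ensemble(
        cohort, prior, ModelConfig(**SMALL_MODEL),
        TrainConfig(batch_size=50, patience=10, warmup_evals=10,
                    max_iterations=80, seed=11),
        n_runs=3,
    )
    return cohort, truth, [m for m, _, _ in trained]


# --------------------------------------------------- TF-tumor-type association
def test_identical_activities_give_p_one():
    act = np.tile(np.linspace(-0.5, 0.5, 4), (30, 1))
    cts = ["A"] * 15 + ["B"] * 15
    table = tf_tumortype_association(act, cts, [f"t{i}" for i in range(4)])
    assert (table["p_value"] == 1.0).all()


def test_planted_shift_has_smallest_fdr():
    rng = np.random.default_rng(1)
    act = rng.normal(0, 0.1, size=(60, 6))
    cts = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
    act[cts == "B", 2] += 0.3  # +3 sigma shift of TF 2 in type B
    table = tf_tumortype_association(act, list(cts), [f"t{i}" for i in range(6)])
    best = table.loc[table["fdr"].idxmin()]
    assert (best["cancer_type"], best["tf"]) == ("B", "t2")
    assert best["direction"] == 1


def test_single_test_bh_equals_raw():
    assert multiple_testing(np.array([0.037]), "BH")[0] == pytest.approx(0.037)


# ------------------------------------------------------------------ clustering
def test_two_blobs_recovered_exactly():
    from sklearn.metrics import adjusted_rand_score
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.05, size=(20, 5)) + 0.8
    b = rng.normal(0, 0.05, size=(20, 5)) - 0.8
    act = np.vstack([a, b])
    res = subtype_clustering(act, [f"t{i}" for i in range(5)], k=2, seed=0)
    target = np.array([0] * 20 + [1] * 20)
    assert adjusted_rand_score(target, res.labels) == 1.0
    assert res.mean_activity.shape == (2, 5)


def test_degenerate_and_duplicate_clustering_cases():
    act = np.tile(np.array([[0.1, -0.2]]), (6, 1))
    res = subtype_clustering(act, ["t0", "t1"], k=1, seed=0)
    assert set(res.labels) == {0}
    np.testing.assert_allclose(res.mean_activity.iloc[0], act.mean(axis=0))

    rng = np.random.default_rng(3)
    base = rng.normal(size=(4, 3))
    dup = np.vstack([base, base])  # duplicates must co-cluster
    res = subtype_clustering(dup, ["a", "b", "c"], k=2, seed=0)
    assert np.array_equal(res.labels[:4], res.labels[4:])
    with pytest.raises(ValueError, match="exceeds"):
        subtype_clustering(base, ["a", "b", "c"], k=9, seed=0)


# --------------------------------------------- alteration-subtype association
def test_balanced_alteration_scores_zero():
    alt = np.array([[1], [0], [1], [0]])
    labels = [0, 0, 1, 1]
    table = alteration_subtype_association(alt, ["g"], labels)
    assert (table["fdr"] == 1.0).all()
    assert (table["score"] == 0.0).all()


def test_exclusive_alteration_positive_score_and_hypergeom_p():
    alt = np.zeros((40, 1), dtype=int)
    alt[:10, 0] = 1
    labels = [0] * 10 + [1] * 30
    table = alteration_subtype_association(alt, ["g"], labels).set_index("subtype")
    # p for 10/10 carriers inside vs 0/30 outside: hypergeometric enumeration
    k = np.arange(0, 11)
    pmf = stats.hypergeom(40, 10, 10).pmf(k)
    obs = pmf[10]
    expect_p = pmf[pmf <= obs * (1 + 1e-7)].sum()
    assert table.at[0, "p_value"] == pytest.approx(expect_p, rel=1e-9)
    assert table.at[0, "score"] > 0 > table.at[1, "score"]


def test_two_subtype_scores_are_antisymmetric_under_label_complement():
    rng = np.random.default_rng(2)
    alt = (rng.random((60, 3)) < 0.3).astype(int)
    labels = (rng.random(60) < 0.5).astype(int)
    t1 = alteration_subtype_association(alt, list("abc"), labels)
    t2 = alteration_subtype_association(alt, list("abc"), 1 - labels)
    m1 = t1.pivot(index="gene", columns="subtype", values="score")
    m2 = t2.pivot(index="gene", columns="subtype", values="score")
    np.testing.assert_allclose(m1[0], m2[1], atol=1e-12)
    np.testing.assert_allclose(m1[1], m2[0], atol=1e-12)


# ------------------------------------------------------------ multiple testing
def test_bh_step_up_arithmetic_and_bonferroni_clipping():
    got = multiple_testing(np.array([0.01, 0.02, 0.03]), "BH")
    np.testing.assert_allclose(got, [0.03, 0.03, 0.03])
    assert multiple_testing(np.array([0.6, 0.5, 0.5]), "bonferroni")[0] == 1.0


def bh_oracle(p):
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return np.minimum(adj, 1.0)


def test_bh_matches_step_up_oracle_and_monotone():
    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.random(rng.integers(1, 30))
        got = multiple_testing(p, "BH")
        np.testing.assert_allclose(got, bh_oracle(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(got[order]) >= -1e-12)


def test_nan_pvalues_propagate():
    got = multiple_testing(np.array([0.01, np.nan, 0.04]), "BH")
    assert np.isnan(got[1]) and not np.isnan(got[[0, 2]]).any()
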