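"""Shared fixtures: small simulated cohorts and session-scoped trained models.

Heavy objects (the reference-cohort ensemble) are trained once per session
and reused across evaluation, attention and knockout tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from citrus import (
    CitrusModel,
    ModelConfig,
    SimConfig,
    TrainConfig,
    simulate_cohort,
    stratified_split,
    normalize_expression,
    train_ensemble,
)

# desk-scale architecture used throughout the tests (the library defaults of
# 512/256/8 target real pan-cancer panels)
SMALL_MODEL = dict(embedding_dim=32, attention_size=16, attention_heads=4,
                   dropout=0.2, max_alterations=100)
SMALL_TRAIN = dict(batch_size=100, patience=20, warmup_evals=30, max_iterations=200)


def make_model(cohort, prior, seed=0, **overrides) -> CitrusModel:
    cfg = ModelConfig(**{**SMALL_MODEL, **overrides})
    return CitrusModel(
        alteration_genes=cohort.alteration_genes,
        cancer_types=cohort.cancer_type_names,
        tf_ids=list(prior.columns),
        expression_genes=cohort.expression_genes,
        mask=prior.loc[cohort.expression_genes].to_numpy(),
        config=cfg,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for unit tests (200 tumors, 100 genes, 12 TFs)."""
    cfg = SimConfig(
        n_tumors=200, n_genes=100, n_alteration_genes=300, n_tfs=12,
        n_cancer_types=3, n_drivers=4, seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference study condition: 600 tumors, 400 genes, 30 TFs,
    6 drivers, effect 1.5, noise sd 0.5, seed 7."""
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def reference_run(reference_cohort):
    """Stratified 20% holdout + a 10-run ensemble trained on the pool."""
    cohort, prior, truth = reference_cohort
    labels = dict(zip(cohort.tumor_ids, cohort.cancer_types))
    plan = stratified_split(labels, 0.2, seed=7)
    idx = {t: i for i, t in enumerate(cohort.tumor_ids)}
    pool = cohort.subset([idx[t] for t in plan.train_ids])
    test = cohort.subset([idx[t] for t in plan.test_ids])
    trained = train_ensemble(
        pool,
        prior,
        ModelConfig(**SMALL_MODEL),
        TrainConfig(**SMALL_TRAIN, seed=7),
        n_runs=10,
    )
    models = [m for m, _, _ in trained]
    scaler = trained[0][2]
    return dict(
        cohort=cohort, prior=prior, truth=truth, pool=pool, test=test,
        models=models, scaler=scaler,
        y_test=scaler.transform(test.expression),
    )


@pytest.fixture
def tiny_model():
    """Hand-sized model for analytic checks; no dropout."""
    rng = np.random.default_rng(0)
    mask = (rng.random((11, 4)) < 0.5).astype(int)
    mask[0] = 0  # one gene with an empty prior row
    cfg = ModelConfig(embedding_dim=7, attention_size=5, attention_heads=3, dropout=0.0)
    return CitrusModel(
        alteration_genes=[f"a{i}" for i in range(6)],
        cancer_types=["x", "y"],
        tf_ids=[f"t{i}" for i in range(4)],
        expression_genes=[f"g{i}" for i in range(11)],
        mask=mask,
        config=cfg,
        seed=1,
    )
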