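"""Data splitting, optimisation loop, early stopping and TF-layer ensembling.

Training minimises mean-squared error with Adam (decoupled L2 weight decay on
non-bias parameters, as in the common Adam-with-weight-decay setting) and
projects the sparse decoder onto its constraint set (non-negative, zero
outside the prior) after every optimizer step.  Validation loss is evaluated
once per epoch; early stopping waits out a warm-up and then fires after
``patience`` evaluations without improvement, restoring the best checkpoint.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig, TrainConfig
from .data import Cohort
from .model import Batch, CitrusModel


# ------------------------------------------------------------------ splitting
@dataclass
class SplitPlan:
    train_ids: List[str]
    test_ids: List[str]
    validation_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.test_ids), set(self.validation_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups overlap")


def stratified_split(
    labels: Dict[str, str] | pd.Series, test_fraction: float, seed: int = 0
) -> SplitPlan:
    """Hold out ``test_fraction`` of tumors preserving cancer-type proportions.

    Per-type test counts use largest-remainder rounding so the total equals
    ``round(test_fraction * n)`` and each type's share is within one sample of
    exact proportionality.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rng = np.random.default_rng(seed)
    by_type: Dict[str, List[str]] = {}
    for tid, ct in labels.items():
        by_type.setdefault(str(ct), []).append(str(tid))
    for ct, ids in by_type.items():
        ids.sort()
        if len(ids) < 5:
            warnings.warn(f"cancer type {ct!r} has only {len(ids)} samples")

    types = sorted(by_type)
    quotas = {ct: test_fraction * len(by_type[ct]) for ct in types}
    counts = {ct: int(math.floor(quotas[ct])) for ct in types}
    total = int(round(test_fraction * len(labels)))
    leftover = total - sum(counts.values())
    order = sorted(types, key=lambda ct: (-(quotas[ct] - counts[ct]), ct))
    for ct in order[: max(leftover, 0)]:
        counts[ct] += 1

    train, test = [], []
    for ct in types:
        ids = list(by_type[ct])
        rng.shuffle(ids)
        k = counts[ct]
        test.extend(ids[:k])
        train.extend(ids[k:])
    return SplitPlan(train_ids=sorted(train), test_ids=sorted(test))


def stratified_folds(
    labels: Dict[str, str] | pd.Series, k: int = 5, seed: int = 0
) -> List[Tuple[List[str], List[str]]]:
    """Stratified k-fold partition of tumors; returns (train, validation) id lists."""
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    ids = np.array(sorted(labels.index.astype(str)))
    y = labels.loc[ids].astype(str).to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = list(counts.index[counts < k])
        warnings.warn(f"types {small} have fewer than {k} tumors; pooled across folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[tr]), list(ids[va]))
        for tr, va in skf.split(np.zeros(len(ids)), y)
    ]


# -------------------------------------------------------------- normalization
@dataclass
class ExpressionScaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.sd

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * self.sd + self.mean


def normalize_expression(
    y_train: np.ndarray, *others: np.ndarray
) -> Tuple[List[np.ndarray], ExpressionScaler]:
    """Per-gene z-score with training-set moments applied to all splits.

    Constant genes (sd == 0) are centered only.  Inputs are expected on log
    scale already.
    """
    if any(np.isnan(m).any() for m in (y_train, *others)):
        raise ValueError("NaN in expression matrix")
    mean = y_train.mean(axis=0)
    sd = y_train.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    scaler = ExpressionScaler(mean=mean, sd=sd)
    return [scaler.transform(m) for m in (y_train, *others)], scaler


# -------------------------------------------------------------- early stopping
class EarlyStopping:
    """Patience-based stopper over validation evaluations.

    No stop is issued during the first ``warmup`` evaluations; afterwards the
    stopper fires once ``patience`` consecutive evaluations have passed without
    a new best loss.  ``update`` returns True when training should stop.
    """

    def __init__(self, patience: int, warmup: int = 0) -> None:
        self.patience = patience
        self.warmup = warmup
        self.best = np.inf
        self.best_eval = 0
        self.n_evals = 0

    def update(self, loss: float) -> bool:
        self.n_evals += 1
        if loss < self.best:
            self.best = loss
            self.best_eval = self.n_evals
        if self.n_evals <= self.warmup:
            return False
        return (self.n_evals - self.best_eval) >= self.patience


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam with optional decoupled L2 weight decay per parameter name."""

    def __init__(
        self,
        params: Dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_params: Sequence[str] = (),
    ) -> None:
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.decay_params = set(decay_params)
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.weight_decay and k in self.decay_params:
                g = g + self.weight_decay * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------- training loop
@dataclass
class TrainingLog:
    steps: List[int] = field(default_factory=list)
    train_mse: List[float] = field(default_factory=list)
    val_mse: List[float] = field(default_factory=list)
    stopped_at: Optional[int] = None
    best_eval: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "train_mse": self.train_mse, "val_mse": self.val_mse}
        )


def _evaluate_mse(model: CitrusModel, batch: Batch, y: np.ndarray) -> float:
    out = model.forward(batch, training=False)
    return model.loss(y, out.predicted)


def train(
    model: CitrusModel,
    train_cohort: Cohort,
    val_cohort: Cohort,
    y_train: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> TrainingLog:
    """Optimise ``model`` in place; returns the per-epoch loss log.

    ``y_train`` / ``y_val`` are the (normalised) expression targets aligned
    with the cohorts.  The decoder projection runs after every Adam step, so
    masked-out entries are exactly zero at all times.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(
        model.params,
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        decay_params=CitrusModel.WEIGHT_DECAY_PARAMS,
    )
    stopper = EarlyStopping(patience=cfg.patience, warmup=cfg.warmup_evals)
    log = TrainingLog()

    train_batch_full = model.encode_batch(train_cohort.alterations, train_cohort.cancer_types)
    val_batch = model.encode_batch(val_cohort.alterations, val_cohort.cancer_types)
    n = train_cohort.n_tumors
    best_params = model.clone_params()

    for epoch in range(1, cfg.max_iterations + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            sub = train_cohort.subset(rows)
            batch = model.encode_batch(sub.alterations, sub.cancer_types)
            out = model.forward(batch, training=True, rng=rng, keep_cache=True)
            yb = y_train[rows]
            epoch_losses.append(model.loss(yb, out.predicted))
            grads = model.backward(out, yb)
            opt.step(model.params, grads)
            model.project_decoder()
        val_mse = _evaluate_mse(model, val_batch, y_val)
        if not np.isfinite(val_mse):
            raise FloatingPointError(
                f"validation loss diverged at epoch {epoch} (val_mse={val_mse})"
            )
        log.steps.append(epoch)
        log.train_mse.append(float(np.mean(epoch_losses)))
        log.val_mse.append(val_mse)
        if val_mse <= stopper.best:
            best_params = model.clone_params()
        if stopper.update(val_mse):
            log.stopped_at = epoch
            break

    log.best_eval = stopper.best_eval
    model.set_params(best_params)
    model.project_decoder()
    return log


def fit_cohort(
    cohort: Cohort,
    prior: pd.DataFrame,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    val_fraction: float = 0.2,
    seed: Optional[int] = None,
) -> Tuple[CitrusModel, TrainingLog, ExpressionScaler, SplitPlan]:
    """Convenience wrapper: split a training pool into train/validation,
    normalise expression, build and train a model."""
    seed = train_cfg.seed if seed is None else seed
    labels = dict(zip(cohort.tumor_ids, cohort.cancer_types))
    plan = stratified_split(labels, val_fraction, seed=seed)
    idx = {t: i for i, t in enumerate(cohort.tumor_ids)}
    tr = cohort.subset([idx[t] for t in plan.train_ids])
    va = cohort.subset([idx[t] for t in plan.test_ids])
    (y_tr, y_va), scaler = normalize_expression(tr.expression, va.expression)
    model = CitrusModel(
        alteration_genes=cohort.alteration_genes,
        cancer_types=cohort.cancer_type_names,
        tf_ids=list(prior.columns.astype(str)),
        expression_genes=cohort.expression_genes,
        mask=prior.loc[cohort.expression_genes].to_numpy(),
        config=model_cfg,
        seed=seed,
    )
    cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
    log = train(model, tr, va, y_tr, y_va, cfg)
    return model, log, scaler, SplitPlan(train_ids=plan.train_ids, test_ids=[], validation_ids=plan.test_ids)


def cross_validate(
    cohort: Cohort,
    prior: pd.DataFrame,
    model_cfg: ModelConfig,
    candidates: Sequence[TrainConfig],
    k: int = 5,
    seed: int = 0,
) -> Tuple[TrainConfig, pd.DataFrame]:
    """Stratified k-fold selection over candidate training configs.

    Returns the config with the lowest mean validation MSE and the per-fold
    metric table.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = pd.Series(cohort.cancer_types, index=cohort.tumor_ids)
    folds = stratified_folds(labels, k=k, seed=seed)
    idx = {t: i for i, t in enumerate(cohort.tumor_ids)}
    records = []
    for ci, cand in enumerate(candidates):
        for fi, (tr_ids, va_ids) in enumerate(folds):
            tr = cohort.subset([idx[t] for t in tr_ids])
            va = cohort.subset([idx[t] for t in va_ids])
            (y_tr, y_va), _ = normalize_expression(tr.expression, va.expression)
            model = CitrusModel(
                alteration_genes=cohort.alteration_genes,
                cancer_types=cohort.cancer_type_names,
                tf_ids=list(prior.columns.astype(str)),
                expression_genes=cohort.expression_genes,
                mask=prior.loc[cohort.expression_genes].to_numpy(),
                config=model_cfg,
                seed=seed + fi,
            )
            cfg = TrainConfig(**{**cand.__dict__, "seed": seed + fi})
            log = train(model, tr, va, y_tr, y_va, cfg)
            records.append(
                {"candidate": ci, "fold": fi, "val_mse": min(log.val_mse)}
            )
    table = pd.DataFrame(records)
    means = table.groupby("candidate")["val_mse"].mean()
    best = int(means.idxmin())
    return candidates[best], table


# ------------------------------------------------------------------- ensemble
@dataclass
class EnsembleResult:
    runs: List[np.ndarray]            # per-run tumors x TFs activity matrices
    mean: np.ndarray
    sd: np.ndarray
    models: List[CitrusModel] = field(default_factory=list)


def infer_tf_activities(model: CitrusModel, cohort: Cohort) -> np.ndarray:
    batch = model.encode_batch(cohort.alterations, cohort.cancer_types)
    return model.forward(batch, training=False).tf_activities


def ensemble_tf_activities(models: Sequence[CitrusModel], cohort: Cohort) -> EnsembleResult:
    """Average inferred TF activities over independently initialised runs."""
    panels = {tuple(m.tf_ids) for m in models}
    if len(panels) != 1:
        raise ValueError("ensemble members have mismatched TF panels")
    runs = [infer_tf_activities(m, cohort) for m in models]
    stack = np.stack(runs)
    return EnsembleResult(
        runs=runs, mean=stack.mean(axis=0), sd=stack.std(axis=0, ddof=0),
        models=list(models),
    )


def train_ensemble(
    cohort: Cohort,
    prior: pd.DataFrame,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_runs: int = 10,
    val_fraction: float = 0.2,
) -> List[Tuple[CitrusModel, TrainingLog, ExpressionScaler]]:
    """Train ``n_runs`` models differing only in initialisation/dropout seeds.

    The train/validation split is shared across runs (seeded by the base
    config seed); each run re-seeds parameter init and dropout.
    """
    out = []
    labels = dict(zip(cohort.tumor_ids, cohort.cancer_types))
    plan = stratified_split(labels, val_fraction, seed=train_cfg.seed)
    idx = {t: i for i, t in enumerate(cohort.tumor_ids)}
    tr = cohort.subset([idx[t] for t in plan.train_ids])
    va = cohort.subset([idx[t] for t in plan.test_ids])
    (y_tr, y_va), scaler = normalize_expression(tr.expression, va.expression)
    for r in range(n_runs):
        model = CitrusModel(
            alteration_genes=cohort.alteration_genes,
            cancer_types=cohort.cancer_type_names,
            tf_ids=list(prior.columns.astype(str)),
            expression_genes=cohort.expression_genes,
            mask=prior.loc[cohort.expression_genes].to_numpy(),
            config=model_cfg,
            seed=train_cfg.seed + 1000 * (r + 1),
        )
        cfg = TrainConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + 1000 * (r + 1)})
        log = train(model, tr, va, y_tr, y_va, cfg)
        out.append((model, log, scaler))
    return out
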