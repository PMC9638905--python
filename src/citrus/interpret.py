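"""Downstream statistics on trained models.

Covers prediction evaluation (per-tumor Spearman), attention aggregation and
driver enrichment, the in silico knockout procedure, TF / tumor-type
association, subtype discovery by k-means on inferred TF activities, and the
signed alteration-subtype association score.

Statistical conventions: two-sample t-tests are Welch's by default
(configurable to pooled variance), Fisher's exact test is two-sided, and
multiple testing uses Benjamini-Hochberg (or Bonferroni) with NaN
propagation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .data import Cohort
from .model import CitrusModel


# ----------------------------------------------------------------- evaluation
def spearman_per_tumor(y: np.ndarray, yhat: np.ndarray) -> Tuple[np.ndarray, float]:
    """Spearman rank correlation between measured and predicted expression,
    one coefficient per tumor (row); returns the per-tumor vector and its
    mean over defined entries.  Constant rows yield NaN and are excluded from
    the mean with a warning."""
    if y.shape != yhat.shape or y.shape[1] < 3:
        raise ValueError("need matched matrices with >= 3 genes")
    rhos = np.full(y.shape[0], np.nan)
    for i in range(y.shape[0]):
        if np.ptp(y[i]) == 0 or np.ptp(yhat[i]) == 0:
            continue
        rhos[i] = stats.spearmanr(y[i], yhat[i]).statistic
    n_bad = int(np.isnan(rhos).sum())
    if n_bad:
        warnings.warn(f"{n_bad} tumors had constant profiles; excluded from mean rho")
    return rhos, float(np.nanmean(rhos))


def evaluate_predictions(
    model: CitrusModel, cohort: Cohort, y_normalized: np.ndarray
) -> pd.DataFrame:
    """Per-tumor Spearman rho and MSE on a (held-out) cohort."""
    batch = model.encode_batch(cohort.alterations, cohort.cancer_types)
    out = model.forward(batch, training=False)
    rhos, _ = spearman_per_tumor(y_normalized, out.predicted)
    mse = np.mean((y_normalized - out.predicted) ** 2, axis=1)
    return pd.DataFrame(
        {
            "tumor_id": cohort.tumor_ids,
            "cancer_type": cohort.cancer_types,
            "spearman_rho": rhos,
            "mse": mse,
        }
    )


# ------------------------------------------------------------------ attention
def attention_report(model: CitrusModel, cohort: Cohort) -> pd.DataFrame:
    """Per (tumor, altered gene): summed-across-heads attention weight."""
    batch = model.encode_batch(cohort.alterations, cohort.cancer_types)
    out = model.forward(batch, training=False)
    rows = []
    for i, idx in enumerate(cohort.alterations):
        # batches order each profile's genes canonically (sorted)
        for slot, g in enumerate(np.sort(np.asarray(idx))):
            rows.append(
                {
                    "tumor_id": cohort.tumor_ids[i],
                    "cancer_type": cohort.cancer_types[i],
                    "gene": cohort.alteration_genes[g],
                    "attention": out.alpha[i, slot],
                }
            )
    return pd.DataFrame(rows, columns=["tumor_id", "cancer_type", "gene", "attention"])


def aggregate_attention(
    report: pd.DataFrame, cohort: Cohort, per_carrier_mean: bool = False
) -> pd.DataFrame:
    """Cumulative attention per gene (sum of summed-head weights over carrier
    tumors) together with pan-cohort alteration frequency.  ``per_carrier_mean``
    switches the aggregate to the mean over carriers."""
    agg = report.groupby("gene")["attention"].agg("mean" if per_carrier_mean else "sum")
    carriers = report.groupby("gene")["tumor_id"].nunique()
    table = pd.DataFrame(index=pd.Index(cohort.alteration_genes, name="gene"))
    table["cumulative_attention"] = agg.reindex(table.index).fillna(0.0)
    table["n_carriers"] = carriers.reindex(table.index).fillna(0).astype(int)
    table["frequency"] = table["n_carriers"] / cohort.n_tumors
    return table.reset_index()


def driver_enrichment(
    summary: pd.DataFrame,
    driver_set: set,
    threshold: float = 2.0,
    log_base: float = np.e,
) -> Tuple[np.ndarray, float]:
    """Fisher's exact test of driver membership vs high/low attention.

    Genes are split at ``log(cumulative_attention + 1) >= threshold`` (natural
    log by default).  Returns the 2x2 table
    [[driver&high, driver&low], [other&high, other&low]] and the two-sided p.
    """
    att = np.log(summary["cumulative_attention"].to_numpy() + 1.0) / np.log(log_base)
    high = att >= threshold
    is_driver = summary["gene"].isin(driver_set).to_numpy()
    table = np.array(
        [
            [int((is_driver & high).sum()), int((is_driver & ~high).sum())],
            [int((~is_driver & high).sum()), int((~is_driver & ~high).sum())],
        ]
    )
    if high.sum() == 0:
        warnings.warn("no gene passes the attention threshold; p = 1")
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def top_frequent_split_enrichment(
    summary: pd.DataFrame,
    driver_set: set,
    n_top: int = 100,
    threshold: float = 2.0,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Driver enrichment within the most frequently altered genes, split into
    a high- and a low-attention group at the given threshold; one Fisher test
    per group against the rest of the gene panel."""
    ranked = summary.sort_values("frequency", ascending=False, kind="mergesort")
    top = ranked.head(n_top)
    att = np.log(top["cumulative_attention"].to_numpy() + 1.0) / np.log(log_base)
    rows = []
    for name, group in (("high", top[att >= threshold]), ("low", top[att < threshold])):
        in_group = summary["gene"].isin(set(group["gene"]))
        is_driver = summary["gene"].isin(driver_set)
        table = np.array(
            [
                [int((in_group & is_driver).sum()), int((in_group & ~is_driver).sum())],
                [int((~in_group & is_driver).sum()), int((~in_group & ~is_driver).sum())],
            ]
        )
        p = 1.0 if table[0].sum() == 0 else float(stats.fisher_exact(table)[1])
        rows.append({"group": name, "n_genes": int(table[0].sum()), "p_value": p})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- knockout
def _t_test(a: np.ndarray, b: np.ndarray, equal_var: bool = False, paired: bool = False):
    with np.errstate(divide="ignore", invalid="ignore"):
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return t, p


def _ensemble_activities(
    models: Sequence[CitrusModel], alterations, cancer_types
) -> np.ndarray:
    acts = []
    for m in models:
        batch = m.encode_batch(alterations, cancer_types)
        acts.append(m.forward(batch, training=False).tf_activities)
    return np.mean(acts, axis=0)


def insilico_knockout(
    models: Sequence[CitrusModel] | CitrusModel,
    cohort: Cohort,
    gene: str,
    min_carriers: int = 5,
    equal_var: bool = False,
    paired: bool = False,
) -> pd.DataFrame:
    """Delete alteration ``gene`` from its carrier tumors and test TF shifts.

    Carrier tumors keep their original profiles ("altered" group) and are
    re-scored with the gene removed ("wild-type" corpus); per TF a two-sample
    t-test compares the two groups of inferred activities.  Raw p-values are
    BH-adjusted across the TF panel.
    """
    if isinstance(models, CitrusModel):
        models = [models]
    if gene not in cohort.alteration_genes:
        raise KeyError(f"gene {gene!r} not in the cohort's alteration panel")
    g = cohort.alteration_genes.index(gene)
    carrier_rows = [i for i, idx in enumerate(cohort.alterations) if g in idx]
    if len(carrier_rows) < min_carriers:
        raise ValueError(
            f"{gene} altered in {len(carrier_rows)} tumors; needs >= {min_carriers}"
        )
    alts_mut = [cohort.alterations[i] for i in carrier_rows]
    alts_wt = [a[a != g] for a in alts_mut]
    cts = [cohort.cancer_types[i] for i in carrier_rows]

    act_mut = _ensemble_activities(models, alts_mut, cts)
    act_wt = _ensemble_activities(models, alts_wt, cts)

    tf_ids = models[0].tf_ids
    stats_rows = []
    for j, tf in enumerate(tf_ids):
        t, p = _t_test(act_mut[:, j], act_wt[:, j], equal_var=equal_var, paired=paired)
        diff = float(act_mut[:, j].mean() - act_wt[:, j].mean())
        stats_rows.append(
            {"gene": gene, "tf": tf, "t": t, "p_value": p,
             "mean_difference": diff, "direction": 1 if diff >= 0 else -1}
        )
    table = pd.DataFrame(stats_rows)
    table["fdr"] = multiple_testing(table["p_value"].to_numpy(), method="BH")
    return table


def knockout_screen(
    models: Sequence[CitrusModel] | CitrusModel,
    cohort: Cohort,
    genes: Optional[Sequence[str]] = None,
    min_carriers: int = 5,
    pool_fdr: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Run the knockout over many alterations.  By default the FDR family is
    the TF panel within each alteration's model; ``pool_fdr`` recomputes BH
    over the pooled raw p-values instead."""
    if isinstance(models, CitrusModel):
        models = [models]
    if genes is None:
        counts = cohort.alteration_matrix().sum(axis=0)
        genes = [
            g for g, c in zip(cohort.alteration_genes, counts) if c >= min_carriers
        ]
    tables = [
        insilico_knockout(models, cohort, g, min_carriers=min_carriers, **kwargs)
        for g in genes
    ]
    table = pd.concat(tables, ignore_index=True)
    if pool_fdr:
        table["fdr"] = multiple_testing(table["p_value"].to_numpy(), method="BH")
    return table


# --------------------------------------------------- TF / tumor-type association
def tf_tumortype_association(
    activities: np.ndarray,
    cancer_types: Sequence[str],
    tf_ids: Sequence[str],
    equal_var: bool = False,
    min_tumors: int = 3,
) -> pd.DataFrame:
    """One-vs-rest t-test of inferred TF activity per (cancer type, TF);
    BH correction within each cancer type's TF family."""
    cts = np.asarray(cancer_types)
    if len(set(cts)) < 2:
        raise ValueError("need at least two cancer types")
    rows = []
    for ct in sorted(set(cts)):
        in_ct = cts == ct
        if in_ct.sum() < min_tumors:
            warnings.warn(f"cancer type {ct!r} has < {min_tumors} tumors; skipped")
            continue
        ps = []
        for j, tf in enumerate(tf_ids):
            t, p = _t_test(activities[in_ct, j], activities[~in_ct, j], equal_var=equal_var)
            diff = float(activities[in_ct, j].mean() - activities[~in_ct, j].mean())
            rows.append(
                {"cancer_type": ct, "tf": tf, "t": t, "p_value": p,
                 "mean_difference": diff, "direction": 1 if diff >= 0 else -1}
            )
            ps.append(p)
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for ct in table["cancer_type"].unique():
        sel = table["cancer_type"] == ct
        table.loc[sel, "fdr"] = multiple_testing(
            table.loc[sel, "p_value"].to_numpy(), method="BH"
        )
    return table


# ----------------------------------------------------------- subtype clustering
@dataclass
class SubtypeResult:
    labels: np.ndarray                 # subtype index per tumor
    mean_activity: pd.DataFrame        # subtypes x TFs
    subtype_order: List[int]
    tf_order: List[str]


def subtype_clustering(
    activities: np.ndarray,
    tf_ids: Sequence[str],
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> SubtypeResult:
    """K-means subtypes on TF-activity rows of one cancer type, with
    average-linkage hierarchical ordering of subtypes and TFs for display."""
    n = activities.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} tumors available")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(activities)
    means = pd.DataFrame(
        [activities[labels == c].mean(axis=0) for c in range(k)],
        index=pd.RangeIndex(k, name="subtype"),
        columns=list(tf_ids),
    )
    if k > 1:
        link = hierarchy.linkage(means.to_numpy(), method="average", metric="euclidean")
        subtype_order = list(hierarchy.leaves_list(link))
    else:
        subtype_order = [0]
    if len(tf_ids) > 1:
        link_t = hierarchy.linkage(means.to_numpy().T, method="average", metric="euclidean")
        tf_order = [tf_ids[i] for i in hierarchy.leaves_list(link_t)]
    else:
        tf_order = list(tf_ids)
    return SubtypeResult(labels, means, subtype_order, tf_order)


def silhouette_scan(
    activities: np.ndarray, ks: Sequence[int], seed: int = 0
) -> pd.DataFrame:
    from sklearn.metrics import silhouette_score

    rows = []
    for k in ks:
        res = subtype_clustering(activities, [str(i) for i in range(activities.shape[1])], k, seed=seed)
        score = silhouette_score(activities, res.labels) if k > 1 else np.nan
        rows.append({"k": k, "silhouette": score})
    return pd.DataFrame(rows)


# ------------------------------------------- alteration / subtype association
def alteration_subtype_association(
    alteration_matrix: np.ndarray,
    alteration_genes: Sequence[str],
    subtype_labels: Sequence[int],
) -> pd.DataFrame:
    """Signed association score between each alteration and each subtype.

    Per (alteration, subtype): Fisher's exact test of carrier counts inside
    vs outside the subtype, BH-adjusted across subtypes within the
    alteration; score = direction x (-log10 FDR) with direction +1 when the
    within-subtype carrier frequency exceeds the outside frequency.
    """
    labels = np.asarray(subtype_labels)
    subtypes = sorted(set(labels.tolist()))
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes")
    rows = []
    for gi, gene in enumerate(alteration_genes):
        carrier = alteration_matrix[:, gi].astype(bool)
        if carrier.sum() == 0:
            continue
        ps, dirs, tables = [], [], []
        for s in subtypes:
            in_s = labels == s
            a = int((carrier & in_s).sum())
            b = int((~carrier & in_s).sum())
            c = int((carrier & ~in_s).sum())
            d = int((~carrier & ~in_s).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]])
            f_in = a / max(a + b, 1)
            f_out = c / max(c + d, 1)
            ps.append(float(p))
            dirs.append(1 if f_in > f_out else -1)
            tables.append((a, b, c, d))
        fdr = multiple_testing(np.array(ps), method="BH")
        for s, p, d, q, tab in zip(subtypes, ps, dirs, fdr, tables):
            rows.append(
                {"gene": gene, "subtype": s, "p_value": p, "fdr": q,
                 "direction": d, "score": d * (-np.log10(max(q, 1e-300))),
                 "carriers_in": tab[0], "carriers_out": tab[2]}
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ multiple testing
def multiple_testing(pvalues: np.ndarray, method: str = "BH") -> np.ndarray:
    """BH step-up or Bonferroni adjustment with NaN propagation."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    out[ok] = multipletests(p[ok], method=key)[1]
    return out
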