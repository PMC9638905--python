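"""Synthetic cohorts with known ground truth.

The generator mirrors the model's own generative assumptions (well-specified
regime): a handful of driver alterations shift latent TF activities through a
tanh link, cancer types contribute a per-TF offset, and expression is a
non-negative sparse linear readout of TF activities (masked by a simulated
chromatin prior) plus Gaussian noise.  Background alterations are inert
Bernoulli noise whose per-gene rates are drawn from a heavy-tailed
(lognormal) distribution around the configured mean density, echoing the
skewed alteration-frequency spectra of real tumor cohorts; a pre-processing
filter then removes genes altered in fewer than 4% of samples of every
cancer type, as done for the real inputs.

``simulate_prior_inputs`` emits toy BED/FIMO/annotation/presence files laid
out so that the prior-building pipeline reproduces a planted constraint
matrix exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .data import Cohort
from .prior import GeneAnnotation, PeakAtlas


@dataclass
class GroundTruth:
    driver_genes: List[str]
    driver_effects: Dict[str, Dict[str, float]]   # driver -> {tf: signed shift}
    driver_frequencies: "pd.DataFrame"            # drivers x cancer types, target rates
    tf_activities: np.ndarray                     # tumors x TFs, in (-1, 1)
    decoder_weights: np.ndarray                   # genes x TFs, non-negative, masked
    intercepts: np.ndarray                        # per-gene expression baseline
    clean_expression: np.ndarray                  # before noise
    background_rates: np.ndarray                  # per alteration gene


def simulate_cohort(cfg: SimConfig) -> Tuple[Cohort, pd.DataFrame, GroundTruth]:
    """Generate (cohort, prior C as genes x TFs frame, ground truth).

    Driver carrier frequencies are drawn per (driver, cancer type) from the
    configured range; each driver shifts ``tfs_per_driver`` randomly chosen
    TFs by ``effect_size`` with random sign.  TF activity is
    ``tanh(driver shifts + cancer-type offset)``; expression is the masked
    non-negative linear readout plus N(0, noise_sd) noise on log scale.
    """
    rng = np.random.default_rng(cfg.seed)
    nt, ng, na, nf = cfg.n_tumors, cfg.n_genes, cfg.n_alteration_genes, cfg.n_tfs

    tumor_ids = [f"T{i:04d}" for i in range(nt)]
    type_names = [f"CT{c}" for c in range(cfg.n_cancer_types)]
    cancer_types = [type_names[i % cfg.n_cancer_types] for i in range(nt)]
    ct_index = np.array([type_names.index(c) for c in cancer_types])

    alteration_genes = [f"AG{i:03d}" for i in range(na)]
    expression_genes = [f"G{i:03d}" for i in range(ng)]
    tf_ids = [f"TF{i:02d}" for i in range(nf)]

    # drivers and their TF effects
    driver_idx = rng.choice(na, size=cfg.n_drivers, replace=False)
    driver_genes = [alteration_genes[i] for i in driver_idx]
    driver_effects: Dict[str, Dict[str, float]] = {}
    effect_mat = np.zeros((cfg.n_drivers, nf))
    for d, gene in enumerate(driver_genes):
        tfs = rng.choice(nf, size=min(cfg.tfs_per_driver, nf), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(tfs))
        effect_mat[d, tfs] = signs * cfg.effect_size
        driver_effects[gene] = {tf_ids[j]: float(effect_mat[d, j]) for j in tfs}

    # alteration matrix: drivers with per-type frequencies, heavy-tailed background
    lo, hi = cfg.driver_frequency
    alt = np.zeros((nt, na), dtype=np.int8)
    target_freqs = np.zeros((cfg.n_drivers, cfg.n_cancer_types))
    for d, gi in enumerate(driver_idx):
        freq_by_type = rng.uniform(lo, hi, size=cfg.n_cancer_types)
        target_freqs[d] = freq_by_type
        alt[:, gi] = rng.random(nt) < freq_by_type[ct_index]
    background = np.setdiff1d(np.arange(na), driver_idx)
    rates = np.zeros(na)
    rates[background] = np.minimum(
        cfg.background_density * rng.lognormal(0.0, 1.25, size=len(background)), 0.5
    )
    alt[:, background] = rng.random((nt, len(background))) < rates[background]

    # latent TF activity and expression readout
    type_offsets = rng.normal(0.0, cfg.cancer_type_sd, size=(cfg.n_cancer_types, nf))
    pre = type_offsets[ct_index] + alt[:, driver_idx].astype(float) @ effect_mat
    if cfg.misspecify:
        # pairwise driver interactions violating the additive model
        for d in range(cfg.n_drivers - 1):
            both = alt[:, driver_idx[d]] * alt[:, driver_idx[d + 1]]
            pre += np.outer(both, effect_mat[d] * 0.5)
    ef = np.tanh(pre)

    mask = (rng.random((ng, nf)) < cfg.prior_density).astype(np.int8)
    none = mask.sum(axis=1) == 0
    mask[none, rng.integers(0, nf, size=int(none.sum()))] = 1
    weights = rng.uniform(0.5, 1.5, size=(ng, nf)) * mask
    weights *= 3.0 / np.sqrt(np.maximum(mask.sum(axis=1, keepdims=True), 1))
    intercepts = rng.normal(8.0, 1.0, size=ng)  # log-scale baseline abundance

    clean = ef @ weights.T + intercepts
    expr = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)

    # pre-processing filter: keep alteration genes present in >= 4% of samples
    # of at least one cancer type
    keep = np.zeros(na, dtype=bool)
    for c in range(cfg.n_cancer_types):
        rows = ct_index == c
        freq = alt[rows].mean(axis=0)
        keep |= freq >= cfg.min_alteration_frequency
    keep[driver_idx] |= alt[:, driver_idx].mean(axis=0) > 0  # drivers always pass in practice
    kept_idx = np.flatnonzero(keep)
    alt = alt[:, kept_idx]
    kept_genes = [alteration_genes[i] for i in kept_idx]

    cohort = Cohort(
        tumor_ids=tumor_ids,
        cancer_types=cancer_types,
        alteration_genes=kept_genes,
        alterations=[np.flatnonzero(alt[i]).astype(int) for i in range(nt)],
        expression_genes=expression_genes,
        expression=expr,
    )
    prior = pd.DataFrame(
        mask, index=pd.Index(expression_genes, name="gene"), columns=tf_ids
    )
    truth = GroundTruth(
        driver_genes=driver_genes,
        driver_effects=driver_effects,
        driver_frequencies=pd.DataFrame(
            target_freqs, index=driver_genes, columns=type_names
        ),
        tf_activities=ef,
        decoder_weights=weights,
        intercepts=intercepts,
        clean_expression=clean,
        background_rates=rates,
    )
    return cohort, prior, truth


def simulate_prior_inputs(
    cfg: SimConfig, planted: pd.DataFrame | None = None
) -> Tuple[PeakAtlas, pd.DataFrame, GeneAnnotation, pd.DataFrame, pd.DataFrame]:
    """Toy genome + motif hits arranged so the prior pipeline recovers a
    planted genes x TFs constraint matrix.

    Returns (atlas, FIMO-style hits, annotation, presence table, planted C).
    Each planted (gene, TF) edge gets its own peak inside the gene's flanked
    window carrying one motif hit, so target-peak sets of distinct TFs are
    disjoint (no deduplication interference); decoy peaks far from every gene
    carry hits that must not leak into C.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:03d}" for i in range(min(cfg.n_genes, 24))]
    tfs = [f"TF{i:02d}" for i in range(min(cfg.n_tfs, 8))]
    if planted is None:
        c = (rng.random((len(genes), len(tfs))) < 0.3).astype(np.int8)
        planted = pd.DataFrame(c, index=pd.Index(genes, name="gene"), columns=tfs)
    else:
        genes = list(planted.index)
        tfs = list(planted.columns)

    spacing = 2_000_000  # >> flank so neighbouring windows cannot collide
    ann_rows = []
    for i, g in enumerate(genes):
        chrom = f"chr{1 + i % 2}"
        start = 500_000 + (i // 2) * spacing
        if i % 3 == 2:  # a few minus-strand genes
            ann_rows.append(
                {"gene_id": g, "chrom": chrom, "tss": start + 20_000,
                 "three_prime_end": start, "strand": "-"}
            )
        else:
            ann_rows.append(
                {"gene_id": g, "chrom": chrom, "tss": start,
                 "three_prime_end": start + 20_000, "strand": "+"}
            )
    annotation = GeneAnnotation(pd.DataFrame(ann_rows))

    peak_rows, hit_rows = [], []
    pid = 0
    for i, g in enumerate(genes):
        row = annotation.genes.iloc[i]
        body_lo = min(row["tss"], row["three_prime_end"])
        for j, tf in enumerate(tfs):
            if planted.loc[g, tf]:
                start = int(body_lo + 1_000 + 600 * j)
                peak = f"peak_{pid:04d}"
                pid += 1
                peak_rows.append(
                    {"chrom": row["chrom"], "start": start, "end": start + 500,
                     "peak_id": peak}
                )
                hit_rows.append(
                    {"motif_id": tf, "peak_id": peak,
                     "score": float(rng.uniform(5.0, 15.0)), "p_value": 1e-6}
                )
    # decoy peaks on an unannotated chromosome, and sub-threshold hits
    for d in range(4):
        peak = f"decoy_{d}"
        peak_rows.append({"chrom": "chrUn", "start": 100 + d * 1000,
                          "end": 600 + d * 1000, "peak_id": peak})
        hit_rows.append({"motif_id": tfs[d % len(tfs)], "peak_id": peak,
                         "score": 12.0, "p_value": 1e-6})
    atlas = PeakAtlas(pd.DataFrame(peak_rows))
    hits = pd.DataFrame(hit_rows, columns=["motif_id", "peak_id", "score", "p_value"])

    presence = pd.DataFrame(
        rng.uniform(0.55, 0.95, size=(len(tfs), 3)),
        index=pd.Index(tfs, name="tf"),
        columns=[f"CT{c}" for c in range(3)],
    )
    return atlas, hits, annotation, presence, planted
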