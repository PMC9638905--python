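"""Construction of the binary TF -> target-gene constraint matrix.

Starting from a pan-tissue atlas of accessible chromatin (BED peaks), motif
scan hits over those peaks (FIMO-style table, already thresholded at
P < 1e-5 and defensively re-filtered on load), a gene annotation with TSS and
3' end, and a TF expression-presence table, the pipeline is:

1. assign peaks to genes: a peak belongs to a gene when it overlaps (>= 1 bp)
   the window spanning the transcription unit extended by ``flank`` bp
   (default 100 kb) on both genomic sides — for either strand the "upstream
   of the TSS" and "downstream of the 3' end" extensions are exactly the two
   genomic sides of the unit, so the strand-aware and symmetric readings
   coincide;
2. per gene and motif, max-pool the motif score over the gene's peaks;
3. drop TFs not expressed in at least ``min_presence`` of samples in at
   least one tumor type;
4. collapse near-duplicate TFs whose predicted target-peak sets have Jaccard
   index above ``jaccard_cutoff`` (iteratively removing, from each offending
   pair, the TF with the larger mean Jaccard against all survivors);
5. binarise: C[gene, tf] = 1 iff the max-pooled score is positive.

Coordinates follow the BED convention (0-based, half-open) throughout.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100_000
DEFAULT_SCAN_P = 1e-5


# ------------------------------------------------------------------- containers
@dataclass
class PeakAtlas:
    peaks: pd.DataFrame  # columns: chrom, start, end, peak_id

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "peak_id"}
        if not need.issubset(self.peaks.columns):
            raise ValueError(f"peak table needs columns {sorted(need)}")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peaks must satisfy start < end (0-based half-open)")
        if self.peaks["peak_id"].duplicated().any():
            raise ValueError("peak_id values must be unique")

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakAtlas":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "peak_id"], usecols=[0, 1, 2, 3],
        )
        return cls(df)

    def to_bed(self, path: str | Path) -> None:
        self.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class GeneAnnotation:
    genes: pd.DataFrame  # columns: gene_id, chrom, tss, three_prime_end, strand

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "tss", "three_prime_end", "strand"}
        if not need.issubset(self.genes.columns):
            raise ValueError(f"annotation needs columns {sorted(need)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        g = self.genes
        plus_bad = (g["strand"] == "+") & (g["tss"] > g["three_prime_end"])
        minus_bad = (g["strand"] == "-") & (g["tss"] < g["three_prime_end"])
        if (plus_bad | minus_bad).any():
            raise ValueError("TSS/3' end ordering inconsistent with strand")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


FIMO_COLUMNS = [
    "motif_id", "motif_alt_id", "sequence_name", "start", "stop",
    "strand", "score", "p-value", "q-value", "matched_sequence",
]


def read_fimo(path: str | Path, scan_p: float = DEFAULT_SCAN_P) -> pd.DataFrame:
    """Load a FIMO-style tab-delimited hit table.

    ``sequence_name`` is interpreted as the scanned peak id.  Hits above the
    scan threshold are dropped defensively (the upstream scan should already
    have applied it)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("motif_id", "sequence_name", "score", "p-value") if c not in df.columns]
    if missing:
        raise ValueError(f"FIMO table lacks columns {missing}")
    df = df.rename(columns={"sequence_name": "peak_id", "p-value": "p_value"})
    before = len(df)
    df = df[df["p_value"] <= scan_p].reset_index(drop=True)
    if len(df) < before:
        logger.info("dropped %d motif hits above P=%g", before - len(df), scan_p)
    return df[["motif_id", "peak_id", "score", "p_value"]]


def write_fimo(hits: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({c: "" for c in FIMO_COLUMNS}, index=hits.index)
    out["motif_id"] = hits["motif_id"].values
    out["motif_alt_id"] = hits["motif_id"].values
    out["sequence_name"] = hits["peak_id"].values
    out["start"], out["stop"], out["strand"] = 1, 10, "+"
    out["score"] = hits["score"].values
    out["p-value"] = hits["p_value"].values
    out["q-value"] = hits["p_value"].values
    out["matched_sequence"] = "N"
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ operations
def assign_peaks_to_genes(
    atlas: PeakAtlas,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
    nearest_only: bool = False,
) -> Dict[str, Set[str]]:
    """Map each gene to the peaks overlapping its flanked transcription unit.

    A peak may serve several genes unless ``nearest_only`` keeps, per peak,
    only the gene with the closest TSS among its candidates.  Peaks on
    chromosomes absent from the annotation are skipped with a warning.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    genes = annotation.genes
    peaks = atlas.peaks
    known_chroms = set(genes["chrom"])
    stray = sorted(set(peaks["chrom"]) - known_chroms)
    if stray:
        warnings.warn(f"skipping peaks on unannotated chromosomes: {stray}")

    assignment: Dict[str, Set[str]] = {g: set() for g in genes["gene_id"]}
    claims: Dict[str, List[Tuple[int, str]]] = {}

    lo = np.minimum(genes["tss"], genes["three_prime_end"]).to_numpy() - flank
    lo = np.clip(lo, 0, None)
    hi = np.maximum(genes["tss"], genes["three_prime_end"]).to_numpy() + flank

    for chrom, pk in peaks.groupby("chrom", sort=False):
        sel = genes["chrom"] == chrom
        if not sel.any():
            continue
        g_ids = genes.loc[sel, "gene_id"].to_numpy()
        g_tss = genes.loc[sel, "tss"].to_numpy()
        g_lo, g_hi = lo[sel.to_numpy()], hi[sel.to_numpy()]
        p_start = pk["start"].to_numpy()[:, None]
        p_end = pk["end"].to_numpy()[:, None]
        overlap = (p_start < g_hi[None, :]) & (p_end > g_lo[None, :])
        pi, gi = np.nonzero(overlap)
        for p_row, g_col in zip(pi, gi):
            pid = pk["peak_id"].iat[p_row]
            if nearest_only:
                centre = (pk["start"].iat[p_row] + pk["end"].iat[p_row]) // 2
                claims.setdefault(pid, []).append(
                    (abs(int(centre) - int(g_tss[g_col])), g_ids[g_col])
                )
            else:
                assignment[g_ids[g_col]].add(pid)
    if nearest_only:
        for pid, cands in claims.items():
            cands.sort()
            assignment[cands[0][1]].add(pid)
    return assignment


def aggregate_motif_scores(
    assignment: Dict[str, Set[str]], hits: pd.DataFrame
) -> pd.DataFrame:
    """Gene x motif matrix of max-pooled motif scores (0 where no assigned
    peak carries the motif)."""
    motifs = sorted(hits["motif_id"].unique())
    genes = sorted(assignment)
    best: Dict[Tuple[str, str], float] = {}
    by_peak = hits.groupby("peak_id")
    peak_groups = {pid: grp for pid, grp in by_peak}
    for gene in genes:
        for pid in assignment[gene]:
            grp = peak_groups.get(pid)
            if grp is None:
                continue
            for m, s in zip(grp["motif_id"], grp["score"]):
                key = (gene, m)
                if s > best.get(key, 0.0):
                    best[key] = float(s)
    mat = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=motifs)
    for (gene, m), s in best.items():
        mat.at[gene, m] = s
    return mat


def filter_tfs_by_expression(
    presence: pd.DataFrame, threshold: float = 0.5, tf_ids: Iterable[str] | None = None
) -> Set[str]:
    """Retain a TF iff it is expressed in at least ``threshold`` of samples in
    at least one tumor type.  ``presence`` is TFs x tumor types with values in
    [0, 1]."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = presence.to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("presence fractions must lie in [0, 1]")
    candidates = set(presence.index.astype(str))
    if tf_ids is not None:
        requested = set(tf_ids)
        absent = requested - candidates
        if absent:
            warnings.warn(f"TFs absent from the presence table dropped: {sorted(absent)}")
        candidates &= requested
    keep = presence.max(axis=1) >= threshold
    return {tf for tf in candidates if keep.loc[tf]}


def jaccard(a: Set[str], b: Set[str]) -> float:
    if not a or not b:
        return 0.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def deduplicate_tfs_by_jaccard(
    target_sets: Dict[str, Set[str]], cutoff: float = 0.5
) -> Set[str]:
    """Iteratively remove redundant TFs whose target-peak sets overlap.

    While any surviving pair exceeds the Jaccard cutoff, the member of the
    most-overlapping pair with the larger mean Jaccard against all other
    survivors is removed (ties by lexicographic id, removing the larger).
    Returns the removed set.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    survivors = sorted(target_sets)
    removed: Set[str] = set()
    while True:
        worst: Tuple[float, str, str] | None = None
        for i, a in enumerate(survivors):
            for b in survivors[i + 1 :]:
                j = jaccard(target_sets[a], target_sets[b])
                if j > cutoff and (worst is None or j > worst[0]):
                    worst = (j, a, b)
        if worst is None:
            return removed
        _, a, b = worst

        def mean_jaccard(tf: str) -> float:
            others = [s for s in survivors if s != tf]
            if not others:
                return 0.0
            return float(np.mean([jaccard(target_sets[tf], target_sets[o]) for o in others]))

        ma, mb = mean_jaccard(a), mean_jaccard(b)
        if ma > mb:
            victim = a
        elif mb > ma:
            victim = b
        else:
            victim = max(a, b)
        survivors.remove(victim)
        removed.add(victim)


def tf_target_peak_sets(
    hits: pd.DataFrame, motif_to_tf: Dict[str, str] | None = None
) -> Dict[str, Set[str]]:
    """Per TF, the set of peaks carrying a significant hit of its motif."""
    sets: Dict[str, Set[str]] = {}
    for m, grp in hits.groupby("motif_id"):
        tf = motif_to_tf.get(m, m) if motif_to_tf else m
        sets.setdefault(tf, set()).update(grp["peak_id"])
    return sets


def build_prior(
    scores: pd.DataFrame,
    retained_tfs: Set[str],
    gene_panel: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binarise max-pooled scores into the genes x TFs constraint matrix C.

    C[g, tf] = 1 iff the aggregated score is positive and the TF survived
    presence filtering and deduplication; rows are restricted to the modelled
    expression gene panel when given.
    """
    missing = retained_tfs - set(scores.columns)
    if missing:
        raise ValueError(f"retained TFs missing from score matrix: {sorted(missing)}")
    tfs = sorted(retained_tfs)
    mat = (scores[tfs] > 0).astype(np.int8)
    if gene_panel is not None:
        mat = mat.reindex(list(gene_panel), fill_value=0)
        mat.index.name = "gene"
    empty = [tf for tf in tfs if mat[tf].sum() == 0]
    if empty:
        logger.warning("TFs retained with no targets in the prior: %s", empty)
    return mat


def build_prior_pipeline(
    atlas: PeakAtlas,
    hits: pd.DataFrame,
    annotation: GeneAnnotation,
    presence: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    min_presence: float = 0.5,
    jaccard_cutoff: float = 0.5,
    gene_panel: Sequence[str] | None = None,
    nearest_only: bool = False,
) -> pd.DataFrame:
    """End-to-end prior construction from raw inputs to the binary C."""
    assignment = assign_peaks_to_genes(atlas, annotation, flank, nearest_only=nearest_only)
    scores = aggregate_motif_scores(assignment, hits)
    retained = filter_tfs_by_expression(presence, threshold=min_presence)
    retained &= set(scores.columns)
    target_sets = tf_target_peak_sets(hits)
    removed = deduplicate_tfs_by_jaccard(
        {tf: target_sets.get(tf, set()) for tf in sorted(retained)}, cutoff=jaccard_cutoff
    )
    return build_prior(scores, retained - removed, gene_panel=gene_panel)


def write_prior_triplets(c: pd.DataFrame, path: str | Path) -> None:
    """Sparse triplet (gene, tf, 1) representation of the prior."""
    rows, cols = np.nonzero(c.to_numpy())
    pd.DataFrame(
        {"gene": c.index[rows], "tf": c.columns[cols], "value": 1}
    ).to_csv(path, sep="\t", index=False)
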