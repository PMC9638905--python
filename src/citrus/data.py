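"""Cohort container and TSV I/O.

A cohort bundles the three tumor-level inputs of the model: a binary somatic
alteration matrix (tumors x alteration genes), a log-scale expression matrix
(tumors x expression genes), and a cancer-type label per tumor.  Alterations
are stored per tumor as index lists (the sets {g_u}); the expression matrix
is dense.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd


@dataclass
class Cohort:
    tumor_ids: List[str]
    cancer_types: List[str]            # one label per tumor
    alteration_genes: List[str]        # vocabulary of alteration gene ids
    alterations: List[np.ndarray]      # per tumor, sorted indices into alteration_genes
    expression_genes: List[str]
    expression: np.ndarray             # tumors x expression genes, log scale

    def __post_init__(self) -> None:
        n = len(self.tumor_ids)
        if not (len(self.cancer_types) == n == len(self.alterations)):
            raise ValueError("tumor-level fields have inconsistent lengths")
        if self.expression.shape != (n, len(self.expression_genes)):
            raise ValueError("expression matrix shape does not match labels")

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    @property
    def cancer_type_names(self) -> List[str]:
        return sorted(set(self.cancer_types))

    def alteration_matrix(self) -> np.ndarray:
        """Dense binary tumors x alteration-genes matrix."""
        a = np.zeros((self.n_tumors, len(self.alteration_genes)), dtype=np.int8)
        for i, idx in enumerate(self.alterations):
            a[i, idx] = 1
        return a

    def subset(self, rows: Sequence[int]) -> "Cohort":
        rows = list(rows)
        return Cohort(
            tumor_ids=[self.tumor_ids[i] for i in rows],
            cancer_types=[self.cancer_types[i] for i in rows],
            alteration_genes=self.alteration_genes,
            alterations=[self.alterations[i] for i in rows],
            expression_genes=self.expression_genes,
            expression=self.expression[rows],
        )

    def carriers(self, gene: str) -> np.ndarray:
        """Row indices of tumors carrying an alteration in ``gene``."""
        g = self.alteration_genes.index(gene)
        return np.array([i for i, idx in enumerate(self.alterations) if g in idx], dtype=int)

    # ------------------------------------------------------------------ I/O
    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        alt = pd.DataFrame(
            self.alteration_matrix(), index=self.tumor_ids, columns=self.alteration_genes
        )
        alt.to_csv(out / "alterations.tsv", sep="\t")
        pd.DataFrame(
            self.expression, index=self.tumor_ids, columns=self.expression_genes
        ).to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
        pd.Series(self.cancer_types, index=self.tumor_ids, name="cancer_type").to_csv(
            out / "labels.tsv", sep="\t"
        )

    @classmethod
    def from_frames(
        cls, alterations: pd.DataFrame, expression: pd.DataFrame, labels: pd.Series
    ) -> "Cohort":
        if not alterations.index.equals(expression.index):
            expression = expression.loc[alterations.index]
        labels = labels.loc[alterations.index]
        alt = alterations.to_numpy()
        idx_lists = [np.flatnonzero(alt[i]).astype(int) for i in range(alt.shape[0])]
        return cls(
            tumor_ids=list(alterations.index.astype(str)),
            cancer_types=list(labels.astype(str)),
            alteration_genes=list(alterations.columns.astype(str)),
            alterations=idx_lists,
            expression_genes=list(expression.columns.astype(str)),
            expression=expression.to_numpy(dtype=float),
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        alt = pd.read_csv(path / "alterations.tsv", sep="\t", index_col=0)
        expr = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
        lab = pd.read_csv(path / "labels.tsv", sep="\t", index_col=0)["cancer_type"]
        return cls.from_frames(alt, expr, lab)


def read_prior(path: str | Path) -> pd.DataFrame:
    """Binary genes x TFs constraint matrix from TSV."""
    c = pd.read_csv(path, sep="\t", index_col=0)
    vals = c.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("prior matrix entries must be 0/1")
    return c.astype(np.int8)


def write_prior(c: pd.DataFrame, path: str | Path) -> None:
    c.to_csv(path, sep="\t")
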