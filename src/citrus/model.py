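"""Encoder-decoder network mapping somatic alteration profiles to expression.

Architecture
------------
Each altered gene ``g`` of a tumor is looked up in a gene-embedding table
(``e_g``, dimension ``M``).  A multi-head self-attention pool scores each
altered gene per head ``j``::

    beta[g, j] = theta_j . tanh(W0 @ e_g)
    alpha[., j] = softmax over the tumor's altered genes of beta[., j]

and the summed head weights ``alpha_g = sum_j alpha[g, j]`` combine the gene
embeddings with the cancer-type embedding ``e_s`` into the tumor embedding::

    e_t = e_s + sum_g alpha_g * e_g

The decoder infers bounded transcription-factor activities
``e_f = tanh(W_f e_t + b_f)`` and predicts expression through a sparse linear
readout ``yhat = W e_f + b_r`` in which ``W`` is constrained elementwise:
``W[i, j]`` may be non-zero only where the chromatin-derived prior
``C[i, j] = 1`` (genes x TFs) and is kept non-negative at all times by
projection after every optimizer step.

Everything is plain numpy; gradients are computed analytically by
:meth:`CitrusModel.backward` and checked against finite differences in the
test suite.  Dropout (training mode only) acts at three sites: whole embedded
gene slots after the input lookup, the tumor embedding, and the activated TF
layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import ModelConfig

NEG_INF = -1e9  # logit assigned to padded slots before softmax


@dataclass
class Batch:
    """Padded mini-batch of alteration profiles.

    ``gene_idx`` is (B, m_max) int, valid entries where ``mask`` is True;
    padded entries index 0 and are excluded from attention by the mask.
    """

    gene_idx: np.ndarray
    mask: np.ndarray
    cancer_idx: np.ndarray

    @classmethod
    def from_profiles(
        cls, alterations: Sequence[np.ndarray], cancer_idx: Sequence[int]
    ) -> "Batch":
        b = len(alterations)
        m = max((len(a) for a in alterations), default=0)
        m = max(m, 1)  # keep at least one (masked) slot for m=0 tumors
        gi = np.zeros((b, m), dtype=np.int64)
        mask = np.zeros((b, m), dtype=bool)
        for i, a in enumerate(alterations):
            # canonical (sorted) slot order: the profile is a set, and a fixed
            # order makes outputs bitwise invariant to input permutation
            gi[i, : len(a)] = np.sort(np.asarray(a, dtype=np.int64))
            mask[i, : len(a)] = True
        return cls(gene_idx=gi, mask=mask, cancer_idx=np.asarray(cancer_idx, dtype=np.int64))


@dataclass
class ForwardOutputs:
    alpha_heads: np.ndarray      # (B, m, h) per-head attention weights
    alpha: np.ndarray            # (B, m) summed across heads
    tumor_embedding: np.ndarray  # (B, M)
    tf_activities: np.ndarray    # (B, K)
    predicted: np.ndarray        # (B, N)
    cache: Optional[dict] = None


class CitrusModel:
    """Holds parameters, vocabularies and the prior mask; pure-numpy network."""

    WEIGHT_DECAY_PARAMS = ("E_gene", "E_cancer", "W0", "Theta", "W_f", "W")

    def __init__(
        self,
        alteration_genes: List[str],
        cancer_types: List[str],
        tf_ids: List[str],
        expression_genes: List[str],
        mask: np.ndarray,
        config: ModelConfig | None = None,
        seed: int = 0,
    ) -> None:
        cfg = config or ModelConfig()
        if mask.shape != (len(expression_genes), len(tf_ids)):
            raise ValueError("prior mask must be expression-genes x TFs")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("prior mask entries must be 0/1")
        self.config = cfg
        self.alteration_genes = list(alteration_genes)
        self.cancer_types = list(cancer_types)
        self.tf_ids = list(tf_ids)
        self.expression_genes = list(expression_genes)
        self.mask = mask.astype(np.float64)
        self._gene_index = {g: i for i, g in enumerate(self.alteration_genes)}
        self._cancer_index = {c: i for i, c in enumerate(self.cancer_types)}
        self.params = self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------ parameters
    def _init_params(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        cfg = self.config
        m_dim, a_dim, h = cfg.embedding_dim, cfg.attention_size, cfg.attention_heads
        n_genes = len(self.expression_genes)
        k_tf = len(self.tf_ids)

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        params = {
            # embeddings: random normal; a hook exists to load pre-trained tables
            "E_gene": rng.normal(0.0, 0.05, size=(len(self.alteration_genes), m_dim)),
            "E_cancer": rng.normal(0.0, 0.05, size=(len(self.cancer_types), m_dim)),
            "W0": glorot((a_dim, m_dim)),
            "Theta": glorot((h, a_dim)),
            "W_f": glorot((k_tf, m_dim)),
            "b_f": np.zeros(k_tf),
            # decoder starts small, non-negative, and inside the mask
            "W": rng.uniform(0.0, 1e-2, size=(n_genes, k_tf)) * self.mask,
            "b_r": np.zeros(n_genes),
        }
        return params

    def load_gene_embeddings(self, table: Dict[str, np.ndarray]) -> None:
        """Overwrite rows of the gene-embedding table (e.g. externally trained)."""
        for gene, vec in table.items():
            if gene in self._gene_index:
                if len(vec) != self.config.embedding_dim:
                    raise ValueError("embedding dimension mismatch")
                self.params["E_gene"][self._gene_index[gene]] = vec

    def project_decoder(self) -> None:
        """Enforce the hard constraints: W >= 0 and W = 0 outside the prior."""
        np.maximum(self.params["W"], 0.0, out=self.params["W"])
        self.params["W"] *= self.mask

    def check_decoder_constraints(self) -> None:
        w = self.params["W"]
        if (np.abs(w) * (1.0 - self.mask)).max(initial=0.0) != 0.0:
            raise RuntimeError("decoder weight outside the prior mask")
        if w.min(initial=0.0) < 0.0:
            raise RuntimeError("negative decoder weight")

    # --------------------------------------------------------------- forward
    def encode_batch(
        self, alterations: Sequence[np.ndarray], cancer_types: Sequence[str], strict: bool = True
    ) -> Batch:
        idx = [self._cancer_index.get(c) for c in cancer_types]
        if any(i is None for i in idx):
            unknown = sorted({c for c in cancer_types if c not in self._cancer_index})
            raise KeyError(
                f"unknown cancer type(s) {unknown}; known: {self.cancer_types}"
            )
        return Batch.from_profiles(alterations, idx)

    def forward(
        self,
        batch: Batch,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        keep_cache: bool = False,
    ) -> ForwardOutputs:
        p = self.params
        cfg = self.config
        h = cfg.attention_heads
        drop = cfg.dropout if training else 0.0
        if training and drop > 0.0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")

        gi, mask, ci = batch.gene_idx, batch.mask, batch.cancer_idx
        B, m = gi.shape
        eg = p["E_gene"][gi]  # (B, m, M)

        # input dropout: drop whole embedded gene slots (inverted scaling)
        if drop > 0.0:
            d1 = (rng.random((B, m, 1)) >= drop) / (1.0 - drop)
            eg = eg * d1
        else:
            d1 = None

        u = np.tanh(eg @ p["W0"].T)            # (B, m, A)
        beta = u @ p["Theta"].T                # (B, m, h)
        beta = np.where(mask[:, :, None], beta, NEG_INF)
        beta_shift = beta - beta.max(axis=1, keepdims=True)
        expb = np.exp(beta_shift) * mask[:, :, None]
        denom = expb.sum(axis=1, keepdims=True)
        # tumors with no alterations get all-zero attention
        alpha_heads = np.divide(expb, denom, out=np.zeros_like(expb), where=denom > 0)
        alpha = alpha_heads.sum(axis=2)        # (B, m)

        e_t = p["E_cancer"][ci] + np.einsum("bm,bmM->bM", alpha, eg)
        if drop > 0.0:
            d2 = (rng.random(e_t.shape) >= drop) / (1.0 - drop)
            e_t_d = e_t * d2
        else:
            d2, e_t_d = None, e_t

        z = e_t_d @ p["W_f"].T + p["b_f"]
        if cfg.activation == "tanh":
            e_f = np.tanh(z)
        else:
            e_f = np.maximum(z, 0.0)
        if drop > 0.0:
            d3 = (rng.random(e_f.shape) >= drop) / (1.0 - drop)
            e_f_d = e_f * d3
        else:
            d3, e_f_d = None, e_f

        yhat = e_f_d @ p["W"].T + p["b_r"]

        cache = None
        if keep_cache:
            cache = dict(
                batch=batch, eg=eg, u=u, alpha_heads=alpha_heads, alpha=alpha,
                e_t=e_t, e_t_d=e_t_d, e_f=e_f, e_f_d=e_f_d, z=z,
                d1=d1, d2=d2, d3=d3,
            )
        return ForwardOutputs(alpha_heads, alpha, e_t, e_f, yhat, cache)

    def loss(self, y: np.ndarray, yhat: np.ndarray) -> float:
        if np.isnan(y).any() or np.isnan(yhat).any():
            raise ValueError("NaN in loss inputs")
        return float(np.mean((y - yhat) ** 2))

    # -------------------------------------------------------------- backward
    def backward(self, out: ForwardOutputs, y: np.ndarray) -> Dict[str, np.ndarray]:
        """Analytic gradients of mean-squared error w.r.t. all parameters."""
        c = out.cache
        if c is None:
            raise ValueError("forward must be called with keep_cache=True")
        p = self.params
        batch: Batch = c["batch"]
        gi, mask, ci = batch.gene_idx, batch.mask, batch.cancer_idx
        B, N = y.shape

        dyhat = 2.0 * (out.predicted - y) / (B * N)

        grads: Dict[str, np.ndarray] = {}
        grads["W"] = dyhat.T @ c["e_f_d"]
        grads["b_r"] = dyhat.sum(axis=0)

        de_f_d = dyhat @ p["W"]
        de_f = de_f_d * c["d3"] if c["d3"] is not None else de_f_d
        if self.config.activation == "tanh":
            dz = de_f * (1.0 - c["e_f"] ** 2)
        else:
            dz = de_f * (c["z"] > 0)

        grads["W_f"] = dz.T @ c["e_t_d"]
        grads["b_f"] = dz.sum(axis=0)
        de_t_d = dz @ p["W_f"]
        de_t = de_t_d * c["d2"] if c["d2"] is not None else de_t_d

        grads["E_cancer"] = np.zeros_like(p["E_cancer"])
        np.add.at(grads["E_cancer"], ci, de_t)

        eg, u, alpha_h, alpha = c["eg"], c["u"], c["alpha_heads"], c["alpha"]
        dalpha = np.einsum("bM,bmM->bm", de_t, eg)                # (B, m)
        deg = alpha[:, :, None] * de_t[:, None, :]                # via weighted sum

        # softmax backward per head; padded slots have alpha == 0 so drop out
        dalpha_h = dalpha[:, :, None]                             # broadcast to heads
        inner = (alpha_h * dalpha_h).sum(axis=1, keepdims=True)
        dbeta = alpha_h * (dalpha_h - inner)                      # (B, m, h)

        grads["Theta"] = np.einsum("bmh,bma->ha", dbeta, u)
        du = dbeta @ p["Theta"]                                   # (B, m, A)
        dpre = du * (1.0 - u ** 2)
        dpre *= mask[:, :, None]
        grads["W0"] = np.einsum("bma,bmM->aM", dpre, eg)
        deg += dpre @ p["W0"]

        if c["d1"] is not None:
            deg = deg * c["d1"]
        deg *= mask[:, :, None]
        grads["E_gene"] = np.zeros_like(p["E_gene"])
        np.add.at(grads["E_gene"], gi.ravel(), deg.reshape(-1, deg.shape[-1]))

        return grads

    # --------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        meta = dict(
            alteration_genes=np.array(self.alteration_genes),
            cancer_types=np.array(self.cancer_types),
            tf_ids=np.array(self.tf_ids),
            expression_genes=np.array(self.expression_genes),
            mask=self.mask,
            config=np.array(
                [
                    self.config.embedding_dim, self.config.attention_size,
                    self.config.attention_heads, self.config.max_alterations,
                ]
            ),
            dropout=np.array([self.config.dropout]),
            activation=np.array([self.config.activation]),
        )
        np.savez(path, **{f"param_{k}": v for k, v in self.params.items()}, **meta)

    @classmethod
    def load(cls, path: str | Path) -> "CitrusModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(
                embedding_dim=int(z["config"][0]),
                attention_size=int(z["config"][1]),
                attention_heads=int(z["config"][2]),
                max_alterations=int(z["config"][3]),
                dropout=float(z["dropout"][0]),
                activation=str(z["activation"][0]),
            )
            model = cls(
                alteration_genes=[str(g) for g in z["alteration_genes"]],
                cancer_types=[str(c) for c in z["cancer_types"]],
                tf_ids=[str(t) for t in z["tf_ids"]],
                expression_genes=[str(g) for g in z["expression_genes"]],
                mask=z["mask"],
                config=cfg,
            )
            for k in model.params:
                model.params[k] = z[f"param_{k}"]
        return model

    def clone_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()
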