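# citrus

Chromatin-informed inference of transcription-factor (TF) activities from
tumor somatic-alteration profiles.

Cancer genomes carry somatic mutations and copy-number events that rewire
signaling and, downstream, transcriptional programs. `citrus` implements a
partially interpretable encoder–decoder network that links the two: the
binary alteration profile of a tumor is encoded — through a multi-head
self-attention pool over altered-gene embeddings plus a cancer-type
embedding — into a tumor embedding, decoded into bounded per-TF activity
scores, and finally mapped to genome-wide expression through a sparse linear
layer whose support is constrained to TF→target edges with motif evidence in
accessible chromatin (ATAC-seq peaks near each gene). The TF layer is the
interpretable core: it yields patient-specific TF activities, attention
weights over somatic alterations, and — via in silico knockouts — estimates
of which TFs each alteration dysregulates.

## Model

For a tumor with altered genes $\{g_u\}_{u=1}^m$ and cancer type $s$:

$$\beta_{g,j} = \theta_j^{\top}\tanh(W_0 e_g), \qquad
\alpha_{\cdot,j} = \mathrm{softmax}(\beta_{\cdot,j}), \qquad
\alpha_g = \sum_{j=1}^{h} \alpha_{g,j}$$

$$e_t = e_s + \sum_{g} \alpha_g e_g, \qquad
e_f = \tanh(W_f e_t + b_f), \qquad
\hat{y} = W e_f + b_r$$

with the decoder constrained elementwise by the binary chromatin prior
$C \in \{0,1\}^{k\times l}$ (genes × TFs): $W_{ij} \ge 0$ and $W_{ij} = 0$
wherever $C_{ij} = 0$, enforced exactly by projection after every optimizer
step. Training minimises MSE against per-gene z-scored log expression with
Adam (lr 1e-3, weight decay 1e-5, batch 100), per-epoch validation, early
stopping (patience 30 evaluations after a 180-evaluation warm-up at full
scale), and TF-activity ensembling over 10 independently initialised runs.

The package also provides:

- **prior builder** — peaks→gene assignment (transcription unit ± 100 kb),
  motif-score max-pooling, TF expression-presence filtering (≥50% of samples
  in ≥1 tumor type), Jaccard deduplication of redundant motifs (> 0.5), and
  binarisation into `C`;
- **interpretation** — per-tumor Spearman evaluation, attention aggregation
  and driver-enrichment Fisher tests, in silico knockout t-tests with BH
  correction, TF/tumor-type association, k-means subtype discovery, and
  signed alteration–subtype association scores;
- **affinity regression** — the bilinear baseline $DWP^{\top}\!\sim Y$
  solved in factored (Kronecker-free) ridge form;
- **synthetic cohorts** — generators with planted drivers, known TF
  activities and a planted chromatin prior, so every stage is testable
  without external downloads.

## Worked example

```python
import numpy as np
from citrus import (SimConfig, simulate_cohort, ModelConfig, TrainConfig,
                    stratified_split, train_ensemble)
from citrus.interpret import insilico_knockout, spearman_per_tumor

cohort, prior, truth = simulate_cohort(SimConfig())   # 600 tumors, 30 TFs
labels = dict(zip(cohort.tumor_ids, cohort.cancer_types))
plan = stratified_split(labels, 0.2, seed=7)
idx = {t: i for i, t in enumerate(cohort.tumor_ids)}
pool = cohort.subset([idx[t] for t in plan.train_ids])
test = cohort.subset([idx[t] for t in plan.test_ids])

runs = train_ensemble(pool, prior,
                      ModelConfig(embedding_dim=32, attention_size=16,
                                  attention_heads=4, max_alterations=100),
                      TrainConfig(batch_size=100, patience=20,
                                  warmup_evals=30, max_iterations=200, seed=7),
                      n_runs=10)
models = [m for m, _, _ in runs]
scaler = runs[0][2]
preds = [m.forward(m.encode_batch(test.alterations, test.cancer_types)).predicted
         for m in models]
_, rho = spearman_per_tumor(scaler.transform(test.expression), np.mean(preds, axis=0))
print(f"held-out mean Spearman rho = {rho:.3f}")

ko = insilico_knockout(models, cohort, truth.driver_genes[0])
print(ko.nsmallest(3, "fdr")[["tf", "t", "fdr", "mean_difference"]])
```

Output from this exact script (seed 7):

```
held-out mean Spearman rho = 0.858
      tf          t           fdr  mean_difference
0   TF00  35.333756  2.278342e-93         1.189730
26  TF26  -7.158398  1.581683e-10        -0.509284
24  TF24  -3.359355  9.064636e-03        -0.310292
```

The held-out correlation says the model recovers most of the rank structure
of a test tumor's expression profile from its alterations and cancer type
alone. The knockout table's three most significant TFs for the first
planted driver (`AG577`, true effects +1.5 on TF00, −1.5 on TF24 and TF26)
are exactly its three true targets, with matching shift directions.

A `citrus` command-line interface mirrors the library
(`citrus simulate | build-prior | train | ensemble | evaluate | attention |
knockout | associate-tf | subtype | associate-alteration | affreg`).

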