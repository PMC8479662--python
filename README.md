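# bifuse

Deep bilinear fusion of genomic and pathological-image feature profiles for
5-year cancer prognosis classification.

## The problem

Given two per-patient feature vectors — a gene-expression profile `g` and a
histology-derived image profile `p`, each reduced to `L = 32` informative
features — classify the patient as a **shorter-term survivor** (death within
5 years, label 1, poor prognosis) or a **longer-term survivor** (label 0).
Direct concatenation of the two vectors ignores multiplicative interactions:
gene effects that only matter in a particular morphological context, and
co-regulation within a modality. `bifuse` encodes those interactions
explicitly with bilinear (outer-product) feature encoders and fuses them
with the raw vectors.

## The model

One cross-modality encoder and two within-modality encoders, each a dense
ReLU layer over a flattened outer product:

    f_inter_k   = ReLU( Σᵢ Σⱼ w_ijk g_i p_j + b_k )      k = 1..K,  K = 20
    f_intra_g_m = ReLU( Σᵢ Σⱼ w_ijm g_i g_j + b_m )      m = 1..M,  M = 20
    f_intra_p_m = ReLU( Σᵢ Σⱼ w_ijm p_i p_j + b_m )

fused as

    h = (g ⊕ f_intra_g) ⊕ f_inter ⊕ (p ⊕ f_intra_p)      |h| = 2L + K + 2M = 124

and classified by a 4-layer dense network (500/256/128/32, ReLU, dropout
0.3/0.3/0.1/0.1) with a two-unit softmax head. Training: binary
cross-entropy, Adam at 4e-4, mini-batches of 16, 150 epochs, fully seeded.
The network (forward, backprop, Adam) is implemented directly in numpy;
a literal double-sum form of each encoder serves as a numerical oracle in
the tests. Seven wiring variants (`baseline_g`, `intra_g`, `baseline_p`,
`intra_p`, `baseline_gp`, `inter_only`, `full_fusion`) support ablation.

The package also implements the surrounding protocol: 5-year label
derivation with explicit exclusion of early-censored patients, NA filtering
(> 10% missing), z-scoring, ternary discretization at z = ±1,
information-gain feature ranking with top-32 selection, tile-density
scoring for histology patches, stratified 5-fold cross-validation with
pooled out-of-fold scoring, ROC/AUC, Harrell's C-index, fixed-specificity
operating points (Sp = 0.90, 0.95) and Kaplan-Meier / log-rank risk-group
comparison. A seeded synthetic-cohort generator with controllable within-
and cross-modality interaction signal and censored proportional-hazards
survival makes every stage testable without external data. See
`docs/methods.md` for the full account.

## Worked example

Simulate a 200-patient cohort with strong cross-modality signal, run the
pooled 5-fold protocol on the full fusion model, and inspect the metrics:

```sh
cat > sim.yaml <<'YAML'
simulate:
  n: 200
  gamma_intra: 0.3
  gamma_inter: 0.5
YAML
bifuse simulate --config sim.yaml --seed 7 --out data/
bifuse cv --genomic data/genomic.tsv --image data/image.tsv \
          --survival data/survival.tsv --variant full_fusion \
          --seed 7 --out run/
```

which logs

```
[bifuse] simulated cohort n=200 -> data
[bifuse] derived labels; excluded 10 censored-early patients
[bifuse] cv variant=full_fusion pooled AUC=0.623 C-index=0.573 -> run
```

`run/scores.tsv` holds one out-of-fold score per labelled patient
(`patient_id, fold, score, label`); `run/metrics_pooled.json` the pooled
metrics. The pooled AUC of 0.623 says that a randomly chosen shorter-term
survivor outranks a randomly chosen longer-term survivor 62% of the time;
the C-index of 0.573 measures the same ranking quality against the censored
survival times themselves; and 10 of the 200 simulated patients were
censored before the 60-month horizon, so their 5-year status is unknown and
they are excluded from classification (never silently). At this cohort size
the network recovers only part of the simulated signal — scoring patients
by the generator's own risk (the ceiling any method could reach) gives AUC
0.89 on the same cohort, and performance climbs steadily with n.
The `operating_points` block reports sensitivity/accuracy/precision/F1 at
the thresholds where specificity first reaches 0.90 and 0.95, and
`logrank_p` tests the survival separation of the median-split risk groups.

Python API equivalent:

```python
from bifuse.simulate import strong_signal_config, generate
from bifuse.preprocess import derive_labels
from bifuse.io import make_folds
from bifuse.network import ModelConfig
from bifuse.evaluation import cross_validate

cohort = generate(strong_signal_config(n=200, seed=7))
records = derive_labels(cohort.records).records
ids = [r.patient_id for r in records]
pooled, report, per_fold = cross_validate(
    cohort.g_matrix.subset_samples(ids),
    cohort.p_matrix.subset_samples(ids),
    records,
    ModelConfig(variant="full_fusion", seed=7),
    make_folds(records, k=5, seed=7),
)
print(report.auc, report.c_index)
```

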