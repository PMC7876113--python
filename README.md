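# pairaudit

Systematic bias auditing for **paired-input biological classifiers** —
protein–protein interaction (PPI) predictors, drug–target binding
classifiers, and any model whose instances are pairs of entities with a
binary relationship label.

Sequence-based pair classifiers often report excellent in-network test AUC
yet collapse on independent data. A common culprit is **node-degree
(differential-recurrence) leakage**: when a protein occurs more often among
positive training pairs than negative ones, a model can simply learn to
recognize that protein and predict "interacting", without using any
biology. pairaudit packages a four-module audit that makes this failure
mode measurable and removable:

1. **Benchmark** — per-round test AUC of the model under audit (10
   train/validation/test rounds, in-network or out-of-network testing).
2. **Generalizability** — the same trained models scored on an independent
   dataset under the same membership mode; a large gap flags
   dataset-specific shortcuts.
3. **Identification** — three auditors isolate the shortcut:
   - *feature auditor*: retrain with every sequence replaced by a random
     one; surviving performance cannot come from the sequences;
   - *node-degree auditor*: a small classifier on the 4-vector
     [A⁺, A⁻, B⁺, B⁻] of training node degrees;
   - *recurrence auditor*: no learner at all — each test pair (A, B) is
     scored by

     &nbsp;&nbsp;&nbsp;&nbsp;Score(A, B) = (A⁺ + B⁺) / (A⁺ + B⁺ + A⁻ + B⁻)

     where A⁺/A⁻ are A's positive/negative node degrees in the training
     set. If four integers replicate your model, your model is reading
     degrees.
4. **Elimination** — *node balancing*: negatives are re-selected so every
   training protein has equal positive and negative degree, removing the
   differential-recurrence signal; combined with feature masking, a model
   that was only reading degrees falls to AUC 0.5.

The library ships sequence feature extractors (3-mer composition, conjoint
triad, physicochemical autocovariance), the pairwise min-product kernel

&nbsp;&nbsp;&nbsp;&nbsp;K((A,B),(C,D)) = exp(−γ · min(‖A−C‖²·‖B−D‖², ‖A−D‖²·‖B−C‖²)),

two bundled learners behind a common adapter contract (a kernel SVM and a
random forest), 10-round in/out-of-network splitters, and a synthetic-data
generator that plants node-degree bias and genuine motif signal
independently — so every auditor verdict can be checked against a known
ground truth.

## Worked example

Audit a synthetic dataset in which interactions are driven *only* by hub
bias (no sequence signal at all):

```yaml
# pure_bias.yaml
fixture: pure_bias
seed: 1
grid:
  - n_estimators: 30
```

```bash
pairaudit audit --config pure_bias.yaml -o runs/pure_bias
```

Output (~5 minutes on one CPU):

```
Benchmark mean AUC 0.65. Masked-feature AUC 0.66 stays above chance:
performance does not require the real sequences. Degree-only auditors
replicate the model, implicating node-degree (differential-recurrence)
bias. Node-balanced debiasing drops the masked model to chance:
node-degree bias drives performance and balancing removes it.
benchmark: mean AUC 0.651 (reference 0.500, delta +0.151) -> inconclusive
feature_masking: mean AUC 0.656 (reference 0.500, delta +0.156) -> bias_indicated
node_degree: mean AUC 0.629 (reference 0.651, delta -0.022) -> bias_indicated
recurrence: mean AUC 0.659 (reference 0.651, delta +0.008) -> bias_indicated
debias_masked: mean AUC 0.503 (reference 0.500, delta +0.003) -> no_bias_indicated
```

Reading the chain: the model beats chance (benchmark 0.65) — but masking
the sequences changes nothing (0.66), a degree-only classifier and the
closed-form recurrence score replicate it (0.63 / 0.66), and after node
balancing plus masking it drops to chance (0.50). Verdict: the
performance was node-degree bias, and balancing removes it. On the
`pure_signal` fixture the chain inverts: the benchmark reaches 0.81,
masking collapses it to ≈0.54, and node-balanced training without
masking keeps it at ≈0.82 — genuine sequence signal survives debiasing.

The same machinery runs on real data via FASTA + pair TSV inputs
(`pairaudit audit --fasta p.fasta --pairs pairs.tsv ...`), with affinity
columns thresholded at pK_d = 6.3 (500 nM) by default, and YAML run
configs (`--config run.yaml`). `pairaudit simulate` writes synthetic
datasets; `pairaudit split` materializes the 10-round splits;
`pairaudit report` renders a saved report.

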