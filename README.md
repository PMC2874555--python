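# ptmnet

Prediction of post-translational modification (PTM) sites in protein
sequences from sequence alone, for proteome-scale screening.

Given a protein, every candidate site is represented by the 9-residue
window centered on it. Each residue is described by ten physicochemical
property scales from the AAindex database (accessibility information
values, side-chain hydrophobicity and interaction parameters, hydration
number, side-chain volume, ...), so a window is a point
**x** ∈ ℝ⁹⁰. A feed-forward sigmoid multilayer perceptron with one
hidden layer and two output neurons (positive/negative class) maps the
window to responses R₁, R₂ ∈ (0, 1):

    a = σ(W₁ᵀx + b₁),   R = σ(W₂ᵀa + b₂),   σ(z) = 1 / (1 + e⁻ᶻ)

trained by per-sample back-propagation with momentum,

    Δw(t) = −η ∂E/∂w + δ Δw(t−1),   E = ½ Σ (y − t)²,

with η = δ = 0.8. The decision is the argmax class and its confidence
the normalized response C_j = R_j / (R₁ + R₂). Evaluation uses random
sub-sampling validation (positives split 4:1 into train/test, five
negatives per positive, three independent splits, metrics averaged),
and overfitting is controlled by *checkpoint selection*: after every
epoch the network is scored on the held-out split and the best weights
so far are retained. For each PTM type three networks are kept — the
checkpoints maximizing ROC **AUC**, **recall** and **precision**
respectively, swept over hidden sizes H ∈ {2, 4, ..., 20} — so users
choose the operating characteristic they need, or combine the three as
a consensus.

See `docs/methods.md` for the full model description, parameter
defaults and limitations.

## Worked example

Train a classifier for a basophilic kinase-like motif (R-R-x-S-L
context) on synthetic labeled windows, inspect the averaged test
metrics, and classify new windows:

```python
from ptmnet import PTMSiteModel, SplitSpec, TrainConfig
from ptmnet.synthetic import default_kinase_motif, generate_dataset

ds = generate_dataset(default_kinase_motif(0.9), n_pos=100, neg_per_pos=5,
                      seed=42, ptm_type="Phosphoserine/PKA-like")
model = PTMSiteModel(ds, split_spec=SplitSpec(n_splits=3, seed=42))
results = model.fit(config=TrainConfig(epochs=60, seed=42), h_values=[4, 8, 12])
print(results.summary())
```

```
PTM site classifier — criterion-optimized MLP triplet
====================================================================
PTM type:        Phosphoserine/PKA-like
Windows:         100 positive / 500 negative (9-mers)
Encoding:        90-dimensional (10 scales x 9 positions, minmax)
Splits:          3 random sub-samples, 80% of positives to training

Test metrics averaged over splits:
                tp       fp       tn       fn   error  recall  precision     tpr     fpr  specificity  accuracy     mcc     auc
criterion
auc        14.0000   3.6667  96.3333   6.0000  0.0806  0.7000     0.8547  0.7000  0.0367       0.9633    0.9194  0.6828  0.9797
recall     19.6667  34.6667  65.3333   0.3333  0.2917  0.9833     0.4421  0.9833  0.3467       0.6533    0.7083  0.5263  0.9645
precision   9.6667   0.3333  99.6667  10.3333  0.0889  0.4833     0.9744  0.4833  0.0033       0.9967    0.9111  0.6261  0.9655
====================================================================
```

The three rows show the intended trade-off: the recall-optimized
network finds 98% of true sites at the cost of false alarms, the
precision-optimized one is right 97% of the time it calls a site, and
the AUC-optimized one balances both. Classifying two windows — one
matching the motif context, one not:

```python
for rec in results.predict(["ARRASLYSG", "LCLYTHIGR"]):
    print(rec.render())
```

```
ARRASLYSG 1 0.9014
LCLYTHIGR 0 0.9912
```

Each line is `SEGMENT DECISION CONFIDENCE`: decision 1 marks a
potential modified site, and the confidence (four decimals) belongs to
the winning class.

The same pipeline is available from the shell in two phases —
dissect FASTA into windows, then classify them:

```bash
ptmnet train --data segments.tsv --ptm-type Phosphoserine/PKA-like \
             --hidden 2:20:2 --splits 3 --seed 1 --out models/
ptmnet generate --fasta proteome.fa --out windows.txt
ptmnet predict --windows windows.txt --models models/ \
               --ptm-type Phosphoserine/PKA-like --optimization auc \
               --out predictions.txt
```

`ptmnet simulate dataset` / `ptmnet simulate proteome` generate
synthetic motif data for experimentation.

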