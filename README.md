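# scemila

Attention-based multiple instance learning (MIL) for single-cell
cytomorphology: classify a patient's bag of blood-smear white-cell images
into one of four genetic AML subtypes (PML::RARA, NPM1, CBFB::MYH11,
RUNX1::RUNX1T1) or healthy control, and explain the decision cell by cell.

The package is aimed at computational hematology and biomedical-imaging
researchers who have per-patient collections of single-cell images (or
precomputed per-cell feature vectors) with only patient-level diagnoses,
and who need both a bag-level classifier and a quantitative account of
*which cells* the classifier relied on.

## The model

A patient is a bag B = {x_1, …, x_N} of instance feature vectors
x_k ∈ R^d supervised by one label y. The model is

    h_k  = f_emb(x_k; γ)                    instance embedding (ReLU MLP)
    e_ik = w_i^T tanh(V_i h_k)              raw attention score of cell k for class i
    α_ik = exp(e_ik) / Σ_j exp(e_ij)        softmax over the bag, per class
    z_i  = Σ_k α_ik h_k                     class-wise attention pooling
    p    = softmax(u_i^T z_i + c_i)         per-class linear heads

The class-wise attention matrix A = (α_ik) gives every class its own,
independently normalized attention distribution over the bag, so attention
values never compete across classes; the row of the predicted class,
α = A_ŷ, is the per-cell explanation. Training minimizes the bag-level
categorical cross-entropy with Adam, one step per bag, with early stopping
on validation loss, under patient-level stratified 5-fold cross-validation
(60/20/20). Because a singleton bag has α = [1], the same fitted model
classifies individual cells ("deconvolution" of the smear's composition).

Around the model the package provides: a QC cascade (Canny edge-sum blur
filter at threshold 5×10⁴, the 20% blast-percentage rule for AML samples,
a manual-exclusion hook, consort-style accounting); the feature-extraction
contract (pre-pooling activations of a supervised single-cell classifier;
a ResNet34 recipe at d = 12,800 plus a trainable tiny CNN); explainability
analyses (attention ranking, annotation-quartile concordance, per-class
representative cells, subsample-size robustness); a UMAP fit-on-one-fold /
transform-the-rest embedding stage; and a synthetic-data generator that
plants a minority of class-signature cells among shared background so every
stage is testable without clinical data. See `docs/methods.md`.

## Worked example

```python
import numpy as np
from scemila import SyntheticCohortSpec, generate_feature_bags, AttentionMIL, explain
from scemila.mil import desk_scale_config

spec = SyntheticCohortSpec(bags_per_class=10, bag_size_range=(60, 150),
                           feature_dim=32, seed=7)
bags = generate_feature_bags(spec)          # 50 patients, 20% planted cells
res = AttentionMIL(bags, desk_scale_config(seed=7)).fit()
print(res.summary())

bag = bags[0]
pred = res.predict(bag)
print("predicted:", pred.predicted_label, "p =", np.round(pred.probabilities, 3))
ranked = explain.rank_by_attention(pred, bag.cell_ids)
top10 = ranked.tail(10)["bag_index"].to_numpy()
print("planted among top-10 attention cells:", int(bag.planted[top10].sum()), "/ 10")
```

prints

```
Attention-MIL results
======================================================
classes:            PML::RARA, NPM1, CBFB::MYH11, RUNX1::RUNX1T1, control
bags (train/val):   40/10
feature dim d:      32
embed dim L:        128   attention dim: 64
parameters:         62661
epochs run:         30   best epoch: 29
best val loss:      0.0423
train accuracy:     1.000
predicted: PML::RARA p = [0.999 0.001 0.    0.    0.   ]
planted among top-10 attention cells: 10 / 10
```

The model recovers the bag label and its predicted-class attention row
concentrates on exactly the cells that carry the class signature (the bag
is only ~19% planted): the mechanism by which a smear's diagnosis can be
traced back to its few pathognomonic cells.

A command-line interface mirrors the library:
`scemila simulate | filter | train | explain | embed`.

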