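# explspace

Latent subtype discovery by clustering in the **explanation space** of a
diagnostic classifier.

Many diseases that present as a single diagnosis are mixtures of distinct
subtypes. Finding those subtypes by clustering raw biomedical features
(voxels, gene expression, imaging phenotypes) is hard: the dimensions are
many, the signal-to-noise ratio is low, and the dominant directions of
variance often have nothing to do with the disease. `explspace` implements an
alternative: train a binary *diagnostic* classifier (healthy vs. diseased),
compute an instance-wise Shapley attribution vector for every subject, and
cluster **those attribution vectors** instead of the raw features. The
attribution vector of a subject captures *why* the model considers them
diseased; subjects who are diseased for different reasons — different latent
subtypes — separate sharply in this space even when they are
indistinguishable in the original one.

## What it computes

For a forest `F` of probability-averaging decision trees and an instance
`x ∈ R^p`, the Shapley value of feature `j` is

    φ_j(x) = Σ_{S ⊆ {1..p}\{j}}  |S|! (p−|S|−1)! / p!  · [ v(S ∪ {j}) − v(S) ]

where `v(S)` is the conditional expectation of the forest output given the
features in `S`, estimated path-dependently: at a split on a feature in `S`
the tree follows `x`; at a split on a feature outside `S` it averages the two
branches weighted by their training covers. The map `x ↦ φ(x)` embeds the
data into an explanation space of the same dimensionality `p`, with the exact
local-accuracy identity `base_value + Σ_j φ_j(x) = P̂(y=1|x)`.

The package provides, from scratch:

* a hypercube benchmark generator (one Gaussian cluster per class on the
  vertices of a hypercube buried among noise features),
* a deterministic random-forest learner in an array interchange format
  (JSON-serialisable; covers and per-node class fractions included),
* exact polynomial-time path-dependent Shapley attribution (verified against
  the brute-force subset enumeration),
* the cluster validity indices Davies–Bouldin, Calinski–Harabasz and
  Silhouette, and Adjusted Mutual Information with the exact hypergeometric
  expected-MI correction,
* the end-to-end protocol: superset split → (optional) inverse-frequency
  balancing → forest → explanations → {feature, explanation} ×
  {none, PCA, Isomap, t-SNE} → Ward clustering → metric grid.

## Worked example

Generate the default benchmark (1600 instances, 16 classes on a 4-D
hypercube, 50 features of which 42 are pure noise), then run the protocol
with classes 0–2 as the positive superset:

```bash
explspace generate -o demo.csv
explspace run --data demo.csv --superset 0,1,2 --reducers none,tsne --seeds 0 -o demo_report
```

which prints:

```
wrote 1600 x 50 dataset to demo.csv
report written to demo_report
none    feature     DB=    8.32 CH=      3.04 Sil=  0.00 AMI= 0.01
none    explanation DB=    1.07 CH=    176.19 Sil=  0.38 AMI= 0.55
tsne    feature     DB=   31.42 CH=      0.41 Sil= -0.03 AMI=-0.01
tsne    explanation DB=    0.47 CH=    783.40 Sil=  0.65 AMI= 0.70
```

Read each row as one representation of the 300 positive-superset instances,
scored against their three ground-truth subclasses. In raw feature space the
subclasses are essentially invisible — near-zero silhouette and an adjusted
mutual information of 0.01 between the Ward clustering and the truth, no
better than chance, and t-SNE cannot rescue it. In explanation space the same
instances form tight, well-separated clusters (Davies–Bouldin drops from 8.3
to 1.1, Calinski–Harabasz rises from 3 to 176) and the clustering recovers
over half of the subclass information (AMI 0.55, rising to 0.70 after
t-SNE). The `demo_report/` directory contains the JSON report, long/wide
metric CSVs and 2-D embedding CSVs ready for scatter plotting.

The same protocol applies to any labelled CSV via `--data`/`--label-col`;
`explspace explain` writes the raw attribution matrix for use in downstream
tools.

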