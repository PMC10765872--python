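# Methods

## Featurization

Structural features are radius-3 Morgan (circular) fingerprints hashed
to 1024 bits with binary presence semantics; chirality is ignored, which
makes fingerprints reproducible across stereo-annotation conventions.
For every set bit the generator's bit-info output is converted into a
list of environments — (center atom, radius, canonical fragment SMILES,
atom indices) — and kept alongside the vector. One bit may carry several
distinct environments (hash collision); all are retained and reported.
Fragment notation is the canonical SMILES of the environment subgraph
with aromatic atoms lowercase; attachment context is not annotated, so a
fragment such as `cc` is a subgraph, not a standalone molecule, and
round-trips only under non-sanitizing parsing.

The eight physicochemical descriptors are computed with RDKit: MW
(g/mol), ALOGP (Crippen log P, unitless), HBD, HBA (counts), PSA
(topological polar surface area, Å²), ROTB, AROM (counts), and ALERT —
the number of matched structural-alert queries from a configurable
SMARTS list. No canonical alert list exists for this endpoint; the
shipped default contains nine hepatotoxicity-linked motifs (hydrazine,
acyl hydrazide, aniline, nitroaromatic, thiophene, quinone, alkyl
halide, Michael acceptor, aromatic N-oxide) and callers may supply their
own. Descriptors are standardized to zero mean and unit (population)
variance; statistics are estimated on the training partition only and
reused for held-out data to avoid information leakage. Zero-variance
columns are mapped to zeros with a logged warning.

The final representation concatenates the 1024 structural bits
(unscaled) with the 8 scaled descriptors, in that order, for 1032
features.

## Label harmonization

Each source corpus has its own class vocabulary; only classes clearly
positive or clearly negative for liver injury are mapped to 1/0, and
intermediate or ambiguous classes are excluded outright. Deduplication
keys on canonical SMILES (registry identifiers, when present, are a
secondary consistency check: one id naming two structures drops both
records). Label conflicts between sources are resolved by a fixed
priority — DILIrank > NCTR > Greene > Xu > Liew — reflecting the
curation strictness of the regulatory lists; the relative order of the
three literature sets is this package's choice and is configurable. A
conflict *within* the winning priority level cannot be adjudicated and
the compound is dropped with a logged reason. The output is sorted by
canonical SMILES, which makes resolution independent of input order and
idempotent. Partitioning is by source: DILIrank records form the test
set, everything else the training set.

## Synthetic data

The generator emulates the statistical structure the interpretation
layers are meant to recover: binary labels driven by the presence of
specific substructures plus a descriptor-level signal and label noise.
Molecules are built from a fixed list of 20 simple scaffolds; each of
the default motifs — an acyl hydrazide (`CC(=O)NN`, attached at its
methyl carbon) and an aniline (`Nc1ccccc1`, attached para to the amine)
— is planted independently with probability 0.25 by single-bond
attachment at a random scaffold carbon with a free valence, followed by
0–2 small decorations (methyl, ethyl, hydroxyl, halogen, methoxy,
isopropyl; nitrogen-bearing decorations are deliberately absent so no
unplanted aniline can arise). Labels are drawn from

    logit P(y=1) = base + β_motif · (#planted motifs) + β_desc · (logP − 2)

with defaults base = −2, β_motif = 6, β_desc = 0.5, then flipped with
probability 0.02. These defaults give a roughly balanced class ratio
(~49% positive) with ~43% of molecules carrying at least one motif, a
strong but not deterministic motif→label association, and a mild
lipophilicity signal mirroring the known ALOGP–hepatotoxicity
correlation.

Ground truth emitted per molecule: planted motif names, their atom
indices in the emitted canonical SMILES, and the fingerprint bits
*attributable* to each motif — bits having at least one environment
whose atoms lie entirely within the motif's atom set. Environments that
cross the attachment bond vary between molecules; a consensus (bits
attributable in ≥50% of a motif's carriers) gives the stable,
context-independent bit set used by recovery checks.

What the generator does not emulate: realistic property distributions,
synthetic accessibility, activity cliffs, correlated assay noise, or
class imbalance of the real corpora. Passing recovery tests therefore
demonstrates that the machinery can find substructure signal it is
pointed at, not that real DILI labels are equally recoverable.

## Models

Random forest and LightGBM use their library implementations; logistic
regression uses L2-regularized scikit-learn. Randomized hyperparameter
search draws 50 configurations from predefined ranges (trees/max
features/depth for RF; leaves/iterations/min-leaf-data/depth for LGBM;
iterations/regularization strength for LR), scored by cross-validated
AUROC, with the full search log retained.

The attention network is implemented in numpy with hand-derived
gradients. The attention layer is a full-rank affine map (1032×1032)
with no activation; a softmax over its output yields strictly positive
weights summing to 1, which multiply the input element-wise before the
MLP head (default one 512-unit layer: dense → batch norm → ReLU →
dropout 0.25; sigmoid output unit). Choices the source description left
open, fixed here: attention-layer weights use small-variance Gaussian
init (σ = 0.01) with zero bias (He init applies only to the ReLU dense
layers); learning rate 1e-3 (Adam); early stopping monitors a 10%
stratified validation split with patience 10 and restores the
best-validation parameters; batch normalization uses exponential running
statistics (momentum 0.9) at inference, so inference is deterministic.
Backpropagation routes through the softmax Jacobian, the batch-statistic
terms of batch norm, and inverted dropout; a finite-difference check in
the test suite bounds the relative gradient error at ~1e-6.

Architecture search over (layer count, nodes per layer) is sequential
model-based: after three random evaluations a random-forest surrogate
proposes the unevaluated candidate with the highest predicted validation
AUROC; the search degrades to random sampling whenever the surrogate
cannot be fit.

## Evaluation

The metric block (accuracy, sensitivity, specificity, precision, F1) is
computed from confusion counts at a configurable threshold (default
0.5). AUROC uses the rank-probability definition with ties counted one
half, which the tests verify against trapezoidal ROC integration (and
scikit-learn) to 1e-12. AUPRC uses step-wise average-precision
integration over distinct score thresholds, matching scikit-learn's
convention; interpolated alternatives were rejected as optimistic.
Zero-denominator metrics are flagged undefined rather than coerced to 0.
Cross-validation is repeated stratified ten-fold on the training
partition (pooling the hold-out source into CV would contaminate the
hold-out contract).

## Interpretation

Permutation importance shuffles one column of the *evaluation* matrix
at a time — the permuted column is an exact rearrangement, so the
marginal distribution is preserved — and records baseline minus permuted
AUROC per replicate (default 50). All replicates of one feature are
scored in a single stacked predict call; this makes tree ensembles
tractable at 1032 features on one core. Note that perfectly correlated
features (e.g. several bits of one planted motif) share importance:
shuffling one leaves its duplicates intact, so per-bit drops understate
the motif's joint effect. Recovery checks therefore score a motif by its
best-ranked attributable bit.

Per-compound explanations run one inference forward pass and report the
raw attention weights (never renormalized after truncation). Among
structural bits set to 1, the top-k (default 3) are selected with ties
broken toward the lower feature index, and each is mapped to *all*
environments hashed to its bit. Descriptor features are reported in a
separate attribution block and never mapped to fragments. The p ≥ 0.8
high-confidence flag is informational; any compound can be explained.
Highlights are rendered as SVG with a JSON sidecar of atom index sets;
rendering failures degrade to sidecar-only with a warning.

## Problem sizes and numerical choices

The recovery study in the test suite uses 2000 generated compounds
(β_motif = 6, noise 0.02), a 75/25 split, 200-tree RF, default LGBM,
LR(C=1), and 5 permutation repeats — enough replicates for stable mean
rankings at this effect size, chosen as the study's standard conditions.
The attention recovery check trains with early stopping (typically
~15–40 epochs of the 100 allowed). Softmax is computed with max
subtraction; sigmoid in a numerically safe two-branch form; BCE with
1e-12 clipping; batch-norm ε = 1e-5. Random seeds: every CLI stage
derives its own sub-seed from the single run seed via a seed sequence,
so end-to-end reruns are byte-identical.

## Limitations

- The ALERT descriptor depends on the configured SMARTS list; the
  default is small and illustrative, not a curated toxicophore corpus.
- Attention weights are a heuristic attribution, not a causal one; a
  high weight on a collided bit cannot distinguish its environments.
- Fingerprint hashing limits substructure resolution (radius ≤ 3,
  1024 bits); larger motifs and collision disambiguation are out of
  scope.
- The published multi-source corpora are not bundled; real-data
  performance is not asserted anywhere in this package.
- Dose dependence of liver injury is not modeled.
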