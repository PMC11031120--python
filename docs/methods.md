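# Methods

## Problem and model

A clinical trial is represented by three components: a treatment set
*T* = {τ₁…τ_Kτ} of drug molecules (SMILES), a target disease set
*D* = {δ₁…δ_Kδ} of ontology codes, and a protocol *P* of inclusion (+) and
exclusion (−) criteria sentences. The outcome ω ∈ {0, 1} marks phase
approval. The predictor estimates ω̂ = h(T, D, P) ∈ (0, 1) and a
selective layer converts ω̂ into a decision or an abstention with a
distribution-free accuracy guarantee on the non-abstained trials.

### Input encoders

* **Drugs** (Eq.-style: e_τ = mean_i g_τ(τ_i)). g_τ is a hashed circular
  substructure fingerprint (Morgan, radius 2, 1024 bits) followed by a
  learned linear projection to d. The projection is linear on purpose: the
  mean over per-molecule embeddings then equals the embedding of the mean
  fingerprint, so multi-drug trials cost one projection. The encoder is
  pluggable; a graph-based molecule encoder can be swapped in.
* **Diseases** (e_δ = mean_j G_δ(δ_j)). Each ontology code owns a basis
  vector; G_δ(δ) is an attention-weighted sum over the basis vectors of δ
  and its ancestors (softmax over a two-layer scorer on concatenated basis
  pairs). Rare codes thereby borrow strength from their parents, the
  standard graph-based-attention construction for medical ontologies.
* **Protocol** (e_π = g_π(P)). Each criterion sentence is embedded by a
  pluggable sentence encoder — the default is a deterministic hashed
  bag-of-tokens with the inclusion/exclusion tag prefixed as a token; a
  contextual sentence encoder can be plugged in through `sentence_fn` —
  then the sentence sequence passes through four sequential 1-D
  convolutions with kernel sizes 2, 3, 4, 5 (four granularities of
  phrasing), ReLU between layers, zero same-padding so one-criterion
  protocols remain valid, masked mean pooling, and a final linear map to
  d. An empty protocol yields the zero vector with a warning. The stack
  is order-sensitive by construction.

### Knowledge heads and interaction graph

Five ADMET heads (absorption, distribution, metabolism, excretion,
toxicity) map e_τ through independent per-property layers Φ\* and a
one-layer FCNN + sigmoid to a property probability; a disease-risk head
maps e_δ through a 2-layer highway network Ψ to a historical-success
probability. Highway layers are y = T(x)⊙H(x) + (1−T(x))⊙x with a sigmoid
gate (bias initialized at −1 so early training favors the carry path) and
tanh transform.

The 13 nodes — 3 input, 6 knowledge, 3 aggregation (PK from the five
ADMET embeddings, interaction from drug/disease/protocol, augmented
interaction from disease-risk + interaction), 1 prediction — are stacked
in a fixed row order into E⁽⁰⁾ ∈ R^{13×d}. Aggregation nodes are each a
concatenating linear layer to d followed by a 2-layer highway stack.

The adjacency J is the symmetrized union of the construction edges (each
head/aggregation node linked to its inputs, prediction linked to PK and
augmented interaction) plus self-loops, which preserve a node's own state
under the unnormalized ReLU GCN update

E⁽ⁿ⁾ = ReLU(B⁽ⁿ⁾ + (A ⊙ J) E⁽ⁿ⁻¹⁾ W⁽ⁿ⁾),  n = 1…N.

A is a learned, layer-independent edge-attention matrix: A_{i,j} =
F([e_i; e_j]) with a 2-layer scorer (ReLU hidden, sigmoid output),
computed from E⁽⁰⁾ only. A is directed (ordered concatenation) over the
symmetric J and is not row-normalized. A doubles as the per-trial
interpretability report. The approval probability is a sigmoid FCNN on
the prediction node's layer-N row. Binary cross-entropy throughout; no
class reweighting.

Defaults: d = 64, N = 2, Adam at lr 1e-3, batch 32, 20 epochs; all
configurable. Numerical core: the network is implemented on a small
in-package reverse-mode autodiff over numpy arrays (`_autodiff.py`) —
the architecture's gated and attention-masked graph needs arbitrary
differentiable composition, and the package carries its own compact
engine for it.

### Training protocol

Three stages, all seeded: (1) ADMET heads + molecule encoder pretrained
on auxiliary (molecule, binary property) tables; (2) disease-risk head +
disease encoder pretrained on historical per-disease outcomes; (3)
end-to-end fine-tuning of every parameter on labeled trials. Stage 3
holds out a 15% validation slice (mirroring the benchmark's validation
protocol), early-stops on validation ROC-AUC with patience 8, and returns
the element-wise average of the parameters from the k = 5 best validation
epochs (stochastic weight averaging): at desk scale the per-epoch
validation ranking is noisy, and averaging the leading snapshots is
markedly more stable than trusting the single best epoch.

## Selective classification

Confidence is P̂ = max(ω̂, 1 − ω̂) (P̂ = 0.5 predicts the positive class —
a deterministic argmax tie-break). On a calibration set, for threshold λ
the kept set is {P̂ ≥ λ} (ties kept), the empirical selective risk R̂(λ)
is stored as exact integer counts (k errors of n kept), and the one-sided
binomial upper bound is

R̂⁺(λ) = sup{ r : BinomCDF(k; n, r) ≥ β },

found by bisection to 1e−9 (zero-error case in closed form,
1 − β^{1/n}); it equals the one-sided Clopper–Pearson bound, the
Beta(k+1, n−k) quantile, which serves as the independent oracle in tests
but never as the implementation. n = 0 conservatively reports R̂⁺ = 1.

The candidate grid is the sorted unique calibration confidences plus
sentinels {0, 1} (the empirical risk only changes at observed
confidences). Scanning the bound downward from the top of the confidence
range, it starts wide (sample starvation: with a handful of kept samples
even zero errors cannot certify a small α), falls as kept samples
accumulate, and rises again when the kept set picks up the bulk error
rate. λ̂ is the infimum of the certified region — the smallest grid
threshold whose own bound clears α — i.e. the last point, walking down,
before the bound exceeds α for good. Because the scan examines many
correlated thresholds, certification during the scan is at level β/2:
half the failure budget pays for the selection. Both choices are
validated empirically by the Monte-Carlo harness (below). Under the
monotone-risk premise of selective classification (higher confidence, no
higher error rate), validity at λ̂ transfers to the starved thresholds
above it. A calibration where no threshold certifies is reported
`feasible = false`; the pipeline then abstains on everything with a
warning. Defaults α = β = 0.1, configurable; binary classification only.

`guarantee_monte_carlo` replays calibrate-then-test on an i.i.d. sampler
and reports the fraction of replications whose test selective accuracy
reaches 1 − α; infeasible (abstain-all) replications vacuously satisfy
the guarantee. The shipped miscalibrated sampler (confidence uniform on
[0.5, 1], correctness probability = confidence − 0.08) yields fractions
0.93–0.96 at α = β = 0.1 across seeds.

## Synthetic data

The generator emulates the study conditions end to end. An ICD-like
balanced code tree (depth 3, branching 3) carries planted failure risks
that diffuse down the hierarchy (children jitter around parents,
sd 0.16). Fifty hand-validated SMILES form the molecule pool, each with
five planted ADMET attributes in (0, 1). Each trial draws 1–3 molecules,
1–2 leaf codes, and 2–6 criteria sentences from rigorous/sloppy template
pools; protocol quality is the realized balance of rigorous sentences in
the written document (a deterministic function of the observable text,
not a latent intention — so the planted Bayes scorer is in principle
attainable from the features). The planted score is linear-logistic:

latent = −5·(mean toxicity − ½) − 5·(max disease risk − ½) + 3·quality
         + phase offset

with label ~ Bernoulli(sigmoid(latent + ε)), ε ~ N(0, noise_sd²).
Phase offsets are solved by bisection so the marginal success rates match
the observed clinical phase marginals (56.3% / 49.8% / 67.8% for phases
I/II/III); the phase mix (0.143/0.490/0.367) follows the benchmark's
composition. noise_sd defaults to 2.0, set by the built-in calibration
routine so the Bayes scorer's ROC-AUC is 0.85 ± 0.03 at n = 5000. Dates
are uniform over a six-year window with the split date at the 60%
quantile, so temporal splits have non-trivial train/test/straddler
partitions. Everything is a deterministic function of one integer seed.

What the generator does **not** emulate: real chemistry (toxicity is
assigned per molecule, not computed from structure), real medical text
(templated sentences), inter-feature correlations of real trial
registries, and non-drug interventions. Passing tests therefore
demonstrate the machinery — encoders that extract each planted signal,
bound and threshold correctness, the guarantee's frequentist validity —
not clinical-grade predictive performance.

## Evaluation choices

PR-AUC is the step-wise average-precision dialect (precision not
interpolated); ROC-AUC is trapezoidal with ties at half weight; both are
tested to 1e−9 against threshold-enumeration and pair-counting oracles.
Temporal splits put trials completing before the split date into the
training pool (15% of it to validation, seeded) and trials starting after
it into test; straddlers are dropped with a logged count. The
significance test is a paired one-sided bootstrap (2000 resamples,
plus-one corrected, single-class resamples redrawn); reported ± values
are bootstrap standard deviations. Relative improvement is
100·(improved − base)/base to two decimals.

## Problem sizes

The shipped study sizes: end-to-end runs train on 1400 synthetic trials
(d = 64, up to 40 epochs with early stopping), calibrate on 300 and test
on 300; the guarantee harness uses 200 replications of 500 calibration /
1000 test samples; bound checks sweep all k ≤ n ≤ 50 at four β levels.
On one CPU the whole acceptance run takes a few minutes. The trained
network's held-out ROC-AUC is typically 0.76–0.83 against a planted
Bayes ceiling of ≈ 0.85; with α = 0.2 the calibrated layer keeps between
a fifth and two thirds of test trials (seed-dependent) and lifts accuracy
on them by 10–20 points over full coverage. α = 0.2 rather than 0.1 is the
demonstration default at this scale because the desk-scale model's
full-coverage error (~0.25) leaves no certifiable 90%-accuracy region of
useful size; α is a free parameter of the layer, not of the theory.

## Known limitations

* The guarantee is marginal over calibration draws, not conditional;
  the β/2 selection margin is a pragmatic, empirically validated control
  of the scan's multiplicity, not a finite-sample theorem.
* The abstention threshold is calibrated post hoc; cost-sensitive or
  learned abstention is out of scope, as are conformal prediction sets
  and multi-class problems.
* Checkpoints store raw parameter arrays keyed by construction order;
  architectural changes invalidate old checkpoints (version-tagged).
* The attention report is a descriptive interpretability aid; edge
  weights are sigmoid scores, not calibrated effect sizes.
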