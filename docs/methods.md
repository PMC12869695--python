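# Methods

This note documents the models and procedures implemented in `combosyn`,
the choices made where the design was genuinely open, and what the
synthetic world does and does not establish.

## 1. Synergy scoring

A dose-response block is a complete (n_a × n_b) checkerboard of %
inhibition values with dose-0 margins.  All four scores are the **mean
excess over interior wells** (observed − null-model expectation), which
makes them grid-size independent.

* **Bliss**: E = y_A + y_B − y_A·y_B/100, computed from the observed
  margins — an exact closed form.
* **HSA**: E = max(y_A, y_B), also exact.
* **Loewe**: monotherapies are fitted with four-parameter Hill curves
  y = b + (E_max−b)·d^h/(EC50^h + d^h) (least squares, bounds
  E_max ∈ [0,120], h ∈ (0.1,10], EC50 > 0, baseline fixed at 0 unless
  stated).  The dose-equivalence equation d₁/D_A(y) + d₂/D_B(y) = 1 is
  solved per well by bisection on y ∈ (0, min(E_max^A, E_max^B)),
  tolerance 1e-6, ≤ 100 iterations.  Wells where no root exists in that
  range (doses too small, or saturated beyond the weaker drug's E_max)
  fall back to the HSA expectation.  Flat response series short-circuit
  to a constant curve; non-monotone series that the optimizer cannot
  explain fall back to a median-interpolation fit flagged
  `converged=False`.
* **ZIP** is implemented as a *conditional-fit delta*: each row (and
  column) of the block is re-fitted with the opposing monotherapy's
  fitted value as a fixed baseline; the mean of the two conditional
  fitted surfaces is compared against the Bliss surface of the fitted
  monotherapies.  This is a documented simplification of the full
  published ZIP formulation (flagged `zip_method: conditional` in file
  output); it shares its defining property — zero on blocks constructed
  as Bliss combinations of Hill monotherapies, and a uniform potency
  shift of c propagates to a delta of c.

**Labels.** A triplet is synergistic iff its Loewe excess strictly
exceeds 0 (an exact 0 is non-synergistic).  Duplicate records of the
same canonical (drug_a ≤ drug_b, sample) key are averaged score-wise and
re-thresholded.

**A caveat worth knowing.** Bliss and Loewe are different null models.
On blocks *generated* under Bliss independence (as the synthetic world
does), the Loewe expectation is systematically below the Bliss surface
at high-effect wells, so Loewe excesses of non-interacting pairs sit a
few points above zero.  Strict-0 Loewe labels on such blocks therefore
over-call synergy; recovering the planted signal instead uses the
central-well Bliss excess (Section 2).  On real screens the label rule
is the field's convention and is implemented exactly.

## 2. The synthetic world

The generator emulates, at desk scale, the data a synergy-prediction
study consumes: 240 genes in 12 pathways of 20; a stochastic-blockmodel
PPI (edge probability 0.3 within a pathway, 0.01 across, confidence
weights U(0.15,1)); 30 drugs, each assigned one pathway and 3 target
genes inside it, with deterministic fragment-table SMILES; 40 samples
whose pathway activities are independent Bernoulli(0.5) and whose
expression is baseline 5 + 2·activity + N(0, 0.5) on the log2(TPM+1)
scale; a mutation matrix of independent Bernoulli(0.05) noise (optionally
with a sentinel gene per pathway copying the activity state, which makes
the mutation branch informative).

**Planted rule.** truth(a, b, s) = 25% inhibition iff pathway(a) ≠
pathway(b) and both pathways are active in s, else 0.  The rule depends
jointly on both drugs and the sample, so leave-drug-out generalization
is a genuine test; about (11/12)·0.25 ≈ 23% of triplets are positive.

**Dose-response blocks** use a 6-point grid (0 plus 5 half-log steps to
10 µM).  Monotherapies are Hill curves with E_max ∈ [80,100],
h ∈ [1,2]; combination wells are the Bliss expectation of the noiseless
monotherapies plus truth·k(i)·k(j), where k is triangular in index
space — 0 on the dose-0 margins, 1 at the central interior index — plus
N(0, 3) noise, clipped to [0,100].

**EC50 calibration.** Base EC50 is drawn log-uniform between the
*central* and the *top* dose, and is multiplied by 0.75 when the drug's
pathway is active (more potent in susceptible samples).  The restriction
to the upper interior is deliberate: if EC50 may fall near the lowest
dose, two potent drugs drive the central-well Bliss expectation above
~90% and the [0,100] clip erases the planted bump exactly for
synergistic triplets (synergy requires both pathways active, which is
also what boosts potency).  With the restriction, the worst-case
noiseless central-well excess is 12.96 > 12.5 = bump/2, so thresholding
the central-well Bliss excess at half the bump recovers the planted
labels exactly at zero noise and at ≥ 95% agreement under the default
noise (`synth.detect_planted_synergy`).

**Survival** times are exponential with a rate ratio equal to the given
hazard ratio between two groups, censored by an independent
Uniform(0, 30); nothing beyond the exponential family is modelled.

**What a green test does not establish.** The world has clean block
structure, binary pathway states, independent noise, and chemistry that
is deliberately uninformative about the planted rule (fragment SMILES
need only parse and be distinct).  Recovery here shows the pipeline is
correct and leakage-free; it says nothing about real tumor
heterogeneity, correlated assay noise, or chemistry-driven synergy.

## 3. Features

* **Chemistry**: Morgan fingerprints (radius 2, 2,048 bits) and, for
  graph-based encoders, heavy-atom molecular graphs (element one-hot,
  degree, formal charge, aromatic flag; symmetric adjacency).
* **Drug targets**: a binary drug × gene matrix diffused by random walk
  with restart, F ← αF₀ + (1−α)·S·F with S = D^{-1/2}AD^{-1/2},
  default α = 0.5, tolerance 1e-6, ≤ 10,000 iterations.  Isolated
  nodes carry a self-loop in S so an edgeless network returns the input
  unchanged.  Variants: `hub_removed` deletes the top ⌈5%⌉ of nodes by
  degree (ties by node id) before normalization; `degree_normalized`
  additionally down-weights edges by 1/√(deg_i·deg_j).
* **Marker genes**: the union of a landmark list, the top 15% of genes
  by expression variance (the "most differentially expressed" rule is
  implemented as top-variance because no contrast groups are defined),
  the 1,000 highest-degree genes in the PPI restricted to confidence
  > 0.7, and the drug-target universe — each gene tagged with its
  provenance.
* **Expression encoder**: a symmetric autoencoder (full-scale widths
  G → 1024 → 256 → 1024 → G; desk defaults scale the hidden/bottleneck
  widths to 96/32 for 240 synthetic genes) trained with input dropout
  0.2, step size 1e-3, 100 epochs, a 10% holdout evaluated per epoch,
  returning the best-holdout-epoch weights.  Inputs are per-gene
  standardized with statistics from the encoder's own training rows;
  inside the predictor the statistics come from the training-fold
  samples only, so no split leakage occurs.
* **Mutation profiles** binarize calls of the five nonsynonymous
  classes (missense, nonsense, frameshift insertion/deletion, splice
  site); other classes are ignored.

## 4. The predictor

Five tokens (chem_a, chem_b, dti_a, dti_b, sample) of common width d.
Desk default d = 64 (the full-scale configuration uses d = 256; all
widths are `ModelConfig` fields).  Branch encoders: fingerprint →
128 → d MLP; propagated targets → 1-D convolution (8 channels, kernel
8, stride 4) → flatten → 500 → d; expression → pre-trained autoencoder
(fine-tuned by default, freezable) → d.  One attention layer, single
head (d_k = 32), all-to-all over the tokens — the printed equation's
ambiguous scaling is normalized to softmax(QKᵀ/√d_k)V, and a
`mask_self_modality` flag restricts attention to cross-modality pairs
for ablation.  Head: 5d → 512 → 128 → 1 with ReLU, sigmoid output.

Training: binary cross-entropy (probabilities clipped to
[1e-7, 1−1e-7]), Adam step 1e-3, batch 128, ≤ 50 epochs (10 suffice on
the synthetic world); pair-order augmentation by a seeded random
ordering flip per epoch; validation AUROC per epoch with best-epoch
selection; inference symmetrizes by averaging both drug orders.
Everything runs on a small in-repo reverse-mode autodiff engine
(`_autodiff.py`) — verified against finite differences to < 1e-6
relative — because no deep-learning framework is assumed.

Variants: `mutation` feeds the sample branch the binary mutation
profile (pre-training its own autoencoder); `ablate_chem` removes both
chemical tokens (3 tokens remain); `ensemble` averages member
probabilities.

## 5. Evaluation

* **leave-combo-out**: canonical drug *pairs* partitioned into k
  balanced folds (a pair never spans folds, even across samples).
* **leave-drug-out**: drugs clustered on Tanimoto distance
  (agglomerative, average linkage, cut to k); a triplet belongs to a
  fold only if *both* drugs are in that fold's cluster; cross-cluster
  triplets are dropped — the only choice that keeps the no-shared-drug
  guarantee exact — and counted in the plan.
* **leave-sample-out**: affinity propagation (damping 0.9, preference =
  median similarity, ≤ 1,000 iterations) on the negative squared
  Euclidean distance over the top-1,000 most variable genes; the
  largest cluster trains (90/10 train/val), the rest test.  On
  non-convergence a PAM-style k-medoids (k = 4) fallback is used and
  logged in the plan's provenance.

Within every fold the nominal training triplets are split 90/10 into
train/validation.  Each plan re-asserts its strategy-specific
disjointness at construction.  Metrics: AUROC (tie-aware rank
probability), AUPRC (step-integrated average precision), Spearman rank
correlation; cross-validation reports per-fold values and mean ± sd
across folds.

## 6. Downstream analyses

* **Stratification**: hierarchical clustering (Euclidean, average
  linkage) of the patient × combination probability matrix cut at
  k = 2; the higher-grand-mean cluster is "responsive".  Combinations
  with probability > 0.5 are "effective"; partners rank by column mean.
* **Survival**: standard two-group log-rank test (chi-squared
  p-value); groups with < 2 samples are rejected as insufficient.
* **LPS**: per-gene two-sample pooled-variance t-statistics on the
  training portion; the 50 largest-|t| genes weight the linear score
  LPS(x) = Σ t_j x_j; per-group Gaussians plus empirical priors give a
  Bayes posterior; the posterior cutoff is 0.5 with ties broken toward
  the first (sorted) group, and a confidence-band option leaves
  low-posterior samples unclassified.
* **LCC test**: observed statistic = size of the largest connected
  component of the interactome subgraph induced by the target set; the
  null draws equally sized uniform node sets (a degree-matched option
  samples within degree deciles but makes no fidelity claim); p uses
  the +1 correction, p = (1 + #{null ≥ obs}) / (1 + n_perm), so it is
  never 0.

## 7. Numerical and reproducibility notes

* Every stochastic stage takes an explicit seed and is bit-reproducible;
  per-block noise streams derive from (world seed, CRC32 of the triplet
  ids) so block generation is order-independent.
* Loewe bisection: tolerance 1e-6% inhibition, ≤ 100 iterations.
* Propagation convergence: max-abs change < 1e-6 (the fixed point
  matches a direct linear solve to better than 1e-6 at that setting).
* Finite-difference gradient checks use a step of 1e-6; larger steps
  can straddle ReLU kinks and inflate the apparent error.
* Degenerate inputs fail loudly: one-class labels, empty folds,
  structurally identical drug libraries (leave-drug-out advises
  leave-combo-out), all-identical samples, or prediction matrices with
  no row structure all raise informative errors rather than returning
  arbitrary partitions.

## 8. Known limitations

* ZIP is the conditional-fit simplification described above, not the
  full published derivation.
* The chemistry branch uses fingerprints (or an optional small graph
  encoder); no pre-trained chemical foundation model is included.
* Synthetic chemistry is decorative: structure carries no signal about
  the planted rule, so chemistry-ablated models perform on par with the
  full model on synthetic data — by design, not as a general claim.
* Survival generation is exponential with uniform censoring only.
* Probabilities are not calibrated; the 0.5 threshold is a convention.
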