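# Methods

## Task and model

Per-residue prediction of ATP binding is cast as binary classification of
sliding windows: the fragment of L = 17 residues centred on residue *i*
(GAP pseudo-residues outside the chain) is positive iff residue *i* is
annotated ATP-binding. The pipeline is: categorical reclassification of
per-residue attributes, window featurization with statistics fitted on
training data only, z-scoring, SMOTE balancing of the training set, and a
small 1-D convolutional classifier, evaluated by chain-level 5-fold CV and
independent testing with Sn/Sp/ACC/MCC/AUC.

## Reclassification

* **Dihedral classes.** phi: [-180,-90) / [-90,-60) / [-60,180];
  psi: [-180,-60) / [-60,0) / [0,180]. The printed interval schemes share
  their boundary points; we adopt the left-closed/right-open convention
  (final interval closed) so each map is total and single-valued on
  [-180, 180]. The supporting statistic bins angles into 24 bins of 15
  degrees and takes the per-bin probability difference between classes;
  +180 folds to -180 so the bins tile the circle.
* **Energy groups.** G,I,S,T,V / C,H,M / F,K,N,R,W,Y / A,D,E,L,P,Q
  (ordered from binding-enriched to binding-depleted). The groups are taken
  as given; the underlying per-residue energy table is not re-derived.
* **RSA intervals.** [0,0.2], (0.2,0.45], (0.45,0.6], (0.6,1]. The nominal
  scheme covers (0, 0.85]; exactly 0 and (0.85, 1] are clamped into the
  nearest interval so the map is total.
* **Hydropathy (6 classes) and polarity (4 classes).** Conventional
  groupings shipped as editable tables: {AGV},{ILFP},{YMTS+C},{HNQW},{RK},
  {DE} and nonpolar/polar-uncharged/acidic/basic. Cysteine is placed in
  the third hydropathy class (mildly hydropathic, like Y/M/T/S). Because
  reasonable alternatives exist, `CategoryMaps.checksum()` fingerprints
  the tables for run provenance.
* Every category alphabet carries one extra vacancy (GAP) category; an
  optional unknown residue symbol `X` also maps to the vacancy.

## Features

For a window of length L over a property with q categories (vacancy
included):

* **Composition**: the length-q frequency vector of the window (sums to 1);
  q = 21 (residue), 4 (SS), 5 (RSA), 4 (phi), 4 (psi), 5 (energy), total
  43.
* **Site conservation**: positive and negative position weight matrices
  per property, m[i,j] = ln(p_ij / p0_j) with the square-root pseudocount
  p_ij = (n_ij + sqrt(N_i)/q) / (N_i + sqrt(N_i)) and p0 the pooled
  background with the same smoothing. The printed pseudocount expression is
  typographically ambiguous; this classic sqrt-N form with a uniform prior
  is the reading consistent with its symbols, and it keeps every log finite
  without tuning. Each fragment contributes (m_pos, m_neg) per position:
  6 x 2L = 204 values.
* **Hydropathy entropy**: Shannon entropy (base 2) of the window's
  hydropathy-class distribution, q = 7; one scalar. Entropy is computed
  for hydropathy only.
* **Propensity factors**: F_ij = (n_ij/N_j) / (n_i/N_t) over training
  centre residues — class-conditional frequency over background frequency,
  so F = 1 means no preference. The printed formula reduces to a class-size
  ratio after its subscripts are untangled, which is dimensionally odd and
  residue-independent; the standard propensity above reproduces the
  expected enrichment pattern (D,G,H,K,R,S,T binding-favoured) and is the
  default, with the literal form available as `propensity_form="verbatim"`.
  How propensities enter the feature vector is not prescribed; we emit per
  window position the (binding, non-binding) pair of the residue occupying
  it (2L values, GAP -> (1,1)), mirroring the PWM convention.
* **Basic set contents**: the named basic features include hydropathy and
  polarity, but only composition/PWM/entropy extraction is described for
  them; with entropy alone they would be nearly absent. The featurizer
  therefore adds per-position one-hot hydropathy (7L) and polarity (5L)
  blocks to B, controlled by `b_onehot` (default on).
* Feature sets B, B+E, B+PP, B+F and their unions select blocks; all
  fitted tables come from the training fold only, and columns are z-scored
  with training-fold statistics before resampling/classification (SMOTE's
  Euclidean geometry and the network both need commensurate scales).

## Resampling

SMOTE runs inside the training fold only, after standardisation, never on
validation or test fragments. k = 5 neighbours (the technique's customary
default); distance ties break by ascending index; parents cycle round-robin
in input order so the synthetic load spreads evenly; lambda ~ U[0,1).
Synthetic provenance (parent, neighbour, lambda) is retained so the
convex-combination and k-NN-membership invariants are checkable after the
fact. The RUS arm draws the majority subset 10 times and averages metrics.

## Classifier

The flat feature vector is treated as a one-channel 1-D signal:
`n_conv_layers` blocks of [conv(kernel 3, stride 1, same padding) ->
batch-norm -> ReLU -> dropout 0.2] -> flatten -> dense(`dense_units`) ->
ReLU -> dense(1) -> sigmoid, trained with Adam (lr 1e-3) on binary
cross-entropy. Early stopping watches a stratified 10% validation split
(patience in epochs; best-validation weights restored). The three searched
hyperparameters are layers (1-6), filters (2-128) and batch size (2-128);
`grid_search` supports the one-axis-at-a-time protocol and a full grid,
selecting by mean CV MCC with ties toward the smaller model. No pooling
layers are used (windows are short) and the dense head is one layer; both
choices are config-exposed. The implementation is pure NumPy (float32),
bit-reproducible for a fixed seed single-threaded. Class probabilities
convert to labels at threshold 0.5 everywhere. Baselines: RBF-kernel SVM
(probabilities via a logistic link on the margin, preserving ranking and
the SVM's own decision boundary) and a 500-tree random forest.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/N (percentages) and
MCC = (TP·TN - FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC = 0
when a denominator factor vanishes. AUC uses the midrank statistic
(equal to trapezoidal ROC integration); curve points are exported. CV
folds are assigned at chain level — all windows of a chain share a fold —
because overlapping windows from one chain are near-duplicates that would
otherwise straddle folds; whether the original protocol split at chain or
fragment level is not stated. Pooled (micro-averaged) held-out metrics are
the headline numbers; per-fold reports are attached.

## Synthetic data

The generator emulates what the predictor exploits, not protein physics:

* binding labels in short consecutive clusters (mean ~2.5 residues,
  mimicking multi-residue binding sites such as P-loops) at an overall
  rate of 0.036, the class imbalance of curated ATP datasets;
* at binding positions, residues favoured at real ATP sites
  (D,G,H,K,R,S,T,I,V) get log-odds enrichment `effect_aa`; phi/psi classes
  are tilted by `effect_angle` (middle class enriched, log-enrichment
  2 x effect_angle) with the angle uniform within its class interval;
  RSA is Beta(2, 2 + effect_rsa) at binding sites vs Beta(2, 2);
* secondary structure follows a persistent 3-state Markov chain
  independent of labels; background residue frequencies are uniform 1/20
  (the simplest null; configurable);
* chains are >= 51 residues, matching the length filter of the curated
  datasets; angles are drawn independently per residue (no Ramachandran
  coupling — only the 3-class reclassification is consumed downstream).

With every effect at 0 the classes are exchangeable, so any pipeline
should score MCC ~ 0 and AUC ~ 1/2; with the defaults (effect_aa 3,
effect_angle 1) the planted signal is strong enough for the pipeline to
recover MCC > 0.3 in 5-fold CV. What passing these tests shows is that the
machinery is sound — encoders recover planted statistics, balancing helps
sensitivity, nothing leaks across folds. It does not certify performance
on real proteins: real windows have homology structure, composition biases
and attribute-prediction errors the generator does not model, and headline
scores on curated datasets depend on stochastic training at much larger
scale. A tiny deterministic micro fixture (three hand-checkable chains)
anchors the propensity, entropy and probability-difference arithmetic to
hand computations.

## Problem sizes and numerics

Test and acceptance runs use deliberately modest study sizes chosen as
representative: null calibration pools five 50-chain datasets (chains of
51-60 residues); signal recovery uses 100 chains; monotonicity checks use
30 chains over tilt levels {0,1,3,5} with five seeds. The network
configurations in these runs are small (1-2 conv layers, 4-8 filters,
<= 20 epochs) — null behaviour is architecture-insensitive and the planted
signal is learnable at this capacity. Seeds fix dataset generation, fold
assignment, resampling and training separately. Degenerate inputs are
errors, not silent defaults: empty classes when fitting tables, single
classes for classifiers or ROC, out-of-range angles/RSA, even window
lengths, overlapping train/test chain ids. Where the minority class is
already balanced the SMOTE sampler is the identity.

## Known limitations

* The deposited-dataset parser (`sdcnn_github`) is best-effort for an
  interleaved id/sequence/labels layout; the native `fasta_plus_labels`
  dialect is the documented format.
* Propensity and PWM tables are refit per CV fold (the conservative
  reading; refitting once on the full training set would leak fold
  information).
* Multi-threaded BLAS can reorder reductions; bit-level training
  determinism is guaranteed single-threaded only.
* The SVM baseline's probabilities are a monotone link on the margin, not
  calibrated probabilities; ROC/AUC and 0.5-threshold labels are
  unaffected.
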