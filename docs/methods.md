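# Methods

## The prediction problem

Drug–target interaction (DTI) prediction is treated as supervised binary
classification over (molecule, protein) pairs: given a molecule `m` and a
protein `p`, predict whether they bind (+1) or not (−1).  The chemogenomic
setting predicts jointly across both spaces, so information flows between
similar molecules and between similar proteins — the property that makes
predictions possible for pairs, and even entities, never seen in training.

## Entity kernels and explicit feature maps

**Molecules** are encoded as ECFP4 fingerprints (Morgan radius 2, folded to
1024 bits; RDKit backend, with a pass-through backend accepting precomputed
bit strings so the numerical core runs without a chemistry toolkit) and
compared with the Tanimoto kernel `k_M(m, m') = |m ∧ m'| / |m ∨ m'|`, a
positive-semidefinite similarity.  The Jaccard index of two all-zero
fingerprints is undefined; such inputs raise an error rather than being
assigned a value.

**Proteins** are compared on their primary sequences with the Local
Alignment (LA) kernel, which sums `exp(β·score(π))` over *all* gapped local
alignments `π` (affine gaps: a gap of length g costs `d + e·(g−1)`), with the
empty alignment contributing 1.  It is a soft Smith–Waterman: as β grows,
`ln K / β` converges to the best local-alignment score.  The summation
dynamic program follows the standard five-matrix recursion in which a gap
run in the first sequence always precedes a gap run in the second between
two aligned pairs, so each alignment is counted exactly once; its
correctness is established against an exhaustive alignment enumerator on
short sequences (max deviation ~1e−15 relative).  When intermediates exceed
1e280 the DP transparently re-runs in log space.  A numba-compiled inner
loop is used when numba is importable, with a bit-identical pure-Python
fallback; pairwise evaluations are memoized per kernel instance.

Hyperparameters default to BLOSUM62, β = 0.5, gap open 11, gap extend 1,
log-transform on — conventional LA-kernel settings; all are exposed in the
configuration.  The log-transformed kernel is not guaranteed PSD, which the
factorization below absorbs by eigenvalue clipping.  Residues B/Z/X/U/O
missing from the substitution matrix score a constant (default −4); a
standard residue missing from a custom matrix is an error.

**Nyström feature maps.** With `m` landmarks drawn uniformly without
replacement from the training entities, the landmark Gram `K_mm` is
eigendecomposed, eigenvalues below 1e−10 are dropped (this truncation is
what handles the indefinite log-LA Gram), and the extrapolation matrix
`E = U_d diag(σ_d)^{−1/2}` maps kernel evaluations against the landmarks to
a `d`-dimensional feature: `ψ(x) = Eᵀ [k(x, ℓ₁), …, k(x, ℓ_m)]`.  With
`m = d = n` the map is exact — `⟨ψ(x_i), ψ(x_j)⟩` reproduces the (clipped)
Gram — which is how the protein side is computed by default, since protein
counts stay small.  Features are then centered with the training-set mean
and ℓ₂-normalized (in that order; the centering mean is computed over the
full training entity set by default, switchable to landmarks only).  When a
requested dimension exceeds the post-clipping rank the map reduces it with
a log notice by default; `strict_dim=True` raises instead and reports the
achievable rank.  Defaults for large data are 3000 landmarks and 1000
dimensions on the molecule side, clipped to the data when smaller.

## The pair-space SVM

A pair's feature vector is the tensor product `z = ψ_M(m) ⊗ ψ_P(p)` of
dimension `d_Z = d_M·d_P`; the classifier is `sign(⟨w, z⟩ + b)` with `w`
viewed as the `d_M × d_P` matrix `W`.  Training minimizes the penalized
empirical hinge risk

    f(W, b) = (1/n_Z) Σ_k max(0, 1 − y_k(⟨m_{i_k}, W p_{j_k}⟩ + b))
              + (λ/2)‖W‖²_F

(loss averaged over pairs; `b` unpenalized and optimized jointly).  The
pair features are never materialized: with `q_j := W p_j` precomputed for
every protein, all scores cost `O(n_P·d_Z + n_Z·d_M)` instead of
`O(n_Z·d_Z)`, and the gradient factorizes the same way by grouping active
pairs per protein.  The identity is checked against a materialized
Kronecker oracle to 1e−10 relative, together with the molecule/protein swap
symmetry.

Optimization is full-batch L-BFGS from the origin (default 200 iterations,
gradient tolerance 1e−6).  Because the hinge is nonsmooth, the quasi-Newton
line search can stall a fraction of a percent above the optimum at a kink;
the solution is therefore polished through a short smoothing homotopy —
softplus-smoothed hinge `μ·softplus((1−m)/μ)` at μ = 1e−2, 1e−4, 1e−6,
warm-started — followed by a final exact-hinge run, keeping the best exact
objective seen.  At the hinge kink itself the subgradient 0 is used.
Margins at exactly zero classify as +1.

**Platt calibration** maps raw margins `⟨z, w⟩` (bias excluded; the offset
is absorbed by `t`) to probabilities `σ(s·f + t)` by minimizing the
logistic loss `Σ_k softplus(−y_k(s·f_k + t))` with the same quasi-Newton
routine.  Degenerate single-class inputs are rejected.

## Dataset curation

The curation path converts a multi-source bioactivity table into binary
labels:

1. *structure filter* — a molecule is kept only if every contributing
   source reports the identical SMILES string (standardization is assumed
   upstream; comparison is plain string equality), its molecular weight is
   within [100, 900] g/mol inclusive, and it has at least one record
   against a human protein ("Homo sapiens", case-insensitive);
2. *measurement selection* — per pair, only the highest-precedence
   measurement type present is used: Kd, else Ki, else IC50;
3. *labeling* — if the selected values agree within one log unit
   (max/min ≤ 10), the arithmetic mean of the molar values decides
   (geometric mean available by configuration): `< 100 nM` positive,
   `> 100 µM` negative, otherwise nonconclusive.  If they disagree by more
   than one log unit, the pair is positive only when *all* values are below
   100 nM, negative only when all are above 100 µM, and nonconclusive
   otherwise — including the contradictory mixed case.  Exact threshold
   values (1e−7 M, 1e−4 M) are nonconclusive: the inequalities are strict.

**Balanced negatives.**  Assuming most unlabeled pairs are non-binding,
training negatives are sampled so that each entity's negative degree
matches its positive degree, which counteracts database bias toward
heavily studied entities.  The greedy procedure repeatedly takes the entity
with the largest remaining deficit and pairs it with a uniformly random
partner that also has a deficit (never re-using positive, known-negative,
nonconclusive, or already-chosen pairs); when no deficit partner exists a
zero-deficit partner is used, leaving that partner one over — so every
entity ends within one of balance whenever the graph permits.  Infeasible
residues are reported per entity, never silently dropped.  Test folds are
topped up to 50% prevalence with uniformly sampled unlabeled pairs, true
negatives first.

**Split scenarios.**  `random` partitions pairs; `unseen_drugs`
(`unseen_targets`) partitions molecules (proteins) and lets pairs follow
their entity, so test entities never occur in training; `orphan` partitions
both sides independently and keeps a pair only when its molecule-fold and
protein-fold coincide — both test-entity sets are disjoint from training,
at the price of dropping mismatched pairs (about a fraction 1 − 1/k of
them for k folds).

## Evaluation protocols

**AUPR** is computed as average precision: candidates sorted by descending
score (ties keep stable input order), mean over positives of the precision
at each positive's rank.  This step-interpolated form is conservative
relative to trapezoidal area and matches scikit-learn's average precision
when scores are distinct.

**Cross-validation.**  The single hyperparameter λ is selected over the
grid {1e−11, …, 10, 100} by 5-fold CV.  Every fold refits the entire
feature pipeline — fresh landmark draw, eigenbasis, centering mean, and
Platt parameters on the training fold only — so no information leaks from
test entities; within a fold the λ path reuses that fold's features, since
the grid varies only the penalty.  Folds with single-class test labels are
skipped with a warning.

**Scaffold hopping.**  A hop case holds a query protein, a known active, a
hidden second active, and decoys (499 in the reference protocol; sizes are
configurable).  For each case the model is trained with the (known active,
query) pair forced positive and *all other* pairs of the query protein
removed, then ranks the hidden active among the decoys.  Tie-aware rank is
`1 + #{strictly greater} + ⌈#ties/2⌉` (a constant scorer over 500
candidates yields 251).  Summaries: the cumulative histogram curve
CHC(r) = fraction of cases solved at rank ≤ r, its area normalized to
[0, 1] (mean of CHC over ranks 1..n), and the top-1% / top-5% fractions
(CHC at ⌊0.01·n⌋ and ⌊0.05·n⌋).

## The synthetic world

The generator produces every input the pipeline consumes, with planted
ground truth so recovery is checkable.  Defaults define the standard study
conditions used throughout the tests: 200 molecules, 30 proteins, 2000
labeled pairs, 5% label-flip noise, 50% positive prevalence.

*Entities are clustered.*  Molecules derive from 20 scaffold fingerprints
(Bernoulli(0.05) over 1024 bits) by per-bit mutation at rate 0.15 (off-bit
activations rescaled to preserve density), giving within-scaffold Tanimoto
similarity around 0.55 — typical of a real chemical series.  Proteins
derive from 6 family base sequences (lengths 30–60, kept short so the LA
kernel stays cheap; real proteins are an order of magnitude longer, which
changes cost but not the math) by per-residue substitution at rate 0.15.
This structure is essential, not cosmetic: with i.i.d. entities both kernel
Grams are near-identity, every pair is an isolated coordinate, and no
method — including an oracle — can transfer information across pairs.

*The planted scorer* acts in the package's own exact kernel feature spaces
(so labels are realizable by the model class; a `raw` variant plants the
scorer on raw fingerprints/compositions for a deliberately misspecified
task).  It has two parts: a rank-4 bilinear form over the leading 16
eigendirections of each side — scaffold/family-level structure-activity
signal — plus a rank-one within-scaffold component (the next 32 molecule
eigendirections against the leading protein direction) carrying 15% of the
score variance.  The fine part behaves like activity-cliff structure: one
latent scalar per molecule, learnable from that molecule's own training
pairs but unpredictable for held-out molecules.  Both fractions are fixed
design constants of the generator.  The bias `b*` is set to the score
quantile that hits the target prevalence; labels are the planted signs,
flipped independently with the noise probability.

*What passing tests show, and what they do not.*  Recovery of the planted
model demonstrates that the pipeline learns a realizable bilinear scorer
through its own feature construction under label noise, and the scenario
ordering (random ≥ unseen_drugs ≥ orphan) shows the splits measure what
they claim.  None of this certifies performance on real bioactivity data,
whose fingerprint statistics, sequence families, measurement error
structure, and label imbalance are all richer than the generator's.

*Recovery is measured against the planted labels.*  With 5% uniform label
flips at 50% prevalence, even the oracle scorer's average precision against
the *noisy* held-out labels is capped near 0.93–0.94 (flipped-in positives
sit deep in the ranking).  Model quality is therefore quantified as AUPR of
cross-validated test-fold scores against the noise-free planted labels —
training still sees only noisy labels — alongside the observed-label AUPR,
which is what λ selection and the scenario comparison use.  A
shuffled-label control (~0.5, the prevalence) verifies the protocol carries
no leakage.  The scenario-ordering comparison fixes λ = 1e−4 (a
mid-grid value) rather than re-selecting per scenario, keeping the
comparison about the splits, not the tuning.

*Bioactivity tables* are generated with distinct base (molecule, protein)
pairs, log-uniform values over [1e−10, 1e−2] M, and a controllable fraction
of second-source duplicates of which a set number carry a mismatched SMILES
(dropped by the structure filter) or a value on the far side of the
conclusive window (a >1-log disagreement that must become nonconclusive);
the generator's bookkeeping of per-stage survivor counts is exact by
construction and is what curation output is compared against.

## Numerical choices

- Eigenvalue clip for feature maps: 1e−10, with automatic rank reduction.
- Gram matrices are symmetrized (`(K + Kᵀ)/2`) before factorization; the
  symmetry invariant is enforced at 1e−10.
- L-BFGS: memory 20, `ftol` effectively disabled (1e−15) so the gradient
  tolerance governs; the homotopy polish adds a bounded number of extra
  L-BFGS runs.
- Probabilities clip the logistic argument at ±500 to avoid overflow.
- Score ties at exactly 0 classify as +1 throughout.
- Batch feature transforms loop the single-entity transform, so batch and
  looped results are bit-identical by construction.
- Prediction TSVs render floats with 17 significant digits and re-read with
  round-trip parsing, so write→read preserves scores exactly.

## Known limitations

- The LA kernel is O(|x|·|y|) per pair in Python/numba; real proteome-scale
  sequence sets would want a compiled batch implementation.
- The greedy negative sampler guarantees ≤1 degree gap only when candidate
  pairs remain; dense positive graphs yield a deficit report instead.
- Platt scaling is fitted on training margins, which slightly biases
  probabilities optimistic relative to calibration on a held-out fold.
- The `raw` (misspecified) planted variant and user-supplied external
  feature vectors are supported but not tuned for; the shipped defaults
  target the realizable setting.
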