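# Methods

## Model and assumptions

`mdboost` treats disease–microbe association prediction as supervised
binary classification over pairs. The working assumptions are the usual
ones for this family of link predictors:

1. *Guilt by association*: diseases with similar known microbe profiles
   (and microbes with similar disease profiles) tend to share partners.
   This is encoded by the Gaussian interaction-profile (GIP) kernel, a
   radial-basis kernel on rows/columns of the adjacency matrix whose
   bandwidth is normalised by the mean squared profile size, so sparser
   datasets get a flatter kernel automatically.
2. *Symptom similarity is informative independently of the adjacency
   matrix*: the symptom-based disease similarity `SDM` is averaged with
   the disease kernel (`SD = (KD + SDM)/2`). Because `SDM` does not
   derive from A, it still carries signal when a disease's interaction
   profile is empty — this is the only reason new-disease prediction
   works at all.
3. *Unknown ≠ negative, but most unknowns are negative*: unknown pairs
   are used as a negative pool. To avoid both class imbalance (~97%
   unknowns) and the bias of a single random draw, the unknowns are
   clustered (k-means, k=23) in pair-feature space and negatives are
   drawn from every cluster, proportionally to cluster size by
   largest-remainder rounding, until the negative count equals
   `round(ratio × positives)`.

The pair feature vector is the concatenation `[SD row i | KM row j]`
(length `nd + nm`). This representation is the main inferential choice in
the package: it is the standard encoding in this literature, it gives the
trees direct access to "similarity to every disease" and "similarity to
every microbe" coordinates, and it makes the feature space independent of
which pair is being scored.

## The boosted scorer

The strong classifier is standard discrete AdaBoost over weight-sensitive
CART trees:

- weighted error `ε_i = Σ_j D_i(j)·1[h_i(j) ≠ y_j]`,
- vote weight `α_i = ½·ln((1−ε_i)/ε_i)`,
- normaliser `Z_i = 2√(ε_i(1−ε_i))` (recorded per round; the weight
  update renormalises explicitly, which is numerically identical),
- update `D_{i+1}(j) ∝ D_i(j)·exp(−α_i y*_j h*_j)` with `y*, h*` the
  0/1 labels mapped to ±1. A literal 0/1 reading of the update would
  leave every weight touching a 0 unchanged and contradict the stated
  intent of up-weighting mistakes; the ±1 mapping is the only reading
  under which `Z_i` is the analytic normaliser.

Rounds whose error reaches 1/2 are rejected and training stops (the trace
keeps accepted rounds only; the stop reason is recorded separately).
A zero-error round has its ε clipped to `epsilon_floor` (1e-10) so α
stays finite, and training stops because further reweighting is
uninformative. The classic bound — thresholded-ensemble training error
≤ Π_i Z_i — is asserted numerically in the test suite on every seeded
synthetic run.

Scoring uses the leaf's weighted positive-class fraction `H_i(j)` rather
than the hard label, giving a graded ranking `s(j) = Σ α_i H_i(j)` in
`[0, Σα_i]`; `hard_votes` restores the hard-label reading.
Classification (`predict`, used for the error bound) always uses hard
votes against the `½Σα` threshold.

### Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `rounds` (T) | 30 | ensemble size; beyond ~30 accuracy plateaus while cost grows |
| `max_depth` | 3 | weak-tree depth cap; see below |
| `k` | 23 | k-means clusters for the unknown pool |
| `negative_to_positive_ratio` | 1.0 | balanced training classes |
| `γ'_d`, `γ'_m` | 1.0 | nominal kernel bandwidths; `γ'_m` set by analogy with the disease side |
| `epsilon_floor` | 1e-10 | keeps α finite for a perfect weak learner |

**Weak-learner depth.** The target concept — "pair (i,j) is plausible" —
is essentially a conjunction: the disease must sit near a positive-rich
disease neighbourhood *and* the microbe near the matching microbe
neighbourhood. Depth-2 trees sit at the edge of expressing one such
conjunction and, in held-out experiments on planted-block data, a depth-2
ensemble memorises identity coordinates and mis-ranks masked pairs
(holdout AUC ≈ 0.47 versus ≈ 0.78 at depth 3). Depth 3 is therefore the
default; it is configurable.

**Split search.** Splits minimise weighted Gini impurity over midpoints
between consecutive distinct sorted feature values. Ties resolve to the
lowest feature index, then the smallest threshold — determinism over
arbitrariness. The training matrix is pre-sorted once per ensemble fit
and the per-feature sorted index lists are filtered down the tree (the
weights change per round, the feature order never does); the inner scan
is JIT-compiled with numba. A depth-1 fit is verified against exhaustive
stump enumeration in the tests.

## Evaluation protocol

Leave-one-out cross validation masks each known pair in turn. By default
the GIP kernels are **recomputed from the masked matrix inside every
fold**: the kernels derive from A, so leaving the held-out 1 inside them
leaks the answer and inflates the AUC (on the default synthetic data the
leaky mode scores noticeably differently). `recompute_kernels=False`
preserves the leaky reading for comparison only. Each fold re-draws its
training set with a seed derived deterministically from (run seed, fold
index), so folds are independent yet the whole run reproduces exactly.

The held-out pair's rank among its comparison set (all unknown pairs
globally; the same disease's unknown pairs locally) is recorded per fold.
The AUC is computed from a single TPR/FPR sweep over rank thresholds —
per-fold score scales differ, so raw scores are never pooled across
folds. The underlying `roc_auc` helper uses the rank-sum (Mann–Whitney)
formula with mid-ranks for ties and is verified against brute-force pair
counting to 1e-12.

Ranking ties in prediction tables break by (score desc, disease label,
microbe label); scores serialise at fixed 6 decimals for bit-stable
diffs.

**New-disease mode** zeroes the queried disease's entire adjacency row,
retrains, and ranks all microbes for it. The query disease's pairs are
excluded from the negative pool (they are the query set). Its GIP profile
is empty, so its `SD` row is driven purely by `SDM` — the model's stated
route to new-disease prediction.

## Synthetic data: what it emulates, what it does not

The generator plants `nBlocks` co-association blocks (round-robin
assignment of diseases and microbes), draws `A(i,j) = 1` with probability
`density_in` inside a shared block and `density_out` otherwise, and
repairs any all-zero row/column with one forced in-block association so
every interaction profile is defined. The symptom matrix is
block-consistent (0.8 within a disease block, 0.1 across) plus clipped
symmetric uniform noise — informative about the planted structure without
deriving from A, the property the real symptom network is used for.

Defaults: 20 diseases × 60 microbes, 4 blocks, `density_in=0.5`,
`density_out=0.02`, `symptom_noise=0.1` (≈170 positives, ≈86% unknown
pairs). At materially sparser settings most microbes carry a single
association; masking such a pair during LOOCV is a pure microbe-side cold
start, and no learner can rank it from these features — with ~100
positives on this shape, global LOOCV AUC stays near chance for boosted
trees, logistic regression and sklearn's AdaBoost alike. The default
density keeps the typical microbe profile informative after one masking
while leaving the task far from saturated.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated databases (many singleton microbes), taxonomy
structure, label noise in curation, and symptom similarities estimated
from text co-occurrence. Passing the synthetic recovery tests therefore
demonstrates that the pipeline recovers plantable block structure under
honest masking — not that it attains any particular AUC on real curated
data, where cold-start pairs are more common.

The degree-preserving permuted control re-places the same number of
associations uniformly at random: it preserves density (up to a few
forced repairs) while destroying the block correspondence, and the
pipeline's AUC advantage over it is the package's end-to-end signal
check (≥18/20 seeded replicates).

## Numerical and degenerate-input choices

- Squared profile norms are exact integer popcounts before any division.
- Similarity matrices validate symmetry (1e-12), unit diagonal and [0,1]
  range at construction; external matrices are symmetrised, clipped with
  a warning, and their diagonal forced to 1.
- Training weights must stay strictly positive and sum to 1 within 1e-9
  after every update (asserted in tests).
- An all-zero adjacency matrix is rejected at the kernel stage ("empty
  interaction profiles"); a training set whose best stump cannot beat
  chance raises rather than returning a vacuous model.
- k-means uses k-means++ with a single seeded restart, 300-iteration cap
  and tolerance 1e-4: reproducibility is preferred over marginal inertia
  gains.
- Sub-seeds derive from `SeedSequence([seed, *keys])` and stay below
  2^31.

## Problem sizes used in the shipped analyses

The acceptance script and the stochastic tests run the default 20 × 60
generator (≈170 positives, ≈170 LOOCV folds per run) with 20 replicates
for the recovery checks, and a 39 × 292 matrix with 450 pairs for the
unknown-pair bookkeeping. These sizes keep a full honest-LOOCV replicate
set in the minutes range on one CPU while leaving every stage of the
pipeline exercised at realistic sparsity.

## Known limitations

- The pair-feature encoding is an inference (the usual one in this
  literature); other encodings (e.g. kernel products) are not explored.
- Microbe-side cold starts are unsolvable by construction: a microbe with
  one known association cannot be ranked for it under honest masking.
  The symptom matrix rescues disease-side cold starts only.
- The ensemble may favour microbes with many known associations
  (profile-degree bias inherited from the GIP kernel).
- No microbe–microbe similarity from sequence data is used; `KM` derives
  solely from A.
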