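# mdboost

Microbe–disease association prediction by adaptive boosting of decision
trees over interaction-profile and symptom similarities.

## The problem

Curated databases of literature-supported disease–microbe associations
(e.g. genus-level lists of a few hundred pairs over a few dozen diseases
and a few hundred microbes) cover only a tiny fraction of all candidate
pairs — typically ~97% of the disease × microbe matrix is unknown.
`mdboost` scores every unknown pair with a relation probability so that
laboratory validation can be prioritised, and it can rank microbes for a
*new* disease that has no known associated microbes at all.

## The model

Let **A** be the binary `nd × nm` adjacency matrix over diseases and
microbes. Each disease's interaction profile `IP(d(i))` is row *i* of A;
each microbe's is a column. Similarities:

- **Gaussian interaction-profile (GIP) kernel**:
  `KD(i,j) = exp(−γ_d ‖IP(d(i)) − IP(d(j))‖²)`, with bandwidth
  `γ_d = γ'_d / mean_i ‖IP(d(i))‖²` and `γ'_d = 1` (microbe kernel `KM`
  analogous).
- **Symptom-based disease similarity** `SDM` (supplied as a square TSV) is
  fused with the kernel: `SD = (KD + SDM) / 2`. This term is what carries
  signal for diseases with an empty interaction profile.

A pair `(i, j)` is represented by the feature vector
`[SD row i | KM row j]` of length `nd + nm`. Known pairs are positives;
since unknowns vastly outnumber them, the unknown pairs are clustered with
k-means (`k = 23`) in feature space and negatives are drawn from every
cluster, proportionally to cluster size, until the classes are balanced.

The scorer is an AdaBoost ensemble of `T = 30` weight-sensitive CART
trees. Round *i* computes the weighted error `ε_i`, vote weight
`α_i = ½·ln((1−ε_i)/ε_i)` and normaliser `Z_i = 2√(ε_i(1−ε_i))`, then
re-weights samples by `D(j) ∝ D(j)·exp(−α_i y*_j h*_j)` with labels mapped
to ±1. A pair's score is `s(j) = Σ_i α_i·H_i(j)`, where `H_i(j)` is the
positive-class fraction of the leaf the pair reaches.

Evaluation is by leave-one-out cross validation: each known pair is
masked, the kernels are rebuilt from the masked matrix (no leakage), the
model is retrained, and the held-out pair is ranked against all unknown
pairs (**global**) or those of the same disease (**local**); the rank
distribution defines the ROC curve and its AUC.

## Worked example

The bundled generator plants co-association blocks shared between the
adjacency matrix and the symptom similarity, so recovery is measurable:

```sh
$ mdboost simulate --seed 7 --out-dir demo
wrote 176 associations to demo

$ mdboost loocv --associations demo/associations.tsv \
                --symptom-sim demo/symptom_similarity.tsv \
                --mode global --seed 0 --out-dir demo
global LOOCV AUC = 0.8184 (176 folds); ROC -> demo/roc_global.tsv
```

An AUC of 0.82 over 176 folds means a masked true association typically
outranks ~82% of the ~1000 unknown pairs it competes with (0.5 would be
chance). Treating disease `D000` as new — all of its associations hidden —
its microbes are still ranked using symptom similarity alone on the
disease side:

```sh
$ mdboost new-disease --associations demo/associations.tsv \
    --symptom-sim demo/symptom_similarity.tsv --disease D000 --out demo/nd.tsv
ranked 60 microbes for 'D000' -> demo/nd.tsv
$ head -4 demo/nd.tsv
disease	microbe	score	rank
D000	M045	4.906732	1
D000	M053	4.889967	2
D000	M038	4.785277	3
```

Scores are `Σ α_i H_i` values (here bounded by `Σ α_i ≈ 12`); the rank
column is what matters for prioritisation. With real data, pass your own
pair list and symptom-similarity TSVs to the same commands.

## Layout

- `src/mdboost/data.py` — containers and TSV I/O (pair lists, similarity
  matrices, prediction tables)
- `src/mdboost/similarity.py` — GIP kernels, symptom fusion, alignment
- `src/mdboost/sampling.py` — pair features, k-means undersampling,
  training-set assembly
- `src/mdboost/boosting.py` — weighted CART weak learner and the
  `PairBoostClassifier` ensemble (scikit-learn-style estimator)
- `src/mdboost/evaluation.py` — LOOCV, ranking, new-disease prediction
- `src/mdboost/simulate.py` — seeded planted-block data generator
- `src/mdboost/cli.py` — `mdboost simulate | loocv | rank | new-disease`

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
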