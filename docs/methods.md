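# Methods

## Problem and model

`resqa` estimates the local accuracy of a single protein structural
model: for residue *i*, the distance *d_i* (Å) between its position in
the model and in the native structure after least-squares CA
superposition. The estimator is an epsilon-insensitive support-vector
regression with an RBF kernel over windowed features; the window (15
residues, 7 on each side of the target residue) captures the local
structural context. The premise is that a model is locally wrong exactly
where the structural properties parsed from its own coordinates disagree
with properties predicted independently from sequence: sequence-based
predictors approximate the *native* structure, so disagreement flags
model error, not predictor error, often enough to carry signal.

Per window position the feature block is, in frozen order:

| columns | content | range |
|---|---|---|
| 1–20 | amino-acid one-hot (basic) or logistic-squashed PSSM row (profile) | {0,1} / (0,1) |
| 21 | parsed secondary structure == predicted (3-state) | {0,1} |
| 22 | parsed exposure == predicted (2-state, RSA ≥ 0.25 = exposed) | {0,1} |
| 23 | mean predicted contact probability over observed contacts | [0,1] |

Window positions outside the chain contribute all-zero blocks; the
*profile+SOV* set appends one whole-chain SOV'99 scalar. Dimensions:
15·23 = 345, or 346 with SOV. The amino-acid column order is alphabetical
by one-letter code throughout; file-format orders (PSSM) are remapped at
read time.

Local predictions are clamped at zero (they are distances) and reduced to
a global score by `(1/L) Σ 1/(1+(d_i/c)²)` with c = 5 Å — each term is a
residue-level similarity in (0,1], so the global score is bounded,
equals 1 only at zero deviation, and decreases strictly in every d_i.

## Structural properties parsed from a model

* **Secondary structure** — a self-contained re-implementation of the
  hydrogen-bond part of the DSSP algorithm: electrostatic bond energy
  `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol`, bond iff
  E < −0.5 kcal/mol; helices need two consecutive n-turns (n = 3, 4, 5),
  strand residues come from parallel/antiparallel bridge patterns; the
  8-state alphabet is reduced by H,G,I→H, E,B→E, else C. Amide hydrogens
  are placed geometrically (N–H along the previous O→C direction, proline
  excluded as donor); missing carbonyl oxygens are reconstructed in the
  peptide plane, so backbone-only models are handled. Against mdtraj's
  DSSP implementation on synthetic mixed fixtures the 3-state agreement
  is above 80% (the discrepancies sit at segment edges).
* **Accessibility** — Shrake–Rupley SASA over heavy atoms (biotite),
  normalised by the Tien et al. theoretical maximum ASA per residue type
  and clamped to [0,1]; 2-state exposure at RSA ≥ 0.25, equality counting
  as exposed.
* **Contacts** — CA–CA distance ≤ 8 Å at sequence separation ≥ 6, both
  thresholds inclusive, symmetric.

All three are invariant under rigid motion of the model (property-tested).

## Training protocol

Cross-validation groups all residues of one model into the same fold —
residues of a model are strongly dependent, and fold leakage would
flatter the error estimate. Group keys are sorted, shuffled with the
seeded generator and dealt round-robin, so the assignment is invariant to
example order. The CV objective is the pooled mean absolute error on
held-out folds, matching the absolute-difference-error metric used for
evaluation; ties break deterministically toward the smallest
(cost, epsilon, gamma). Default grids: cost {0.1, 1, 10}, epsilon
{0.1, 0.5, 1.0}, gamma {0.001, 0.01, 0.1}. Training targets are capped at
15 Å by default (configurable, can be disabled): real deviations are
heavy-tailed and uncapped regression is dominated by the tail. Models
that lack any target residue or CA atom are rejected ("partial models
are discarded"); an explicit override keeps them.

## Evaluation machinery

Ground-truth deviations use a single whole-chain least-squares CA
superposition (Kabsch, SVD form, det(R) = +1 enforced — mirror solutions
are never accepted). This is a documented approximation of
assessment-grade practice, which uses sequence-dependent, trimming
superpositions; a single global fit slightly inflates deviations of
well-modelled regions when another region is grossly wrong. Local
predictions are scored by mean |pred − real|, by that error binned on
real deviation rounded to the nearest integer Å (bins under 10 points
flagged sparse), and by per-model Pearson correlation (constant vectors
excluded as undefined). Global predictions are scored per target by
average and pooled correlation, the mean true quality of each target's
top-ranked model, and the ranking loss (best true quality minus
top-ranked true quality). The true global score for ranking is the same
S-score form applied to real deviations, keeping the evaluation
internally consistent; assessment-style GDT-TS is deliberately not
computed.

## Synthetic data generator

The generator makes the whole loop runnable offline and defines the
conditions of the package's own benchmark.

* **Natives** — backbones (N, CA, C, O, CB) grown from ideal internal
  coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°;
  helix φ/ψ = −57/−47°, strand −120/+120°, coil from a fixed 5-torsion
  set), with a self-clash constraint (CA–CA ≥ 3.5 Å for |i−j| > 2). Open
  chains carry almost no long-range contacts, which would leave the
  contact feature dead, so among clash-free torsion samples the most
  compact is kept and then collapsed further by greedy coil-torsion moves
  that minimise the radius of gyration — giving fold-like chains with
  genuine contacts and buried residues. Sequences are sampled from
  state-conditioned residue pools (helix/strand formers inside segments).
* **Decoys** — a hinge rotation at a random coil position (angle
  ~N(0, 10°)) plus per-residue rigid displacements from a Gaussian field
  smoothed along the chain (unit-norm kernel, variance preserving):
  model errors are locally coherent, so neighbouring residues move
  together and local geometry survives where the noise is small. The
  displacement sigma follows a smooth per-target profile
  (0.3–1.7 × base) scaled per decoy by quality levels
  {0.4, 0.8, 1.3, 1.9, 2.6} × 1.5 Å, so every target has a graded set of
  models. True deviations are measured by superposing each decoy back
  onto its native.
* **Annotations** — "predicted" secondary structure and exposure are the
  native's parsed truth with states flipped at base rate 0.12,
  preferentially where deviations are large: flip probability
  `sigmoid(logit(rate) + linkage·z)` with z the standardised deviation
  profile and linkage 0.6. This rule is exact at the endpoints (rate 0
  never flips, rate 1 always flips). Contact probabilities are Beta
  distributed (concentration 8) around 0.8 for native contacts and 0.15
  for an equal number of random non-contact pairs; the PSSM is a noisy
  one-hot log-odds profile. The corruption–deviation linkage is the
  learnable signal, and each corpus is verified to exhibit a positive
  correlation between window feature corruption and true deviation.

Everything is a pure function of (spec, seed); writers for every input
format round-trip exactly through the package's readers.

### What the generator does and does not emulate

It emulates the *structure* of the learning problem — graded decoys,
locally varying error, sequence-based annotations that are mostly right
and wrong preferentially in bad regions — but not real physics: no side
chains beyond CB, no realistic beta-sheet topologies (isolated strands
assign as coil), idealised bond geometry, and an error process whose
conditional scatter (|3-D Gaussian| given its sigma) is larger than the
feature set can fully resolve. Passing the benchmark therefore shows the
pipeline is correctly wired and recovers a designed signal; it does not
certify accuracy on real CASP-style data.

## Benchmark problem sizes and observed behaviour

The package's benchmark (also run by `scripts/acceptance.py`) uses
8 targets × 5 decoys of length 50–70 (~2,500 residues), trains on six
targets (~1,850 examples, 27 grid triples × 5 folds) and predicts the two
held-out targets. Global-score behaviour is robust: per-target
correlations of predicted versus true global quality are high and the
ranking loss is near zero across seeds. Pooled per-residue correlation on
held-out residues is the harder quantity: an oracle knowing the exact
generating noise field attains r ≈ 0.78 (the intrinsic scatter bound of
the displacement process), a linear model on the 45 informative columns
reaches ≈ 0.54, and the SVR typically lands between 0.35 and 0.6
depending on the seed — the binary match bits and sparse contact
agreement, diluted by 300 sequence columns inside the RBF distance,
cannot fully decode the noise profile from ~1,850 training residues. The
generator's conditions are fixed; they are not adjusted to flatter this
number.

## Numerical and design notes

* SOV'99 is computed in exact rational arithmetic with one final float
  conversion, so independent enumerations of the definition agree
  bit-for-bit; per-state scores with an empty normalisation (state absent
  from the reference string) report 1.0. The observed (model-parsed)
  string plays the asymmetric reference role.
* PSSM log-odds are squashed by the logistic function before use, keeping
  profile features on the same (0,1) scale as the indicator features.
* The columnar secondary-structure reader takes the argmax of the three
  probabilities with ties broken H > E > C; duplicate contact-map pairs
  keep the last value; contact matrices are stored dense and symmetric
  with absent pairs read as 0.
* Internal residue numbering is contiguous 1..L regardless of PDB
  numbering gaps (original ids kept as metadata); MSE and a small table
  of modified residues map to standard letters, anything else to 'X',
  whose amino-acid block encodes as all zeros.
* Missing-residue positions in the completeness report come from a greedy
  left-to-right alignment of the model sequence into the target sequence;
  with equal lengths, mismatching positions are reported instead.
* Seeds: every stochastic step (layout, torsions, decoy noise, annotation
  corruption, fold shuffling) derives from one integer seed through
  numpy `default_rng` seed sequences; repeated runs are bit-identical.

## Known limitations

* Single chain, single domain, PDB only (no mmCIF); no ligands.
* The superposition ground truth is a single global fit, not LGA-style.
* Synthetic strands rarely pair, so the 'E' state is under-represented in
  generated corpora.
* The SVR is not calibrated probabilistically; predicted deviations are
  point estimates.
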