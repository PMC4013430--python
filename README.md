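# resqa

Per-residue error prediction for **single** protein structural models.

Given one predicted tertiary-structure model of a protein (a PDB file) and
a handful of cheap sequence-based predictions — 3-state secondary
structure, 2-state solvent exposure, a residue–residue contact probability
map (CASP RR format) and optionally a PSI-BLAST profile — `resqa`
estimates, for every residue *i*, the absolute distance deviation *d_i*
(Å) between the residue's position in the model and its position in the
(unknown) native structure after optimal superposition. The local
estimates are summarised into one global quality score

```
global = (1/L) · Σ_i 1 / (1 + (d_i / c)²) ,   c = 5 Å
```

(the Levitt–Gerstein / S-score form), which lies in (0, 1] and equals 1
only for a perfect model. This is the *single-model* flavour of model
quality assessment: no ensemble of alternative models is needed, and the
output is an absolute local error, not a relative rank.

## Method

For each residue a 15-residue window contributes, per position, a
23-value feature block: 20 amino-acid indicators (or logistic-squashed
PSSM profile values), one bit recording whether the secondary structure
parsed from the model's own coordinates agrees with the sequence-based
prediction, one bit for the same comparison of 2-state solvent exposure,
and the mean predicted contact probability over the residue's observed
structural contacts (CA–CA ≤ 8 Å at sequence separation ≥ 6). The
*profile+SOV* variant appends the whole-chain segment-overlap (SOV'99)
score between predicted and model-parsed secondary structure. Feature
vectors are 345 wide (346 with SOV). An RBF-kernel support-vector
regressor maps windows to deviations; hyper-parameters (cost, epsilon
tube, gamma) are chosen by grid search under 5-fold cross-validation with
all residues of one model grouped into the same fold.

The package is self-contained: it re-implements hydrogen-bond-based
secondary-structure assignment (Kabsch–Sander energy model), computes
accessibility by Shrake–Rupley SASA normalised per residue type, derives
ground-truth deviations by Kabsch CA superposition against a native
structure, and ships a synthetic native/decoy generator so the full
train → predict → evaluate loop runs offline.

## Worked example

Simulate a small corpus, train on it, and score a model:

```bash
resqa simulate --out demo --seed 7 --n-targets 3 --n-decoys 3

# featurize every decoy of every target with native-derived targets
for t in T000 T001 T002; do
  for k in 0 1 2; do
    resqa featurize demo/targets/$t/model_$k.pdb demo/targets/$t/target.fasta \
        demo/targets/$t/ss.pred demo/targets/$t/acc.pred demo/targets/$t/contacts.rr \
        --native demo/targets/$t/native.pdb --out demo/${t}_$k.tsv
  done
done

resqa train demo/T000_*.tsv demo/T001_*.tsv -c 1 -w 0.3 -g 0.01 \
    --folds 3 --seed 0 --out demo/model.joblib
resqa predict --model demo/model.joblib \
    demo/targets/T002/model_1.pdb demo/targets/T002/target.fasta \
    demo/targets/T002/ss.pred demo/targets/T002/acc.pred \
    demo/targets/T002/contacts.rr --out demo/pred.tsv
```

`train` echoes the fitted summary (feature set, 345 columns, chosen
hyper-parameters, CV table) and `predict` prints the derived global
score:

```
global quality score: 0.882883
```

`demo/pred.tsv` holds one row per residue
(`residue_index  aa  predicted_deviation_A`) — here 55 rows, starting

```
1	D	2.5864
2	Q	2.6782
```

— and ends with the same `GLOBAL` line. A score of 0.88 corresponds to
residues displaced by ~2 Å on average on the S-score scale; the
per-residue rows identify which segments carry the error. `resqa eval`
compares such
a prediction file against a model/native pair and reports the mean
absolute difference error, per-model correlation and the error binned by
real deviation.

The same workflow runs unchanged on real inputs: a CASP-style model,
secondary-structure/exposure predictions from tools of the SSPRO family,
contacts in CASP RR format and a PSI-BLAST ASCII PSSM.

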