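# hotspots

Classification of protein–protein interface residues as binding
**hot-spots (HS)** or **null-spots (NS)** from a complex structure and its
sequences.

A hot-spot is an interfacial residue whose mutation to alanine changes the
binding free energy by ΔΔG_binding ≥ 2.0 kcal/mol; null-spots fall below
that threshold. Because alanine-scanning experiments are slow and
expensive, a structure/sequence-based classifier trained on curated
ΔΔG data offers a fast computational surrogate. This package provides the
whole workflow as a library plus a command-line tool: feature extraction
from PDB complexes, the preprocessing regimes, classifier benchmarking and
clustering, and the final stacked ensemble.

## Method

**Features.** For a two-partner complex (chain groups given by the user;
their order is irrelevant), interfacial residues are those buried on
complexation, ΔSASA = SASA_monomer − SASA_complex > 0, with solvent
accessibility computed by Shrake–Rupley quadrature (probe 1.4 Å, 960
sphere points, Bondi radii). Each interfacial residue carries:

* 12 SASA features — absolute complex/monomer/ΔSASA, the same three
  normalised by the residue type's theoretical Gly-X-Gly maximum,
  side-chain complex/monomer/ΔSASA, the buried fraction ΔSASA/SASA_monomer,
  and complex/monomer SASA relative to the same-type mean;
* 3 contact counts — intermolecular atomic contacts within 2.5 Å and
  4.0 Å, and C–C contacts ≤ 4.5 Å between apolar residues;
* 20 interfacial composition counts (protein-level, one per amino-acid
  type);
* protein-level sequence descriptors per chain group — amino-acid
  composition, Chou's pseudo amino-acid composition (PAAC, order λ,
  weight w), amphiphilic PAAC, and auto/cross-covariances of the top-5
  BLOSUM62 principal-component projections;
* optionally 40 positional PSSM features (20 log-odds + 20 weighted
  observed percentages) from an externally produced ASCII profile.

**Training regime.** Observations are labelled HS iff ΔΔG ≥ 2.0 kcal/mol
and split 70/30 stratified by class. Six dataset variants are built:
z-scoring (sample sd, train statistics reapplied to test), optionally
followed by PCA retaining the fewest components with Σλᵢ/Σλ ≥ 95%, each
optionally followed by up-sampling of the minority class (with
replacement, preserving every majority row) or down-sampling of the
majority.

**Model.** Candidate classifiers are described by binary capability tags;
complete-linkage hierarchical clustering of Jaccard distances over the
tags yields five clusters, whose separation in metric space is testable
by one-way MANOVA (Pillai trace). A representative scikit-learn registry
spanning the clusters is benchmarked with repeated stratified 10-fold CV
(resampling applied inside each training fold), and the champion of each
cluster maximises AUROC + TPR + TNR. Champions are stacked by a logistic
meta-model

    logit(π) = β₀ + Σᵢ βᵢ Xᵢ

fitted on their **out-of-fold** binary classifications and pruned by
bidirectional stepwise selection on Wald statistics (α = 0.05). A residue
is called HS when π ≥ 0.5.

## Worked example

Everything below runs on synthetic fixtures generated by the package
itself:

```bash
# a two-chain complex with a 5-residue contact patch
hotspots simulate --kind complex --out complex.pdb --seed 4 \
    --n-residues 12 --patch-size 5
# wrote 119 atoms; 12 residues in contact

hotspots extract complex.pdb --chains A:B --out features.csv \
    --paac-lambda 4 --acc-lag 3
# wrote 12 interfacial residues to features.csv

# a labelled table emulating the curated dataset's imbalance (~24% HS)
hotspots simulate --kind table --out train.csv --seed 5
# wrote 534 observations (123 HS)

hotspots train train.csv --out-dir run/ --seed 1 --folds 3 --repeats 1
# champions: {'I': 'LogitBoost', 'II': 'pda', 'III': 'plr', 'IV': 'nb', 'V': 'svmRadial'}
# meta-model keeps: ['LogitBoost', 'nb', 'pda', 'svmRadial']
#        AUROC  Accuracy    TPR    TNR    PPV    NPV    FDR    FNR     F1    MCC
# train  1.000     0.997  0.993  1.000  1.000  0.993  0.000  0.007  0.997  0.993
# test   0.951     0.906  0.703  0.967  0.867  0.915  0.133  0.297  0.776  0.724
```

The report rows are the stacked model's metrics on the 70% training and
the held-out 30% split: an AUROC of 0.95 on held-out data means the
planted informative block was recovered; the train row is near-perfect
because the champions are flexible learners on separable data.
`predict` needs a model trained on structure-extracted features (same
schema), and then assigns every interfacial residue to exactly one of
the two output tables:

```bash
hotspots predict run2/model.joblib complex.pdb --chains A:B \
    --out-dir pred/ --paac-lambda 4 --acc-lag 3
# 0 HS / 12 NS -> pred
```

writing `hotspots.csv` / `nullspots.csv` with columns chain, residue
number, residue name, probability, classification.

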