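# Methods

This note documents the models and numerical choices behind the package,
what the synthetic generators emulate, and the known limitations.

## Problem and labels

Binding hot-spots are interfacial residues whose alanine mutation raises
the binding free energy by at least 2.0 kcal/mol; the boundary is
inclusive (ΔΔG = 2.0 → HS). Observations with missing ΔΔG are excluded
from training with a logged count. HS is the positive class in every
metric.

## Structure handling

PDB input is reduced to protein ATOM records. Alternate locations keep
the highest-occupancy conformer (ties: first encountered). Modified
residues with an unambiguous parent (MSE→MET, SEP→SER, …) are renamed;
other non-standard residues are dropped with a warning. Structures are
accepted with or without hydrogens and all features are computed on the
atoms present; note that the 2.5 Å contact channel is hydrogen-sensitive,
so protonated and unprotonated inputs are not directly comparable there.
Residue identity is (chain, author residue number, insertion code) end
to end; no renumbering ever happens.

## SASA and the interface definition

Solvent accessible surface area uses Shrake–Rupley quadrature with a
1.4 Å water probe, 960 quasi-uniform (golden-spiral) sphere points per
atom and Bondi van der Waals radii (defaults; points and radii are
configurable). Side-chain subtotals exclude N, CA, C, O, OXT and
backbone hydrogens. A residue is interfacial when its SASA in the
isolated binding partner exceeds its SASA in the complex by more than
1e-6 Å² — burial on complexation. This threshold is a numerical guard,
not a biophysical parameter: quadrature noise is orders of magnitude
above machine epsilon but strictly zero for atoms with no intermolecular
neighbour within the occlusion bound, so any positive tolerance below
~1e-3 Å² gives identical interfaces.

The 12 SASA features per residue span the absolute / normalised / ratio
families: complex, monomer and ΔSASA; the same three divided by the
residue type's theoretical Gly-X-Gly maximum (Tien et al. 2013 values,
shipped as a configurable table); side-chain complex, monomer and
ΔSASA; the buried fraction ΔSASA/monomer (defined 0 when the monomer
SASA is 0); and complex (monomer) SASA relative to the mean over
same-type residues in the complex. The set is configurable because
several closely related 12-feature conventions exist in the
SASA-predictor lineage.

## Contacts

Contacts at cutoff c count intermolecular atom pairs with distance ≤ c;
2.5 Å and 4.0 Å channels are attached per residue. Hydrophobic contacts
count carbon–carbon pairs ≤ 4.5 Å where both carbons belong to residues
in {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO} — the most common
operationalisation of an "intermolecular hydrophobic interaction".
Cross-group conservation (Σ over group A equals Σ over group B) and
monotonicity in the cutoff are enforced by property tests.

## Sequence descriptors

Protein-level descriptors are computed on the concatenated sequence of
each chain group and attached to every residue observation of that
group:

* **AAC** — the 20 residue-type fractions.
* **PAAC** (order λ = 30, weight w = 0.05 by default, both configurable;
  λ must be below the sequence length) — Chou's pseudo amino-acid
  composition. The three scales (Tanford hydrophobicity, Hopp–Woods
  hydrophilicity, side-chain mass) are standardized over the 20 amino
  acids with the population (n = 20) standard deviation; correlation
  factors average the mean squared scale differences at each lag; the
  20 + λ entries share one normalisation and sum to 1.
* **APAAC** — amphiphilic variant with separate hydrophobicity and
  hydrophilicity channels. The correlation terms are lag products of the
  standardized scale values (the published product form), so for a
  homopolymer they equal the residue's squared scale value rather than
  vanishing; the 20 + 2λ entries still sum to 1 by construction.
* **Substitution-matrix covariances** — each residue is projected onto
  the top-5 principal components of BLOSUM62 (taken from biopython's
  substitution matrices); auto- and cross-covariances of the centred
  projections up to lag 7 give k²·lag = 175 values. Any 20 × k scale
  matrix (fingerprint or physicochemical scale sets) can be plugged in
  with the identical contract; centring makes the descriptor invariant
  to per-column scale shifts.
* **PSSM** (40 per residue) — log-odds and weighted observed
  percentages at the residue's own position, read from an externally
  produced ASCII profile. Profile generation depends on the search tool
  and database, so the package deliberately has no internal homology
  search; with no profile supplied the 40 features are imputed as zero
  and a `pssm_imputed` flag column is set. Profiles declaring fewer than
  10 homologs (configurable) raise a structured error.

## Preprocessing

Z-scores use the training mean and the **sample** (ddof = 1) standard
deviation; test data always reuse the training statistics.
Zero-variance columns are dropped and recorded (their z-score is
undefined). PCA is fitted on the scaled training block and retains the
smallest d with cumulative explained variance ≥ 95%. Up-sampling draws
the minority class with replacement until it matches the majority,
keeping every majority row exactly once; down-sampling subsamples every
class without replacement to the minority size. The six variants are
Scaled, ScaledUp, ScaledDown, PCA, PCAUp, PCADown, composed
scale → [PCA] → [resample].

The stratified 70/30 split fixes the total training size at
round(0.7·n) and allocates per-class sizes by largest remainder, which
reproduces both documented cases exactly (127/407 → 89 + 285 = 374
train, 160 test; a 5/5 table at 50% → 5/5). A plain per-class rounding
cannot satisfy both, since 0.7·127 and 0.7·407 both round up while a
2.5/2.5 split must round one class down.

## Benchmarking and clustering

The 51 candidate algorithm names are characterised by binary capability
tags (55-tag vocabulary); Jaccard distances feed complete-linkage
hierarchical clustering cut at five clusters. The cut happens after the
first n − k merges (R's `cutree` convention) rather than at a height
threshold: Jaccard distances produce many tied merge heights of 1.0, at
which a horizontal cut cannot yield exactly five clusters. Rows enter
the linkage in lexicographic order so tie-breaks are deterministic, and
champion ties also break lexicographically.

The shipped registry implements a representative subset of the
catalogue with scikit-learn (random forest, gradient-boosted trees,
plain and L2-penalised logistic regression, polynomial- and RBF-kernel
SVM, k-NN, Gaussian naive Bayes, LDA, regularised QDA, and a shrinkage
discriminant standing in for penalised discriminant analysis); it spans
all five clusters. Benchmarking uses repeated stratified k-fold CV
(default 10 × 10) with up-/down-sampling re-applied **inside each
training fold only** — resampling before fold assignment would leak
duplicated minority rows across folds and inflate the CV metrics.
Models that fail a fold are kept with the surviving folds; models that
fail everywhere are omitted with a warning. The champion of each
cluster maximises AUROC + TPR + TNR. One-way MANOVA on the
per-algorithm metric vectors uses the standard Pillai trace
V = Σ λᵢ/(1+λᵢ) over the eigenvalues of H E⁻¹ with the usual F
approximation (verified against statsmodels).

## The stacked ensemble

Default base learners are the random forest, polynomial-kernel SVM and
shrinkage discriminant (champion selection can replace them). The
logistic meta-model is fitted on **out-of-fold** base classifications
produced by internal stratified k-fold cross-fitting (default 5 folds),
never on in-sample base outputs; a fitted model records this provenance
flag. Base outputs are binary labels by default, with a switch to use
probabilities.

Bidirectional stepwise selection adds the candidate with the smallest
coefficient p-value (enter if p < 0.05) and removes the included
covariate with the largest p-value (drop if p > 0.05), scanning in
lexicographic order. With near-perfect base learners the logit is
(quasi-)separated and Wald statistics degenerate (Hauck–Donner), so the
forward step falls back to a one-degree likelihood-ratio test in that
regime, and the backward step is skipped under separation; the final
model falls back to a lightly L2-penalised fit when the MLE diverges,
flagged on the model. If everything is removed the intercept-only model
is kept, flagged. Prediction applies the logit inverse and calls HS at
π ≥ 0.5 (boundary inclusive; threshold configurable in (0, 1)).

Model archives (joblib) embed the preprocessing state and a schema
version; loading verifies the version and reproduces predictions
bitwise.

## Synthetic data

The table generator emulates the curated alanine-scanning dataset's
study conditions: 534 observations from 53 complexes with ~24% HS (the
"curated-style" variant pins exactly 127/407 and 881 feature
columns), ΔΔG values drawn consistently with the labels around the
2.0 kcal/mol boundary, and an informative feature block whose class
means differ by a fixed effect size (default 0.8 σ over 30 of 881
features — comfortably separable, matching the parameter-recovery
design) among standard-normal noise. It does **not** emulate feature
correlation structure, per-complex batch effects, measurement error in
ΔΔG, or the mixed discrete/continuous nature of real descriptors; tests
passing on it demonstrate correctness of the pipeline mechanics and
recoverability of planted signal, not real-data accuracy.

The complex generator builds two parallel synthetic chains (3.8 Å
residue spacing, five-atom residue templates) with a contiguous contact
patch pulled to a chosen separation (default 4 Å) against a 30 Å
background, and records per-residue minimum intermolecular distances.
Residues with a pair below 4.5 Å are guaranteed buried; residues with
no pair below the occlusion bound (r₁ + r₂ + 2·probe < 6.4 Å) are
guaranteed not buried — these two sets bracket the true interface and
serve as the oracle in tests. The geometry is deliberately artificial:
it exercises the SASA/contact machinery, not protein stereochemistry.

## Problem sizes

Library defaults follow the documented regime (10 × 10 CV, λ = 30).
The test suite and the acceptance script use reduced sizes chosen as
sensible demonstration scales — 3–5 fold CV with 1–2 repeats, three
retraining seeds, 20 stepwise-recovery seeds, 240–960 sphere points on
small fixtures — all overridable through the public parameters.

## Known limitations

* The exact published train/test membership is unrecoverable (the
  original split seed is unpublished), so retrained metrics are
  reported as a distribution over seeds rather than point matches.
* The capability-tag table is curated; a few algorithms may cluster
  differently from the original dendrogram.
* No internal protonation, structure repair or mmCIF support.
* PCA components are dense linear combinations; per-feature
  interpretability is lost on the PCA variants.
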