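# Methods

## The problem

A temperature-sensitive (TS) mutant carries a single amino-acid substitution
that leaves the protein active at a permissive temperature (roughly
25–30 °C) but inactivates it at a restrictive temperature (37 °C and above).
TS alleles are prized tools for conditional loss-of-function genetics, but
only a few percent of random substitutions produce one. `tsmut` implements a
statistical route to them: describe every candidate substitution by sequence
and structure features of its site and of its *neighborhood*, and rank
substitutions by a fitted posterior probability of temperature sensitivity.

## Neighborhood definitions

Given a single chain with Cα coordinates, a mutation site `i` has three
neighborhoods, each excluding the site itself:

* **sequence** — residues within ±w chain positions (default w = 11,
  truncated at the termini);
* **Euclidean** — residues whose Cα lies within radius r of the site's Cα
  (default r = 13 Å, boundary inclusive);
* **topological** — residues that share a Delaunay tetrahedron (hence a
  Delaunay edge) with the site, capped at the same radius r. By
  construction the topological neighborhood is a subset of the Euclidean one
  at equal radius.

The Delaunay tessellation is computed on the Cα point set (Qhull via
`scipy.spatial.Delaunay`; an optional deterministic joggle handles
cospherical degeneracies at the cost of exact Delaunayhood). Each
tetrahedron containing the site is classified by how its four chain
positions split into maximal runs of consecutive indices:
{4}→I, {3,1}→II, {2,2}→III, {2,1,1}→IV, {1,1,1,1}→V. Only the partition
classes matter downstream (counts per class); the numeral assignment is a
labelling convention.

## Features

The engine emits ~160 named features per substitution: physicochemical
change at the site (hydrophobicity, volume, charge, Grantham dissimilarity,
3+3 class indicators and the 9 class-substitution indicators, of which
exactly one fires), solvent accessibility (Shrake–Rupley, 960
golden-spiral points, probe 1.4 Å; relative accessibility via a bundled
tripeptide max-ASA table), residue and side-chain thermal factors with
z-scores over the chain (population standard deviation; Gly side chains
fall back to the residue value), per-column alignment conservation (Shannon
entropy and relative entropy in bits, gaps excluded, background = pooled
alignment composition), secondary-structure and functional-site annotations
when supplied, and — per neighborhood — the member count, the 20-D
residue-count vector, mean physicochemical/burial/thermal/conservation
aggregates, the hydrophobic moment of the sequence window (100° turn
angle), geometric hydrogen-bond and salt-bridge counts (N/O pairs ≤ 3.5 Å;
side-chain N⁺/O⁻ pairs of Lys/Arg/His × Asp/Glu ≤ 4.0 Å), and
Delaunay-tetrahedron counts by connectivity type.

Missing values (no alignment, no annotations, empty neighborhood, Cα-only
structures) are carried in an explicit mask, never silently imputed at
feature time. Mutant-side structural features are approximated from the
wild-type structure: mutant SASA equals wild-type SASA and mutant RSA
renormalizes it by the mutant's max-ASA. The "unusual residue" indicator
set defaults to {Gly, Pro, Cys} and the turn-breaker set to
{Val, Ile, Leu, Met, Phe, Trp}; both are configurable guesses, not
reconstructions of any external convention.

## Classifier

The model is a two-stage, class-weighted logistic regression:

1. **Selection.** Least-angle regression with the Lasso modification runs
   on the weighted least-squares surrogate (class weights folded into row
   weights, features standardized to weighted mean 0 / sd 1, y ∈ {0,1}
   centered). The selection point along the path is chosen by K-fold
   cross-validated deviance of the downstream logistic refit (default
   K = 5); `--lasso-steps` forces a step count instead.
2. **Refit.** A plain weighted logistic regression on the selected subset,
   fitted by damped iteratively-reweighted least squares to gradient
   tolerance 1e-8, yields P(TS|x) = σ(β₀ + Σ βᵢ xᵢ). Perfect separation is
   detected by fully saturated fitted probabilities and resolved by a
   1e-6 ridge with a warning.

Positive and negative examples are weighted inversely to their class
counts, normalized so total weight equals n — training behaves like a
50-50 TS/neutral mixture regardless of the corpus imbalance. Imputation of
masked cells uses weighted training means, stored in the model so test-time
imputation never peeks at test data. Standardization before the LARS stage
is required for scale-free selection and is absorbed into the stored model
constants, so predictions are invariant to affine rescaling of any input
feature.

## Evaluation

Five measures, threshold 0.5 (p ≥ t predicts TS, inclusive):

* ACC = (TP+TN)/n and MCC (any zero denominator factor ⇒ MCC = 0);
* KL = Σᵢ P(i) log₂(P(i)/Q(i)) between predicted and observed class
  probabilities over {TS, neutral};
* DD — the same divergence applied to the 10-bin histograms of posterior
  probabilities of the two classes over [0,1] (an `empirical` range option
  bins over the observed score range instead); empty bins are smoothed with
  ε = 1e-10; DD = 0 iff the binned distributions coincide;
* AUC — the Mann–Whitney probability with ties counted ½, with a
  trapezoid-consistent ROC curve; precision–recall curves stop at the first
  threshold achieving full recall.

Cross-validation is stratified k-fold (default k = 10) with pooled
out-of-fold scoring (a per-fold-averaged mode is available); the fold
builder reduces exactly to leave-one-out at k = n. A leave-one-protein-out
scheme holds out all mutations of one protein per fold and emits one report
per scorable protein. Measure concordance across single-feature classifiers
uses Pearson correlation and mutual information with 10 equal-width bins
per measure.

## Synthetic data

The generator stands in for a mutagenesis corpus; it emulates the
*geometry and statistics* the pipeline consumes, not protein physics:

* **structures** — self-avoiding random walks with Cα–Cα bonds of
  3.8 ± 0.01 Å, non-consecutive separation ≥ 4.0 Å, and a compactness bias
  toward the centroid (default 0.55, enough to give interior residues
  Delaunay coordination like a globular fold). Each residue carries
  backbone N and O atoms and (except Gly) a CB pseudo side chain.
  B-factors increase with distance from the centroid (coupling 0.8,
  mean 20 Å², sd 8 Å²) so burial and rigidity correlate as in crystal
  structures.
* **alignments** — the first row is the structure's sequence; a configurable
  fraction of columns (default 0.4) is conserved with strength 0.9
  (probability a row copies the consensus), the rest uniform. Subfamily
  alignments use full strength, superfamily alignments 0.6× (more diverse).
* **labels** — Bernoulli draws from a logistic truth model over
  cohort-standardized features computed by the *real* pipeline, with the
  ground-truth probabilities stored. The default truth model weights only
  structural-neighborhood features (burial, packing density, neighborhood
  rigidity and conservation, tetrahedron count), expressing the hypothesis
  that the environment of a buried residue determines temperature
  sensitivity.

Default cohort sizes (80 residues, 300–400 substitutions) keep a full
simulate→featurize→fit→evaluate cycle in seconds while leaving class counts
large enough for stable ten-fold statistics. What passing tests on these
cohorts shows is that the machinery — features, selection, weighting,
scoring — behaves as specified and that the neighborhood-over-site contrast
is recoverable when it is present in the generative truth; it does not
show that real TS corpora have that structure, and no dataset-dependent
headline number is claimed.

## Numerical choices

* SASA: 960 sphere points (quadrature error ~1–2%); fixed lab-frame
  directions make SASA exactly translation-invariant but only
  approximately rotation-invariant, like any fixed-quadrature
  Shrake–Rupley.
* Thermal-factor z-scores: population (not sample) standard deviation; a
  constant-B chain yields z = 0.
* Entropy: no pseudocounts, no sequence weighting; all-gap columns are
  missing. The pooled-composition background makes relative entropy
  strictly finite wherever a column has mass.
* LARS: breakpoint ties and sign crossings resolved at tolerance 1e-10;
  active-set correlations tie to 1e-6 at every breakpoint (tested).
* Buried threshold rsa ≤ 0.05 inclusive; neighborhood radius boundary
  inclusive; the site is excluded from its own neighborhood aggregates
  (a config switch folds it in).

## Known limitations

* Conservation scores that require external profile software (positional
  hidden-Markov-model scores), disorder predictors, ΔΔG calculators and
  ligand-site databases are out of scope; the annotation pass-through
  accepts their outputs as files instead.
* Hydrogen bonds and salt bridges use simple distance criteria on heavy
  atoms, not modelled hydrogens or energetics.
* Mutant side chains are not modelled; mutant-side features are wild-type
  approximations as described above.
* The synthetic chain generator makes no claim of realistic secondary
  structure or packing beyond bond geometry and excluded volume.
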