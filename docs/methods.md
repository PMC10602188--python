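# Methods

## Scope and model

`stabvar` analyses the association between protein destabilization and
missense-variant pathogenicity in monogenic disease genes. Two
per-variant physical quantities act as pathogenicity scores: the folding
free-energy change ΔΔG (kcal/mol, mutant minus wild type; negative =
destabilizing) and the relative solvent accessibility RSA of the mutated
residue ([0, 1]; low = buried). Both point the same way — pathogenicity
rises as the score falls — so every threshold rule in the package defaults
to "call pathogenic iff score ≤ cutoff", with the boundary itself
predicting pathogenic. ΔΔG and RSA predictors themselves are external
tools; the package consumes their outputs as columns or through the scorer
contract `(sequence, position, wt, mut) → ΔΔG` and never retrains them.

## Synthetic-data generator

The generator produces the study conditions under which the pipeline is
validated. Its defaults model a curated monogenic-disease variant set:

- **ΔΔG**: per label, three predictor columns from a multivariate Gaussian.
  Pathogenic N(−1.5, 1.5²), benign N(−0.3, 1.0²) kcal/mol on each
  predictor — pathogenic variants destabilize more on average, with heavy
  overlap, giving a single-predictor concordance AUC of
  Φ(1.2/√3.25) ≈ 0.747. Inter-predictor correlation 0.6 via a common-factor
  construction: each standardized column is √ρ·Z_shared + √(1−ρ)·Z_own, so
  pairwise Pearson correlation is exactly ρ. A full covariance matrix was
  deliberately not used; the common factor is simpler and sufficient for
  equicorrelated columns.
- **RSA**: Beta(2, 5) for pathogenic (mean 0.29, buried-shifted) vs
  Beta(4, 3) for benign (mean 0.57). RSA is drawn independently of ΔΔG
  within each label, so the two features carry independent evidence — this
  is what the two-feature-synergy test exercises. The implied RSA AUC
  (≈ 0.88, by quadrature of P(X_p < X_b)) is computable via
  `synth.analytic_auc_rsa`.
- **Allele frequencies**: log-uniform, benign in [10⁻³, 0.2] and pathogenic
  in [10⁻⁶, 0.02], so both classes produce values on both sides of the
  0.01 population-frequency filter and the filter is exercised in both
  directions.
- **Significance classes**: default mix 15% benign, 10% likely benign,
  25% pathogenic, 15% likely pathogenic, 30% VUS, 5% conflicting; per-gene
  mixes are jittered with a Dirichlet draw (concentration 4) so the 10%
  gene rule fires both ways. VUS and conflicting rows also receive ΔΔG/RSA
  values — that curation drops them is itself a tested behavior.
- **Residue usage**: uniform over the 20 canonical amino acids by default;
  an `aa_bias` weighting (e.g. Arg-heavy) reproduces the skewed wild-type
  spectra of real clinical databases when wanted.

Determinism: all draws flow through NumPy's PCG64 (`default_rng`); each
operation seeds its own child generator as `default_rng([offset, seed])`
with fixed offsets (11 raw table, 23 annotated, 37 sequences), so outputs
are byte-identical for a given config across runs and platforms and
independent of call order.

What the generator does **not** emulate: evolutionary conservation,
3D structure, per-gene phenotypes, predictor-specific biases, or any
dependence of ΔΔG on residue identity or position. Passing tests therefore
demonstrate correctness of the pipeline's mathematics and bookkeeping under
known ground truth — not performance claims about real clinical variants.

## Curation rules

Three stages in a fixed, audited order (the order is a package decision;
the report makes it reconcilable stage by stage):

1. **Conflict drop** — variants whose clinical significance disagrees
   between sources are removed.
2. **Frequency filter** — benign-side variants with allele frequency
   strictly below 0.01 and pathogenic-side variants strictly above 0.01
   are removed. Values exactly at 0.01 are retained on both sides (the
   rule's wording is "below"/"above"). Missing frequencies are retained by
   default (`keep_missing_af`), on the reading that the filter only acts on
   observed frequencies.
3. **Gene rule** — a gene enters Dataset 1 when its definitive fraction
   (benign + pathogenic over all of the gene's variants) strictly exceeds
   10%, and Dataset 2 when the fraction additionally counting likely
   benign/pathogenic exceeds 10%; Dataset 1 genes are always Dataset 2
   genes. The denominator is the gene's total variant count across all
   significance classes (configurable to labeled-only via `denominator`).
   Exactly 10% is excluded (strict inequality).

Dataset 1 keeps only benign (label 0) and pathogenic (label 1) rows;
Dataset 2 additionally maps likely benign → 0 and likely pathogenic → 1.
VUS never reach either output. Curation is idempotent on its own output.

## Chemistry categories

Five fixed axes over the 20 canonical residues: hydrophobic
{A,C,G,I,L,M,F,P,W,V} / polar (complement); small {A,C,G,S,N,D,P,T,V} /
large (complement); aromatic {H,F,W,Y}; aliphatic {A,I,K,L,M,P,V};
positive {H,K,R}; negative {D,E}. Two deliberate oddities are kept verbatim
from the source categorization rather than corrected to textbook
convention: Lys sits in the aliphatic set and Gly in the hydrophobic set.
Substitution pair labels are directional (wt→mut) because charge reversals
in the two directions associate differently with pathogenicity;
symmetric labels are identical under reversal and asymmetric ones mirror
(small-large ↔ large-small), a property the tests check for all 380 ordered
pairs.

## Evaluation mathematics

- **AUC** is computed two ways that agree algebraically and are asserted
  against each other to 1e-12: the midrank Mann–Whitney estimator
  (fraction of pathogenic/benign pairs ordered correctly, ties ½) and the
  trapezoidal area under the ROC swept over unique score values with
  (0,0)/(1,1) endpoints. scikit-learn's `roc_auc_score` serves as a third,
  independent reference in the tests only.
- **MCC** uses the standard confusion-matrix form, with the convention
  MCC = 0 whenever a denominator factor vanishes.
- **Optimal threshold**: exhaustive scan over midpoints of consecutive
  sorted unique scores plus sentinels one unit below the minimum and above
  the maximum. MCC ties break toward the smallest |threshold|, then the
  smaller threshold. The scan is vectorized with sorted cumulative counts;
  a plain-loop brute force re-derives it in the tests.
- **Balanced resampling**: N = ⌊0.5·min(n_benign, n_pathogenic)⌋ per class,
  drawn uniformly without replacement, 100 repeats by default; TPR, FPR,
  FNR and accuracy computed per repeat, then averaged (sd with ddof 1).
  The threshold is calibrated once on the full dataset and reused inside
  resampling — this reproduces the upstream protocol *including its
  information leakage*, which is documented rather than silently repaired.
  Because the rule is fixed, per-variant predictions are constant and the
  implementation accepts them precomputed.
- **Stratified AUC** reports groups with strictly more than 100 cases
  (configurable) and both classes present.
- The absolute-ΔΔG variant analysis (score |ΔΔG| with the
  pathogenic-if-greater rule) is available through the `pathogenic_if_ge`
  rule and a caller-side transform.

## Classifier protocol

Classes are balanced by a seeded subsample of the majority class (how
equality is achieved was an open choice; subsampling keeps rows i.i.d.).
The balanced set is split 80/20 with stratification. On the training
portion, each candidate c is scored by stratified 5-fold cross-validation
repeated with reshuffled folds — the default protocol uses 100 repetitions
and a 13-point log-spaced grid over [10⁻³, 10³]; fold plans are shared
across the grid so the comparison is paired — and the c with the best mean
validation AUC wins, ties toward the smaller c (stronger regularization).
The final model is refit on the whole training portion. Features are
standardized with training-portion statistics only, stored on the model so
prediction is self-contained. MCC is reported at probability threshold 0.5
(the classification threshold for the model was an open choice). Train and
test metrics are computed independently and are not forced to agree.
The solver is scikit-learn lbfgs, tol 1e-8, max 10⁴ iterations —
deterministic given data and c.

The test suite and the acceptance script run this protocol at reduced size
(2–5 CV repetitions, 3–7 grid points) — a sizing choice that leaves the
selection logic identical while keeping runs at desk scale; the full
defaults remain the package defaults.

## Saturation mutagenesis

`enumerate_substitutions` yields exactly 19·L (position, wt, mut) tuples,
1-based, mutants alphabetical. `scan` scores each with the supplied scorer
and flags pathogenic iff ΔΔG ≤ cutoff (default −1.1 kcal/mol,
configurable). Non-canonical residues abort with the offending position
named. `scan_to_tsv` streams one row per substitution so proteome-scale
runs hold O(1) rows in memory. `SyntheticScorer` is a synthetic stand-in:
a keyed BLAKE2b hash of (seed, position, wt, mut) mapped through the
Gaussian quantile function — deterministic, platform-independent,
physically meaningless. `TableScorer` joins precomputed ΔΔG tables
(`external-tsv` mode in the CLI) for use with real predictor output.

## Numerical and degenerate-input conventions

- AUC/ROC require at least one case of each class; single-class input is an
  error, not a default value.
- Score equal to threshold predicts pathogenic (closed boundary at the
  cutoff).
- Beta/Gaussian parameters are validated at config construction with the
  offending field named.
- `fraction_destabilizing` means ΔΔG < 0 strictly — "any destabilization" —
  distinct from the magnitude-cutoff stability classes
  (destabilizing ≤ −cutoff, stabilizing ≥ +cutoff, else neither).

## Known limitations

- The generator's Gaussians/Betas are a deliberately simple ground truth;
  real predictor outputs are heavier-tailed and correlated with residue
  identity and burial.
- The equicorrelation common-factor construction cannot express unequal
  pairwise predictor correlations.
- Balanced resampling reuses the full-data threshold (see above), so its
  accuracies are optimistic relative to a leakage-free protocol.
- The pipeline assumes one isoform per protein; isoform selection from
  reference sequence databases is out of scope.
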