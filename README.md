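# stabvar

Protein-stability-informed pathogenicity analysis for missense variants in
monogenic disease genes.

Most pathogenic missense variants destabilize the protein they hit. `stabvar`
implements the full analysis chain that quantifies this link: it curates
ClinVar-style variant tables into benign/pathogenic datasets, evaluates
folding free-energy change (ΔΔG, kcal/mol; negative = destabilizing) and
relative solvent accessibility (RSA ∈ [0, 1]; low = buried) as pathogenicity
scores, calibrates classification cutoffs by maximizing the Matthews
correlation coefficient (MCC), assesses fixed-threshold classifiers with
balanced benign/pathogenic resampling, trains a two-feature (ΔΔG, RSA)
L2-regularized logistic classifier, and drives in-silico saturation
mutagenesis (all 19·L substitutions of a protein) through a pluggable ΔΔG
scorer.

External ΔΔG/RSA predictors are *inputs* here, never reimplemented: they
enter as score columns in a TSV or through the scorer contract
`(sequence, position, wt, mut) → ΔΔG`. A seeded synthetic-data generator
with known ground truth (label-conditional Gaussians for ΔΔG, Betas for RSA,
correlated predictor columns, allele frequencies straddling the 0.01 filter)
stands in for those predictors so every stage is verifiable at desk scale.

## The statistics at the core

For a score *s* with labels *y* (1 = pathogenic), discrimination is the
concordance AUC — the probability that a random pathogenic case scores more
pathogenic than a random benign case, ties counting ½ — which equals the
trapezoidal area under the ROC curve exactly (both are implemented and
asserted against each other). A variant is *called* pathogenic when its
score falls at or below a cutoff *t* (both ΔΔG and RSA point the same way:
lower = more pathogenic); *t* is chosen by exhaustive scan of

MCC(t) = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

over the midpoints of consecutive sorted unique scores. Fixed-threshold
classifiers are then evaluated on 100 balanced subsamples of
N = ⌊½·min(n_benign, n_pathogenic)⌋ per class, reporting mean ± sd of TPR,
FPR, FNR and accuracy. The logistic model σ(w·x + b) with penalty
‖w‖²/(2c) is fit on standardized (ΔΔG, RSA) features, with c selected by
repeated stratified 5-fold cross-validation on an 80% training split.

## Worked example

```python
from stabvar import synth, evaluate, annotate

cfg = synth.GeneratorConfig(seed=7)           # default study conditions
df = synth.generate_annotated(cfg, 2000, 2000)

auc = evaluate.auc_concordance(df["ddg_p1"], df["label"])
t, m = evaluate.optimal_threshold(df["ddg_p1"].to_numpy(),
                                  df["label"].to_numpy())
print(f"AUC={auc:.3f}  analytic={synth.analytic_auc(cfg):.3f}  "
      f"cutoff={t:.2f} kcal/mol  MCC={m:.3f}")
```

prints

```
AUC=0.734  analytic=0.747  cutoff=-1.44 kcal/mol  MCC=0.417
```

The empirical AUC of one simulated ΔΔG predictor (0.734 at 2000 variants
per class) scatters around the closed-form value Φ((μ_b−μ_p)/√(σ_b²+σ_p²))
= 0.747 implied by the generator's Gaussians; the MCC-optimal cutoff lands
around −1.4 kcal/mol, i.e. variants destabilizing by more than ~1.4 kcal/mol
are called pathogenic, with MCC 0.417 at that cutoff.

The same analyses run from the shell:

```
stabvar synth --seed 7 --out run/
stabvar curate --input run/raw_variants.tsv --out run/curated
stabvar evaluate --input run/annotated_variants.tsv --score ddg_p1 --out run/eval.json
stabvar classify --input run/annotated_variants.tsv --ddg ddg_p1 --rsa --out run/model.json
stabvar saturate --fasta run/protein.fasta --scorer synthetic --cutoff -1.1 --out run/sat
stabvar run-all --seed 7 --out run/full
```

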