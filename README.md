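# hiscom

Hierarchical structural component modeling of targeted-proteomics peptide
panels for binary drug-response prediction.

## The problem

Multiple-reaction-monitoring mass spectrometry (MRM-MS) quantifies a
preselected panel of peptides in serum — here, panels shaped like 231
peptides digested from 124 proteins measured in ~115 patients — as
log2(light/heavy) ratios against spiked stable-isotope standards.  The
clinical question is whether such a panel predicts a binary drug response
(e.g. tumor response to a tyrosine kinase inhibitor under mRECIST, with CR /
PR / SD as positive and PD as negative).  Peptide columns are strongly
correlated within each parent protein, so a plain logistic regression on
peptides is ill-conditioned and hard to interpret at the protein level.

`hiscom` addresses this with a hierarchical structural component model
(HisCoM): each protein k with peptides x_jki is collapsed into a latent
component score

    f_jk = Σᵢ x_jki · w_ki

and the response follows a logistic model on the K component scores plus
age and sex:

    logit(π_j) = β₀ + Σₖ f_jk βₖ + AGE_j β_age + SEX_j β_sex .

Peptide weights **w** and protein path coefficients **β** are estimated
jointly by maximizing a doubly ridge-penalized Bernoulli log-likelihood

    φ₁ = Σⱼ log P(y_j; η_j) − ½ λ_pep ‖w‖² − ½ λ_prot Σₖ βₖ² ,

via iteratively reweighted least squares (IRLS): each outer step builds the
working weights v_j = μ_j(1−μ_j) and adjusted responses
z_j = η_j + (y_j−μ_j)/v_j, and the resulting penalized weighted
least-squares problem — bilinear in (w, β) — is solved by alternating least
squares (ALS), each block having a closed-form ridge solution.  Both
λ default to 10.

On top of the estimator the package provides:

- **Permutation inference** — per-protein p-values from label-permuted
  refits, plus a consistency screen over repeated ratio-preserving
  train/validation halvings (how protein biomarker panels are selected);
- **Evaluation** — stratified test / train / validation splits that preserve
  the positive:negative ratio, Mann–Whitney AUC, and logistic baselines
  (unpenalized GLM and ridge GLMwR) for model comparison;
- **Simulation** — block-correlated synthetic MRM-MS cohorts and a study
  runner that redraws responses from fixed true probabilities and compares
  the three methods by AUC.

## Worked example

Generate a synthetic cohort with the 231-peptide / 124-protein / 115-sample
panel shape, fit the model, and run the simulation comparison:

```
$ hiscom generate --out-prefix demo --seed 11
wrote demo.quant.tsv (115 x 231), demo.hierarchy.tsv (124 proteins), demo.pheno.tsv (40 positive / 75 negative)

$ hiscom fit --quant demo.quant.tsv --hierarchy demo.hierarchy.tsv \
             --pheno demo.pheno.tsv --out demo.model.hiscom
fit converged in 3 iterations; objective -71.6260; model written to demo.model.hiscom

$ hiscom simulate --model 2 -B 100 --seed 11 --out demo.sim.tsv
mean AUC hiscom: 0.8174
mean AUC glm: 0.7887
mean AUC glmwr: 0.7993
```

The first command writes a wide quantitation TSV (rows = samples, columns =
peptides, cells = log2 light:heavy ratios), a two-column peptide→protein
hierarchy and a phenotype table (response, age, sex).  The `fit` objective
is the penalized log-likelihood φ₁, reported per iteration at `-v`.  The
`simulate` design pairs a 2-peptide associated protein with a 7-peptide
noise protein (within-protein correlation 0.7): collapsing peptides into
protein components pays off exactly here, and the component model's mean
held-out AUC (0.817) exceeds both the unpenalized logistic baseline (0.789)
and the ridge baseline (0.799) over 100 replicates.

Library use mirrors the CLI: `hiscom.irls_als_fit`, `hiscom.predict_proba`,
`hiscom.permutation_test`, `hiscom.compare_models`,
`hiscom.run_simulation_study`; see the module docstrings.

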