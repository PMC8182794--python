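# dimoshift

Statistical pipeline for **sex-specific cold-response transcriptomics**:
does cold acclimation move the two sexes' transcriptomes the same way, and
does it *reduce sexually dimorphic expression*?  The package targets the
classic 2 sexes x 2 temperatures x n replicates bulk RNA-seq design
(plus a chill-coma phenotype assay) and ships a synthetic-data generator
with known ground truth, so every estimator can be validated end to end.

It is written for quantitative biologists who have a gene x library count
matrix and want the full chain — filtering, TMM normalization,
negative-binomial quasi-likelihood differential expression, sex-bias
classification, feminization-shift estimation, concordance and enrichment
analyses, and the CTmin mixed model — as composable, tested Python.

## The statistics at the core

* **Differential expression.** Per gene, counts are NB(μ, φ) with
  variance μ + φμ² and a log link over the four design groups with a log
  effective-library-size offset (TMM-scaled).  Dispersions come from a
  Cox–Reid adjusted profile likelihood with shrinkage toward the common
  value; each contrast (cold effect per sex, sex effect per condition,
  interaction) is tested with a quasi-F statistic
  F = (Δdeviance / df₁) / s²,  s² a trend-moderated quasi-dispersion,
  with p from F(df₁, df_res + d₀) and BH FDR across genes.
* **Sex bias.** A gene is male-biased iff FDR < 0.05 and log₂FC ≥ +1
  (male − female) in *both* temperature conditions; female-biased
  symmetrically at ≤ −1.
* **Feminization shift.** Within each sex, biased genes' cold log₂FC is
  normalized by subtracting the unbiased genes' median cold change, then
  summarized by the Hodges–Lehmann pseudomedian (median of all Walsh
  averages (xᵢ+xⱼ)/2) with a distribution-free signed-rank 95% CI, plus
  a Wilcoxon rank-sum test of each class against unbiased genes.
* **Concordance.** Exact multi-set intersection tests (hypergeometric /
  successive-conditioning convolution), Spearman correlation of cold
  responses, Fisher z comparison of male–female expression correlations
  across conditions, leading-log-FC MDS, and bootstrap-supported
  hierarchical clustering of libraries.
* **Phenotype.** log(CTmin + 5) in a REML linear mixed model with sex,
  treatment, their interaction and weight as fixed effects, batch as a
  random intercept, and per-term 1-df Wald chi-squares.

Details, assumptions and known limitations: [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import dimoshift as dm

# a synthetic study: 2000 genes, 12 libraries, known feminization
cm, truth = dm.simulate_counts(dm.SimulationConfig(n_genes=2000, seed=7))

filtered = dm.filter_low_expression(cm)                  # CPM < 0.5 rule
norm = dm.TMMNormalizer().fit(filtered).transform(filtered)
de = dm.QLDifferentialExpression().fit(filtered, norm=norm)

labels = dm.classify_sex_bias(de.results_["sex_in_control"],
                              de.results_["sex_in_cold"])
shifts = dm.normalized_shift_summary(
    {"F": de.results_["cold_in_females"]["log2_fc"],
     "M": de.results_["cold_in_males"]["log2_fc"]}, labels)
print(shifts.to_string(index=False))
```

```
sex    bias_class  n_genes   wilcoxon_p  wilcoxon_fdr  pseudomedian_normalized    ci_low   ci_high
  F female_biased      332 7.831249e-06  7.831249e-06                 0.119601  0.073474  0.167011
  F   male_biased      369 2.211023e-08  2.948030e-08                -0.149429 -0.193091 -0.106867
  M female_biased      332 7.182769e-56  2.873107e-55                 0.507834  0.461479  0.555665
  M   male_biased      369 4.283070e-46  8.566141e-46                -0.432487 -0.479287 -0.384682
```

The generator applied a −0.5 log₂ feminization delta in males and −0.1 in
females.  The recovered pseudomedians (−0.43 in males, −0.15 in females)
show male-biased genes dropping and female-biased genes rising in males —
the male transcriptome moving toward the female profile, much more
strongly in males than in females.  The mild attenuation relative to the
simulated deltas is the threshold-selection effect of the classification
step, discussed in `docs/methods.md`.

The same chain is available from the shell:

```bash
dimoshift simulate --out-dir sim --seed 7
dimoshift run-all --counts sim/counts.tsv --design sim/design.tsv \
    --ctmin-data sim/ctmin.csv --out-dir results --seed 7
```

which writes per-stage TSVs (DE tables, sex-bias labels, shift summary,
MDS coordinates, a support-annotated Newick dendrogram, the CTmin Wald
table) plus a `manifest.json` of checksums; reruns with the same seed are
byte-identical.

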