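# musclenet

Two-group expression analysis with surrogate-calibrated Pearson
co-expression networks.

`musclenet` is a reusable, tested implementation of a case–control
transcriptome analysis strategy developed for small cohorts — the
motivating setting is bulk microarray profiling of ALS patient skeletal
muscle against matched healthy controls (two groups of 7 samples,
~8800 probesets, log2 RMA-normalised intensities).  The pipeline
combines a conventional differential expression analysis with an
unsupervised, correlation-based view of the same data:

1. **Variance filtering.**  Genes with interquartile range
   ≤ 0.25 (log2) across all samples are removed as uninformative.
2. **Moderated differential expression.**  Each gene is tested with a
   two-group linear model whose residual variances are shrunk by
   empirical Bayes: with pooled variance $s_g^2$ on $d_g$ degrees of
   freedom and an inverse-chi-square prior $(d_0, s_0^2)$ fitted by
   moment matching on $\log s_g^2$,

   $$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},\qquad
     \tilde t_g = \frac{\hat\Delta_g}{\tilde s_g\sqrt{1/n_1 + 1/n_2}}
     \sim t_{d_0 + d_g},$$

   followed by Benjamini–Hochberg adjustment and selection at
   |log2FC| ≥ 1, adjusted p ≤ 0.05.
3. **Transposed PCA and discriminant genes.**  PCA is run with genes as
   statistical units and patients as variables.  PC1 absorbs the shared
   tissue profile (typically >97% of variance); among the remaining
   components, the one whose *factor loadings* (FL — the correlation of
   each patient's expression vector with the component's gene-score
   vector) best separate the two groups by the Fisher discriminant ratio
   is chosen, and the 100 genes with the largest |score| on it form the
   discriminant list.  Classical MDS of the samples provides the
   quality-control embedding.
4. **Correlation networks.**  On the top-100 genes, each group's
   samples yield a Pearson correlation matrix; genes are connected when
   $r > \tau$.  The threshold τ is calibrated with surrogate data: each
   gene's values are independently permuted across individuals (1000
   realizations), and a grid threshold qualifies when the mean surrogate
   connection count is at least 10% below the original count (plus an
   ensemble upper-tail guard against lone chance edges at n = 7).
   Networks are compared by average degree $AD = 2C/N$, connected
   components and isolated-node counts.
5. **Over-representation (optional).**  Gene lists are tested against
   user-supplied GMT gene sets with the one-sided Fisher
   exact/hypergeometric test (EASE variant available) and BH FDR.

A fully parameterised synthetic-data generator reproduces the study
regime — dominant tissue axis, planted ±log2 shifts, case-only
correlation blocks — so every stage is testable with known ground
truth and no downloads.  Fixtures transcribing the study's printed
cohort, differential expression and discriminant tables are packaged.

## Worked example

```python
import musclenet as mn

cfg = mn.SyntheticConfig(seed=42)          # study-regime defaults
matrix, annotation, truth = mn.generate_two_group_dataset(cfg)

report = mn.run_pipeline(
    mn.PipelineConfig(case_group="case", out_dir="demo_run", seed=42),
    matrix=matrix, annotation=annotation,
)

print(report.de_results.summary())
print(f"PC1 variance fraction : {report.decomposition.variance_fractions[0]:.4f}")
print(f"discriminant component: PC{report.discriminant.component}")
print(report.calibration.summary())
print("case network    :", report.network_case.summary())
print("control network :", report.network_control.summary())
```

prints

```
Moderated two-group differential expression
  contrast        : case - control
  genes tested    : 7526
  residual df     : 12
  prior df (d0)   : inf
  prior var (s0^2): 0.09686
  adj p <= 0.05   : 103
PC1 variance fraction : 0.9857
discriminant component: PC2
Surrogate calibration over 50 thresholds, 1000 realizations (seed 42); margin 10%; selected threshold: 0.99
case network    : 100 nodes, 94 edges (τ = 0.99, positive rule); AD = 1.880; 78 isolated; largest component 22 nodes
control network : 100 nodes, 0 edges (τ = 0.99, positive rule); AD = 0.000; 100 isolated; largest component 1 nodes
```

Reading the output: 7526 of 8793 genes survive the IQR filter; the
moderated model finds the variance prior dominant (`d0 = inf`) because
the simulated noise is homoskedastic; PC1 carries 98.6% of variance (the
tissue axis) and PC2 separates the groups.  The case network recovers
the planted 22-gene co-expression module as its largest connected
component while the control network — where that module is absent —
falls apart into isolated nodes, reproducing the dense-in-disease /
sparse-in-control contrast the method is designed to expose.

The same stages are scriptable from the shell (`musclenet simulate`,
`de`, `pca`, `network`, `enrich`, `run`, `fixtures`); see
`musclenet --help`.

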