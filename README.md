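# noisefit

Quantitative tools for asking whether gene-expression **noise** —
cell-to-cell variability of expression among genetically identical
cells — affects organismal **fitness**, and for measuring both
quantities precisely enough to find out.

The package re-implements, as a tested pipeline plus simulator, the
complete methodology of a promoter-allele study in budding yeast in
which a panel of promoter variants driving a fluorescent reporter
spans a wide range of median expression and expression noise, fitness
is measured by competition against a common reference, and the
noise–fitness relationship is tested on LOESS residuals. It is aimed
at quantitative geneticists and systems biologists who want to run the
same analysis on their own flow-cytometry / competition / pyrosequencing
data, or to explore the underlying model.

## What is inside

| module | role |
|---|---|
| `cytometry_expression` | flow-cytometry events → median expression and four noise metrics (noise strength s²/m, SD, CV, log CV) relative to a reference, with singlet gating, PCA size normalization, log-log mRNA calibration (log₁₀ y = a·log₁₀ x + b with a = 10.469, b = −9.586), batch correction and MAD outlier filtering |
| `competition_fitness` | two-color counts or allele-frequency trajectories → competitive fitness w = exp(slope of ln(N_Y/N_G) on generations), including the Hardy-Weinberg-style doublet correction DY = (DYG/2)·√(TY/TG) |
| `pyroseq_quant` | pyrogram peak heights → allele frequencies (0.86 A-peak factor, linear or monotone-spline PCR-bias correction), relative mRNA ratio A = (1−G)·C/((1−C)·G), and promoter copy-number calls (expected frequencies 1/2, 2/3, 3/4) |
| `noise_fitness_analysis` | ΔNoise/ΔFitness: residuals of LOESS fits (tricube local quadratic, span 2/3) of noise and fitness on median expression; far/close-to-optimum split at a 0.005 fitness drop; Pearson correlations; 10⁵-shuffle permutation tests; 100-combination robustness grid |
| `growth_simulator` | individual-based model: each cell redraws expression E ~ N(μ_E, σ_E²) at division, a DT function (linear −40E+160 or inverted-Gaussian −160·exp(−(E−1)²/0.18)+240) maps E to doubling time, fitness = exp(ln(N_i/N_ref)/T) |
| `assay_power_design` | simulation-based power analysis of serial-dilution competition assays (drift at bottlenecks + counting noise; minimum detectable selection coefficient via noncentral-t power inversion) |
| `synthetic_data` | generators for every input format with known ground truth: flow events, competition trajectories, pyrograms, and a full 43-genotype study panel with a plantable noise-on-fitness effect |
| `cli` | the `noisefit` command: `synth`, `expression`, `fitness`, `pyroseq`, `analyze`, `simulate`, `power` |

## Worked example

Generate a synthetic 43-allele panel with a planted positive effect of
noise on fitness below the expression optimum (0.001 fitness units per
percentage point of ΔNoise), push it through the full pipeline, and
test the noise–fitness association:

```python
from noisefit.synthetic_data import gen_study_panel
from noisefit.pipeline import analysis_panel, correlation_by_class
from noisefit.noise_fitness_analysis import AnalysisConfig, delta_metrics

panel = gen_study_panel(n_genotypes=43, noise_effect=0.001, seed=1)
table = analysis_panel(panel, noise_metric="strength")
print(table.head(3).round(2).to_string(index=False))

delta = delta_metrics(table, AnalysisConfig())
print(f"optimum threshold: {delta.threshold:.1f}% of wild-type expression")
cors = correlation_by_class(delta, method="permutation",
                            n_perm=100_000, seed=1)
print(cors.round(3).to_string(index=False))
```

Output:

```
genotype  median_expression_pct  noise_pct  fitness
   var00                   4.55       8.60     0.96
   var01                   7.63      17.36     0.96
   var02                  11.17      28.06     0.97
optimum threshold: 59.7% of wild-type expression
optimum_class  n      r     p  r_squared
          far 19  0.982 0.000      0.964
        close 24 -0.228 0.285      0.052
```

Reading the numbers: each genotype's median expression and noise
strength are percentages of the wild-type reference, recovered from
raw synthetic flow events; fitness is relative to the wild-type allele,
recovered from simulated competition counts. The LOESS fit of fitness
on expression puts the "close to optimum" boundary at 59.7% of
wild-type expression (the generator's analytic boundary is 58.1%).
Genotypes far below the optimum show a strong positive ΔNoise–ΔFitness
correlation (r = 0.98; a permutation p of 0.000 means no shuffle
reached the observed correlation, i.e. p < 10⁻⁵), while genotypes near
the optimum show no significant association — noise is beneficial when
expression is too low and neutral-to-harmful near the optimum, exactly
the planted truth.

The same flow works from the shell:

```sh
noisefit synth --out run1 --genotypes 43 --seed 1
noisefit expression --events run1/events --out run1/expression.tsv
noisefit fitness --competition run1/competition.csv --out run1/fitness.tsv
noisefit analyze --panel run1/panel.tsv --out-dir run1/analysis \
    --permutations 100000 --seed 1
```

## Documentation

`docs/methods.md` describes the models and estimators, all default
parameters and their provenance, what the synthetic data do and do not
emulate, and known limitations.
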