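# accelseg

Segmental-moment analysis of rodent accelerometry for preclinical
Parkinson's disease phenotyping.

## The problem

Unilateral 6-hydroxydopamine (6-OHDA) lesioning of the median forebrain
bundle is a standard rat model of Parkinson's disease. Bradykinesia — the
slowing and impoverishment of movement — should be visible in continuous
accelerometry from a backpack-worn 3-axis MEMS sensor (25 Hz, 16 bit,
±4 g per axis), recorded over the animals' 12 h dark/active phase. The
question this package answers is whether simple statistics of the
acceleration signal separate lesioned animals from vehicle-injected sham
controls, and which statistic carries the signal.

`accelseg` implements the complete analysis chain for such cohorts, and —
because no public recording archive exists — a calibrated synthetic-cohort
generator so that every stage is testable end to end.

## The method

For each animal *d* the orientation-free magnitude
m_{d,i} = √(x² + y² + z²) is computed per sample, trimmed to
I = 1,080,000 samples (12 h at f_s = 25 Hz starting 19:45), and split
into N = 720 non-overlapping one-minute segments of S = 1500 samples.
Each segment yields four moments:

- μ = (1/S) Σ m_s
- σ² = 1/(S−1) Σ (m_s − μ)²
- γ = [(1/S) Σ (m_s − μ)³] / (σ²)^{3/2}
- κ = [(1/S) Σ (m_s − μ)⁴] / (σ²)²  (plain, not excess)

(the deliberate 1/S-numerator / unbiased-denominator mix is kept
verbatim; see `docs/methods.md`). Per-animal segment means μ̄_d, σ̄²_d,
γ̄_d, κ̄_d summarize each dataset.

Anomalous datasets are screened with the MAD-median rule on the overall
variance σ²_d, separately per class: flag when
|σ²_d − median| / (MAD/0.6745) > K with K = √χ²₀.₉₇₅,₁ ≈ 2.24, with a 2-D
PCA projection of the cohort magnitude matrix as a visual diagnostic.

Group differences in σ̄²_d and γ̄_d (absolute skewness) are tested with a
nonparametric battery — Mann-Whitney U, two-sample Kolmogorov-Smirnov,
and Baumgartner-Weiß-Schindler (exact permutation p at cohort sizes) —
corrected with the literal Holm-Bonferroni step-down p̃_i = p_i(N+1−i)
and its sequential rejection rule at α = 0.05. Welch's t-test validates
the apomorphine-rotation split of the cohort, and Pearson/Spearman
correlations probe whether σ̄²_d grades lesion severity.

## Worked example

```python
from accelseg import AnalysisConfig, SimulationConfig, run_analysis

cfg = AnalysisConfig(simulation=SimulationConfig(seed=1, duration_s=3600.0), seed=1)
report = run_analysis(cfg)
print(f"datasets: {report.d_all} total, {report.d_final} after outlier exclusion")
print(f"segments per dataset: {report.n_segments}")
sham = report.summaries[report.summaries.condition == "sham"]
pd_ = report.summaries[report.summaries.condition == "pd"]
print(f"mean segmental variance: sham {sham.mean_var.mean():.3f}, "
      f"lesioned {pd_.mean_var.mean():.3f} m2/s4")
for feat, cmp in report.batteries.items():
    for name, p, padj, sig in zip(cmp.test_names, cmp.p_raw, cmp.p_adjusted, cmp.significant):
        print(f"{feat:>10s} {name:>20s} p={p:.4f} p_adj={padj:.4f} "
              f"{'significant' if sig else 'n.s.'}")
```

prints

```
datasets: 15 total, 15 after outlier exclusion
segments per dataset: 60
mean segmental variance: sham 0.277, lesioned 0.171 m2/s4
  mean_var       mann_whitney_u p=0.0007 p_adj=0.0020 significant
  mean_var                  bws p=0.0007 p_adj=0.0013 significant
  mean_var   kolmogorov_smirnov p=0.0007 p_adj=0.0007 significant
 mean_skew       mann_whitney_u p=0.1645 p_adj=0.4935 n.s.
 mean_skew                  bws p=0.2244 p_adj=0.4489 n.s.
 mean_skew   kolmogorov_smirnov p=0.3506 p_adj=0.3506 n.s.
```

A one-hour synthetic 5-vs-10 cohort at the calibrated effect size (class
mean segmental variances ≈ 0.279 vs 0.163 m²/s⁴, a 41.5% bradykinetic
reduction): the variance battery rejects decisively while the skewness
battery does not — the variance of the acceleration magnitude is the
discriminating feature. The same chain is available from a shell:

```sh
accelseg simulate --seed 1 --out data/
accelseg analyze data/manifest.yaml --seed 1 --out results/
accelseg report results/
```

## Layout

| module | contents |
|---|---|
| `accelseg.io` | recording CSV + YAML sidecar format, manifests, window trimming, cohort matrix |
| `accelseg.synth` | calibrated synthetic cohort generator |
| `accelseg.features` | magnitude, segmentation, segmental moments, g-normalization, summaries, directional transforms |
| `accelseg.outliers` | PCA latent projection, MAD-median rule, exclusion |
| `accelseg.stats` | MWU / KS / BWS battery, literal Holm-Bonferroni, Welch's t, correlations |
| `accelseg.histograms` | log-binned per-class histograms |
| `accelseg.pipeline` | orchestration, reports, caching |
| `accelseg.cli` | `accelseg simulate / analyze / report` |
| `accelseg.reference` | published cohort metadata and class-mean anchors |
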