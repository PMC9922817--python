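# mitopulse

Analysis toolkit for monitoring **mitochondrial translation with pulse
SILAC**. The thirteen proteins encoded in the mitochondrial genome are
hydrophobic, low-abundance subunits of the OXPHOS complexes and are
notoriously hard to see in shotgun proteomics. `mitopulse` implements the
computational side of a mitochondria-focused pSILAC workflow for the
scientist who wants to quantify how a perturbation of the mitoribosome
(e.g. chloramphenicol) propagates through synthesis and degradation of
mitochondrially and nuclear-encoded OXPHOS subunits — and to test every
stage against simulated data with known ground truth.

## What it does

- **In-silico digestion** (`mitopulse.digest`): trypsin, lysC and
  chymotrypsin (F/W/Y) site rules with missed cleavages and the 6–30
  residue "theoretically observable" window; observable-peptide count
  matrices and iBAQ (intensity / observable peptides). This reproduces,
  e.g., why MT-ND4L (one arginine, no lysine) yields only a 23-mer and a
  75-mer under lysC+trypsin and is therefore invisible in that protocol.
- **Synthetic SILAC evidence** (`mitopulse.simulate`): a generative
  first-order turnover model `dX/dt = s(t) − k_d(t)·X` per protein, with a
  drug multiplier `f` on synthesis and `g ≥ 1` on degradation of newly
  made cohorts. Closed forms for both designs — 8 h pre-label + 16 h
  label+drug pSILAC (pooled M/H channels, label swap across replicates)
  and 4 h heavy pulse / 4 h medium chase — expanded to peptide-level L/M/H
  intensities with log-normal peptide and channel noise, channel mixing
  bias and intensity-dependent logistic dropout.
- **Quantification** (`mitopulse.quant`): peptide log2(H/M) ratios
  oriented so positive = higher under drug, median aggregation to
  protein × replicate, per-replicate median-centering, and a one-sample
  empirical-Bayes moderated t-test with posterior variance
  `s̃² = (d₀s₀² + d·s²)/(d₀ + d)` on `d₀ + d` degrees of freedom; the
  prior `(d₀, s₀²)` is fit by digamma/trigamma moment matching of the log
  sample variances. BH-adjusted volcano tables, filtered to proteins
  quantified in all replicates.
- **Pulse-chase degradation** (`mitopulse.chase`): synthesis score
  log2(M/L drug ÷ M/L vehicle), degradation score log2(H/L drug ÷ H/L
  vehicle), classification on the pSILAC mean log2 H/M (≥ −0.5 unchanged,
  < −0.5 CAP-sensitive), one-sided Wilcoxon rank-sum group comparisons
  (exact null for combined n ≤ 12 without ties).
- **OXPHOS complexes & modules** (`mitopulse.complexes`): a packaged
  98-subunit annotation (CI 45, CII 4, CIII 11, CIV 21, CV 17; 13
  mitochondrially encoded) with assembly-module labels; per-category,
  per-complex and per-module fold-change summaries and cross-experiment
  Pearson correlations.
- **Enrichment** (`mitopulse.enrichment`): one-sided hypergeometric term
  enrichment with Benjamini–Hochberg correction.

## Worked example

```python
from mitopulse import default_psilac_scenario, quantify_psilac, volcano_table

scenario = default_psilac_scenario(seed=2024, n_proteins=300, n_mt=13, n_orphans=25)
results = quantify_psilac(scenario.generate(), {"r1": "H", "r2": "M"})
table = volcano_table(results, scenario.annotation_table())
print(table.nsmallest(3, "mean_log2_fc").to_string(index=False))
```

prints (see `examples/03_quantify_volcano.py` for the full script):

```
protein_id  mean_log2_fc      p_value          fdr      encoding
      MT05     -1.850764 2.556065e-87 7.668195e-85 mitochondrial
      MT01     -1.841176 1.951223e-86 2.926834e-84 mitochondrial
      MT03     -1.772484 3.025333e-80 3.025333e-78 mitochondrial
```

The most suppressed proteins are exactly the 13 simulated
mitochondrially encoded subunits (planted synthesis multiplier
`f = 0.05`): their new-protein cohort is ~3.5-fold down
(`mean_log2_fc ≈ −1.8`), with moderated-t p-values far below any FDR
threshold. On this run all 38 planted effects are recovered and 3 of 262
null proteins are flagged at FDR < 0.05.

Each script in `examples/` is a self-contained narrative: digestion and
iBAQ (`01`), the generative model and its noiseless exactness (`02`), the
volcano pipeline (`03`), pulse-chase degradation of orphan subunits
(`04`), and module summaries plus enrichment (`05`). A thin CLI
(`mitopulse digest|simulate|quantify|chase|modules|enrich|run`) wraps the
same functions for shell pipelines.

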