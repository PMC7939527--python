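# epipair

Integrative analysis of paired tumour/non-tumour methylome and
transcriptome data, built around the BS/oxBS array design: bisulfite (BS)
β values read 5mC + 5hmC jointly, oxidative-bisulfite (oxBS) β values read
5mC alone, and their difference per probe and sample — the 5hmC-score —
estimates hydroxymethylation.  The package targets studies of paired
hepatocellular carcinoma (HCC) and matched non-tumour liver (NTL) tissue
with an age-stratified cohort (AYA ≤ 44 years vs MOA > 44), and ships a
planted-truth simulator so every stage can be validated by recovery of
known effects.

The pipeline stages:

1. **cohort** — descriptive statistics per age stratum with χ²/Fisher and
   Welch-t comparisons, plus AFP normalised by tumour diameter
   (ng/mL/tumour-cm).
2. **dmp** — differentially methylated positions by paired empirical-Bayes
   moderated t on M-values: a probe is a DMP when q < 0.05 (BH) and
   |Δβ| ≥ 0.2, with Δβ = mean β(HCC) − mean β(NTL); stringent post-filters
   keep probes with (c1) |Δβ| ≥ 0.20, (c2) > 70% of tumour samples beyond
   the normal mean ± 2 SD, and (c3) mean normal β ≤ 0.25 (hyper) /
   ≥ 0.25 (hypo); an age-related probe exclusion list is honoured.
3. **dmr** — regions of ≥ 2 significant same-direction CpGs with > 20%
   methylation difference and ≤ 250 bp between neighbours.
4. **hydroxy** — 5hmC calls per tissue (score ≥ 0.3 in ≥ 3 samples, upper
   75% of candidate mean scores) and per-CpG transition categories:
   I non-5mC→5hmC, II 5mC→5hmC, III 5hmC→non-5mC, IV 5hmC→5mC.
5. **dge** — paired moderated-t differential expression on log2 values.
6. **integrate** — DEGs merged by gene symbol with stringent DMPs and de
   novo (category I) 5hmC probes; Spearman ρ between expression and β (or
   5hmC-score) per dyad; dyads with |ρ| > 0.5 selected and labelled by
   concordance (e.g. hypermethylated-and-downregulated); hypergeometric
   gene-set enrichment (e.g. of PRC2 targets) with Bonferroni correction.

The shared inferential core is a statsmodels-style model class:
`PairedModeratedTTest(a, b).fit()` returns results with `effect`,
`tvalues`, `pvalues`, BH `qvalues` and a `summary()`; variance moderation
estimates a scaled inverse-chi-square prior across features by the method
of moments.

## Worked example

Simulate a 30-pair study (5 000 probes, 500 genes) and run every stage:

```python
from epipair import SimulationConfig, PipelineConfig
from epipair.pipeline import run_all

res = run_all(PipelineConfig(seed=7),
              sim_cfg=SimulationConfig(n_pairs=30, n_probes=5000,
                                       n_genes=500, seed=7))
print(res.report["dmp"])
print(res.report["hydroxy"]["category_counts"])
print(res.report["integration"]["n_selected"])
```

prints

```
{'n_tested': 5000, 'n_called': 143, 'n_stringent': 113,
 'hyper_fraction': 0.7876106194690266}
{'I': 10, 'II': 3, 'III': 16, 'IV': 9}
29
```

— 143 of 5 000 probes pass q < 0.05 and |Δβ| ≥ 0.2, 113 of them survive
the stringent filters (79% hypermethylated, matching the planted bias at
this configuration), the transition classifier distributes the planted
hydroxymethylation changes over the four categories, and 29 gene–probe
dyads show |Spearman ρ| > 0.5 between expression and methylation.  The
PRC2-target set planted by the simulator over the coupled genes is
recovered at a Bonferroni-corrected p ≈ 1.6e−19
(`res.report["integration"]["enrichment"]`).

The underlying model object prints a statsmodels-like summary:

```python
from epipair import PairedModeratedTTest, beta_to_m
st = res.study
fit = PairedModeratedTTest(beta_to_m(st.beta_bs_hcc.to_numpy()),
                           beta_to_m(st.beta_bs_ntl.to_numpy()),
                           feature_ids=st.beta_bs_hcc.index).fit()
print(fit.summary(top=3))
```

```
Paired moderated t-test
  features: 5000   pairs: 30
  prior df: 5.713   prior variance: 0.4705
  q < 0.05: 159

            effect  statistic         p         q
cg00002333  -4.257     -31.85 2.779e-27 8.528e-24
cg00003631  -3.668     -31.38  4.57e-27 8.528e-24
cg00001370   3.655      31.27 5.117e-27 8.528e-24
```

Every stage is also exposed on the command line (`epipair simulate`,
`cohort`, `dmp`, `dmr`, `hydroxy`, `dge`, `integrate`, `run-all`); see
`epipair --help`.

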