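# Methods

`epipair` re-implements, as a tested and reusable pipeline, an integrative
epigenomic analysis of paired hepatocellular carcinoma (HCC) and matched
non-tumour liver (NTL) tissue: differential methylation calling on Infinium
β values with stringent post-filters, region aggregation, 5-hydroxymethyl-
cytosine (5hmC) detection from paired bisulfite (BS) / oxidative-bisulfite
(oxBS) measurements, paired differential expression, and gene-level
expression–methylation integration with gene-set enrichment.  A
planted-truth simulator generates every input the pipeline consumes, so
recovery of known effects can be tested end to end.

## The measurement model

A BS array reads 5mC + 5hmC jointly; an oxBS array reads 5mC alone.  The
simulator therefore generates, per probe *i* and tissue,

    β_BS  = clamp(m_i + h_i) + ε,     β_oxBS = clamp(m_i) + ε,

where *m* is the true 5mC fraction, *h* the true 5hmC fraction and ε is
beta-distributed measurement noise with mean 0 relative to the true value:
observed values are drawn from Beta(μφ, (1−μ)φ) with μ the true fraction
and φ = `beta_dispersion` (default 50, giving a per-probe SD of ≈ 0.05 at
μ = 0.15).  `beta_dispersion = None` disables noise, which makes the
additivity identity `β_BS − β_oxBS = h` exact; several tests rely on this
limit.  Baseline 5mC depends on genomic context (islands ≈ 0.12, shores ≈
0.35, shelves ≈ 0.50, open sea ≈ 0.65), matching the usual unmethylated-
island / methylated-open-sea profile of normal tissue.

## Planted effects

* **DMPs** — a fraction `dmp_fraction` of probes shift by
  ±`delta_beta_effect` in tumour (default 0.3).  Hypermethylated plants land
  on CpG-island TSS200/TSS1500 probes with probability 0.8 (else uniform),
  hypomethylated plants on open-sea gene-body probes likewise; 30% of
  planted probes recruit their genomic neighbour when it lies within 250 bp,
  so that planted regions of ≥ 2 probes exist.  Shifted means are clamped
  into (0.02, 0.98) with a warning.  The default hyper fraction among DMPs
  is 0.99, the overwhelming-hypermethylation regime the pipeline models.
* **5hmC transitions** — a disjoint probe subset carries planted
  hydroxymethylation with a four-category mix (I: non-5mC→5hmC, II:
  5mC→5hmC, III: 5hmC→non-5mC, IV: 5hmC→5mC; default mix 0.372 / 0.056 /
  0.366 / 0.206).  Planted 5hmC levels are uniform on [0.35, 0.55], safely
  above the 0.3 calling threshold.
* **DEGs** — `deg_fraction` of genes shift by ±`log_fc_effect` (default 1.5
  log2 units) in tumour columns.
* **Correlated dyads** — `corr_dyad_fraction` of genes are coupled to one
  of their planted DMP probes through a Gaussian copula on rank scores,
  with the normal-score correlation set to 2·sin(π·ρ/6) so the population
  Spearman ρ equals `rho_effect` (default 0.9).  Negative coupling is drawn
  with probability 0.8, so hypermethylated-and-downregulated is the modal
  concordance.  Because the coupled probe is differentially methylated, the
  coupling itself induces a tumour/normal expression shift; dyad genes are
  therefore genuine DEGs and the truth table records them as such.

The truth table is exhaustive: tissues differ only at planted probes (a
noise-free test asserts this), and truth DMR intervals are derived from the
planted DMP set with the same neighbouring-probe rule the caller uses.

## Differential testing

Both the methylation and the expression tests use one shared model class,
`PairedModeratedTTest`: per-feature paired differences (M-values for
methylation, log2 expression otherwise) are tested with empirical-Bayes
variance moderation.  The scaled inverse-chi-square prior (d₀, s₀²) is
estimated across features by the method of moments on log variances
(digamma/trigamma matching, with a Newton trigamma inverse); the posterior
variance is (d₀s₀² + df·s²)/(d₀ + df) and the statistic is referred to a t
distribution on df + d₀ degrees of freedom.  `prior_df = 0` recovers the
ordinary paired t-test (tested), and an infinite prior (no excess spread)
collapses all variances to the common value.  M-values use
M = log2((β+ε)/(1−β+ε)) with ε = 1e−3; effect sizes (Δβ) are reported on
the β scale.  Multiple testing uses Benjamini–Hochberg across all tested
features; a brute-force step-up oracle checks the adjustment.

A probe is a DMP when q < 0.05 and |Δβ| ≥ 0.2.  The stringent filters are:
c1, |Δβ| ≥ 0.20; c2, more than 70% of tumour samples beyond the normal
mean ± 2·SD bound at that probe (above for hyper, mirrored below for hypo —
the mirroring is this package's reading, since the published form states
only the hypermethylated case); c3, mean normal β ≤ 0.25 for hyper and
≥ 0.25 for hypo probes, implemented exactly as printed even though the
hypomethylated bound is near-vacuous (a plausible misprint for ≥ 0.75); all
three thresholds are configuration.  A zero-variance normal probe would
make c2 degenerate, so the SD has a floor (default 0.01).  Age-related
probes are removed via a user-supplied exclusion list; the simulator emits
one drawn from effect-free probes.

## DMRs

A DMR is a maximal run of ≥ 2 significant same-direction probes with
|Δβ| > 0.2 in which consecutive probes lie ≤ 250 bp apart (chain rule).
Reading "within a 250 bp region" as a chain constraint rather than a total
span keeps multi-probe regions well-defined; a span mode (total span ≤ 250
bp, maximal non-nested windows) is available behind a flag.  "Significant"
defaults to q < 0.05 before the stringent filters, with a switch to require
the stringent pass.  An exhaustive run-enumeration oracle checks the caller
on random instances of ≤ 50 probes.

## 5hmC calling and transitions

The per-sample 5hmC-score is β_BS − β_oxBS (negative scores are retained
for QC but never produce calls).  Candidates need a score ≥ 0.3 in ≥ 3
samples of a tissue; definite calls keep the upper 75% of candidate mean
scores (the density cut's quantile is exposed — the published description
of this filter is internally inconsistent, simultaneously citing a third
quartile and > 80% retention, so the package documents the ambiguity and
makes the quantile a parameter).  Calls are made independently per tissue.
States are then assigned per tissue: called ⇒ hydroxymethylated; otherwise
methylated iff mean β_oxBS ≥ 0.3 (this numeric boundary is an artifact
decision, as no published definition exists) — and state changes are
classified into categories I–IV.

Transition-recovery tests run with the density cut disabled
(`density_quantile = 1.0`): the cut removes the bottom quarter of
candidates *by construction*, so recovered counts under the default filter
are ≈ 75% of planted counts for any planted level distribution; the
rank-and-cut behaviour of the filter is tested separately and exactly.

## Integration

Significant DEGs are merged by gene symbol with stringent DMP probes and
with category-I (de novo 5hmC) transition probes.  For every dyad,
Spearman's ρ is computed between the gene's expression and the probe's β
(or 5hmC-score for the de novo layer) across all samples, pooling both
tissues — pooling maximises dynamic range and is the default; a sample
subset can be supplied for per-tissue analysis.  Dyads with |ρ| strictly
above 0.5 are selected and labelled by concordance.  The 0.5 threshold
follows the headline usage; a conflicting 0.05 also appears in the source
description and would act as a near-null filter, so 0.5 is the default and
the threshold is configurable.  Selected genes are tested against gene
sets (GMT) with an upper-tail hypergeometric test, Bonferroni-corrected
across sets by default (BH available).

## Problem sizes and tolerances

Tests and the acceptance script run desk-scale studies chosen to make the
recovery statistics stable: 3 000–5 000 probes, 300–500 genes, 20–50 pairs
(the modelled study used 450K/EPIC arrays with ~10⁵–10⁶ probes and 70
pairs; effect recovery does not depend on probe count beyond multiple-
testing burden, which BH handles identically at both scales).  Documented
tolerances: DMP sensitivity ≥ 0.9 and empirical FDR ≤ 0.1 at Δβ = 0.3 with
30 pairs; DEG sensitivity ≥ 0.9 at log-FC 1.5; per-category transition
counts within ±15% of planted; end-to-end dyad recovery ≥ 85% at ρ = 0.9
with 50 pairs at the seed fixed in the tests.  Dyad recovery is bounded by
design below 100%: roughly one planted hyper DMP in five lands outside the
island/TSS context, where higher normal methylation fails stringent c3 (and
occasionally clamping shrinks the planted effect), so its dyad cannot pass
the stringent merge — across seeds end-to-end recovery ranges roughly
70–90%.  DMP-recovery simulations disable planted 5hmC: a 5hmC gain or
loss is a genuine BS-visible methylation change, and would otherwise be
counted as a false positive against the DMP truth table.

## What the simulator does not emulate

Probe chemistry (Type I/II design bias), batch and slide effects,
copy-number contamination of β values, cell-type composition, probe
cross-reactivity and SNP artifacts, and spatial autocorrelation of
methylation beyond the planted neighbour recruitment.  Passing recovery
tests therefore demonstrates correctness of the statistical machinery on
idealised beta-noise data, not robustness to array artifacts; on real
arrays the usual normalisation (e.g. Noob) and QC must happen upstream,
since the pipeline consumes normalised matrices by design.
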