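# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential expression model

Counts for gene g, sample j are modelled as negative binomial with mean
μ<sub>gj</sub> and dispersion α<sub>g</sub> (Var = μ + αμ²), log link, and
the median-of-ratios size factor as offset. Two designs are supported:
`~ sex + tissue` over all tissues of one species (tissue-combined) and
`~ sex` within one tissue (tissue-specific). The contrast is male minus
female, reported on the log2 scale, so positive LFC = male-biased. A gene
is an SBG when its BH-adjusted Wald p is below α = 0.05 (configurable);
there is deliberately no fold-change cutoff, because ongoing sexually
antagonistic selection is expected to produce nuanced expression
differences that a hard LFC threshold would discard.

**Filtering.** A gene is kept when it has ≥ `min_count` (5) reads in
strictly more than `min_samples_exclusive` (3) samples, i.e. in ≥ 4 samples
at the defaults. Filtering is applied to the exact matrix entering each
run.

**Size factors.** Median-of-ratios over reference genes (positive counts in
all samples): factor_j = median_g count_gj / geomean_g. If no gene is
positive everywhere the estimator refuses and points at filtering.

**Dispersion.** Per gene, a method-of-moments estimate pooled over design
cells (sex × tissue groups with ≥ 2 replicates):

    α̂ = Σ_c df_c (v_c − ξ m_c) / Σ_c df_c (m_c² − v_c/n_c),   ξ = mean(1/s_j)

The ξ term removes the Poisson contribution of normalized counts; the
`m² − v/n` denominator is unbiased for μ² (using m² alone biases α̂ low).
With 3 replicates per cell the gene-wise estimate is very noisy, and noise
in α̂ translates directly into anti-conservative Wald statistics, so the
estimates are moderated: a trend α(μ) = a₀ + a₁/μ is fitted through binned
mean estimates and each gene's log-dispersion is shrunk towards the trend
by a precision-weighted average, treating the gene-wise log-estimate's
sampling variance as 2/df and the gene-to-gene spread of true
log-dispersions as `prior_var` = 0.1. Raw estimates are clipped to
trend × e<sup>±4</sup> first so a single outlier cannot drag the average,
and everything is floored at 1e-8. `trend_shrinkage=False` restores the raw
estimator. There is no outlier replacement, no independent filtering, and
no likelihood-based MAP step; these simplifications are intentional and
their absence is visible mainly as slightly conservative behaviour on
genuinely high-dispersion outlier genes.

**Fitting.** IRLS (Fisher scoring) with fixed per-gene dispersion,
vectorised across genes (shared design matrix, batched p×p solves);
convergence at relative coefficient change < 1e-8, max 100 iterations.
Genes that fail to converge or produce a non-positive-definite information
matrix get p = NA and are excluded from the BH family. Standard errors come
from the inverse Fisher information at the optimum; the Wald p is two-sided
standard normal. The Poisson-limit closed form (α → 0, two groups: the
coefficient equals the log-ratio of size-factor-weighted group means) and
statsmodels' NB GLM serve as independent oracles in the tests.

**QC.** `pca_qc` runs a centred PCA of samples over the top-variance genes
of log2(normalized count + 1). A full variance-stabilising transformation
with a fitted dispersion trend is not implemented; the QC claims this PCA
supports (tissue separation, replicate clustering) are qualitative.

## Chromosome landscape

Genes are classed per species as sex_chromosome (per declared sex-linked
linkage group), autosome, or excluded (mitochondrial or unplaced; flags
come from annotation columns, falling back to configurable
chromosome-name patterns). Species with unknown heterogamety yield no
sex-chromosome labels and are excluded from those contrasts. Enrichment
tests are two-sided Fisher exact tests on (SBG vs not) × (chromosome vs
autosomes); sidedness is configurable but two-sided is the conservative
default. For a species with two sex-linked groups each is tested against
autosomes excluding the other. Shared-SBG tests intersect the two species'
tested gene universes first and count a gene as shared when it has the same
bias class in both. Denominators for per-chromosome proportions are
*expressed* (tested) genes, not all annotated genes; this choice is
deliberate and configurable at the call level by passing a different DE
table. Bias-intensity comparisons use Wilcoxon–Mann–Whitney for two groups
and Kruskal–Wallis for three or more.

## Divergence statistic

Δx = d/(f·r) per gene, computed on log2(TPM + pseudocount) replicate
vectors, per tissue and sex. The printed ancestral form of d is ambiguous
about parenthesisation; this package reads d as the *relative* divergence
(x̄_focal − x̄_related)/x̄_focal, consistent with r being a relative range
— the alternative reading (x̄_focal − x̄_related/x̄_focal) is available as
`divergence_form="unnormalized_focal"` for comparison but is not a
relative quantity and is not the default. f = √((mN−1)/(mN−m)) with N = 3
by default; note f *increases* with m towards √(N/(N−1)), so larger focal
sample sizes shrink |Δx| slightly. Genes with zero focal mean or zero
range get an undefined class rather than ±∞ and are, by default, excluded
from both cells of enrichment tables (`undefined_policy="not_selected"`
counts them as not-under-selection instead). The TPM pseudocount (1.0) is
applied before the log; it is configurable because the original procedure
leaves it unstated.

## RRHO

DDE = −log10(p) × sign(LFC), with p floored at 1e-300 before the log and
adjusted p used by default (raw p available via `p_source`). Both profiles
are restricted to shared genes, ranked ascending in DDE (rank 1 = most
female-biased; ties broken by gene id for determinism), and binned with
stepsize ⌈√n⌉ unless overridden. Each grid cell's p-value is the
hypergeometric tail matching the observed direction (over- vs
under-enrichment relative to the expected overlap s₁s₂/n); BY step-up over
all cells is used for correction since the overlapping prefixes are
arbitrarily dependent. The concordance proportion counts sign agreement of
DDE among genes with nonzero DDE in both species; a quadrant-based
definition was considered and rejected as the default because it depends on
the significance map, but the grid output contains everything needed to
compute it. The two-sided "split" RRHO variant is out of scope.

## Synthetic-data generator

The generator emulates the underlying study's design: per species, five
tissues (gonad, brain, gills, liver, lower pharyngeal jaw) × two sexes ×
three replicates; ~25,000 genes on 22 linkage groups plus a mitochondrial
contig (37 genes at full scale) and ~3% unplaced scaffold genes. Counts are
NB with

    μ = 2^(baseline_g + tissue_gt + s_j·lfc_g/2) · sf_j

(s_j = ±1 by sex), so a gene's male/female log2-ratio equals its true lfc
while its overall level is unaffected. Defaults, chosen once as realistic
bulk RNA-seq values where the emulated study states none: baseline log2
mean 5 ± 2, tissue effects N(0, 1), dispersion α = 0.15, library-size
spread 1.5×, gene lengths uniform on 200–20,000 bp. Sex-bias structure:
2% of autosomal and 10% of sex-linked genes are SBGs, |lfc| ~ |N(2, 0.5)|,
and the female-bias probability on sex-linked chromosomes is 0.8 for ZW
species (mirrored to 0.2 for XY) versus 0.5 on autosomes — this is the
feminisation/masculinisation the landscape module must recover.

Randomness is split into a universe stream (gene ids, chromosomes, lengths,
baselines, tissue effects, shared bias assignments) and one stream per
species seeded by (seed, CRC-32(species name)), so adding or reordering
species never changes another species' data. Cross-species sharing: each
gene's bias assignment is taken from the universe draws with probability
`shared_sbg_fraction` (default 0.7) and drawn privately otherwise; both
routes use the same class-dependent fractions, so the marginal SBG rate is
unchanged while the expected fraction of a species' SBGs shared with
another species equals the configured value.

For the divergence statistic, `simulate_species_pair_for_dx` produces
linear TPM-like replicate tables (log-normal noise, CV 0.1) for a focal and
a related species on the same gene universe, with a +2 log2 mean shift in
the focal species for 40% of sex-biased and 5% of unbiased genes
(`outgroup_shift_fraction_sbg` / `outgroup_shift_fraction`). The split into
two shift rates exists so that selection-enrichment recovery is a real
signal, not a tautology.

What the generator does **not** emulate: read-level artefacts (mapping
bias, multi-mapping, 3' bias), batch effects, isoform structure,
correlated gene-gene expression, dosage compensation gradients along the
sex chromosome, and lineage-specific dispersion differences. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Problem sizes used by tests and the acceptance script

Simulation-based checks run at 2,000 genes (150-gene sex chromosome where
one is needed), three tissues for DE calibration and five for the
landscape recovery, 3 replicates per sex, with 20 seeds for null
calibration and 50 for the recovery rates; exact-test oracles enumerate
2×2 tables with totals up to 60 and RRHO instances up to 30 genes. These
sizes keep the full suite in the low tens of seconds while leaving the
Monte-Carlo error of each reported rate at or below the percent level. The
numbered analysis scripts run five species at 4,000 genes.

## Known limitations

- The DE machinery approximates, but is not, DESeq2: no MAP dispersion
  estimation, Cook's-distance outlier handling, or independent filtering.
  At 3 replicates per cell its empirical FDR in signal-rich simulations
  runs above nominal (as small-n NB Wald pipelines generally do), though
  null calibration is good.
- N (the reference sample size in f) is a global parameter, default 3; it
  is not recomputed per tissue when replicates are missing.
- Fisher tests are two-sided throughout; one-sided variants exist behind
  flags but are not used by the drivers.
- The RRHO map reports directional tail p-values per cell; permutation
  calibration of whole-map significance is out of scope.
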