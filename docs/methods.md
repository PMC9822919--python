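# Methods

## Statistical model

### Gene expression prediction models

Prediction weights are built from marginal cis-eQTL summary statistics, not
from penalized re-training on individual-level data. For each gene:

1. **FDR filter.** Benjamini–Hochberg is applied to the gene's own cis
   p-values (within-gene scope), and records with adjusted p ≥ 0.1 are
   dropped. The sentence-level ambiguity between within-gene and
   transcriptome-wide adjustment is genuine in this design, so the scope is
   a config switch (`BuildConfig.fdr_scope`, default `"gene"`); within-gene
   is the default because the filter is described as acting inside each
   gene's record set.
2. **LD clumping.** Greedy: the remaining variant with the smallest p-value
   is kept, and every other remaining variant within ±250 kb whose squared
   dosage correlation with it in the reference panel is ≥ 0.1 is discarded;
   repeat. Ties in p are broken by (position, variant_id) so the result is
   invariant to input row order. r² is computed on panel dosages (panels
   ship as genotypes, not haplotypes).
3. **Weights and variance.** Each retained variant keeps its marginal eQTL
   beta as weight w_l (SD of expression per effect allele). Its variance
   share is 2·p·q·β² (p, q the allele frequencies from the eQTL file,
   Hardy–Weinberg), and V_g = Σ_l 2p_l q_l β_l².
4. **Gene-level variance bounds.** Genes with V_g > 2 or V_g < 0.01 are
   excluded; the bounds themselves survive because the exclusion is strict.
   The lower bound removes genes with essentially no genetic regulation, the
   upper bound removes genes whose marginal-weight models are inconsistent
   with standardized expression (total explained variance cannot sensibly
   exceed the expression variance by that much; it indicates LD
   double-counting or unstable estimates).

Because weights are marginal betas after clumping rather than joint
estimates, residual LD below the r² = 0.1 threshold can double-count a
little signal. This is a property of the modeled procedure, not an
implementation artifact.

### Summary-statistic association

For weights w over the model variants, GWAS per-variant z-scores z_l and
betas β_l, and reference dosage SDs σ_l and covariance Γ:

    σ_g² = wᵀ Γ w
    Z_g  = Σ_l w_l σ_l z_l / σ_g
    γ̂_g  = Σ_l w_l σ_l² β_l / σ_g
    se_g = |γ̂_g / Z_g|,  p = 2 Φ(−|Z_g|)

Σ_l w_l σ_l² β_l equals the covariance between the trait and the weighted
dosage score, so γ̂_g is the regression slope of the trait per **standard
deviation** of predicted expression — the scale on which effects are
comparable across genes and tissues, and the scale on which a simulated
α (trait SD per SD of GReX) is recovered. Dividing instead by σ_g² would
give the slope per raw unit of the weighted score, which depends on the
arbitrary overall scale of the weights. Both Z_g and γ̂_g are invariant to
multiplying all of a gene's weights by a positive constant.

σ_l and Γ default to panel-empirical dosage moments (ddof = 1) so numerator
and denominator are mutually consistent; the Hardy–Weinberg value
σ_l² = 2p(1−p) is available as a fallback when no panel is supplied but a
covariance file is. When a per-gene covariance file is present it is used;
genes whose covariance entries are incomplete fall back to the panel, and
genes with neither are reported in the skip table rather than silently
dropped. A predicted-expression variance at or below 1e-12 marks the gene
"degenerate" (a fully pruned or monomorphic model) instead of dividing by
numerical zero. p-values are two-sided standard normal, matching the
statistic's asymptotic null.

### Multi-tissue accounting and exclusivity

All gene×tissue results for one phenotype are pooled; the Bonferroni
threshold is α / (pooled test count), because the headline percentages in
this study design are quoted against the pooled totals rather than
per-tissue counts. "Suggestive" means p < 0.05; both comparisons are strict.
A gene significant in the focal tissue is *exclusive* when no other tissue
in which it was tested is significant at the study-wide threshold. A
focal-significant gene with no model anywhere else cannot be distinguished
from "tested and null" by significance alone, so it counts as exclusive but
carries `tested_in_n_tissues = 1`, letting downstream consumers apply either
reading. Genes are matched across tissues by version-stripped stable ID, so
distinct genes sharing a symbol remain distinct.

### Enrichment

Over-representation of a query list in a gene set uses the upper-tail
hypergeometric probability P(X ≥ k), X ~ Hypergeom(N, K, n), with BH
adjustment across the tested sets (matching the adjusted-p convention of
common web annotation tools). The background defaults, in pipeline use, to
all genes that had a prediction model in the focal tissue — the least biased
universe available to a summary-statistic pipeline. Sets below the overlap
floor (default 1) are omitted; query or set genes outside the background are
dropped with a warning so the urn stays consistent.

## Synthetic data generator

The generator emulates the three study inputs with known truth.

**Genotypes.** A haplotype-copy model: variants sit every `variant_spacing`
bp (default 5 kb) on one chromosome and are grouped into blocks of
`ld_block_size` (default 10). Each block draws one allele frequency uniform
on `maf_range` (default [0.05, 0.5]); within a block, each haplotype allele
copies the previous variant's allele with probability ρ (default 0.7) and is
redrawn from the block frequency otherwise. Sharing one frequency per block
makes the adjacent-variant correlation exactly ρ (lag-k: ρᵏ); blocks are
independent. Dosages are sums of two independent haplotypes. The reference
panel, eQTL cohort(s) and GWAS cohort are independent draws from this same
population, mirroring the use of an external LD reference while keeping the
summary≈individual-level equivalence exact in expectation.

**eQTL summary statistics.** Each gene has `n_causal_eqtl` causal cis
variants (a fraction `shared_frac` shared across tissues with shared raw
effects b ~ N(0,1); the rest tissue-specific). Raw expression is the causal
dosage sum plus Gaussian noise scaled so the cis-genetic fraction of
expression variance is `eqtl_h2`; expression is then standardized, and the
reported records are per-variant simple regressions (t-based p, n−2 df) of
standardized expression on dosage over the gene's cis window (default
±50 kb). Genes listed in `exclusive_true_genes` are genetically regulated
only in the first (focal) tissue. The default eQTL cohort size of 150
matches the scale of a single-tissue placental expression study.

**GWAS summary statistics.** The trait is Σ_g α_g · standardized-GReX_g plus
N(0, `trait_noise_sd`²) noise, then standardized to unit variance (a z-score
trait); GReX uses the focal tissue's causal architecture. Records are
per-variant marginal regressions over all panel variants. Because the
genetic contribution inflates the pre-standardization trait variance, the
estimand of γ̂ for a truth gene is α·corr(GReX, predicted GReX)/sd(trait) —
e.g. ≈ 0.287 for α = 0.3 at the default noise SD of 1 with a near-perfect
model. Recovery tests compare against α with a ±0.05 band that absorbs this
designed attenuation.

**What the generator does not emulate:** realistic human LD maps and allele
frequency spectra, imputation noise, sample overlap between the eQTL and
GWAS cohorts, population stratification, trans effects, and non-Gaussian
expression. Passing tests therefore demonstrate the correctness and
calibration of the procedure under its own assumptions, not robustness to
those real-data complications.

## Numerical and interface choices

- Files are plain TSV with header; floats are written as `%.17g` and parsed
  with round-trip-exact converters, so every writer/reader pair is an exact
  inverse.
- Allele harmonization aligns GWAS and panel to the model's effect allele:
  swapped alleles flip the signs of beta and z and replace eaf by 1−eaf;
  palindromic (A/T, C/G) variants are dropped by default since summary files
  carry no strand information; pairs matching neither orientation are
  dropped and counted as mismatched. Harmonizing an already-harmonized set
  is a no-op, and retained+dropped counts always sum to the input count.
- Gene IDs are version-stripped before any cross-source matching.
- Coordinates are 1-based basepairs; the clump window is ±250 kb around the
  index variant (standard clumping convention).
- Determinism: every stochastic step derives its generator from the scenario
  seed through named streams (population, architecture, panel, per-tissue
  eQTL cohort, per-phenotype GWAS cohort), so any artifact is reproducible
  from (scenario, seed) alone and re-runs are byte-identical.

## Validation study sizes

The seeded validation studies in `sumtwas.studies` use desk-scale designs
chosen to make their target quantities measurable with comfortable margins:
global-null calibration over 500 modeled genes (eQTL n = 2,000, GWAS
n = 5,000); summary-vs-individual z comparison over 50 genes with the GWAS
cohort (n = 5,000) doubling as the reference panel, where the two routes
agree to corr > 0.999 and max |Δz| < 0.1; effect recovery with 50
independent replicates at α = 0.3 (eQTL n = 5,000, GWAS n = 20,000,
single-causal-variant genes); and a five-tissue exclusivity study (60 genes,
eQTL n = 3,000 per tissue, GWAS n = 15,000) with six focal-only truth genes,
three cross-tissue truth genes, and a second phenotype sharing one focal-only
truth gene.

## Known limitations

- Marginal-beta weights are not jointly fit; models in long-range LD regions
  can double-count signal below the clumping threshold.
- The exclusivity call inherits the power of every comparison tissue: a gene
  can be "exclusive" simply because other tissues' models are weak. The
  `tested_in_n_tissues` field exposes the most extreme case only.
- The enrichment background must be supplied (or defaulted to model genes);
  results are sensitive to that choice, and no gene-set database ships with
  the package.
- Only biallelic A/C/G/T variants are supported; no liftover, rsID
  resolution, VCF/PLINK ingestion, colocalization, or joint multi-gene
  fine-mapping.
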