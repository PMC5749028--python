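# Methods

## The resampling model

`triadgen` simulates genome-wide autosomal SNP genotypes by resampling an
existing panel of case-parent triads (an affected offspring and both
biological parents) rather than by simulating an evolutionary process.  The
construction has three ingredients:

1. **Complement triads.**  For every observed triad the pool also contains
   a hypothetical triad with the same parents and a child carrying the
   parental alleles *not* transmitted to the case.  At the genotype-count
   level the complement child is `m + f − c`, which is well defined without
   phasing: even when mother, father and child are all heterozygous, both
   phase resolutions leave a heterozygous complement.  Because every
   transmitted allele in the pool is balanced by its non-transmitted
   counterpart, the pool carries no net association between child genotype
   and the ascertained phenotype — resampling from it destroys the risk
   signals in the source data while leaving parental allele frequencies
   untouched (parents are duplicated, not resampled).

2. **Fragment resampling at recombination hotspots.**  For each simulated
   triad a fresh set of `k` break points per chromosome (default 3) is
   drawn uniformly without replacement from the candidate boundaries of a
   hotspot track; each resulting chromosomal fragment is then filled by the
   mother/father/child slices of one pool triad drawn uniformly with
   replacement from all 2N rows.  Treating the *triple* of fragments as the
   resampling unit preserves local LD and transmission patterns exactly and
   imposes no random-mating assumption.  LD between markers separated by a
   chosen break point is attenuated by the probability that the boundary is
   cut, which is small when candidates are numerous (see *Fixture
   geometry*).

3. **Parent-label switching.**  After splicing, mother and father vectors
   are exchanged with probability 1/2, removing parental asymmetries (e.g.
   maternal-effect enrichment) from the source.  The switch is applied once
   per simulated triad, after assembly.

## Trait models

Phenotypes are assigned to the simulated offspring through log-linear
models in *pathway indicators*.  A pathway is a set of SNPs; its indicator
X is 1 when the offspring carries at least one variant allele at every SNP
in the set (dominant coding per SNP; a single SNP is a 1-SNP pathway).
With p pathways, exposure E ∈ {0,1}, and parameter vectors β, γ:

* dichotomous: `log P(affected | X, E) = α + β′X + θE + γ′(E·X)` —
  α is the log baseline risk among unexposed non-carriers, β the log
  relative risks, θ the exposure main effect, γ the interaction effects;
  pathway contributions combine multiplicatively on the RR scale.  The
  model is validated at construction: a configuration whose penetrance
  exceeds 1 at any realizable (X, E) cell is rejected.
* quantitative: `Y = α + β′X + θE + γ′(E·X) + ε`, ε ~ Normal(0, σ),
  σ defaulting to 1; effects are additive mean shifts.

Effects may be given as odds ratios (`effect_scale="OR"`); each effect cell
is converted to a relative risk against the baseline via
`RR = OR / (1 − p0 + p0·OR)` before use.  Conversion is cellwise — each
single-effect contrast is converted on its own and multi-effect cells use
the product of converted RRs — the simplest reading consistent with
accepting either scale.

## Study designs and the two-stage generation loop

Designs: `case_parents`, `control_parents`, `case_only`, `case_control`
(with a user-set control:case ratio filled from a single candidate stream),
and `population_qt` (every offspring retained).  With stratified sources,
each candidate first draws a subpopulation by its population proportion;
subpopulations share all risk parameters except the baseline α and the
exposure prevalence.

At a realistic baseline risk (~1.7 per 1000) a case design discards ~99.8%
of candidates, so generating whole genomes per candidate is wasteful.  The
loop therefore draws, at stage 1, the candidate's fragment plan *and the
pool row for every fragment*, materializes only the pathway-SNP genotypes,
computes X, draws E and the phenotype, and applies the retention rule.
Stage 2 materializes full genomes only for retained candidates from the
stored draws.  Because the phenotype depends on the genome solely through
the pathway loci, which are fixed at stage 1 together with every fragment
choice, the two-stage path is *exactly* the full-generation path with
materialization deferred; a chi-square test against an independently coded
full-generation implementation confirms the retained pathway-genotype
distribution matches.  Within a batch, retention is capped in candidate
order so quotas never overshoot (capping the assembled output instead
would bias the subpopulation mix of the last batch).

## Estimators

* **Case-parent studies** are analyzed by the matched case-complement
  conditional likelihood: within each family,
  `P(case child | pair) = exp(η_case) / (exp(η_case) + exp(η_comp))` with
  `η = β′X + γ′(E·X)`; α and θE cancel within pairs, which also makes the
  estimator invariant to baseline risk and robust to population
  stratification.  The likelihood is exact because a child genotype vector
  and its complement are equally probable transmissions.  The score is
  solved by Newton iteration with Firth's Jeffreys-prior correction by
  default: interaction terms may be informed by only a few dozen
  discordant pairs per study, where the unpenalized estimate carries
  first-order bias and can fail to exist under separation.  Wald 95% CIs
  are formed on the log scale and reported exponentiated.
* **Cohort samples** use statsmodels: least squares for quantitative
  traits (with subpopulation intercepts when labels are present),
  log-link binomial regression for cohort RRs, logistic regression for ORs.
* **TDT**: transmissions b vs non-transmissions c of the counted allele
  from heterozygous parents, `χ² = (b−c)²/(b+c)` on 1 df.
* **MAF prediction intervals** use exact binomial quantiles (not the
  normal approximation), which matters for rare alleles.

## The synthetic source generator

Real triad GWAS panels are access-controlled, so evaluation runs on
generated sources.  Each chromosome is a chain of haplotype blocks; a block
holds H = 10 haplotypes with fixed rank frequencies
(0.30, 0.20, 0.15, 0.14, 0.10, 0.05, 0.03, 0.02, 0.005, 0.005).  A parental
chromosome walks the blocks keeping its haplotype rank with probability
1 − r at each boundary (default r = 0.35); children receive one recombinant
haplotype per parent with crossovers only at block boundaries.  Emitted
triads are therefore Mendelian-consistent by construction, blocks show
strong internal LD, cross-block LD decays as (1 − r) per boundary, and the
generator's block boundaries double as the hotspot track handed to the
fragmenter — fixture and simulator share one recombination geography.

Per-SNP allele frequencies are set by assigning the variant allele to the
subset of haplotype ranks whose total frequency best matches a target
(exact enumeration of all 2^10 subset sums, ties sampled at random).  The
default rank weights realize the scenario frequencies 0.15, 0.30 and 0.50
exactly and rare frequencies down to 0.005.  The default test fixture uses
4 chromosomes × 500 SNPs in 25-SNP blocks with ~15% rare (< 0.02) SNPs.
An ascertained variant of the generator retains only families whose child
is affected under a planted risk model, producing genuine transmission
distortion for signal-destruction experiments.

What the generator does *not* emulate: coalescent-realistic allele
frequency spectra, mutation, genotyping error and missingness patterns of
real arrays, and LD that decays smoothly *within* a block.  Tests passing
on these fixtures certify the resampling, ascertainment and estimation
machinery, not robustness to real-data artifacts.

## Evaluation study conditions and problem sizes

The evaluation battery (`triadgen.experiments`, driven by
`scripts/acceptance.py`) uses:

* **LD/MAF preservation**: 4 chromosomes × 500 SNPs, all common
  (MAF ≥ 0.05), 10-SNP blocks, 1000 source families; 200 null replicates of
  1000 triads with k = 3.  Ten-SNP blocks give 49 candidate boundaries per
  chromosome so a single boundary is cut in ~6% of triads — the desk-scale
  analogue of drawing 3 break points among the hundreds of hotspots on a
  real chromosome.  Reported: correlation between source pairwise genotype
  r (pairs within 200 kb) and the across-replicate mean r; average fraction
  of pairs with |Δr| < 0.1; average fraction of SNPs with |ΔMAF| < 0.02;
  mean/median empirical coverage of exact 95% binomial MAF prediction
  intervals over the 4000 parental alleles per replicate.
* **Signal destruction**: one 200-SNP chromosome, 1000 families ascertained
  on a planted dominant RR = 3 locus at MAF 0.3; 2000 null replicates, TDT
  at the planted locus.
* **Stratified-null recovery**: two subpopulations with pathway-SNP MAFs
  ~0.15 vs ~0.50, subpopulation-two proportion 0.46, baseline risks 1.7%
  and 5%; 200 case-parent studies of 1000 triads.
* **Quantitative recovery**: mean shifts 0.1 / 0.15 at two disjoint 4-SNP
  pathways picked at founder MAF 0.30 ± 0.02 (minimum inter-SNP gap 300 kb,
  scaled to the ~1.6 Mb fixture chromosomes); 200 population samples of
  1000 offspring.
* **G×E recovery**: pure-interaction RRs 1.65 / 2.71, genetic and exposure
  main effects 1, exposure prevalence 0.5 (a design choice; any moderate
  prevalence works); 100 case-parent studies of 1000 triads.

The case-design scenarios run at baseline risks ten times the
epidemiological values they emulate (1.7% / 5% instead of 0.17% / 0.5%;
1.66% instead of 1.66 per 1000).  The matched conditional likelihood is
exactly invariant to the baseline — it cancels within every pair — so the
recovered effects are unchanged while candidate counts drop tenfold.

## Numerical choices and degenerate inputs

* Genotypes are `int8` counts of the counted allele with −1 for missing;
  for text input the counted allele is the founder minor allele (ties
  broken lexicographically) unless overridden.
* Mendelian QC: a locus-level inconsistency is routed per policy (`error`,
  `drop_triad`, `set_missing`, default `set_missing`); families with more
  than 1% inconsistent loci are dropped as evident nonpaternity.
  Complement children are missing wherever any of (m, f, c) is missing.
* Constant genotype columns yield flagged NaN correlations and are excluded
  from LD summaries; empty decay-curve bins are NaN, never zero.
* A hotspot nominates boundary b only when its midpoint falls strictly
  inside the gap (bp[b−1], bp[b]); without a track every inter-marker
  boundary is a candidate.  Requests for more break points than candidates
  use all candidates with a warning; k = 0 copies whole chromosomes.
* Case generation aborts with a diagnostic after a candidate cap (default
  10⁷) when the retention probability is (near) zero.
* Reproducibility: one `numpy` Generator per study, spawned via
  `SeedSequence` from the master seed, with all within-study draws in fixed
  order; parallelism is across studies only, so results do not depend on
  the worker count.

## Known limitations

* Resampling cannot introduce variants absent from the source, and rare
  alleles (MAF < 0.02) show the largest relative LD/MAF fluctuations.
* Only dominant per-SNP coding within pathways; no maternal-effect,
  parent-of-origin, polytomous or multivariate traits; no haplotype-level
  output; autosomes only.
* At a locus with a *strong* planted dominant signal, resampled null data
  make the classic TDT slightly conservative: ascertainment enriches
  heterozygous children, whose complements are also heterozygous at
  double-heterozygous-parent loci, so both pool children contribute zero
  net transmissions and the pool's transmission variance falls below the
  b + c denominator (variance ratio ≈ 0.90–0.95 at RR = 3, MAF 0.3,
  rejection ≈ 0.039–0.045 at α = 0.05).  Type I error is never inflated;
  the effect shrinks with the planted effect size and disappears for
  non-ascertained sources, where the TDT is exactly calibrated.
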