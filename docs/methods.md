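# Methods

This note records the models implemented, the defaults and why, the
numerical choices, what the synthetic data do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Selection theory (`mkconcord.theory`)

The closed-form layer models new nonsynonymous mutations as a three-point
mixture: neutral (fraction 1 − p − q), advantageous (fraction p,
coefficient s₁ > 0) and deleterious (fraction q, s₂ < 0), with fixation
probability f(N, s) = (1 − e^(−2s)) / (1 − e^(−2Ns)) in a haploid
population of size N (`ploidy=2` doubles N at the interface). The expected
divergence ratio is R = (1 − p − q) + p·N·f(N, s₁) + q·N·f(N, s₂); when s₁
is small but 2Ns₁ ≥ 1 and deleterious mutations essentially never fix, this
reduces to R = 1 + p(2Ns − 1) − q, and the polymorphism ratio to
Pa/Ps ≈ 1 − q. `f` is evaluated with `expm1` and switches to log-space
when −2Ns > 700, so it is stable for |Ns| to at least 10⁴ and underflows
cleanly to 0 for strongly deleterious mutations. A warning is emitted when
s₁ or |s₂| falls below 1/(2N), where the reduced form's assumptions break;
the package guards rather than guesses there. Only point-mass selection
coefficients are supported — no distribution of fitness effects.

## Codon counting (`mkconcord.counting`)

Ka/Ks is estimated by an approximate counting method of the Nei–Gojobori
family, with two refinements:

* **Kappa-weighted site counting.** Each codon position contributes the
  kappa-weighted fraction of its viable single-base changes that are
  synonymous (transitions weighted κ, transversions 1), normalized per
  position so synonymous + nonsynonymous sites = 3 per codon exactly.
  Changes that would create a stop codon are excluded from the opportunity
  before normalizing: nonsense mutations are removed essentially instantly
  and are not part of the observable mutational opportunity. This choice is
  load-bearing: counting stop-targets as nonsynonymous opportunity biases
  the neutral (ω = 1) estimate about 5% downward (computed analytically
  from the estimator's large-length limit), while with nonsense exclusion
  the neutral limit is within 1% of 1 across the divergence range used
  here. κ defaults to a fourfold-degenerate-site estimate (twice the
  observed ts/tv count ratio, since one transition target faces two
  transversion targets), falling back to 2 when uninformative.
* **Pathway-averaged differences with stop avoidance.** Differences between
  codons are classified by averaging over all orderings of the changed
  positions whose intermediates are not stops; pairs with no stop-free path
  are skipped with a warning. Proportions are corrected for multiple hits
  with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3) (toggleable); p ≥ 3/4 or
  Ks = 0 flag the ratio undefined rather than raising.

The estimator is accurate for ω up to a few but compresses large ratios
(at ω = 11 the large-length limit is ≈ 7.5 at 4% divergence, dropping with
divergence) — multiple hits within codons outrun the per-site correction.
The likelihood machinery, not counting, is the tool for strongly selected
genes; the class-convergence test therefore checks counting in its valid
regime (ω ≤ ~2.5) and the qualitative elevation beyond it.

Lineage-specific ratios use unweighted parsimony per alignment position:
where the ingroup sequences differ and the outgroup matches exactly one
state, the matched state is ancestral and the change is assigned to the
other lineage. A codon containing a position the outgroup resolves for
neither state is discarded and tallied as ambiguous. Position-wise (rather
than whole-codon) resolution matters at realistic divergence: requiring the
outgroup to match an entire ingroup codon preferentially discards
fast-evolving codons and with them most of the adaptive signal. Site totals
are shared between the two lineages (averaged over the ingroup sequences).
Gapped or ambiguous codons are dropped pairwise throughout.

## Polymorphism (`mkconcord.polymorphism`, `mkconcord.vcfio`)

Segregating coding sites are classified synonymous/nonsynonymous/nonsense
from their ancestral codon context; nonsense variants are excluded from Pa
by default (toggle provided). Polarization uses a single outgroup allele:
if it matches one of the two segregating alleles the other is derived;
otherwise the site is flagged unpolarized and excluded, as are triallelic
sites — the frequency cutoff is defined on derived frequency, so folding is
not an option. Singletons are derived-allele count 1. The CpG flag marks a
site whose ancestral context places it in a CG dinucleotide on either
strand (C before G, or G after C); ancestral context is preferred, the
reference context is the documented fallback, and missing context leaves
the site unflagged with a warning. The frequency cutoff defaults to 0.2
(strictly greater) everywhere; the placement of the "steady level" seen in
real frequency profiles is a user decision, not auto-detected. Per-site
sample sizes are carried per site, so missing genotypes shrink individual
denominators rather than dropping sites. The heterozygous mode computes
Pa/Ps over the heterozygous sites of a single diploid genome (sample size
2; no cutoff applies). VCF input (biallelic SNPs with an `AA` ancestral
tag, allele counts from `AC`/`AN` or genotypes) is mapped to codon
coordinates through BED coding intervals plus the coding sequence;
plus-strand, in-order intervals are assumed.

## MK test (`mkconcord.mk`)

The 2×2 table holds integer Dn, Ds (raw assigned differences, not
JC-corrected — table integrality; a correction toggle exists but is off)
and filtered Pn, Ps. Fisher's exact test defaults to one-sided in the
adaptive direction (excess Dn/Ds), with the two-sided variant available;
degenerate margins return p = 1 with a flag. α = 1 − (Ds·Pn)/(Dn·Ps) may be
negative (reported as-is); A1 = max(α, 0)·Dn is floored at zero because it
counts sites. For merged genes two pooled estimators are implemented:
summing the four counts before applying the formula (exactly the merged
table's α), and a divergence-weighted average of the per-gene neutral
ratios with weights ∝ Dn, which damps the bias arising when polymorphism
level and nonsynonymous divergence are negatively correlated across loci.
The weighted variant is the default for supergenes and the method used is
recorded in the result metadata.

## Codon site models (`mkconcord.sitemodel`)

The substitution process is Goldman–Yang-style on the 61 sense codons: only
single-nucleotide changes, target-frequency πⱼ times κ for transitions
times ω for nonsynonymous changes; reversible by construction. Codon
frequencies default to F1x4 (F3x4 and uniform available) — the choice a
practitioner's default configuration would make. Likelihoods use
Felsenstein pruning over alignment column patterns (compressed once per
fit), with transition matrices from the symmetrized eigendecomposition
P(t) = Π^(−1/2) U e^(Λt) Uᵀ Π^(1/2), memoized per (κ, ω). Mixtures share
one normalization: class matrices are left unscaled and branch lengths are
divided by the weighted mean rate, so lengths are expected substitutions
per codon averaged over classes.

M1a (p₀ with ω₀ ∈ (0,1); p₁ with ω₁ = 1) and M2a (plus p₂ with
ω₂ ∈ [1, 50]) are maximized with L-BFGS-B over log-κ, log branch lengths
and bounded class parameters (M2a proportions parameterized as p₂ and the
conserved share of the remainder, keeping the simplex constraint built-in).
M2a starts at the M1a solution with a vanishing selected class plus
`n_restarts` random restarts (default 2, seeded and recorded), and the
reported lnL_M2a is never allowed below lnL_M1a — the p₂ → 0 boundary
reproduces M1a exactly, so the fit falls back there when the optimizer
finds nothing better. The LRT statistic 2ΔlnL is referred to χ²(2),
standard practice for this comparison; the boundary-mixture refinement is
noted but not implemented, making the test conservative (the calibration
test shows rejection well under the nominal 5%). ω₂ is capped at 50 to
keep matrices well-conditioned. A2 = p₂·L; A2′ counts codons whose
posterior probability of the selected class exceeds 0.5 (configurable).
Posteriors are naive empirical Bayes at the MLEs (NEB) — full
Bayes-empirical-Bayes integration over parameter uncertainty is out of
scope, and outputs are labeled NEB to avoid misrepresentation. Optimizer
non-convergence flags the result instead of raising. Branch-site and
free-ratio models, and gamma rate variation beyond the 2/3-class mixtures,
are out of scope.

## Synthetic data (`mkconcord.simulate`)

The generator reproduces the statistical structure the analysis assumes,
at two levels.

**Sequence level.** Codon sites are assigned i.i.d. to neutral /
deleterious / advantageous classes; each class evolves along the tree with
ω from the fixation model (1, N·f(N, s₂) ≈ 0, and min(N·f(N, s₁), 50)).
Per-class matrices are rescaled so one unit of branch length is one
expected synonymous substitution per synonymous site in every class —
Ks is then shared and each class's expected Ka/Ks is its ω. Root codons
are drawn from the stationary (uniform) codon distribution. The default
tree is a four-taxon (focal, sister, two outgroups) topology with 10%
focal–sister synonymous divergence, a melanogaster/simulans-like setting;
defaults elsewhere are q = 0.8 (the canonical genome-wide Ka/Ks ≈ 0.2),
2Ns₁ = 11 (the worked adaptive regime), 2Ns₂ = −100 (effectively no
deleterious fixation), 10% advantageous sites within adaptive genes, θ =
0.02 per site and n = 20 sampled haplotypes (Drosophila-like polymorphism),
κ = 2, and 300-codon genes.

**Polymorphism.** Segregating sites follow the Poisson-random-field
stationary density θ·(1 − e^(−γ(1−x))) / ((1 − e^(−γ))·x·(1−x)) with
γ = 2Ns (→ θ/x as γ → 0), discretized on a 2048-point grid, thinned by the
probability that an n-haplotype binomial sample is polymorphic, and
down-sampled binomially. Synonymous sites and the neutral nonsynonymous
fraction use γ = 0; the deleterious fraction uses γ = 2Ns₂; advantageous
mutations contribute nothing (they are fixed or gone too fast to sample).
Sites are attached to concrete codon positions drawn from the gene's actual
mutational opportunities, so downstream classification is self-consistent.
A count-level shortcut (`CountSimConfig`/`draw_mk_table`) draws Poisson MK
tables directly from the same masses for studies that never touch
sequences (type-I calibration, α recovery, the fluctuating-q experiment).

**Scenarios.** `scenario_concordance_experiment` builds the constant-selection experiment:
3000 genes of which 1000 adaptive (scalable; the scale must keep the
composition integral), merged into 10-gene supergenes two ways — randomly,
and with a fixed composition of (60, 50, 30, 30, 30, 30, 20, 20, 10, 10,
10) groups containing 0…10 adaptive genes (summing to 300 groups and 1000
adaptive genes at full scale). `fluctuating_q_tables` pairs one divergence
draw (Ka/Ks 0.184, ~10⁴ substitutions) with two polymorphism sources whose
filtered Pa/Ps are 0.152 and 0.248 — an Arabidopsis-like sister pair — so
the MK conclusion depends on the polymorphism source.

**What the generator does not emulate:** linkage and hitchhiking,
demography (bottlenecks, growth), recombination, rate variation beyond the
three-class mixture, base-composition bias (uniform root frequencies), or
selection on synonymous sites. Passing tests therefore show that the
pipeline behaves correctly when its own assumptions hold — the point of the
concordance experiment — not that real genomes satisfy those assumptions.

## Supergenes and concordance

Location-based grouping sorts genes by (chromosome, start) and cuts
consecutive runs of a target size (total/target-groups clipped to 20–30),
folding each chromosome's remainder into its last group rather than
dropping genes; label-based grouping makes one candidate group per shared
label within the size bounds, and a gene with several labels may appear in
several groups (reported). Merging sums MK tables element-wise and
concatenates alignments; the merged table's α equals the pooled-counts α of
the members exactly. Supergene site-model fits reuse the single shared
tree; per-gene branch-length heterogeneity inside a supergene is ignored —
a documented limitation. Concordance statistics: expected overlap
|A|·|B|/N under independence, one-sided hypergeometric enrichment (the
"higher than expected" direction), concordance rate = overlap/|MK set|,
relaxed joint threshold √α per test (0.224 for a joint 5%), and a
Mann–Whitney rank comparison for the leftward shift of one test's p-values
after pre-filtering by the other. No multiple-testing correction across
genes: raw-P cutoffs are compared, as the analysis design intends.

## Problem sizes and numerical conventions

The calibration studies run at sizes chosen to make their statistical
claims sharp rather than large: the LRT null calibration uses 500
replicates of 100-codon, 3-taxon genes (the rejection bound is
5% + 3·SE); the MK null uses 2000 count-level tables; α recovery uses
≥10⁴ substitutions; the concordance experiment runs at one-tenth the full
scenario (300 genes, 30 supergenes of 10). The Wright–Fisher oracle
comparison (N = 100, 2Ns ∈ {0, −5}) pools snapshots taken 2N generations
apart and compares ~1200 sampled sites by KS test — enough to catch any
density-shape error while the O(1/N) discreteness of the forward model
(singleton share 0.265 vs the continuum 0.282, measured at 6.8k sites)
stays below detection. Neutral-ratio convergence is asserted on the mean
of eight 10⁴-codon genes because a single gene at 10% divergence carries
~5% sampling error on the ratio itself.

Determinism: every stochastic routine takes an explicit
`numpy.random.Generator` or integer seed; pipeline manifests record seeds,
config and output digests, and rerunning a manifest's config reproduces
identical digests.

## Known limitations

* Approximate counting compresses ω ≫ 1 (see above); use the site model
  for strongly selected genes.
* NEB rather than BEB posteriors: site identification is anticonservative
  when parameter estimates are noisy; A2′ inherits this.
* χ²(2) for a boundary null makes the LRT conservative.
* The per-position parsimony assignment undercounts substitutions on
  saturated codons and silently drops outgroup-homoplasic positions.
* The VCF reader assumes plus-strand, in-order coding intervals and a
  single outgroup-derived `AA` tag; it is a convenience path, not a
  general-purpose variant annotator.
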