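# mkconcord

Concurrent McDonald–Kreitman and codon site-model scans for adaptive
molecular evolution — and the machinery to ask whether their answers agree.

## The problem

Two tests dominate the search for positive selection in protein-coding
genes. The **McDonald–Kreitman (MK) test** contrasts fixed differences on a
phylogenetic lineage (Dn nonsynonymous, Ds synonymous) with segregating
variation inside an extant species (Pn, Ps): under neutrality
Dn/Ds ≈ Pn/Ps, and an excess of Dn/Ds signals adaptive fixation, quantified
by α = 1 − (Ds·Pn)/(Dn·Ps) and A1 = max(α, 0)·Dn adaptive sites per gene.
The **codon site-model test** fits mixture models of the nonsynonymous-to-
synonymous rate ratio ω across codons: M1a (a conserved class with ω₀ < 1
plus a neutral class) against M2a (which adds a selected class with
ω₂ ≥ 1), compared by a likelihood-ratio test against χ²(2), with adaptive-
site counts A2 = p₂·L and A2′ from empirical-Bayes site posteriors.

Both tests rest on the same population-genetic decomposition. With a
fraction *p* of new nonsynonymous mutations advantageous (coefficient
s₁ > 0), a fraction *q* deleterious (s₂ < 0), and fixation probability
f(N, s) = (1 − e^(−2s)) / (1 − e^(−2Ns)) in a haploid population of size N:

    R = Ka/Ks = (1 − p − q) + p·N·f(N, s₁) + q·N·f(N, s₂)
              ≈ 1 + p(2Ns₁ − 1) − q          (modest s₁, strongly deleterious s₂)
    Pa/Ps ≈ 1 − q                            (advantageous alleles fix too fast
                                              to linger as polymorphism)

The catch: R = 0.2 is equally consistent with (p = 0, q = 0.8) and with
(p = 0.01, 2Ns = 11, q = 0.9). Every test must therefore estimate *q*
somewhere — MK from one species' polymorphism, the site model from the
phylogeny-wide average — and both silently assume *q* is constant. This
package implements both tests, supergene merging (concatenating 20–30 genes
to boost power), overlap/concordance statistics, and a synthetic-data
generator in which the deleterious fraction *q* can be held constant or made
to differ between lineages, so the consequences of that assumption can be
measured.

## A worked example

`examples/fluctuating_selection.py` reproduces the central confound at count
level: two sister species share their divergence (Ka/Ks = 0.184) but differ
in purifying-selection strength, so their filtered polymorphism ratios are
0.152 and 0.248:

```
fluctuating q (Pa/Ps 0.152 vs 0.248, shared Ka/Ks 0.184):
  significant with species A's polymorphism: 100%
  significant with species B's polymorphism: 0%
  replicates where the conclusion flips:     100%

constant-q control (both species at Pa/Ps 0.152):
  significant with A: 100%, with B: 100%, flips: 0%
```

The same divergence data yield "positive selection" or "nothing" depending
only on which species supplies the polymorphism reference — but only when
*q* fluctuates; the constant-*q* control is fully concordant.

`examples/site_model.py` fits both site models to a 500-codon gene simulated
with 10% of sites at ω ≈ 5:

```
lnL M1a = -5498.82   lnL M2a = -5489.08
LRT statistic = 19.47, chi2(2) P = 5.9e-05
M2a selected class: p2 = 0.064, omega2 = 5.52
adaptive-site counts: A2 = 31.8, A2' = 21 (truth: 45 sites)
```

The other examples cover the closed-form theory (`selection_theory.py`),
Ka/Ks counting (`kaks_counting.py`), the MK test end to end (`mk_test.py`)
and the supergene concordance experiment (`supergene_concordance.py`).

## Command line

A thin CLI mirrors the library:

```bash
mkconcord theory --params regime.yaml
mkconcord kaks --pair aln.fa --kappa auto
mkconcord paps --sites sites.tsv --ln 675 --ls 225 --min-freq 0.2
mkconcord mk --tables tables.tsv
mkconcord sitemodel --aln gene.fa --tree tree.nwk
mkconcord supergene --mode location --bed genes.bed --groups 200
mkconcord concord --a mk_sig.txt --b paml_sig.txt --universe genes.txt
mkconcord simulate --config sim.yaml --seed 42 --out data/
mkconcord run --config run.yaml --seed 1 --out results/
```

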