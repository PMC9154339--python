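"""The M1a-vs-M2a codon site-model test on a simulated adaptive gene.

Simulates a 500-codon gene in which 10% of sites evolve at omega ~ 5 across
a four-taxon tree, fits both mixture models by maximum likelihood and runs
the likelihood-ratio test, then counts adaptive sites two ways (A2 from the
class proportion, A2' from empirical-Bayes site posteriors).
"""

import numpy as np

from mkconcord import PhyloTree, fit_site_models, site_posteriors
from mkconcord.simulate import SimulationConfig, simulate_divergence

cfg = SimulationConfig(
    tree="((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);",
    n_genes=1, n_codons=500, adaptive_fraction=1.0,
    adaptive_site_fraction=0.10, q=0.4, s1=0.0025, focal="a",
)
gene = simulate_divergence(cfg, np.random.default_rng(42))[0]
tree = PhyloTree.from_newick(cfg.tree)

fit = fit_site_models(tree, gene.alignment, seed=0, n_restarts=1)
true_sites = int((gene.site_classes == 2).sum())
print(f"lnL M1a = {fit.lnl_m1a:.2f}   lnL M2a = {fit.lnl_m2a:.2f}")
print(f"LRT statistic = {fit.lrt_stat:.2f}, chi2(2) P = {fit.p_value:.2g}")
print(f"M2a selected class: p2 = {fit.m2a['p2']:.3f}, omega2 = {fit.m2a['omega2']:.2f}")
print(f"adaptive-site counts: A2 = {fit.a2:.1f}, A2' = {fit.a2prime} "
      f"(truth: {true_sites} sites)")

post = site_posteriors(fit, tree, gene.alignment)
flagged = np.nonzero(post > 0.9)[0]
hits = sum(gene.site_classes[i] == 2 for i in flagged)
print(f"sites with posterior > 0.9: {len(flagged)}, of which {hits} truly adaptive")
print("\nA significant LRT with omega2 > 1 recovers the planted selected class;")
print("A2 estimates its size and the posteriors point at individual codons.")
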