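"""Pairwise and lineage-specific Ka/Ks from simulated codon alignments.

Simulates one purifying-selection gene (80% deleterious sites) on the
default four-taxon tree, then estimates the divergence ratio by
kappa-weighted Nei-Gojobori counting, both pairwise and per lineage with an
outgroup.
"""

import numpy as np

from mkconcord import ka_ks, lineage_kaks
from mkconcord.simulate import SimulationConfig, simulate_divergence

cfg = SimulationConfig(n_genes=1, n_codons=5000, adaptive_fraction=0.0, q=0.8)
gene = simulate_divergence(cfg, np.random.default_rng(1))[0]
print(f"simulated gene: {gene.alignment.n_codons} codons, "
      f"true Ka/Ks = {gene.expected_kaks['focal']:.3f}")

pair = gene.alignment.subset(["focal", "sister"])
r = ka_ks(pair, kappa=cfg.kappa)
print(f"pairwise focal-sister:  Ka={r.ka:.4f} Ks={r.ks:.4f} Ka/Ks={r.ratio:.3f}")

res = lineage_kaks(gene.alignment, "focal", "sister", "out1", kappa=cfg.kappa)
for branch in ("focal", "sister"):
    k = res[branch]
    print(f"{branch:>6} branch: Nd={k.nd:.1f} Sd={k.sd:.1f} Ka/Ks={k.ratio:.3f}")
print(f"codons discarded as parsimony-ambiguous: {res['ambiguous_codons']}")
print("\nBoth estimates sit near the true 0.2: ~80% of nonsynonymous changes")
print("are removed by negative selection while synonymous changes accumulate freely.")
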