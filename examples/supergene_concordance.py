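"""Concordance of the two tests on a miniature supergene experiment.

Runs a scaled-down constant-selection experiment (300 short genes, a third
of them adaptive, merged randomly into 30 ten-gene supergenes), applies the
MK test and the site-model LRT to every supergene, and reports the overlap
of their significant calls.  Under constant negative selection the
less-powerful test's calls nest inside the other's, so the concordance rate
(overlap / MK calls) is close to 1.
"""

from mkconcord.pipeline import run_pipeline

manifest = run_pipeline(
    {"scale": 0.1, "simulation": {"n_codons": 60}}, "scratch/example_run", seed=11
)
import json

report = json.loads(open("scratch/example_run/concordance.json").read())
for scheme, rep in report.items():
    print(f"{scheme}:")
    print(f"  MK significant:         {rep['size_a']}/{rep['universe']}")
    print(f"  site-model significant: {rep['size_b']}/{rep['universe']}")
    print(f"  overlap observed {rep['overlap']} vs expected {rep['expected_overlap']:.1f} "
          f"by chance; concordance = {rep['concordance']:.2f}")
print("\nWith constant selection both tests flag the same supergenes, unlike the")
print("near-chance overlap seen on real genomes where negative selection fluctuates.")
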