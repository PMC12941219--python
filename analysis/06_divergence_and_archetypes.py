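#!/usr/bin/env python
"""Measure pairwise divergence with identity-weighted ANI in an all-vs-all
matrix, select maximally dissimilar archetypes, and summarize gene lengths.

Writes the matrix and archetype list under results/run/ani."""

from lncortho.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="results/run", seed=1)
state = run_pipeline(cfg, until="ani")

a = state.summary["ani"]
print(f"mean off-diagonal ANI: {a['mean_ani_offdiag']:.1f}%")
print(f"archetypes (k={cfg.archetype_k}): {', '.join(a['archetypes'])}")
print(f"mean divergent-gene length: {a['mean_gene_length']:.0f} bp")
print(f"outputs: {state.out / 'ani'}")
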