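#!/usr/bin/env python
"""Profile short sequence features on every gene: canonical G-quadruplexes,
the full hexamer spectrum with shared-motif discovery, and nucleotide usage.

Writes BED/TSV tables under results/run/motifs."""

from lncortho.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="results/run", seed=1)
state = run_pipeline(cfg, until="motifs")

m = state.summary["motifs"]
print(f"G-quadruplex hits: {m['n_g4']} across {len(state.genes)} genes")
print("top shared hexamers (min count across genes):",
      ", ".join(m["top_shared_hexamers"]))
print(f"outputs: {state.out / 'motifs'}")
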