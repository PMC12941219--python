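#!/usr/bin/env python
"""Call the short-isoform polyadenylation signal on every located gene:
project the reference PAS position, require a single AATAAA within +-110 bp,
and scan +-600 bp for alternative signals.

Writes the call table under results/run/pas."""

from lncortho.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="results/run", seed=1)
state = run_pipeline(cfg, until="pas")

print(f"main PAS called on {state.summary['pas']['n_main_called']} "
      f"of {len(state.genes)} genes")
for leaf, models in sorted(state.models.items()):
    m = models.get("divergent")
    if m is not None and m.pas_main is not None:
        alts = ", ".join(str(p) for p in m.pas_alternatives) or "none"
        print(f"  {leaf}: main PAS at +{m.pas_main} bp; alternatives: {alts}")
print(f"outputs: {state.out / 'pas'}")
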