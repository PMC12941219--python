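# lncortho

Comparative feature analysis of a syntenic long-non-coding-RNA gene pair —
the NEAT1/MALAT1 configuration: one long, fast-evolving gene and one short,
highly conserved gene encoded a few tens of kilobases apart on the same
strand. Orthologs of genes like NEAT1 share almost no primary sequence, yet
keep their function; what is conserved instead is a portfolio of short
features — the TATA-box, a single polyadenylation signal defining the short
isoform, 3'-end triple-helix and tRNA-like structures, G-quadruplexes,
GU-repeat protein-binding motifs, transposable-element integration hot
spots, and self-complementary (inverted-repeat) regions. This package
implements the full analysis chain that detects and quantifies those
features, and a synthetic-locus generator that evolves a planted locus
along a phylogeny so every step can be validated against exact ground
truth.

Intended users: molecular evolution and lncRNA researchers who want the
individual analyses (ANI, TE annotation, PAS calling, covariation, PWM
scanning) as tested library functions, and method developers who need a
planted-truth benchmark for synteny-anchored ortholog delineation.

## The statistics at the core

**Average nucleotide identity (ANI).** For two genes, every local alignment
hit longer than 100 bp contributes its identity-weighted length
w = pident/100 x L_aln, and

```
ANI = ( Σw / len(gene1) + Σw / len(gene2) ) / 2 x 100 .
```

The formula is applied literally (overlapping hits all count; values above
100 are clamped and flagged); an optional mode merges query-side overlaps
first.

**The 80-80-80 rule** accepts a transposable-element annotation only when
the alignment is ≥ 80 bp long, ≥ 80 % identical, and covers ≥ 80 % of the
element consensus; overlaps are resolved greedily by pident x length.

**PAS calling** requires exactly one canonical AATAAA within ±110 bp of the
position projected from a reference gene; alternative signals are collected
within ±600 bp. **Covariation** classifies each MSA row at a structural
base pair as canonical (WC/GU), compensatory (canonical but different from
the majority pair) or inconsistent, and scores
(f_canonical + f_compensatory) − f_inconsistent, clamped to [−1, 1].
**PWM scanning** uses log₂-odds scores with *exact* null p-values computed
by dynamic programming on a 1/1000-bit score lattice (p < 10⁻⁴ for a hit).

## Worked example

```python
from lncortho.pipeline import PipelineConfig, run_pipeline

state = run_pipeline(PipelineConfig(out_dir="runs/demo", seed=1))
print(state.summary["locate"]["n_both_located"])   # 6
print(state.summary["motifs"]["top_shared_hexamers"])
```

Running the numbered drivers in `analysis/` reproduces the whole study on
the default synthetic cohort (seed 1, six leaves). Output actually printed
by `analysis/02_locate_orthologs.py` and `analysis/04_annotate_repeats.py`:

```
both genes located on 6 of 6 leaves
  alpha: divergent 21006 bp, conserved 7001 bp, distance 36774 bp, same strand: True
  ...
TE annotations: 36 across 6 genes; 6 homologous loci; 0 excision(s) flagged
TE positional profile peaks in bins 30-35%, 75-80%
self-complementary regions per gene: {'alpha': 2, 'beta': 2, ...}
```

Every leaf's divergent gene is recovered within a few bp of its planted
21 kb extent, the intergenic distances sit near the planted 36,755 bp, all
six planted TEs per gene pass the 80-80-80 rule, and the summed TE
positional profile peaks inside the planted 30–40 % and 70–80 % bins. The
`lncortho` command exposes the same stages as subcommands
(`lncortho run-all --set seed=2 --set out_dir=runs/demo2`).

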