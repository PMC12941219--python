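# Methods

## The locus model

The package analyses a two-gene syntenic configuration: a *divergent* gene
(default 21,000 bp) and a *conserved* gene (default 7,000 bp) on one strand
of a contig, separated by a default intergenic distance of 36,755 bp. Each
gene runs from the first base of its TATA-box to the last base of its
triple-helix element; the tRNA-like element sits immediately downstream of
the gene end (it is excised from the primary transcript during maturation,
so the mature 3' end is the triple helix). The divergent gene additionally
carries a single polyadenylation signal (AATAAA) 3,500 bp from its start —
the 3' end of the short isoform — with a guard zone of ±600 bp that
contains no other AATAAA at generation time, plus planted transposable
elements, inverted-repeat pairs, G-quadruplexes, GU-repeat tracts and core
hexamer cassettes.

## Synthetic-data generator

`lncortho.simulate` builds the root locus and evolves it along a
user-supplied newick tree.

*Background composition* is T-rich and C-poor (A 0.27, C 0.18, G 0.22,
T 0.33), matching the compositional signature of this gene class.
*Feature placement* uses fixed fractional anchors for structured elements
(G-quadruplexes near both ends; core hexamer cassettes at 45–55 %;
GU tracts at 84–90 %; inverted-repeat pairs anchored at 56.5 %/58.5 % with
proximal/distal separations) and randomized slots inside the permitted
30–40 % and 70–80 % bins for TEs. The TE library is a fixed synthetic set
of five consensus sequences (SINE/LINE/LTR/DNA-like lengths 280–600 bp)
generated once from a constant seed so that every cohort is annotated
against the same library. Collisions raise an error naming the colliding
features rather than silently repacking.

*Evolution* applies exact Jukes–Cantor substitutions per branch (each site
is redrawn uniformly with probability 1 − e^(−4tr/3), which composes
correctly across branches), geometric-length indels (mean 3 bp, rate 0.01
per site per unit branch length), and optional TE insertion/excision
events. Excisions remove a planted element cleanly (junction ligation) and
can be forced on a named leaf branch for benchmarking. All planted
coordinates are lifted exactly through every edit. Per-branch RNG streams
are derived from (global seed, CRC32 of the branch's leaf set), so results
are stable when unrelated parts of the tree change.

*Purifying selection.* Features reported as invariant in real orthologs —
the TATA-box, the PAS hexamer, the triple-helix motifs, and the planted
promoter TF site — receive substitution rate 0 and admit no indels. The
remaining 3'-block (hairpin, linker, tRNA-like), G-quadruplexes, GU tracts,
core cassettes and inverted-repeat arms evolve at 0.2x the local rate
(indel-free); promoters at 0.3x; the conserved gene at 0.3x overall. Without
these factors the generator would erase the very features whose detection
the benchmark measures, and the planted-truth recovery studies would
quantify motif decay instead of method error. A branch-level scrub also
removes mutation-born AATAAA motifs inside the ±110 bp ambiguity window of
the active PAS (selection against cryptic polyadenylation); new signals
beyond that window may arise freely, which is how alternative PASs appear
in leaves.

*What the generator does not emulate:* rearrangements and duplications,
context-dependent mutation, selection on codon structure, assembly gaps
(N runs), sequencing error, and genome-scale background outside the one
contig. Passing recovery tests therefore demonstrate correctness of the
measurement chain under a faithful-but-clean locus model, not robustness
to assembly artefacts.

## Local homology search

`lncortho.align.local_align` is a seed–chain–extend aligner: exact 11-mer
seeds (N never seeds and always scores as mismatch), same-diagonal seed
merging, collinear chaining (gap ≤ 500 bp, diagonal drift ≤ 50), and a
cluster-merge pass on diagonal bands (gap ≤ 1 kb; the tolerated band
scales with envelope size, span/6 capped at 400, so a short element cannot
absorb a far-diagonal seed). Envelopes are extended by an ungapped x-drop
pass (match +1, mismatch −2, x-drop 20) capped at 600 bp per side — an
uncapped extension never triggers the x-drop across moderately diverged
sequence and would overrun neighbouring clusters — then aligned globally
with edlib and trimmed to the maximum-scoring contiguous cigar span
(run-level Kadane), which makes every HSP a genuine local alignment.
Refinement failures (identity below threshold, or one internal gap
dominating the alignment) split the cluster at its largest seed gap and
retry, so a merge that bridged non-homologous sequence is undone instead
of reported. Near-duplicate HSPs (≥ 50 % mutual overlap on both query and
subject) are culled, keeping the best score. Inputs of ≤ 64 bp bypass the
heuristic entirely and are aligned with an exact affine-gap Smith–Waterman
(gap open −5, extend −2). Gap and scoring defaults are package choices,
not literature constants; the downstream filters (> 100 bp for ANI,
80-80-80 for TEs) are the semantically meaningful thresholds.

## Analysis choices and tie-breaks

- **Gene delineation** lifts the TATA-box start and triple-helix end
  through the anchor-alignment cigar (not HSP endpoints), so boundary
  error is local alignment noise only. Anchor hits must cover ≥ 50 % of
  their fragment, which prevents a cross-gene hit to the shared
  structural motifs from mimicking an anchor. Two candidate loci of
  similar score raise an ambiguity error; they are never silently
  resolved.
- **ANI** counts hits strictly longer than 100 bp; `ani_pair(g, g)` is
  exactly 100 after clamping (a repeat-carrying gene can exceed 100 under
  the literal formula; the result is clamped and flagged).
- **Archetype selection** maximizes the minimum pairwise dissimilarity
  d = 100 − ANI. The implementation is exact (exhaustive with
  lexicographic tie-break) whenever C(n, k) ≤ 2x10⁵ and falls back to
  farthest-first traversal plus deterministic 1-swap local search beyond
  that. The pure farthest-first heuristic is also exposed
  (`greedy_archetypes`); it carries the classical 1/2-approximation
  guarantee only on metric dissimilarities and measurably misses the
  optimum on 15–30 % of random instances, which is why it is not the
  default selector at benchmark sizes.
- **TE annotation**: when a local hit passes identity but stops inside a
  diverged element end, the full consensus is re-fitted to the
  proportionally extended window (infix alignment) and the 80-80-80 rule
  is judged on that full-element alignment, as repeat annotators
  conventionally do. Overlap resolution is greedy by pident x length,
  ties by pident, then leftmost start, then name — the accepted set is
  the unique greedy independent set.
- **Presence/absence and excision**: loci are matched across leaves by
  ±200 bp flank liftover (word size 8 for diverged flanks), with a
  name+position fallback when anchoring fails but an annotation exists.
  A locus is *absent* only when the donor's TE-deleted junction probe
  (±100 bp flanks joined) aligns contiguously in the target with no
  deletion run longer than 10 bp — the probe statistic measures junction
  residue directly, where a span-difference statistic would confuse
  lineage indel drift with residue. Anchoring failure is *unresolved*,
  never absent. An excision is flagged when the smallest clade containing
  the absent leaf and a present leaf is otherwise all-present.
- **Self-complementarity** keeps minus-strand self-hits only, canonicalizes
  arm order, and collapses mirror/trimmed duplicates by arm overlap
  (≥ 50 %), keeping the longest variant; proximal means arm separation
  ≤ 2,000 bp, chosen so the human IRAlu geometry falls in the proximal
  class. The 100 bp / 80 % thresholds are transferred from the ANI hit
  filter.
- **G-quadruplexes** use the canonical four-tract pattern
  (G≥3, loops 1–7 nt) with maximal G-tracts chained greedily left to
  right; minus-strand structures come from the C-tract mirror. Counts
  from thermodynamic scoring tools are not comparable and not targeted.
- **Hexamers**: window-start binning for point-like motifs (TEs bin by
  interval midpoint — the documented asymmetry); RNA motifs are handled
  in DNA space (U→T).
- **PWM p-values** are exact on a 1/1000-bit lattice: the null pmf of the
  lattice-rounded score under the background is computed by dynamic
  programming, so the p-value of a hit equals exhaustive enumeration over
  all 4^width words by construction. Background defaults to uniform 0.25.
  Counts get a 0.1 pseudocount per cell.
- **Covariation** scores (f_canonical + f_compensatory) − f_inconsistent
  per structural pair, clamped to [−1, 1]; gapped rows are excluded from
  the denominator. The progressive MSA (align each sequence to the running
  column consensus, guide order = input order) is intended for the short,
  well-conserved 3'-end elements only; externally produced aligned FASTA
  is accepted anywhere an MSA is consumed.

## Benchmark sizes

The recovery study uses 20 cohorts of 6 leaves on the default tree
(branch lengths 0.02–0.10 expected substitutions/site); the Jukes–Cantor
calibration uses 21 kb sequences at d ∈ {0.05, 0.1, 0.2, 0.3} with 5
replicates each. These sizes give binomial standard errors well below the
tolerances being checked while keeping a full run in minutes on one CPU.

## Known limitations

- The aligner is designed for locus-scale inputs (tens of kb); it has no
  genome-scale index and the spec excludes spliced and protein alignment.
- ANI inherits the literal summation's repeat sensitivity; for repeat-rich
  pairs prefer `merge_overlaps=True` and compare both modes.
- The excision caller assumes clean junctions; ragged deletions that
  remove flanks are reported unresolved by design.
- Shared-TF analysis reports prevalence only; no enrichment statistics
  are computed, and absolute per-promoter hit counts depend on the PWM
  set's information content.
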