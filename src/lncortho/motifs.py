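"""G-quadruplex detection, hexamer profiling and nucleotide usage.

The G4 detector implements the canonical four-tract pattern
(G{>=3} N{1..7}){3} G{>=3}, scanned greedily left to right with maximal
G-tracts; minus-strand structures are found from the C-tract mirror and
reported in forward coordinates. RNA motifs from the literature (GUGUGU
etc.) are handled in DNA space (U -> T) since all inputs are genomic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .seq import DnaSequence, GenomicInterval, KmerCounts, SequenceError, kmer_counts, revcomp


@dataclass
class G4Hit:
    iv: GenomicInterval
    n_tracts: int
    tract_lengths: List[int]
    loop_lengths: List[int]
    strand: str


@dataclass
class HexamerProfile:
    gene_id: str
    counts: Dict[str, int]
    n_skipped: int
    gene_length: int
    motif_bins: Dict[str, List[int]] = field(default_factory=dict)  # motif -> per-bin counts
    n_bins: int = 10


@dataclass
class NucleotideUsage:
    overall: Dict[str, float]                       # percent per base, N excluded
    per_bin: List[Dict[str, float] | None]          # None for all-N bins
    n_bins: int


def _tracts(residues: str, base: str, min_tract: int) -> List[Tuple[int, int]]:
    return [(m.start(), m.end())
            for m in re.finditer(f"{base}{{{min_tract},}}", residues)]


def _scan_strand(residues: str, base: str, min_tract: int, loop_min: int,
                 loop_max: int) -> List[Tuple[int, int, List[int], List[int]]]:
    """Greedy left-to-right maximal four-tract matches; non-overlapping."""
    tracts = _tracts(residues, base, min_tract)
    hits = []
    i = 0
    while i + 3 < len(tracts) + 1 and i < len(tracts):
        chain = [tracts[i]]
        j = i
        while len(chain) < 4 and j + 1 < len(tracts):
            loop = tracts[j + 1][0] - tracts[j][1]
            if loop_min <= loop <= loop_max:
                chain.append(tracts[j + 1])
                j += 1
            else:
                break
        if len(chain) == 4:
            start, end = chain[0][0], chain[3][1]
            tract_lengths = [e - s for s, e in chain]
            loops = [chain[k + 1][0] - chain[k][1] for k in range(3)]
            hits.append((start, end, tract_lengths, loops))
            # resume after the hit (greedy non-overlapping)
            i = next((k for k, t in enumerate(tracts) if t[0] >= end), len(tracts))
        else:
            i += 1
    return hits


def find_g4(seq: DnaSequence, min_tract: int = 3, loop_min: int = 1,
            loop_max: int = 7, both_strands: bool = True) -> List[G4Hit]:
    """Canonical G-quadruplex pattern scan.

    Plus-strand hits come from G-tracts; minus-strand hits from C-tracts on
    the forward sequence, reported in forward coordinates with strand '-'.
    """
    res = seq.residues
    out = [G4Hit(GenomicInterval(seq.id, s, e, "+"), 4, tl, ll, "+")
           for s, e, tl, ll in _scan_strand(res, "G", min_tract, loop_min, loop_max)]
    if both_strands:
        for s, e, tl, ll in _scan_strand(res, "C", min_tract, loop_min, loop_max):
            out.append(G4Hit(GenomicInterval(seq.id, s, e, "-"), 4, tl, ll, "-"))
    out.sort(key=lambda h: (h.iv.start, h.strand))
    return out


def _to_dna(motif: str) -> str:
    return motif.upper().replace("U", "T")


def hexamer_profile(gene: DnaSequence, query_motifs: Sequence[str] = (),
                    n_bins: int = 10) -> HexamerProfile:
    """Global hexamer counts plus per-bin occurrence profiles of query motifs.

    Occurrences are positioned by window start and binned by fractional
    position; overlapping occurrences all count.
    """
    kc: KmerCounts = kmer_counts(gene, 6)
    profile = HexamerProfile(gene.id, kc.counts, kc.n_skipped, len(gene),
                             n_bins=n_bins)
    L = len(gene)
    for motif in query_motifs:
        m = _to_dna(motif)
        if len(m) != 6:
            raise SequenceError(f"query motif {motif!r} is not a hexamer")
        bins = [0] * n_bins
        pos = gene.residues.find(m)
        while pos >= 0:
            bins[min(n_bins - 1, int(pos / L * n_bins))] += 1
            pos = gene.residues.find(m, pos + 1)
        profile.motif_bins[m] = bins
    return profile


def shared_motifs(profiles: Sequence[HexamerProfile], min_per_gene: int = 1
                  ) -> List[Tuple[str, int, float]]:
    """Hexamers present at least min_per_gene times in EVERY profile.

    Ranked by the minimum count across genes (descending), then mean count,
    then lexicographically.
    """
    if len(profiles) < 2:
        raise SequenceError("need at least two profiles")
    keys = set(profiles[0].counts)
    for p in profiles[1:]:
        keys &= set(p.counts)
    rows = []
    for k in sorted(keys):
        counts = [p.counts.get(k, 0) for p in profiles]
        if min(counts) >= min_per_gene:
            rows.append((k, min(counts), float(np.mean(counts))))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows


def nucleotide_usage(gene: DnaSequence, n_bins: int = 20) -> NucleotideUsage:
    """Overall and per-bin base percentages; N excluded from denominators."""
    res = gene.residues

    def pct(chunk: str):
        tot = sum(chunk.count(b) for b in "ACGT")
        if tot == 0:
            return None
        return {b: 100.0 * chunk.count(b) / tot for b in "ACGT"}

    overall = pct(res)
    if overall is None:
        raise SequenceError("sequence is all N")
    edges = np.linspace(0, len(res), n_bins + 1).astype(int)
    per_bin = [pct(res[edges[i]:edges[i + 1]]) for i in range(n_bins)]
    return NucleotideUsage(overall, per_bin, n_bins)
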