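"""3'-end structural elements: extraction, conservation, covariation.

The triple-helix block (structure-forming motifs, hairpin, linker) and the
downstream tRNA-like element are measured by aligning each ortholog's 3'
region to a reference layout and lifting the sub-element boundaries through
the alignment. Column conservation and base-pair covariation are computed
from an MSA: a pair's rows are classified as canonical (WC or GU wobble in
RNA space), compensatory (canonical but different from the majority
canonical pair) or inconsistent, and the covariation score is

    score = (f_canonical + f_compensatory) - f_inconsistent

bounded in [-1, 1] (compensatory rows are a subset of canonical ones; the
compensatory fraction rewards pairs whose pairing survives sequence change).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .align import parse_cigar
from .locate import GeneModel
from .seq import DnaSequence, GenomicInterval, SequenceError, revcomp

GAP = "-"
_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class ReferenceLayout:
    """Reference 3'-end element with sub-element offsets (element frame)."""

    element: str
    helix_a: Tuple[int, int]
    hairpin: Tuple[int, int]
    linker: Tuple[int, int]
    helix_b: Tuple[int, int]
    trna_like: Tuple[int, int]

    @classmethod
    def from_truth(cls, root: DnaSequence, truth, gene_key: str = "divergent"
                   ) -> "ReferenceLayout":
        g = truth.genes[gene_key]
        e0 = g.helix_a.start
        rel = lambda iv: (iv.start - e0, iv.end - e0)
        return cls(element=root.residues[e0:g.trna_like.end],
                   helix_a=rel(g.helix_a), hairpin=rel(g.hairpin),
                   linker=rel(g.linker), helix_b=rel(g.helix_b),
                   trna_like=rel(g.trna_like))


@dataclass
class EndStructureModel:
    helix_motif_iv: Optional[GenomicInterval]
    hairpin_iv: Optional[GenomicInterval]
    linker_iv: Optional[GenomicInterval]
    trna_like_iv: Optional[GenomicInterval]

    def lengths(self) -> Dict[str, Optional[int]]:
        return {name: (iv.length if iv is not None else None)
                for name, iv in (("helix_motif", self.helix_motif_iv),
                                 ("hairpin", self.hairpin_iv),
                                 ("linker", self.linker_iv),
                                 ("trna_like", self.trna_like_iv))}


def extract_end_structures(contig: DnaSequence, model: GeneModel,
                           layout: ReferenceLayout,
                           min_segment_identity: float = 65.0
                           ) -> EndStructureModel:
    """Locate the 3'-end sub-elements of a gene model on its contig.

    The reference element is infix-aligned to the transcript-oriented 3'
    region (gene end +- padding); each sub-element boundary is lifted through
    the cigar. A sub-element whose aligned segment falls below
    ``min_segment_identity`` percent identity is reported absent.
    """
    pad = len(layout.element) + 150
    if model.strand == "+":
        lo = max(0, model.gene_iv.end - pad)
        hi = min(len(contig), model.gene_iv.end + 150)
        region = contig.residues[lo:hi]
        to_fwd = lambda a, b: GenomicInterval(contig.id, lo + a, lo + b, "+")
    else:
        lo = max(0, model.gene_iv.start - 150)
        hi = min(len(contig), model.gene_iv.start + pad)
        region = revcomp(contig.residues[lo:hi])
        # transcript offset t in region maps to forward [hi - b, hi - a)
        to_fwd = lambda a, b: GenomicInterval(contig.id, hi - b, hi - a, "-")

    res = edlib.align(layout.element, region, mode="HW", task="path")
    if res["editDistance"] < 0:
        return EndStructureModel(None, None, None, None)
    start = res["locations"][0][0]
    # per-reference-offset target positions and per-column match flags
    ref_to_tgt = np.full(len(layout.element) + 1, -1, dtype=int)
    match_flag = np.zeros(len(layout.element), dtype=bool)
    q = 0
    s = start
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            for i in range(n):
                ref_to_tgt[q + i] = s + i
                match_flag[q + i] = op == "="
            q += n
            s += n
        elif op == "I":  # reference base absent from the target
            for i in range(n):
                ref_to_tgt[q + i] = s
            q += n
        elif op == "D":
            s += n
    ref_to_tgt[len(layout.element)] = s

    def segment(bounds: Tuple[int, int]) -> Optional[GenomicInterval]:
        a, b = bounds
        ta, tb = int(ref_to_tgt[a]), int(ref_to_tgt[b])
        if tb <= ta:
            return None
        ident = 100.0 * match_flag[a:b].mean()
        if ident < min_segment_identity:
            return None
        return to_fwd(ta, tb)

    helix_a = segment(layout.helix_a)
    helix_b = segment(layout.helix_b)
    helix = None
    if helix_a is not None and helix_b is not None:
        helix = GenomicInterval(contig.id, min(helix_a.start, helix_b.start),
                                max(helix_a.end, helix_b.end), helix_a.strand)
    return EndStructureModel(
        helix_motif_iv=helix if helix is not None else helix_a or helix_b,
        hairpin_iv=segment(layout.hairpin),
        linker_iv=segment(layout.linker),
        trna_like_iv=segment(layout.trna_like))


# ---------------------------------------------------------------------------
# progressive MSA for short conserved elements
# ---------------------------------------------------------------------------

def align_msa(seqs: Sequence[str]) -> List[str]:
    """Progressive multiple alignment (guide order = input order).

    Each sequence is aligned to the running column consensus; suitable for
    the short, well-conserved 3'-end elements this module analyses, not for
    divergent full genes. Externally produced aligned FASTA is accepted
    anywhere an MSA is consumed.
    """
    if not seqs:
        raise SequenceError("empty MSA input")
    rows: List[List[str]] = [list(seqs[0])]
    for s in seqs[1:]:
        consensus = _consensus(rows)
        res = edlib.align(s, consensus, mode="NW", task="path")
        new_row: List[str] = []
        col = 0
        q = 0
        for n, op in parse_cigar(res["cigar"]):
            if op in ("=", "X"):
                new_row.extend(s[q:q + n])
                q += n
                col += n
            elif op == "I":  # new sequence has extra bases: new columns
                for r in rows:
                    r[col:col] = [GAP] * n
                new_row.extend(s[q:q + n])
                q += n
                col += n
            elif op == "D":  # consensus columns missing from new sequence
                new_row.extend(GAP * n)
                col += n
        rows.append(new_row)
        width = max(len(r) for r in rows)
        for r in rows:
            r.extend(GAP * (width - len(r)))
    return ["".join(r) for r in rows]


def _consensus(rows: List[List[str]]) -> str:
    width = len(rows[0])
    out = []
    for c in range(width):
        col = [r[c] for r in rows if r[c] != GAP]
        if not col:
            out.append("N")
            continue
        counts = sorted(((col.count(b), b) for b in set(col)),
                        key=lambda t: (-t[0], t[1]))
        out.append(counts[0][1])
    return "".join(out)


# ---------------------------------------------------------------------------
# column conservation and covariation
# ---------------------------------------------------------------------------

@dataclass
class ColumnConservation:
    frequencies: List[Dict[str, float]]   # per column, gaps excluded
    identical: List[bool]
    identical_fraction: float


def column_conservation(msa: Sequence[str]) -> ColumnConservation:
    """Per-column base frequencies and the identical-column fraction.

    A column is identical iff a single base has frequency 1.0 among non-gap
    rows and at least half the rows are non-gap.
    """
    if not msa:
        raise SequenceError("empty MSA")
    width = len(msa[0])
    if any(len(r) != width for r in msa):
        raise SequenceError("ragged MSA")
    freqs: List[Dict[str, float]] = []
    ident: List[bool] = []
    n_rows = len(msa)
    for c in range(width):
        col = [r[c] for r in msa]
        non_gap = [b for b in col if b != GAP]
        if non_gap:
            f = {b: non_gap.count(b) / len(non_gap) for b in sorted(set(non_gap))}
        else:
            f = {}
        freqs.append(f)
        ident.append(bool(f) and max(f.values()) == 1.0
                     and len(non_gap) >= 0.5 * n_rows)
    return ColumnConservation(freqs, ident,
                              sum(ident) / width if width else 0.0)


@dataclass
class PairCovariation:
    i: int
    j: int
    n_canonical: int
    n_compensatory: int
    n_inconsistent: int
    n_gapped: int
    score: float


@dataclass
class CovariationResult:
    pairs: List[PairCovariation]

    @property
    def mean_score(self) -> float:
        return float(np.mean([p.score for p in self.pairs])) if self.pairs else 0.0


def pairs_from_dotbracket(structure: str) -> List[Tuple[int, int]]:
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise SequenceError("unbalanced dot-bracket structure")
            pairs.append((stack.pop(), idx))
    if stack:
        raise SequenceError("unbalanced dot-bracket structure")
    return sorted(pairs)


def covariation(msa: Sequence[str], pairs: Sequence[Tuple[int, int]]
                ) -> CovariationResult:
    """Base-pair covariation across MSA rows.

    Per pair, each row is canonical (WC/GU in RNA space), else inconsistent
    (gapped rows counted separately); compensatory rows are canonical rows
    whose pair differs from the majority canonical pair.
    """
    if not msa:
        raise SequenceError("empty MSA")
    width = len(msa[0])
    out: List[PairCovariation] = []
    for i, j in pairs:
        if not (0 <= i < width and 0 <= j < width):
            raise SequenceError(f"pair ({i}, {j}) outside alignment width {width}")
        observed: List[Tuple[str, str]] = []
        n_gap = 0
        for row in msa:
            a, b = row[i].upper().replace("U", "T"), row[j].upper().replace("U", "T")
            if a == GAP or b == GAP:
                n_gap += 1
            else:
                observed.append((a, b))
        canon = [p for p in observed if p in _CANONICAL]
        n_inc = len(observed) - len(canon)
        if canon:
            maj = sorted(((canon.count(p), p) for p in set(canon)),
                         key=lambda t: (-t[0], t[1]))[0][1]
            n_comp = sum(1 for p in canon if p != maj)
        else:
            n_comp = 0
        n_rows = len(msa)
        denom = n_rows - n_gap
        if denom == 0:
            score = 0.0
        else:
            score = (len(canon) + n_comp) / denom - n_inc / denom
        out.append(PairCovariation(i, j, len(canon), n_comp, n_inc, n_gap,
                                   max(-1.0, min(1.0, score))))
    return CovariationResult(out)
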