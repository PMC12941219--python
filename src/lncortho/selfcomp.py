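"""Reverse-complementary region pairs within a gene.

A gene aligned against itself on the minus strand reveals inverted-repeat
geometry (IRAlu-like when the two arms are close). The trivial full-length
plus-strand self-hit never appears because only minus-strand HSPs are kept;
each pair is counted once with the leftmost arm first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .align import AlignParams, local_align
from .seq import DnaSequence, GenomicInterval, SequenceError

PROXIMAL_THRESHOLD = 2_000


@dataclass
class SelfComplementRegion:
    iv_a: GenomicInterval
    iv_b: GenomicInterval          # iv_a.start < iv_b.start
    pident: float
    aln_length: int
    separation: int                # bp between iv_a.end and iv_b.start
    cls: str                       # proximal | distal

    def __post_init__(self) -> None:
        if self.iv_a.start >= self.iv_b.start:
            raise SequenceError("region arms not in canonical order")


def find_self_complementary(gene: DnaSequence, min_len: int = 100,
                            min_pident: float = 80.0,
                            proximal_threshold: int = PROXIMAL_THRESHOLD,
                            params: Optional[AlignParams] = None
                            ) -> List[SelfComplementRegion]:
    """Detect reverse-complementary region pairs within one gene.

    Arms shorter than min_len or below min_pident are discarded; overlapping
    arms (palindrome centred on one point) are skipped since neither arm then
    reaches min_len independently.
    """
    if len(gene) <= 2 * min_len:
        raise SequenceError("gene too short for self-complementarity search")
    p = params or AlignParams(min_len=min_len, min_pident=min_pident)
    p = AlignParams(**{**p.__dict__, "min_len": min_len, "min_pident": min_pident,
                       "both_strands": True})
    hsps = [h for h in local_align(gene, gene, p) if h.strand == "-"]
    regions: List[SelfComplementRegion] = []
    for h in hsps:
        a, b = h.query_iv, h.subject_iv
        if a.start > b.start:
            a, b = b, a  # canonical order; the mirror collapses below
        if a.start == b.start and a.end == b.end:
            continue  # perfect palindrome hit (both arms are the same span)
        if a.end > b.start:
            continue  # overlapping arms: neither arm is min_len independently
        sep = b.start - a.end
        regions.append(SelfComplementRegion(
            iv_a=GenomicInterval(gene.id, a.start, a.end, "+"),
            iv_b=GenomicInterval(gene.id, b.start, b.end, "-"),
            pident=h.pident, aln_length=h.aln_length, separation=sep,
            cls="proximal" if sep <= proximal_threshold else "distal"))
    # collapse symmetric/trimmed duplicates: two regions describe the same
    # pair when both arms overlap substantially; keep the longest variant
    def _same_arm(x: GenomicInterval, y: GenomicInterval) -> bool:
        ov = min(x.end, y.end) - max(x.start, y.start)
        return ov >= 0.5 * min(x.length, y.length)

    regions.sort(key=lambda r: (-r.aln_length, r.iv_a.start))
    unique: List[SelfComplementRegion] = []
    for r in regions:
        if any(_same_arm(r.iv_a, u.iv_a) and _same_arm(r.iv_b, u.iv_b)
               for u in unique):
            continue
        unique.append(r)
    unique.sort(key=lambda r: (r.iv_a.start, r.iv_b.start))
    return unique
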