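"""Synteny-anchored gene delineation.

The conserved gene is found first by chaining local hits to a conserved
reference; the divergent gene is then delineated from two short anchors whose
conservation survives the divergence of the gene body: a promoter fragment
containing the TATA-box and a 3'-end fragment containing the triple-helix
motifs and the tRNA-like element. The gene interval runs from the mapped
TATA-box start to the mapped triple-helix end; anchor offsets are lifted
through the alignment cigar, so boundary error is limited to local alignment
noise rather than HSP end effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import AlignParams, Hsp, local_align, map_query_to_subject
from .seq import DnaSequence, GenomicInterval, SequenceError


class NoCallError(ValueError):
    """A gene could not be delineated; `reason` names the missing evidence."""

    def __init__(self, reason: str, detail: str = "") -> None:
        self.reason = reason
        super().__init__(f"no-call({reason})" + (f": {detail}" if detail else ""))


class AmbiguityError(ValueError):
    """Multiple candidate loci of similar score; mirrors manual curation."""

    def __init__(self, candidates: List[GenomicInterval]) -> None:
        self.candidates = candidates
        super().__init__(f"ambiguous locus: {len(candidates)} candidates "
                         + ", ".join(str(c) for c in candidates))


@dataclass
class AnchorSet:
    """Anchors used to delineate one gene."""

    conserved_gene_reference: DnaSequence
    promoter_fragment: DnaSequence
    end_fragment: DnaSequence
    tata_offset_in_promoter: int
    helix_end_offset_in_end_fragment: int
    helix_start_offset_in_end_fragment: int = 0
    trna_offsets_in_end_fragment: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.promoter_fragment) < 30 or len(self.end_fragment) < 30:
            raise SequenceError("anchor fragments must be >= 30 bp")
        if not (0 <= self.tata_offset_in_promoter < len(self.promoter_fragment)):
            raise SequenceError("tata offset outside promoter fragment")
        if not (0 < self.helix_end_offset_in_end_fragment <= len(self.end_fragment)):
            raise SequenceError("helix end offset outside end fragment")

    @classmethod
    def from_truth(cls, root: DnaSequence, truth, gene_key: str = "divergent",
                   promoter_pad: Tuple[int, int] = (400, 100),
                   end_pad: Tuple[int, int] = (50, 20)) -> "AnchorSet":
        """Build anchors from a (plus-strand) root locus and its truth."""
        g = truth.genes[gene_key]
        if g.gene.strand != "+":
            raise SequenceError("anchor extraction expects a plus-strand root locus")
        p0 = g.tata.start - promoter_pad[0]
        p1 = g.tata.start + promoter_pad[1]
        e0 = g.helix_a.start - end_pad[0]
        e1 = g.trna_like.end + end_pad[1]
        conserved = truth.genes["conserved"]
        return cls(
            conserved_gene_reference=root.slice(conserved.gene.start,
                                                conserved.gene.end,
                                                f"{gene_key}_conserved_ref"),
            promoter_fragment=root.slice(p0, p1, f"{gene_key}_promoter_frag"),
            end_fragment=root.slice(e0, e1, f"{gene_key}_end_frag"),
            tata_offset_in_promoter=g.tata.start - p0,
            helix_end_offset_in_end_fragment=g.helix_b.end - e0,
            helix_start_offset_in_end_fragment=g.helix_a.start - e0,
            trna_offsets_in_end_fragment=(g.trna_like.start - e0,
                                          g.trna_like.end - e0),
        )


@dataclass
class GeneModel:
    """Delineated ortholog: TATA-box start to triple-helix end."""

    gene_iv: GenomicInterval
    tata_iv: GenomicInterval
    helix_iv: GenomicInterval
    trna_like_iv: GenomicInterval
    contig_id: str
    strand: str
    pas_main: Optional[int] = None          # transcript-frame offset of the motif start
    pas_alternatives: List[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.gene_iv.length


@dataclass
class SyntenyReport:
    same_contig: bool
    same_strand: bool
    intergenic_distance: Optional[int]


@dataclass
class LocatorParams:
    align: AlignParams = field(default_factory=lambda: AlignParams(min_len=50))
    max_chain_gap: int = 5_000
    score_floor: float = 22.0          # 2 x word_size matches
    ambiguity_ratio: float = 0.8
    min_gene_len: int = 2_000
    max_gene_len: int = 60_000
    min_anchor_coverage: float = 0.5   # anchor hit must cover this fraction
                                       # of its fragment (rejects cross-gene
                                       # hits to shared short motifs)


@dataclass
class _Chain:
    hsps: List[Hsp]

    @property
    def strand(self) -> str:
        return self.hsps[0].strand

    @property
    def score(self) -> float:
        return sum(h.score for h in self.hsps)

    @property
    def subject_iv(self) -> GenomicInterval:
        s = min(h.subject_iv.start for h in self.hsps)
        e = max(h.subject_iv.end for h in self.hsps)
        return GenomicInterval(self.hsps[0].subject_iv.seq_id, s, e, self.strand)


def _chain_hsps(hsps: Sequence[Hsp], max_gap: int) -> List[_Chain]:
    """Greedy collinear chaining of HSPs (same strand, consistent order)."""
    chains: List[_Chain] = []
    for h in sorted(hsps, key=lambda x: (x.strand, x.query_iv.start, -x.score)):
        placed = False
        for c in chains:
            last = c.hsps[-1]
            if c.strand != h.strand:
                continue
            q_gap = h.query_iv.start - last.query_iv.end
            if q_gap < -last.query_iv.length // 2 or q_gap > max_gap:
                continue
            if h.strand == "+":
                s_gap = h.subject_iv.start - last.subject_iv.end
            else:  # forward-frame subject runs backwards along the query
                s_gap = last.subject_iv.start - h.subject_iv.end
            if -50 <= s_gap <= max_gap:
                c.hsps.append(h)
                placed = True
                break
        if not placed:
            chains.append(_Chain([h]))
    return chains


def locate_conserved_anchor(contig: DnaSequence, anchors: AnchorSet,
                            params: Optional[LocatorParams] = None
                            ) -> Optional[GenomicInterval]:
    """Locate the conserved gene on a contig by chained homology.

    Returns the contig interval covered by the best chain (strand from the
    chain), None when no chain reaches the score floor, and raises
    :class:`AmbiguityError` when a second, non-overlapping chain scores
    within ``ambiguity_ratio`` of the best.
    """
    p = params or LocatorParams()
    hsps = local_align(anchors.conserved_gene_reference, contig, p.align)
    if not hsps:
        return None
    chains = [c for c in _chain_hsps(hsps, p.max_chain_gap) if c.score >= p.score_floor]
    if not chains:
        return None
    chains.sort(key=lambda c: -c.score)
    best = chains[0]
    rivals = [c for c in chains[1:]
              if not c.subject_iv.overlaps(best.subject_iv)
              and c.score >= p.ambiguity_ratio * best.score]
    if rivals:
        raise AmbiguityError([best.subject_iv] + [c.subject_iv for c in rivals])
    return best.subject_iv


def _best_anchor_hit(fragment: DnaSequence, contig: DnaSequence,
                     window: GenomicInterval, p: LocatorParams) -> Optional[Hsp]:
    sub = contig.slice(window.start, window.end, contig.id)
    hits = [h for h in local_align(fragment, sub, p.align)
            if h.query_iv.length >= p.min_anchor_coverage * len(fragment)]
    if not hits:
        return None
    h = hits[0]
    # shift subject coordinates back onto the full contig
    return Hsp(query_iv=h.query_iv,
               subject_iv=h.subject_iv.shifted(window.start),
               pident=h.pident, aln_length=h.aln_length, strand=h.strand,
               score=h.score, cigar=h.cigar)


def _map_offset(hsp: Hsp, offset: int, window: GenomicInterval,
                contig_len: int) -> Optional[int]:
    """Forward-frame contig position of a fragment offset, via the cigar."""
    qpos = min(max(offset, hsp.query_iv.start), hsp.query_iv.end - 1)
    if abs(qpos - offset) > 50:
        return None  # the anchor hit does not cover the offset closely enough
    window_len = window.length
    pos = map_query_to_subject(hsp, qpos, window_len if hsp.strand == "-" else None)
    delta = offset - qpos  # extrapolate outside the aligned part
    if hsp.strand == "+":
        return pos + delta
    return pos - delta


def locate_gene(contig: DnaSequence, search_window: GenomicInterval,
                anchors: AnchorSet, params: Optional[LocatorParams] = None
                ) -> GeneModel:
    """Delineate a gene inside a window from its promoter and 3'-end anchors.

    Raises :class:`NoCallError` naming the missing anchor, a strand conflict,
    inverted boundaries, or an implausible gene length.
    """
    p = params or LocatorParams()
    if not (0 <= search_window.start < search_window.end <= len(contig)):
        raise SequenceError("search window outside contig")
    prom = _best_anchor_hit(anchors.promoter_fragment, contig, search_window, p)
    endf = _best_anchor_hit(anchors.end_fragment, contig, search_window, p)
    if prom is None:
        raise NoCallError("5prime_anchor", "promoter fragment not found")
    if endf is None:
        raise NoCallError("3prime_anchor", "end fragment not found")
    if prom.strand != endf.strand:
        raise NoCallError("strand_conflict",
                          f"promoter on {prom.strand}, end on {endf.strand}")
    strand = prom.strand
    L = len(contig)

    tata_start = _map_offset(prom, anchors.tata_offset_in_promoter, search_window, L)
    helix_last = _map_offset(endf, anchors.helix_end_offset_in_end_fragment - 1,
                             search_window, L)
    if tata_start is None:
        raise NoCallError("5prime_anchor", "TATA offset outside promoter hit")
    if helix_last is None:
        raise NoCallError("3prime_anchor", "helix end outside end-fragment hit")

    def span(a: int, b: int) -> GenomicInterval:
        return GenomicInterval(contig.id, min(a, b), max(a, b) + 1, strand)

    if strand == "+" and tata_start >= helix_last:
        raise NoCallError("inverted_boundaries")
    if strand == "-" and tata_start <= helix_last:
        raise NoCallError("inverted_boundaries")
    gene_iv = span(tata_start, helix_last)
    if not (p.min_gene_len <= gene_iv.length <= p.max_gene_len):
        raise NoCallError("implausible_length", f"{gene_iv.length} bp")

    tata_end_off = anchors.tata_offset_in_promoter + 5
    tata_iv = span(tata_start,
                   _map_offset(prom, tata_end_off, search_window, L) or
                   (tata_start + 5 if strand == "+" else tata_start - 5))
    helix_first = _map_offset(endf, anchors.helix_start_offset_in_end_fragment,
                              search_window, L)
    helix_iv = span(helix_first if helix_first is not None else helix_last, helix_last)
    t0, t1 = anchors.trna_offsets_in_end_fragment
    if t1 > t0:
        a = _map_offset(endf, t0, search_window, L)
        b = _map_offset(endf, t1 - 1, search_window, L)
        trna_iv = span(a, b) if a is not None and b is not None else helix_iv
    else:
        trna_iv = helix_iv
    return GeneModel(gene_iv=gene_iv, tata_iv=tata_iv, helix_iv=helix_iv,
                     trna_like_iv=trna_iv, contig_id=contig.id, strand=strand)


def check_synteny(a: GeneModel, b: GeneModel) -> SyntenyReport:
    """Strand and distance relationship of two gene models."""
    same_contig = a.contig_id == b.contig_id
    same_strand = a.strand == b.strand
    if not same_contig:
        return SyntenyReport(False, same_strand, None)
    gap = max(a.gene_iv.start, b.gene_iv.start) - min(a.gene_iv.end, b.gene_iv.end)
    return SyntenyReport(True, same_strand, max(0, gap))


def gene_sequence(contig: DnaSequence, model: GeneModel) -> DnaSequence:
    """Extract the gene in transcript orientation."""
    from .seq import reverse_complement

    sub = contig.slice(model.gene_iv.start, model.gene_iv.end,
                       f"{contig.id}|gene")
    return sub if model.strand == "+" else reverse_complement(sub)
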