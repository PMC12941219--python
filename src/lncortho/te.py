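"""Transposable-element annotation under the 80-80-80 rule.

A candidate alignment of a library consensus to a gene is accepted when it is
at least 80 bp long, at least 80% identical, and covers at least 80% of the
consensus. Overlap resolution is greedy by identity-weighted length
(pident x aln_length) with deterministic tie-breaks, which makes the accepted
set the unique greedy independent set of the overlap graph. Presence/absence
across orthologs is resolved by lifting +-200 bp flanks between leaves; a
clean flank junction (<= 10 bp residue) at a locus absent from exactly one
leaf of a clade is flagged as an excision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .align import AlignParams, Hsp, best_hit, cigar_stats, local_align
from .seq import DnaSequence, GenomicInterval, revcomp
from .simulate import PhyloTree

MIN_ALN_LEN = 80
MIN_PIDENT = 80.0
MIN_TE_COVERAGE = 0.80
FLANK = 200
JUNCTION_TOLERANCE = 10


@dataclass
class TeAnnotation:
    te_name: str
    te_class: str
    gene_iv: GenomicInterval
    pident: float
    aln_length: int
    te_coverage: float

    @property
    def priority(self) -> float:
        return self.pident * self.aln_length


@dataclass
class BinnedProfile:
    """Counts over equal fractional-length bins of [0, 1]."""

    n_bins: int
    counts: List[int]
    normalization: str = "per-gene fractional length"

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_bins:
            raise ValueError("counts length must equal n_bins")

    def __add__(self, other: "BinnedProfile") -> "BinnedProfile":
        if other.n_bins != self.n_bins:
            raise ValueError("bin counts differ")
        return BinnedProfile(self.n_bins,
                             [a + b for a, b in zip(self.counts, other.counts)],
                             self.normalization)


def apply_80_80_80(candidates: Sequence[TeAnnotation],
                   min_len: int = MIN_ALN_LEN, min_pident: float = MIN_PIDENT,
                   min_coverage: float = MIN_TE_COVERAGE) -> List[TeAnnotation]:
    """The three-threshold filter, exposed separately for auditability."""
    return [c for c in candidates
            if c.aln_length >= min_len and c.pident >= min_pident
            and c.te_coverage >= min_coverage]


def select_nonoverlapping(candidates: Sequence[TeAnnotation]) -> List[TeAnnotation]:
    """Greedy acceptance by descending pident x aln_length.

    Ties break by higher pident, then leftmost gene start, then te_name.
    """
    ordered = sorted(candidates,
                     key=lambda c: (-c.priority, -c.pident, c.gene_iv.start, c.te_name))
    accepted: List[TeAnnotation] = []
    for c in ordered:
        if any(c.gene_iv.overlaps(a.gene_iv) for a in accepted):
            continue
        accepted.append(c)
    accepted.sort(key=lambda c: c.gene_iv.start)
    return accepted


def _full_length_fit(te: DnaSequence, gene: DnaSequence, h: Hsp,
                     slack: int = 30) -> Optional[TeAnnotation]:
    """Fit the whole consensus around a partially covering hit.

    A local hit can stop inside a diverged element end; extending the
    subject window by the uncovered consensus length and infix-aligning the
    full consensus judges the 80-80-80 rule on the complete element, as
    repeat annotators conventionally do.
    """
    miss_left = h.query_iv.start
    miss_right = len(te) - h.query_iv.end
    if h.strand == "+":
        w0 = max(0, h.subject_iv.start - miss_left - slack)
        w1 = min(len(gene), h.subject_iv.end + miss_right + slack)
        window = gene.residues[w0:w1]
    else:
        w0 = max(0, h.subject_iv.start - miss_right - slack)
        w1 = min(len(gene), h.subject_iv.end + miss_left + slack)
        window = revcomp(gene.residues[w0:w1])
    res = edlib.align(te.residues, window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    m, x, ins, dele, cols = cigar_stats(res["cigar"])
    if cols == 0:
        return None
    a, b = res["locations"][0]
    b += 1
    if h.strand == "+":
        iv = GenomicInterval(gene.id, w0 + a, w0 + b, "+")
    else:
        iv = GenomicInterval(gene.id, w1 - b, w1 - a, "-")
    te_class = te.meta.get("class") or te.meta.get("description", "#unknown").lstrip("#")
    return TeAnnotation(te_name=te.id, te_class=te_class, gene_iv=iv,
                        pident=100.0 * m / cols, aln_length=cols,
                        te_coverage=1.0)


def annotate_tes(gene: DnaSequence, library: Sequence[DnaSequence],
                 params: Optional[AlignParams] = None,
                 min_pident: float = MIN_PIDENT,
                 min_coverage: float = MIN_TE_COVERAGE) -> List[TeAnnotation]:
    """Annotate TEs on a gene from a consensus library (both strands)."""
    if not library:
        raise ValueError("empty TE library")
    p = params or AlignParams(min_pident=70.0, min_len=60)
    candidates: List[TeAnnotation] = []
    for te in library:
        te_class = te.meta.get("class") or te.meta.get("description", "#unknown").lstrip("#")
        for h in local_align(te, gene, p):
            coverage = h.query_iv.length / len(te)
            if coverage < min_coverage and h.pident >= min_pident:
                fitted = _full_length_fit(te, gene, h)
                if fitted is not None and fitted.pident >= min_pident:
                    candidates.append(fitted)
                    continue
            candidates.append(TeAnnotation(
                te_name=te.id, te_class=te_class,
                gene_iv=GenomicInterval(gene.id, h.subject_iv.start,
                                        h.subject_iv.end, h.strand),
                pident=h.pident, aln_length=h.aln_length, te_coverage=coverage))
    return select_nonoverlapping(apply_80_80_80(
        candidates, min_pident=min_pident, min_coverage=min_coverage))


def te_positional_profile(annotations: Sequence[TeAnnotation], gene_length: int,
                          n_bins: int = 20) -> BinnedProfile:
    """Bin TEs by the fractional position of their interval midpoint."""
    counts = [0] * n_bins
    for a in annotations:
        frac = a.gene_iv.midpoint / gene_length
        idx = min(n_bins - 1, int(frac * n_bins))
        counts[idx] += 1
    return BinnedProfile(n_bins, counts)


# ---------------------------------------------------------------------------
# presence/absence matrix and excision detection
# ---------------------------------------------------------------------------

PRESENT = "present"
ABSENT = "absent"
UNRESOLVED = "unresolved"


@dataclass
class TeLocus:
    locus_id: str
    te_name: str
    status: Dict[str, str]                 # leaf -> present/absent/unresolved
    positions: Dict[str, Tuple[int, int]]  # leaf -> projected/annotated interval
    excised_in: List[str]


def _project_flanks(donor_gene: str, iv: GenomicInterval, target: DnaSequence,
                    params: AlignParams) -> Optional[Tuple[int, int]]:
    """Map a TE locus onto another gene by its +-FLANK bp flanks.

    Returns (left_end, right_start) in target coordinates: the insertion
    breakpoints the flanks imply. None when either flank fails to anchor.
    """
    lf_lo = max(0, iv.start - FLANK)
    rf_hi = min(len(donor_gene), iv.end + FLANK)
    if iv.start - lf_lo < 50 or rf_hi - iv.end < 50:
        return None
    left = DnaSequence("lf", donor_gene[lf_lo:iv.start])
    right = DnaSequence("rf", donor_gene[iv.end:rf_hi])
    hl = best_hit(left, target, params)
    hr = best_hit(right, target, params)
    if hl is None or hr is None or hl.strand != "+" or hr.strand != "+":
        return None
    # extrapolate to the flank edge in case the HSP stops short
    left_end = hl.subject_iv.end + (len(left) - hl.query_iv.end)
    right_start = hr.subject_iv.start - hr.query_iv.start
    if right_start < left_end - 2 * FLANK:
        return None
    return left_end, right_start


def _junction_clean(donor_gene: str, iv: GenomicInterval, target: DnaSequence,
                    center: int, tolerance: int = JUNCTION_TOLERANCE,
                    min_identity: float = 65.0, probe_flank: int = 100) -> bool:
    """True when the donor's flanks ligate cleanly in the target.

    The probe is the donor sequence with the TE deleted (left + right flank
    joined); it must infix-align around the projected junction spanning its
    own length within the tolerance — a still-present TE would force a
    TE-sized gap into the alignment. The probe uses short flanks so lineage
    indel drift does not masquerade as junction residue.
    """
    lf_lo = max(0, iv.start - probe_flank)
    rf_hi = min(len(donor_gene), iv.end + probe_flank)
    probe = donor_gene[lf_lo:iv.start] + donor_gene[iv.end:rf_hi]
    if len(probe) < probe_flank:
        return False
    w0 = max(0, center - len(probe) - 100)
    w1 = min(len(target), center + len(probe) + 100)
    res = edlib.align(probe, target.residues[w0:w1], mode="HW", task="path")
    if res["editDistance"] < 0:
        return False
    from .align import parse_cigar

    m, x, ins, dele, cols = cigar_stats(res["cigar"])
    if cols == 0 or 100.0 * m / cols < min_identity:
        return False
    # a TE remnant at the junction appears as one contiguous deletion run
    # in the probe alignment; lineage indels are short and scattered
    max_del = max((n for n, op in parse_cigar(res["cigar"]) if op == "D"),
                  default=0)
    return max_del <= tolerance


def te_presence_matrix(annotated: Dict[str, List[TeAnnotation]],
                       genes: Dict[str, DnaSequence], tree: PhyloTree,
                       params: Optional[AlignParams] = None) -> List[TeLocus]:
    """Cluster homologous TE loci across leaves and flag excisions.

    A locus is `absent` in a leaf only when both flanks anchor and ligate
    with <= 10 bp of residue; anchoring failure yields `unresolved`, never
    `absent`. An excision is flagged when the locus is present in all leaves
    of the smallest clade containing the absent leaf and a present leaf.
    """
    # flanks are short and may be diverged: smaller seeds make anchoring
    # robust down to ~70% identity
    p = params or AlignParams(word_size=8, min_pident=65.0, min_len=50)
    leaves = [lf for lf in tree.leaf_names if lf in genes]
    loci: List[TeLocus] = []
    assigned: Dict[str, set] = {lf: set() for lf in leaves}

    for donor in leaves:
        for ai, ann in enumerate(annotated.get(donor, [])):
            key = (donor, ai)
            if key in assigned[donor]:
                continue
            locus = TeLocus(locus_id=f"{donor}:{ann.te_name}:{ann.gene_iv.start}",
                            te_name=ann.te_name, status={}, positions={},
                            excised_in=[])
            locus.status[donor] = PRESENT
            locus.positions[donor] = (ann.gene_iv.start, ann.gene_iv.end)
            assigned[donor].add(key)
            for other in leaves:
                if other == donor or other in locus.status:
                    continue
                proj = _project_flanks(genes[donor].residues, ann.gene_iv,
                                       genes[other], p)
                if proj is None:
                    # flank anchoring failed: fall back to name + position
                    # matching (leaf gene frames share the ancestral
                    # coordinate system up to indel drift), else unresolved
                    match = None
                    for bi, b in enumerate(annotated.get(other, [])):
                        if (other, bi) not in assigned[other] \
                                and b.te_name == ann.te_name \
                                and abs(b.gene_iv.start
                                        - ann.gene_iv.start) <= 2 * FLANK:
                            match = (bi, b)
                            break
                    if match is not None:
                        bi, b = match
                        locus.status[other] = PRESENT
                        locus.positions[other] = (b.gene_iv.start, b.gene_iv.end)
                        assigned[other].add((other, bi))
                    else:
                        locus.status[other] = UNRESOLVED
                    continue
                left_end, right_start = proj
                match = None
                for bi, b in enumerate(annotated.get(other, [])):
                    if (other, bi) in assigned[other]:
                        continue
                    if (b.te_name == ann.te_name
                            and abs(b.gene_iv.start - left_end) <= 2 * FLANK
                            and abs(b.gene_iv.end - right_start) <= 2 * FLANK):
                        match = (bi, b)
                        break
                if match is not None:
                    bi, b = match
                    locus.status[other] = PRESENT
                    locus.positions[other] = (b.gene_iv.start, b.gene_iv.end)
                    assigned[other].add((other, bi))
                elif _junction_clean(genes[donor].residues, ann.gene_iv,
                                     genes[other],
                                     (left_end + right_start) // 2):
                    locus.status[other] = ABSENT
                    locus.positions[other] = (left_end, right_start)
                else:
                    locus.status[other] = UNRESOLVED
            loci.append(locus)

    for locus in loci:
        present = [lf for lf, st in locus.status.items() if st == PRESENT]
        for lf, st in locus.status.items():
            if st != ABSENT:
                continue
            clade = tree.minimal_clade_leaves(lf, present)
            others = [x for x in clade if x != lf and x in locus.status]
            if others and all(locus.status.get(x) == PRESENT for x in others):
                locus.excised_in.append(lf)
    return loci
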