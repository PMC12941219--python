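"""Polyadenylation-signal calling for the short isoform.

The canonical hexamer AATAAA is the only motif considered. The expected PAS
position is projected from a reference gene carrying a known PAS; a main call
requires exactly one motif within +-110 bp of the projection, and alternative
signals are collected within +-600 bp of the main call. All positions are
transcript-frame offsets of the motif start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import edlib

from .align import local_align, map_query_to_subject, AlignParams
from .seq import DnaSequence, SequenceError

PAS_MOTIF = "AATAAA"
MAIN_WINDOW = 110
ALT_WINDOW = 600


class ProjectionError(ValueError):
    """No homology near the reference PAS (distinct from 'no PAS present')."""


@dataclass
class PasCall:
    position: int                      # motif start, transcript frame
    motif: str
    kind: str                          # main | alternative | marsupial_pair
    offset_from_projection: int
    rescue: bool = False


def _motif_positions(residues: str, lo: int, hi: int) -> List[int]:
    lo = max(0, lo)
    hi = min(len(residues) - len(PAS_MOTIF) + 1, hi)
    out = []
    pos = residues.find(PAS_MOTIF, lo)
    while 0 <= pos < hi:
        out.append(pos)
        pos = residues.find(PAS_MOTIF, pos + 1)
    return out


def project_reference_pas(gene: DnaSequence, reference: DnaSequence,
                          ref_pas_pos: int) -> int:
    """Project the reference PAS position onto a gene (transcript frames).

    Uses the best HSP covering the reference position; if no HSP covers it,
    falls back to an infix alignment of the reference neighbourhood.
    """
    if not (0 <= ref_pas_pos < len(reference)):
        raise SequenceError("reference PAS position outside the reference")
    hits = local_align(reference, gene, AlignParams(both_strands=False))
    for h in sorted(hits, key=lambda x: -x.score):
        if h.query_iv.start <= ref_pas_pos < h.query_iv.end:
            return map_query_to_subject(h, ref_pas_pos)
    # fallback: infix alignment of +-300 bp around the reference PAS
    lo = max(0, ref_pas_pos - 300)
    hi = min(len(reference), ref_pas_pos + 300)
    res = edlib.align(reference.residues[lo:hi], gene.residues, mode="HW", task="path")
    if res["editDistance"] < 0 or res["editDistance"] > 0.4 * (hi - lo):
        raise ProjectionError(
            f"no homology near reference PAS of {reference.id} in {gene.id}")
    start = res["locations"][0][0]
    # walk the cigar to the offset of the PAS inside the aligned block
    from .align import parse_cigar

    q = lo
    s = start
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            if q + n > ref_pas_pos:
                return s + (ref_pas_pos - q)
            q += n
            s += n
        elif op == "I":
            if q + n > ref_pas_pos:
                return s
            q += n
        elif op == "D":
            s += n
    raise ProjectionError("reference PAS beyond the aligned block")


def call_main_pas(gene: DnaSequence, projected: int, window: int = MAIN_WINDOW
                  ) -> Optional[PasCall]:
    """Call the main PAS: exactly one AATAAA within +-window of the projection.

    Returns None for zero (reason 'absent') or multiple motifs (reason
    'ambiguous'); the reason is retrievable via :func:`main_pas_status`.
    """
    call, _ = _main_pas(gene, projected, window)
    return call


def main_pas_status(gene: DnaSequence, projected: int, window: int = MAIN_WINDOW
                    ) -> str:
    """'called', 'absent' or 'ambiguous' for the main-PAS scan."""
    call, reason = _main_pas(gene, projected, window)
    return "called" if call else reason


def _main_pas(gene: DnaSequence, projected: int, window: int):
    if not (0 <= projected < len(gene)):
        raise SequenceError("projected position outside gene")
    positions = _motif_positions(gene.residues, projected - window,
                                 projected + window + 1)
    if len(positions) == 1:
        p = positions[0]
        return PasCall(p, PAS_MOTIF, "main", p - projected), "called"
    return None, ("absent" if not positions else "ambiguous")


def find_alternative_pas(gene: DnaSequence, main: PasCall,
                         window: int = ALT_WINDOW) -> List[PasCall]:
    """All AATAAA occurrences within +-window of the main call (excluded)."""
    positions = _motif_positions(gene.residues, main.position - window,
                                 main.position + window + 1)
    return [PasCall(p, PAS_MOTIF, "alternative", p - main.position)
            for p in positions if p != main.position]


def call_two_pas(gene: DnaSequence, projected: int, window: int = ALT_WINDOW
                 ) -> List[PasCall]:
    """Marsupial-like mode: report all signals within +-window of the
    projection; the closest is the main call, the rest are pair members."""
    positions = _motif_positions(gene.residues, projected - window,
                                 projected + window + 1)
    positions.sort(key=lambda p: (abs(p - projected), p))
    calls = []
    for i, p in enumerate(positions):
        kind = "main" if i == 0 else "marsupial_pair"
        calls.append(PasCall(p, PAS_MOTIF, kind, p - projected))
    return sorted(calls, key=lambda c: c.position)


def rescue_pas(gene: DnaSequence, lo: int = 3_000, hi: int = 4_500
               ) -> Optional[PasCall]:
    """Optional rescue when projection fails: a single motif in the prior
    window of short-isoform lengths is accepted, flagged rescue=True."""
    positions = _motif_positions(gene.residues, lo, hi)
    if len(positions) == 1:
        p = positions[0]
        return PasCall(p, PAS_MOTIF, "main", 0, rescue=True)
    return None
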