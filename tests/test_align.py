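"""Local homology search: identity, planted-fragment recovery, negative
controls, brute-force DP agreement, symmetry and liftover."""

import numpy as np
import pytest
from Bio import Align

from lncortho.align import AlignParams, local_align, map_query_to_subject
from lncortho.seq import DnaSequence, SequenceError, revcomp

from conftest import random_dna


def _mutate(rng, s, n_subs):
    out = list(s)
    for i in rng.choice(len(s), n_subs, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


class TestBasics:
    def test_identical_sequences_single_full_hsp(self, rng):
        s = random_dna(rng, 500)
        hits = local_align(DnaSequence("a", s), DnaSequence("b", s))
        assert len(hits) == 1
        h = hits[0]
        assert h.pident == 100.0 and h.aln_length == 500 and h.strand == "+"

    def test_planted_fragment_recovered(self, rng):
        frag = random_dna(rng, 300)
        mutated = _mutate(rng, frag, 15)  # 5% point mutations
        bg = random_dna(rng, 5000)
        subject = bg[:2000] + mutated + bg[2000:]
        hits = local_align(DnaSequence("f", frag), DnaSequence("g", subject))
        assert hits, "planted fragment not found"
        h = hits[0]
        assert h.query_iv.length >= 0.95 * 300
        assert 90.0 <= h.pident <= 100.0
        assert abs(h.subject_iv.start - 2000) <= 15

    def test_minus_strand_reported_on_forward_frame(self, rng):
        frag = random_dna(rng, 300)
        subject = random_dna(rng, 1000) + revcomp(frag) + random_dna(rng, 1000)
        hits = local_align(DnaSequence("f", frag), DnaSequence("g", subject))
        h = hits[0]
        assert h.strand == "-"
        assert abs(h.subject_iv.start - 1000) <= 10

    def test_random_pairs_no_spurious_long_hits(self, rng):
        # expected chance of a >=100 bp 70% match between random 200-mers is
        # negligible; check over seeded replicates
        n_hits = 0
        for _ in range(25):
            a = DnaSequence("a", random_dna(rng, 200))
            b = DnaSequence("b", random_dna(rng, 200))
            n_hits += len(local_align(a, b, min_len=100))
        assert n_hits == 0

    def test_word_size_precondition(self, rng):
        with pytest.raises(SequenceError):
            local_align(DnaSequence("a", "ACGTACGT"),
                        DnaSequence("b", "ACGTACGT"), word_size=3)


class TestOracle:
    """On short sequences the HSP identity must track an exact local DP."""

    @staticmethod
    def _biopython_local_pidents(a, b, max_alignments=50):
        """Identity of each score-optimal local DP alignment (ties differ)."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        out = []
        for i, aln in enumerate(aligner.align(a, b)):
            if i >= max_alignments:
                break
            cols = aln.length
            matches = sum(x == y for x, y in zip(aln[0], aln[1])
                          if x != "-" and y != "-")
            out.append(100.0 * matches / cols if cols else 0.0)
        return out

    def test_pident_matches_exact_dp_within_one_point(self, rng):
        checked = 0
        for _ in range(30):
            core = random_dna(rng, 40)
            a = random_dna(rng, 10) + core + random_dna(rng, 10)
            b = random_dna(rng, 8) + _mutate(rng, core, 3) + random_dna(rng, 8)
            hits = local_align(DnaSequence("a", a), DnaSequence("b", b),
                               word_size=5, min_len=20, min_pident=50)
            if not hits:
                continue
            oracle = self._biopython_local_pidents(a, b)
            assert min(abs(hits[0].pident - o) for o in oracle) <= 1.0 + 1e-9
            checked += 1
        assert checked >= 20


class TestProperties:
    def test_role_swap_symmetry(self, rng):
        frag = random_dna(rng, 400)
        a = DnaSequence("a", random_dna(rng, 300) + frag + random_dna(rng, 300))
        b = DnaSequence("b", random_dna(rng, 500) + _mutate(rng, frag, 20)
                        + random_dna(rng, 200))
        fwd = local_align(a, b)
        rev = local_align(b, a)
        assert len(fwd) == len(rev)
        for hf, hr in zip(fwd, rev):
            assert (hf.query_iv.start, hf.query_iv.end) == \
                (hr.subject_iv.start, hr.subject_iv.end)
            assert (hf.subject_iv.start, hf.subject_iv.end) == \
                (hr.query_iv.start, hr.query_iv.end)
            assert hf.pident == pytest.approx(hr.pident, abs=1e-6)

    def test_weighted_length_invariant(self, rng):
        frag = random_dna(rng, 300)
        b = DnaSequence("b", random_dna(rng, 100) + _mutate(rng, frag, 30)
                        + random_dna(rng, 100))
        for h in local_align(DnaSequence("a", frag), b):
            assert h.weighted_length <= h.aln_length
            assert (h.pident == 100.0) == (h.weighted_length == h.aln_length)

    def test_sorted_by_score(self, rng):
        frag1, frag2 = random_dna(rng, 400), random_dna(rng, 150)
        a = DnaSequence("a", frag1 + random_dna(rng, 100) + frag2)
        b = DnaSequence("b", random_dna(rng, 50) + frag2
                        + random_dna(rng, 400) + frag1)
        hits = local_align(a, b)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)


class TestLiftover:
    def test_exact_positions_through_cigar(self, rng):
        s = random_dna(rng, 600)
        # insert 50 bp at position 300 in the subject
        subject = s[:300] + random_dna(rng, 50) + s[300:]
        hits = local_align(DnaSequence("q", s), DnaSequence("s", subject))
        h = max(hits, key=lambda x: x.aln_length)
        assert map_query_to_subject(h, 100) == 100
        assert map_query_to_subject(h, 400) == 450

    def test_minus_strand_liftover(self, rng):
        s = random_dna(rng, 400)
        subject = random_dna(rng, 200) + revcomp(s) + random_dna(rng, 200)
        h = local_align(DnaSequence("q", s), DnaSequence("s", subject))[0]
        # query position p maps to forward position 200 + (400 - 1 - p)
        for p in (0, 100, 399):
            assert map_query_to_subject(h, p, len(subject)) == 200 + 399 - p
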