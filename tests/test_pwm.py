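"""PWM reading, scanning, exact DP p-values, shared-TF analysis."""

import numpy as np
import pytest

from lncortho.pwm import (LATTICE, Pwm, go_join, null_distribution, read_pwms,
                          scan_pwm, score_pvalue_fn, shared_between,
                          shared_tfs, write_jaspar)
from lncortho.seq import DnaSequence, SequenceError, revcomp

from conftest import random_dna

JASPAR_TEXT = """\
>MA0001.1 TESTTF
A [ 10 0 0 20 5 0 0 2 ]
C [ 5 0 30 0 5 0 0 8 ]
G [ 10 30 0 0 15 0 30 10 ]
T [ 5 0 0 10 5 30 0 10 ]
"""

MEME_TEXT = """\
MEME version 4

ALPHABET= ACGT

MOTIF TESTTF
letter-probability matrix: alength= 4 w= 8 nsites= 30
0.3333 0.1667 0.3333 0.1667
0.0 0.0 1.0 0.0
0.0 1.0 0.0 0.0
0.6667 0.0 0.0 0.3333
0.1667 0.1667 0.5 0.1667
0.0 0.0 0.0 1.0
0.0 0.0 1.0 0.0
0.0667 0.2667 0.3333 0.3333
"""


class TestReaders:
    def test_jaspar_counts_block(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        pwms = read_pwms(p)
        assert len(pwms) == 1
        pwm = pwms[0]
        assert pwm.tf_name == "TESTTF" and pwm.width == 8
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_meme_equivalent_to_counts(self, tmp_path):
        pj = tmp_path / "m.jaspar"
        pj.write_text(JASPAR_TEXT)
        pm = tmp_path / "m.meme"
        pm.write_text(MEME_TEXT)
        # the MEME probabilities above are the JASPAR counts / 30
        a = read_pwms(pj)[0]
        b = read_pwms(pm)[0]
        assert np.allclose(a.matrix, b.matrix, atol=2e-3)

    def test_malformed_record_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT + ">BROKEN\nA [ 1 2\n")
        pwms = read_pwms(p)
        assert len(pwms) == 1

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.jaspar"
        p.write_text("")
        with pytest.raises(SequenceError):
            read_pwms(p)

    def test_write_read_round_trip(self, tmp_path, rng):
        counts = rng.dirichlet([1] * 4, size=9) * 100
        pwm = Pwm.from_counts("RT", counts)
        path = tmp_path / "rt.jaspar"
        write_jaspar([pwm], path, nsites=10_000)
        back = read_pwms(path)[0]
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-3)


def _sharp_pwm(consensus, weight=200.0):
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.full((len(consensus), 4), 1.0)
    for w, b in enumerate(consensus):
        counts[w, idx[b]] = weight
    return Pwm.from_counts("SHARP", counts)


class TestScan:
    def test_planted_consensus_found_with_max_score(self, rng):
        consensus = "GATTACAGGT"
        pwm = _sharp_pwm(consensus)
        seq = DnaSequence("s", random_dna(rng, 400) + consensus
                          + random_dna(rng, 400))
        hits = scan_pwm(seq, pwm)
        assert any(h.iv.start == 400 for h in hits)
        best = max(hits, key=lambda h: h.score)
        max_score = pwm.lattice_scores().max(axis=1).sum() / LATTICE
        assert best.score == pytest.approx(max_score, abs=1e-6)

    def test_uniform_pwm_no_hits(self, rng):
        pwm = Pwm("FLAT", np.full((8, 4), 0.25))
        seq = DnaSequence("s", random_dna(rng, 500))
        assert scan_pwm(seq, pwm) == []

    def test_strand_symmetry(self, rng):
        pwm = _sharp_pwm("GATTACAGG")
        s = random_dna(rng, 300) + "GATTACAGG" + random_dna(rng, 300)
        fwd = scan_pwm(DnaSequence("s", s), pwm, both_strands=True)
        rc_only = scan_pwm(DnaSequence("r", revcomp(s)), pwm,
                           both_strands=False)
        minus_expected = {(len(s) - h.iv.end, len(s) - h.iv.start)
                          for h in rc_only}
        minus_found = {(h.iv.start, h.iv.end) for h in fwd if h.strand == "-"}
        assert minus_expected <= minus_found | \
            {(h.iv.start, h.iv.end) for h in fwd}

    def test_lowering_threshold_never_adds_hits(self, rng):
        pwm = _sharp_pwm("GGATCCA", weight=20)
        seq = DnaSequence("s", random_dna(rng, 2000))
        loose = {(h.iv.start, h.strand) for h in scan_pwm(seq, pwm, 1e-3)}
        tight = {(h.iv.start, h.strand) for h in scan_pwm(seq, pwm, 1e-5)}
        assert tight <= loose


class TestExactPvalues:
    def test_null_distribution_sums_to_one(self, rng):
        counts = rng.dirichlet([0.5] * 4, size=12) * 50
        pmf, _ = null_distribution(Pwm.from_counts("X", counts))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dp_equals_exhaustive_enumeration(self, rng):
        # widths <= 8: enumerate all 4^w words, score on the same lattice
        for width in (4, 6, 8):
            counts = rng.dirichlet([0.7] * 4, size=width) * 40
            pwm = Pwm.from_counts("X", counts)
            scores = pwm.lattice_scores()
            pvalue = score_pvalue_fn(pwm)
            word_scores = np.zeros(1, dtype=np.int64)
            for w in range(width):
                word_scores = (word_scores[:, None]
                               + scores[w][None, :]).ravel()
            word_scores.sort()
            n = word_scores.size
            for s in np.quantile(word_scores, [0.2, 0.5, 0.9, 0.999]).astype(int):
                exhaustive = np.sum(word_scores >= s) / n
                assert pvalue(int(s)) == pytest.approx(exhaustive, abs=1e-9)

    def test_pvalues_monotone_in_score(self, rng):
        counts = rng.dirichlet([1] * 4, size=10) * 30
        pvalue = score_pvalue_fn(Pwm.from_counts("X", counts))
        grid = np.linspace(-20_000, 20_000, 101).astype(int)
        ps = [pvalue(int(s)) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestSharedTfs:
    def test_threshold_boundary(self):
        hits = {f"g{i}": ({"TF1"} if i < 7 else set()) for i in range(10)}
        assert shared_tfs(hits, 0.65) == ["TF1"]          # 7/10 >= 0.65
        hits = {f"g{i}": ({"TF1"} if i < 6 else set()) for i in range(10)}
        assert shared_tfs(hits, 0.65) == []               # 6/10 < 0.65

    def test_intersection_of_two_regulomes(self):
        assert shared_between(["SP1", "EGR1", "X"], ["EGR1", "SP1", "Y"]) == \
            ["EGR1", "SP1"]

    def test_go_join_counts_terms(self):
        table = {"SP1": ["proliferation", "apoptosis"],
                 "EGR1": ["apoptosis"]}
        rows = go_join(["SP1", "EGR1"], table)
        assert rows[0] == ("apoptosis", 2, ["EGR1", "SP1"])
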