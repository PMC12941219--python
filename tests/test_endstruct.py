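"""3'-end structures: extraction, progressive MSA, conservation, covariation."""

import numpy as np
import pytest

from lncortho.endstruct import (ReferenceLayout, align_msa, column_conservation,
                                covariation, extract_end_structures,
                                pairs_from_dotbracket)
from lncortho.locate import locate_gene
from lncortho.seq import DnaSequence, GenomicInterval, SequenceError
from lncortho.simulate import TRNA_LIKE, TRNA_LIKE_STRUCTURE

from conftest import random_dna


class TestExtraction:
    def test_zero_divergence_lengths_exact(self, default_cohort,
                                           default_anchors):
        root, truth = default_cohort["root"], default_cohort["truth"]
        layout = ReferenceLayout.from_truth(root, truth)
        model = locate_gene(root, GenomicInterval(root.id, 0, len(root)),
                            default_anchors["divergent"])
        esm = extract_end_structures(root, model, layout)
        g = truth.genes["divergent"]
        lengths = esm.lengths()
        assert lengths["hairpin"] == g.hairpin.length
        assert lengths["linker"] == g.linker.length
        assert lengths["trna_like"] == g.trna_like.length

    def test_indel_free_elements_constant_length_across_leaves(
            self, default_cohort, default_anchors):
        root, truth = default_cohort["root"], default_cohort["truth"]
        layout = ReferenceLayout.from_truth(root, truth)
        hairpins, linkers = [], []
        for leaf, (contig, _) in default_cohort["leaves"].items():
            model = locate_gene(contig,
                                GenomicInterval(contig.id, 0, len(contig)),
                                default_anchors["divergent"])
            esm = extract_end_structures(contig, model, layout)
            hairpins.append(esm.lengths()["hairpin"])
            linkers.append(esm.lengths()["linker"])
        # the generator forbids indels in the 3' block: sd must be 0
        assert np.std(hairpins) == 0.0 and np.std(linkers) == 0.0

    def test_missing_element_partial_model(self, default_cohort,
                                           default_anchors, rng):
        root, truth = default_cohort["root"], default_cohort["truth"]
        layout = ReferenceLayout.from_truth(root, truth)
        g = truth.genes["divergent"]
        # scramble the tRNA-like element only
        res = list(root.residues)
        res[g.trna_like.start:g.trna_like.end] = random_dna(
            rng, g.trna_like.length)
        broken = DnaSequence(root.id, "".join(res))
        model = locate_gene(broken, GenomicInterval(root.id, 0, len(root)),
                            default_anchors["divergent"])
        esm = extract_end_structures(broken, model, layout)
        assert esm.trna_like_iv is None
        assert esm.hairpin_iv is not None and esm.linker_iv is not None


class TestMsa:
    def test_identical_rows(self):
        msa = align_msa(["ACGTACGT"] * 4)
        assert msa == ["ACGTACGT"] * 4

    def test_insertion_creates_gap_columns(self):
        msa = align_msa(["ACGTACGT", "ACGTTTACGT"])
        assert len(msa[0]) == len(msa[1]) == 10
        assert msa[0].count("-") == 2


class TestColumnConservation:
    def test_all_identical_fraction_one(self):
        cons = column_conservation(["ACGT"] * 10)
        assert cons.identical_fraction == 1.0

    def test_single_mutation_breaks_column(self):
        rows = ["ACGT"] * 9 + ["ACTT"]
        cons = column_conservation(rows)
        assert cons.identical == [True, True, False, True]

    def test_gap_majority_column_not_identical(self):
        rows = ["A-"] * 6 + ["AC"] * 4
        cons = column_conservation(rows)
        assert cons.identical == [True, False]

    def test_conserved_gene_more_identical_than_divergent(self, default_cohort):
        msas = {}
        for key in ("conserved", "divergent"):
            seqs = []
            for leaf, (contig, lt) in sorted(default_cohort["leaves"].items()):
                g = lt.genes[key].gene
                seqs.append(contig.residues[g.start:g.start + 2000])
            msas[key] = align_msa(seqs)
        f_con = column_conservation(msas["conserved"]).identical_fraction
        f_div = column_conservation(msas["divergent"]).identical_fraction
        assert f_con > f_div

    def test_empty_msa_rejected(self):
        with pytest.raises(SequenceError):
            column_conservation([])


class TestCovariation:
    def test_all_gc_score_one(self):
        res = covariation(["G" + "A" * 3 + "C"] * 6, [(0, 4)])
        p = res.pairs[0]
        assert p.score == 1.0 and p.n_compensatory == 0

    def test_gc_au_mix_compensatory(self):
        rows = ["G...C"] * 5 + ["A...T"] * 5
        rows = [r.replace(".", "A") for r in rows]
        res = covariation(rows, [(0, 4)])
        p = res.pairs[0]
        assert p.score == 1.0
        assert p.n_compensatory == 5
        assert p.n_canonical == 10

    def test_half_inconsistent_score_zero(self):
        rows = ["GAAAC"] * 5 + ["GAAAA"] * 5
        res = covariation(rows, [(0, 4)])
        p = res.pairs[0]
        assert p.score == pytest.approx(0.0)
        assert p.n_inconsistent == 5

    def test_gu_wobble_is_canonical(self):
        res = covariation(["GAAAT"] * 4, [(0, 4)])
        assert res.pairs[0].n_canonical == 4

    def test_row_permutation_invariance(self, rng):
        rows = ["GAAAC", "AAAAT", "GAAAA", "CAAAG"] * 3
        pairs = [(0, 4)]
        base = covariation(rows, pairs).pairs[0].score
        perm = list(rows)
        rng.shuffle(perm)
        assert covariation(perm, pairs).pairs[0].score == base

    def test_unbalanced_dotbracket_rejected(self):
        with pytest.raises(SequenceError):
            pairs_from_dotbracket("((.)")

    def test_planted_structure_pairs_are_complementary(self):
        pairs = pairs_from_dotbracket(TRNA_LIKE_STRUCTURE)
        res = covariation([TRNA_LIKE], pairs)
        assert all(p.n_canonical == 1 for p in res.pairs)

    def test_compensatory_constraint_raises_scores(self, rng):
        """A stem evolved under compensatory constraint scores higher than
        the same columns evolved independently."""
        stem5 = "GCGGCGGC"
        stem3 = "GCCGCCGC"  # reverse complement pairing
        pairs = [(i, 15 - i) for i in range(8)]
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            cons_rows, free_rows = [], []
            for _ in range(12):
                s5 = list(stem5)
                s3 = list(stem3)
                for i in range(8):
                    if r.random() < 0.3:  # substitute, compensating the partner
                        b = "ACGT"[r.integers(0, 4)]
                        s5[i] = b
                        s3[7 - i] = {"A": "T", "T": "A", "G": "C", "C": "G"}[b]
                cons_rows.append("".join(s5) + "".join(s3))
                f5 = [("ACGT"[r.integers(0, 4)] if r.random() < 0.3 else c)
                      for c in stem5]
                f3 = [("ACGT"[r.integers(0, 4)] if r.random() < 0.3 else c)
                      for c in stem3]
                free_rows.append("".join(f5) + "".join(f3))
            mean_c = covariation(cons_rows, pairs).mean_score
            mean_f = covariation(free_rows, pairs).mean_score
            wins += mean_c > mean_f
        assert wins >= 18
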