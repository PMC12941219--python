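"""ANI formula, matrices, archetype selection, length statistics."""

import itertools

import numpy as np
import pytest

from lncortho.ani import (AniMatrix, ani_matrix, ani_pair,
                          archetype_objective, brute_force_archetypes,
                          greedy_archetypes, length_stats, select_archetypes)
from lncortho.locate import GeneModel
from lncortho.seq import DnaSequence, GenomicInterval, SequenceError
from lncortho.simulate import PhyloTree

from conftest import random_dna


def _shared_block_pair(rng, block_len=500, len1=1000, len2=2000):
    """Two genes sharing one exact block; homopolymer flanks make chance
    extension at the block edges impossible."""
    block = random_dna(rng, block_len)
    g1 = DnaSequence("g1", "A" * 250 + block + "A" * (len1 - 250 - block_len))
    g2 = DnaSequence("g2", "C" * 700 + block + "C" * (len2 - 700 - block_len))
    return g1, g2


class TestAniPair:
    def test_worked_formula_case(self, rng):
        g1, g2 = _shared_block_pair(rng)
        r = ani_pair(g1, g2)
        # (500/1000 + 500/2000) / 2 * 100
        assert r.ani == pytest.approx(37.5, abs=1e-9)
        assert r.weighted_sum_g1 == pytest.approx(500.0)

    def test_identity_is_100(self, rng):
        g = DnaSequence("g", random_dna(rng, 3000))
        r = ani_pair(g, DnaSequence("h", g.residues))
        assert r.ani == 100.0

    def test_disjoint_is_zero(self, rng):
        r = ani_pair(DnaSequence("a", random_dna(rng, 1500)),
                     DnaSequence("b", random_dna(rng, 1500)))
        assert r.ani == 0.0

    def test_symmetry(self, rng):
        g1, g2 = _shared_block_pair(rng)
        a = ani_pair(g1, g2)
        b = ani_pair(g2, g1)
        assert a.ani == pytest.approx(b.ani, abs=1e-9)

    def test_non_increasing_in_min_hit_len(self, rng):
        g1, g2 = _shared_block_pair(rng, block_len=300)
        assert ani_pair(g1, g2, min_hit_len=100).ani >= \
            ani_pair(g1, g2, min_hit_len=299).ani >= \
            ani_pair(g1, g2, min_hit_len=400).ani

    def test_hits_must_be_strictly_longer_than_threshold(self, rng):
        g1, g2 = _shared_block_pair(rng, block_len=100)
        assert ani_pair(g1, g2, min_hit_len=100).ani == 0.0


class TestAniMatrix:
    def test_identical_genes_all_100(self, rng):
        s = random_dna(rng, 2000)
        genes = [DnaSequence(f"g{i}", s) for i in range(3)]
        m = ani_matrix(genes)
        assert np.allclose(m.values, 100.0)

    def test_symmetric_with_fixed_diagonal(self, rng):
        genes = [DnaSequence(f"g{i}", random_dna(rng, 1500)) for i in range(3)]
        block = random_dna(rng, 600)
        genes.append(DnaSequence("g3", genes[0].residues[:500] + block))
        m = ani_matrix(genes)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)

    def test_duplicate_ids_rejected(self, rng):
        g = DnaSequence("g", random_dna(rng, 1500))
        with pytest.raises(SequenceError):
            ani_matrix([g, g])

    def test_clade_structure_preserved(self, default_cohort):
        # within-clade ANI must exceed between-clade ANI on the default tree
        genes = []
        for leaf, (contig, lt) in sorted(default_cohort["leaves"].items()):
            g = lt.genes["divergent"].gene
            genes.append(contig.slice(g.start, g.end, leaf))
        m = ani_matrix(genes)
        clades = [("alpha", "beta"), ("gamma", "delta"), ("epsilon", "zeta")]
        within = np.mean([m[a, b] for a, b in clades])
        between = np.mean([m[a, b] for (a, _), (b, _) in
                           itertools.combinations(clades, 2)])
        assert within > between


class TestArchetypes:
    def _matrix(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        ids = ids or [f"g{i}" for i in range(len(values))]
        return AniMatrix(ids, values)

    def test_block_matrix_one_per_cluster(self):
        n = 9
        v = np.full((n, n), 10.0)
        for c in range(3):
            for i, j in itertools.product(range(3 * c, 3 * c + 3), repeat=2):
                v[i, j] = 95.0
        np.fill_diagonal(v, 100.0)
        m = self._matrix(v)
        chosen = select_archetypes(m, 3)
        clusters = {m.ids.index(x) // 3 for x in chosen}
        assert clusters == {0, 1, 2}
        # exhaustive check of the max-min objective over all 3-subsets
        _, opt = brute_force_archetypes(m, 3)
        assert archetype_objective(m, chosen) == pytest.approx(opt)

    def test_k_equals_n_returns_all(self):
        v = np.array([[100, 50, 30], [50, 100, 40], [30, 40, 100.0]])
        m = self._matrix(v)
        assert sorted(select_archetypes(m, 3)) == sorted(m.ids)

    def test_k_out_of_range(self):
        m = self._matrix(np.full((3, 3), 100.0))
        with pytest.raises(SequenceError):
            select_archetypes(m, 4)

    def test_selection_matches_exact_optimum_small_n(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, min(4, n) + 1))
            v = rng.uniform(0, 100, (n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 100.0)
            m = self._matrix(v)
            exact, opt = brute_force_archetypes(m, k)
            assert archetype_objective(m, select_archetypes(m, k)) == \
                pytest.approx(opt)

    def test_greedy_half_guarantee_on_metric_matrices(self, rng):
        # farthest-first traversal: >= 1/2 optimum when d is a metric
        for _ in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, min(4, n) + 1))
            pts = rng.uniform(0, 50, (n, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            v = 100.0 - d
            np.fill_diagonal(v, 100.0)
            m = self._matrix(v)
            greedy = greedy_archetypes(m, k)
            _, opt = brute_force_archetypes(m, k)
            assert archetype_objective(m, greedy) >= opt / 2 - 1e-9


class TestLengthStats:
    def _model(self, cid, length):
        iv = GenomicInterval(cid, 0, length)
        sub = GenomicInterval(cid, 0, 6)
        return GeneModel(iv, sub, sub, sub, cid, "+")

    def test_mean_and_sample_sd(self):
        models = [self._model(f"m{i}", ln) for i, ln in
                  enumerate((2010, 2020, 2030))]
        stats = length_stats(models, {f"m{i}": "t" for i in range(3)})
        mean, sd, n = stats.per_taxon["t"]
        assert mean == pytest.approx(2020.0)
        assert sd == pytest.approx(10.0)

    def test_sd_absent_for_singleton_taxon(self):
        models = [self._model("a", 2000), self._model("b", 3000)]
        stats = length_stats(models, {"a": "t1", "b": "t2"})
        assert stats.per_taxon["t1"][1] is None

    def test_null_lengths_uncorrelated_with_tree(self, rng):
        tree = PhyloTree("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        models = [self._model(lf, 2000 + int(rng.integers(0, 500)))
                  for lf in "abcd"]
        stats = length_stats(models, {lf: "t" for lf in "abcd"}, tree=tree,
                             reference_leaf="a", n_permutations=199, seed=0)
        assert stats.rho is not None and stats.rho_pvalue > 0.01

    def test_long_clade_has_largest_mean(self):
        # a marsupial-like clade generated 1.4x longer dominates the means
        models = [self._model(f"e{i}", 21_000 + i * 100) for i in range(3)]
        models += [self._model(f"m{i}", int(21_000 * 1.4) + i * 100)
                   for i in range(3)]
        taxonomy = {f"e{i}": "eutherian" for i in range(3)}
        taxonomy.update({f"m{i}": "marsupial" for i in range(3)})
        stats = length_stats(models, taxonomy)
        means = {t: v[0] for t, v in stats.per_taxon.items()}
        assert max(means, key=means.get) == "marsupial"
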