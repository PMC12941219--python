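"""Synthetic locus generator: construction, determinism, JC69 calibration,
truth liftover and serialization, TE turnover."""

import re

import numpy as np
import pytest

from lncortho.ani import ani_pair
from lncortho.seq import DnaSequence
from lncortho.simulate import (DEFAULT_TREE, EvolutionRates, GenerationError,
                               PhyloTree, SyntheticLocusSpec, SyntheticTruth,
                               build_root_locus, default_te_library,
                               evolve_along_tree, simulate_cohort)

from conftest import random_dna


class TestRootLocus:
    def test_layout_and_truth(self, default_cohort):
        spec, truth = default_cohort["spec"], default_cohort["truth"]
        root = default_cohort["root"]
        assert len(root) >= 21_000 + 7_000 + 36_755
        div = truth.genes["divergent"]
        assert div.gene.length == spec.geneA_length
        assert div.pas[0].start == div.gene.start + 3_500
        assert root.residues[div.pas[0].start:div.pas[0].end] == "AATAAA"
        assert root.residues[div.tata.start:div.tata.end] == "TATAAA"
        con = truth.genes["conserved"]
        assert con.gene.start - div.gene.end == spec.intergenic_distance

    def test_single_pas_in_guard_zone(self, default_cohort):
        truth = default_cohort["truth"]
        root = default_cohort["root"]
        div = truth.genes["divergent"]
        rel = div.pas[0].start - div.gene.start
        gene = root.residues[div.gene.start:div.gene.end]
        in_guard = [m.start() for m in re.finditer("(?=AATAAA)", gene)
                    if abs(m.start() - rel) <= 600]
        assert in_guard == [rel]

    def test_zero_feature_spec_gives_empty_truth(self):
        spec = SyntheticLocusSpec(n_te=0, n_inverted_repeat_pairs=0, n_g4=0)
        _, truth = build_root_locus(spec, 3)
        div = truth.genes["divergent"]
        assert div.tes == [] and div.ir_pairs == [] and div.g4s == []

    def test_byte_identical_determinism(self, default_cohort):
        root2, _ = build_root_locus(default_cohort["spec"], 1)
        assert root2.residues == default_cohort["root"].residues

    def test_marsupial_mode_plants_two_pas(self):
        spec = SyntheticLocusSpec(n_pas=2)
        root, truth = build_root_locus(spec, 5)
        pas = truth.genes["divergent"].pas
        assert len(pas) == 2
        assert pas[1].start - pas[0].start == spec.alt_pas_separation
        for p in pas:
            assert root.residues[p.start:p.end] == "AATAAA"

    def test_minus_strand_locus(self):
        spec = SyntheticLocusSpec(strand="-")
        root, truth = build_root_locus(spec, 2)
        div = truth.genes["divergent"]
        assert div.gene.strand == "-"
        from lncortho.seq import revcomp
        tata = root.residues[div.tata.start:div.tata.end]
        assert revcomp(tata) == "TATAAA"

    def test_infeasible_packing_raises(self):
        with pytest.raises(GenerationError):
            SyntheticLocusSpec(pas_offset=30_000)


class TestEvolution:
    def test_zero_rates_identity(self, default_cohort):
        leaves = evolve_along_tree(
            default_cohort["root"], default_cohort["truth"],
            default_cohort["tree"],
            EvolutionRates(subst_rate_scale=0.0, indel_rate=0.0), seed=1)
        for seq, _ in leaves.values():
            assert seq.residues == default_cohort["root"].residues

    def test_jc69_closed_form(self):
        d = 0.2
        L = 21_000
        rng = np.random.default_rng(5)
        root = DnaSequence("bare", random_dna(rng, L))
        truth = SyntheticTruth.empty("bare", L)
        tree = PhyloTree(f"(a:{d / 2},b:{d / 2});")
        leaves = evolve_along_tree(root, truth, tree,
                                   EvolutionRates(indel_rate=0.0), seed=3)
        sa = leaves["a"][0].residues
        sb = leaves["b"][0].residues
        obs = np.mean([x == y for x, y in zip(sa, sb)])
        exp = 0.25 + 0.75 * np.exp(-4 * d / 3)
        sd = np.sqrt(exp * (1 - exp) / L)
        assert abs(obs - exp) <= 3 * sd

    def test_truth_liftover_tracks_features(self, default_cohort):
        # extracting a lifted interval must recover the descendant of the
        # planted feature: the TE there still aligns to its consensus far
        # above background
        from lncortho.align import global_identity

        lib = {t.id: t for t in default_te_library()}
        seq, truth = default_cohort["leaves"]["epsilon"]
        div = truth.genes["divergent"]
        for te in div.tes[:3]:
            region = seq.residues[te.iv.start:te.iv.end]
            cons = lib[te.name.split(".")[0]]
            pid, _, _ = global_identity(cons.residues, region)
            assert pid > 60.0  # background global identity is ~40%

    def test_truth_round_trip_serialization(self, default_cohort, tmp_path):
        _, truth = default_cohort["leaves"]["alpha"]
        p = tmp_path / "truth.json"
        truth.save(p)
        assert SyntheticTruth.load(p).to_json() == truth.to_json()

    def test_rate_monotonic_ani_decrease(self):
        from lncortho.simulate import GuTractSpec

        spec = SyntheticLocusSpec(geneA_length=6_000, geneB_length=2_000,
                                  intergenic_distance=2_000, n_te=0,
                                  n_inverted_repeat_pairs=0, n_g4=0,
                                  gu_tract_spec=GuTractSpec(n_tracts=2,
                                                            n_core=5))
        tree = PhyloTree("(a:0.05,b:0.05);")
        anis = []
        for scale in (0.5, 1.0, 2.0):
            root, truth, leaves = simulate_cohort(
                spec, tree, EvolutionRates(subst_rate_scale=scale,
                                           indel_rate=0.0), seed=11)
            anis.append(ani_pair(leaves["a"][0], leaves["b"][0]).ani)
        assert anis[0] > anis[1] > anis[2]

    def test_forced_excision_updates_truth(self, default_cohort):
        truth = default_cohort["truth"]
        te_name = truth.genes["divergent"].tes[0].name
        rates = EvolutionRates(forced_excisions=(("alpha", te_name),))
        leaves = evolve_along_tree(default_cohort["root"], truth,
                                   default_cohort["tree"], rates, seed=1)
        assert te_name not in {t.name for t in
                               leaves["alpha"][1].genes["divergent"].tes}
        for other in ("beta", "gamma"):
            assert te_name in {t.name for t in
                               leaves[other][1].genes["divergent"].tes}

    def test_missing_excision_target_is_skipped(self, default_cohort, caplog):
        rates = EvolutionRates(forced_excisions=(("alpha", "NO_SUCH_TE"),))
        leaves = evolve_along_tree(default_cohort["root"],
                                   default_cohort["truth"],
                                   default_cohort["tree"], rates, seed=1)
        assert "alpha" in leaves  # skipped, not raised
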