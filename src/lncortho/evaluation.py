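"""Recovery studies: how well the analyses reconstruct planted truth.

Each study simulates cohorts under the default study conditions (or caller
overrides), runs the corresponding analysis, and scores it against the
recorded ground truth. These drive the acceptance checks and the analysis
scripts; they are ordinary library code so tests can run them at reduced
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ani import ani_pair
from .locate import AnchorSet, GeneModel, NoCallError, gene_sequence, locate_gene
from .motifs import hexamer_profile, shared_motifs
from .pas import ProjectionError, call_main_pas, find_alternative_pas, \
    project_reference_pas
from .seq import DnaSequence, GenomicInterval
from .selfcomp import find_self_complementary
from .simulate import (CORE_HEXAMERS, DEFAULT_TREE, EvolutionRates, GU_HEXAMERS,
                       PhyloTree, SyntheticLocusSpec, SyntheticTruth,
                       default_te_library, evolve_along_tree, simulate_cohort)
from .te import annotate_tes

PLANTED_HEXAMERS = tuple(GU_HEXAMERS) + tuple(CORE_HEXAMERS)
POSITION_TOLERANCE = 50  # bp tolerance when matching a recovered feature to truth


@dataclass
class CohortRecovery:
    seed: int
    n_leaves: int = 0
    boundaries_total: int = 0
    boundaries_within_tol: int = 0
    boundary_errors: List[int] = field(default_factory=list)
    te_planted: int = 0
    te_recovered: int = 0
    te_false_positives: int = 0        # on the feature-free control
    ir_planted: int = 0
    ir_recovered: int = 0
    ir_false_positives: int = 0
    pas_planted: int = 0
    pas_recovered: int = 0
    pas_false_positives: int = 0
    alt_pas_exact: bool = True
    te_profile: List[int] = field(default_factory=lambda: [0] * 20)
    shared_top4: List[str] = field(default_factory=list)


def _control_gene(seed: int, length: int = 21_000) -> DnaSequence:
    """Feature-free control: a random sequence with the background
    composition but no planted features."""
    from .simulate import DEFAULT_BACKGROUND, _rand_seq

    rng = np.random.default_rng([seed, 404])
    return DnaSequence(f"control_{seed}", _rand_seq(rng, length, DEFAULT_BACKGROUND))


def run_cohort_recovery(seed: int, spec: Optional[SyntheticLocusSpec] = None,
                        tree: Optional[PhyloTree] = None,
                        rates: Optional[EvolutionRates] = None,
                        boundary_tol: int = 20) -> CohortRecovery:
    """Simulate one cohort, run locate/pas/te/selfcomp/motifs, score vs truth."""
    spec = spec or SyntheticLocusSpec()
    tree = tree or PhyloTree(DEFAULT_TREE)
    rates = rates or EvolutionRates()
    root, truth, leaves = simulate_cohort(spec, tree, rates, seed)
    anchors = AnchorSet.from_truth(root, truth, "divergent")
    ref_truth = truth.genes["divergent"]
    reference = root.slice(ref_truth.gene.start, ref_truth.gene.end, "ref")
    ref_pas = ref_truth.pas[0].start - ref_truth.gene.start
    library = default_te_library()

    r = CohortRecovery(seed=seed, n_leaves=len(leaves))
    profiles = []
    for leaf, (contig, ltruth) in sorted(leaves.items()):
        g = ltruth.genes["divergent"]
        win = GenomicInterval(contig.id, 0, len(contig))
        try:
            model = locate_gene(contig, win, anchors)
        except NoCallError:
            r.boundaries_total += 2
            continue
        r.boundaries_total += 2
        e5 = abs(model.gene_iv.start - g.gene.start)
        e3 = abs(model.gene_iv.end - g.gene.end)
        r.boundary_errors += [e5, e3]
        r.boundaries_within_tol += (e5 <= boundary_tol) + (e3 <= boundary_tol)

        gene = gene_sequence(contig, model)
        g0 = model.gene_iv.start

        # --- TEs ----------------------------------------------------------
        anns = annotate_tes(gene, library)
        r.te_planted += len(g.tes)
        for te in g.tes:
            rel_lo, rel_hi = te.iv.start - g0, te.iv.end - g0
            for a in anns:
                overlap = min(a.gene_iv.end, rel_hi) - max(a.gene_iv.start, rel_lo)
                if (a.te_name == te.name.split(".")[0].split("@")[0]
                        and overlap >= 0.5 * (rel_hi - rel_lo)):
                    r.te_recovered += 1
                    break
        for a in anns:
            mid = g0 + a.gene_iv.midpoint
            frac = (mid - g.gene.start) / g.gene.length
            r.te_profile[min(19, int(frac * 20))] += 1

        # --- inverted repeats --------------------------------------------
        regions = find_self_complementary(gene)
        r.ir_planted += len(g.ir_pairs)
        for a_iv, b_iv in g.ir_pairs:
            ra, rb = a_iv.start - g0, b_iv.start - g0
            matches = [x for x in regions
                       if abs(x.iv_a.start - ra) <= POSITION_TOLERANCE
                       and abs(x.iv_b.start - rb) <= POSITION_TOLERANCE]
            if len(matches) == 1:
                r.ir_recovered += 1

        # --- PAS ----------------------------------------------------------
        r.pas_planted += 1
        try:
            projected = project_reference_pas(gene, reference, ref_pas)
            call = call_main_pas(gene, projected)
        except ProjectionError:
            call = None
        truth_pas = g.pas[0].start - g0
        if call is not None and call.position == truth_pas:
            r.pas_recovered += 1
            alts = find_alternative_pas(gene, call)
            # exactness vs an independent brute-force window scan (mutation
            # can legitimately create new motifs; the scanner must report
            # exactly what the window contains)
            res = gene.residues
            lo = max(0, call.position - 600)
            hi = min(len(res) - 5, call.position + 601)
            brute = [i for i in range(lo, hi)
                     if res[i:i + 6] == "AATAAA" and i != call.position]
            if sorted(a.position for a in alts) != brute:
                r.alt_pas_exact = False

        profiles.append(hexamer_profile(gene, PLANTED_HEXAMERS))

    # --- feature-free control gene ---------------------------------------
    control = _control_gene(seed)
    r.te_false_positives = len(annotate_tes(control, library))
    r.ir_false_positives = len(find_self_complementary(control))
    try:
        proj = project_reference_pas(control, reference, ref_pas)
        if call_main_pas(control, proj) is not None:
            r.pas_false_positives += 1
    except ProjectionError:
        pass  # expected: no homology, distinct from a false call

    if len(profiles) >= 2:
        r.shared_top4 = [k for k, _, _ in shared_motifs(profiles)[:4]]
    return r


@dataclass
class RecoveryStudy:
    cohorts: List[CohortRecovery]

    @property
    def boundary_fraction(self) -> float:
        tot = sum(c.boundaries_total for c in self.cohorts)
        return sum(c.boundaries_within_tol for c in self.cohorts) / tot if tot else 0.0

    @property
    def te_recall(self) -> float:
        tot = sum(c.te_planted for c in self.cohorts)
        return sum(c.te_recovered for c in self.cohorts) / tot if tot else 0.0

    @property
    def ir_recall(self) -> float:
        tot = sum(c.ir_planted for c in self.cohorts)
        return sum(c.ir_recovered for c in self.cohorts) / tot if tot else 0.0

    @property
    def pas_recall(self) -> float:
        tot = sum(c.pas_planted for c in self.cohorts)
        return sum(c.pas_recovered for c in self.cohorts) / tot if tot else 0.0

    @property
    def total_false_positives(self) -> int:
        return sum(c.te_false_positives + c.ir_false_positives
                   + c.pas_false_positives for c in self.cohorts)

    @property
    def shared_motif_fraction(self) -> float:
        """Fraction of cohorts whose top-4 shared hexamers are exactly the
        planted set."""
        n = sum(1 for c in self.cohorts
                if set(c.shared_top4) == set(PLANTED_HEXAMERS))
        return n / len(self.cohorts) if self.cohorts else 0.0

    def summed_profile(self) -> List[int]:
        out = [0] * 20
        for c in self.cohorts:
            out = [a + b for a, b in zip(out, c.te_profile)]
        return out

    def profile_peaks_in_planted_bins(self,
                                      bins=((0.30, 0.40), (0.70, 0.80))) -> bool:
        prof = self.summed_profile()
        order = sorted(range(20), key=lambda i: -prof[i])
        top = order[:2]
        ok = []
        for idx in top:
            lo, hi = idx / 20, (idx + 1) / 20
            ok.append(any(b_lo <= lo and hi <= b_hi + 1e-9 for b_lo, b_hi in bins))
        return all(ok)


def run_recovery_study(n_seeds: int, base_seed: int = 1, **kwargs) -> RecoveryStudy:
    seeds = [(base_seed * 1_000 + i) % (2 ** 31) for i in range(n_seeds)]
    return RecoveryStudy([run_cohort_recovery(s, **kwargs) for s in seeds])


# ---------------------------------------------------------------------------
# closed-form divergence checks
# ---------------------------------------------------------------------------

def jc69_expected_identity(d: float) -> float:
    """P(same base) for two sequences at total path length d under JC69."""
    return 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)


@dataclass
class DivergencePoint:
    d: float
    observed_identity: float
    expected_identity: float
    mean_ani: float
    n_replicates: int
    length: int


def jc_divergence_study(distances: Sequence[float], n_replicates: int = 5,
                        length: int = 21_000, seed: int = 1,
                        with_ani: bool = True) -> List[DivergencePoint]:
    """Evolve featureless sequence pairs at each distance; compare observed
    identity (and ANI) with the JC69 closed form."""
    from .simulate import DEFAULT_BACKGROUND, _rand_seq

    out = []
    for d in distances:
        idents, anis = [], []
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, int(d * 1000), rep])
            bare = DnaSequence("bare", _rand_seq(rng, length, DEFAULT_BACKGROUND))
            truth = SyntheticTruth.empty("bare", length)
            tree = PhyloTree(f"(a:{d / 2},b:{d / 2});")
            leaves = evolve_along_tree(bare, truth, tree,
                                       EvolutionRates(indel_rate=0.0),
                                       int(rng.integers(2 ** 31)))
            sa = leaves["a"][0].residues
            sb = leaves["b"][0].residues
            idents.append(np.mean([x == y for x, y in zip(sa, sb)]))
            if with_ani:
                anis.append(ani_pair(leaves["a"][0], leaves["b"][0]).ani)
        out.append(DivergencePoint(
            d=d, observed_identity=float(np.mean(idents)),
            expected_identity=float(jc69_expected_identity(d)),
            mean_ani=float(np.mean(anis)) if anis else float("nan"),
            n_replicates=n_replicates, length=length))
    return out
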