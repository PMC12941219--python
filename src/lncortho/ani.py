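"""Average nucleotide identity, all-vs-all matrices, archetypes, lengths.

ANI between two genes sums the identity-weighted lengths
(pident/100 x aln_length) of every local hit longer than ``min_hit_len``
over both genes, normalizes each sum by its gene length, and averages the
two coverages:

    ANI = ( sum(w)/len_g1 + sum(w)/len_g2 ) / 2 x 100

The formula is applied literally: overlapping hits are all summed, which can
push repeat-rich pairs above 100; the value is then clamped at 100 and
flagged. An optional mode merges query-side overlaps before summing.
Archetypes are a maximally mutually dissimilar subset chosen by the
farthest-first traversal on d = 100 - ANI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .align import AlignParams, local_align
from .locate import GeneModel
from .seq import DnaSequence, SequenceError
from .simulate import PhyloTree

MIN_HIT_LEN = 100  # hits must be strictly longer than this


@dataclass
class AniResult:
    gene1_id: str
    gene2_id: str
    weighted_sum_g1: float
    weighted_sum_g2: float
    length_g1: int
    length_g2: int
    ani: float
    clamped: bool = False


@dataclass
class AniMatrix:
    ids: List[str]
    values: np.ndarray  # symmetric, diagonal 100

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])


def _merge_intervals(spans: List[Tuple[int, int, float]]) -> float:
    """Merge query-side overlaps, keeping the identity-weighted coverage of
    the union (max pident wins inside overlaps, approximated by sweeping)."""
    if not spans:
        return 0.0
    spans = sorted(spans)
    total = 0.0
    cur_s, cur_e, cur_w = spans[0]
    for s, e, w in spans[1:]:
        if s >= cur_e:
            total += (cur_e - cur_s) * cur_w
            cur_s, cur_e, cur_w = s, e, w
        else:
            cur_w = max(cur_w, w)
            cur_e = max(cur_e, e)
    total += (cur_e - cur_s) * cur_w
    return total


def ani_pair(g1: DnaSequence, g2: DnaSequence, min_hit_len: int = MIN_HIT_LEN,
             params: Optional[AlignParams] = None,
             merge_overlaps: bool = False) -> AniResult:
    """ANI between two genes from local hits strictly longer than min_hit_len."""
    p = params or AlignParams()
    hsps = [h for h in local_align(g1, g2, p) if h.aln_length > min_hit_len]
    if merge_overlaps:
        w1 = _merge_intervals([(h.query_iv.start, h.query_iv.end, h.pident / 100.0)
                               for h in hsps])
        w2 = _merge_intervals([(h.subject_iv.start, h.subject_iv.end, h.pident / 100.0)
                               for h in hsps])
    else:
        w1 = w2 = sum(h.weighted_length for h in hsps)
    raw = (w1 / len(g1) + w2 / len(g2)) / 2.0 * 100.0
    return AniResult(g1.id, g2.id, w1, w2, len(g1), len(g2),
                     min(100.0, raw), clamped=raw > 100.0)


def ani_matrix(genes: Sequence[DnaSequence], min_hit_len: int = MIN_HIT_LEN,
               params: Optional[AlignParams] = None,
               order: Optional[Sequence[str]] = None) -> AniMatrix:
    """All-vs-all symmetric ANI matrix with a fixed diagonal of 100."""
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate gene ids")
    if len(genes) < 2:
        raise SequenceError("need at least two genes")
    n = len(genes)
    m = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        val = ani_pair(genes[i], genes[j], min_hit_len, params).ani
        m[i, j] = m[j, i] = val
    if order is not None:
        perm = [ids.index(x) for x in order]
        m = m[np.ix_(perm, perm)]
        ids = list(order)
    return AniMatrix(ids, m)


EXACT_SEARCH_LIMIT = 200_000  # max subsets enumerated by the exact search


def select_archetypes(m: AniMatrix, k: int) -> List[str]:
    """Select k maximally mutually dissimilar genes (max-min on d = 100 - ANI).

    When the subset space C(n, k) is small enough the exact optimum is
    returned (lexicographically smallest among ties); otherwise the
    farthest-first traversal refined by deterministic 1-swap local search is
    used. The farthest-first heuristic alone carries only a 1/2-factor
    guarantee on metric dissimilarities and can miss the optimum, so the
    exact route is preferred wherever it is affordable.
    """
    n = len(m.ids)
    if not (2 <= k <= n):
        raise SequenceError(f"k={k} outside [2, {n}]")
    if math.comb(n, k) <= EXACT_SEARCH_LIMIT:
        subset, _ = brute_force_archetypes(m, k)
        return subset
    chosen = greedy_archetypes(m, k)
    return _local_search(m, chosen)


def _local_search(m: AniMatrix, subset: List[str]) -> List[str]:
    """Deterministic 1-swap hill climbing on the max-min objective."""
    current = sorted(subset)
    improved = True
    while improved:
        improved = False
        obj = archetype_objective(m, current)
        for out_id in list(current):
            for in_id in sorted(set(m.ids) - set(current)):
                cand = sorted(set(current) - {out_id} | {in_id})
                if archetype_objective(m, cand) > obj + 1e-12:
                    current, improved = cand, True
                    break
            if improved:
                break
    return current


def greedy_archetypes(m: AniMatrix, k: int) -> List[str]:
    """Farthest-first traversal on dissimilarity d = 100 - ANI.

    Starts from the most dissimilar pair (ties by lexicographic id order) and
    repeatedly adds the gene maximizing its minimum dissimilarity to the
    selected set. Deterministic; guarantees >= 1/2 of the optimal max-min
    objective on metric dissimilarities.
    """
    n = len(m.ids)
    if not (2 <= k <= n):
        raise SequenceError(f"k={k} outside [2, {n}]")
    d = 100.0 - m.values
    order = np.argsort(m.ids)  # lexicographic tie-break helper
    best_pair = None
    best_d = -1.0
    for a, b in itertools.combinations(sorted(range(n), key=lambda i: m.ids[i]), 2):
        if d[a, b] > best_d + 1e-12:
            best_d = d[a, b]
            best_pair = (a, b)
    chosen = list(best_pair)
    while len(chosen) < k:
        rest = [i for i in sorted(range(n), key=lambda i: m.ids[i]) if i not in chosen]
        gains = [(min(d[i, j] for j in chosen), i) for i in rest]
        best_gain = max(g for g, _ in gains)
        pick = next(i for g, i in gains if g >= best_gain - 1e-12)
        chosen.append(pick)
    return [m.ids[i] for i in sorted(chosen)]


def archetype_objective(m: AniMatrix, subset: Sequence[str]) -> float:
    """Minimum pairwise dissimilarity of a subset (the max-min objective)."""
    d = 100.0 - m.values
    idx = [m.ids.index(s) for s in subset]
    return min(d[a, b] for a, b in itertools.combinations(idx, 2))


def brute_force_archetypes(m: AniMatrix, k: int) -> Tuple[List[str], float]:
    """Exhaustive max-min subset; lexicographically smallest among ties."""
    best: Tuple[float, Tuple[str, ...]] = (-1.0, ())
    for subset in itertools.combinations(sorted(m.ids), k):
        obj = archetype_objective(m, subset)
        if obj > best[0] + 1e-12:
            best = (obj, subset)
    return list(best[1]), best[0]


# ---------------------------------------------------------------------------
# gene length statistics
# ---------------------------------------------------------------------------

@dataclass
class LengthStats:
    per_taxon: Dict[str, Tuple[float, Optional[float], int]]  # mean, sd (None if n<2), n
    overall_mean: float
    overall_sd: Optional[float]
    rho: Optional[float]
    rho_pvalue: Optional[float]


def length_stats(models: Sequence[GeneModel], taxonomy: Dict[str, str],
                 tree: Optional[PhyloTree] = None,
                 reference_leaf: Optional[str] = None,
                 leaf_of_model: Optional[Dict[str, str]] = None,
                 n_permutations: int = 999, seed: int = 0) -> LengthStats:
    """Mean +- sd of gene length per taxon, and the rank correlation of
    length with patristic distance from a reference leaf (permutation p)."""
    lengths = np.array([m.length for m in models], dtype=float)
    ids = [m.contig_id for m in models]
    per_taxon: Dict[str, Tuple[float, Optional[float], int]] = {}
    for taxon in sorted(set(taxonomy.get(i, "unknown") for i in ids)):
        vals = np.array([ln for i, ln in zip(ids, lengths)
                         if taxonomy.get(i, "unknown") == taxon])
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
        per_taxon[taxon] = (float(vals.mean()), sd, len(vals))
    overall_sd = float(np.std(lengths, ddof=1)) if len(lengths) >= 2 else None

    rho = pval = None
    if tree is not None and reference_leaf is not None:
        lom = leaf_of_model or {i: i for i in ids}
        dists = np.array([tree.patristic_distance(lom[i], reference_leaf)
                          for i in ids])
        rho = float(stats.spearmanr(lengths, dists).statistic)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(lengths)
            r = stats.spearmanr(perm, dists).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        pval = (count + 1) / (n_permutations + 1)
    return LengthStats(per_taxon, float(lengths.mean()), overall_sd, rho, pval)
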