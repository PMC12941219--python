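"""Synthetic syntenic two-gene loci with planted, fully recorded features.

The generator emulates the statistical structure of a NEAT1/MALAT1-like
locus: one long, fast-evolving gene and one shorter, conserved gene ~36 kb
apart on one strand of a contig, with a TATA-box at each 5' end, a single
polyadenylation signal ~3.5 kb into the long gene, a triple-helix/tRNA-like
element block at each 3' end, transposable elements concentrated in the
30-40% and 70-80% fractional-length bins, inverted-repeat pairs,
G-quadruplexes, GU-rich tracts and core hexamer cassettes. Divergence is
simulated with Jukes-Cantor point substitutions plus geometric-length indels
along a user-supplied newick tree; features reported as invariant in real
orthologs (TATA-box, PAS hexamer, triple-helix motif) are excluded from
mutation, and other planted features evolve under a purifying-selection
rate factor. Every planted coordinate is lifted over through every edit, so
each leaf carries an exact recovery oracle.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .gffio import write_gff3
from .seq import DnaSequence, GenomicInterval, SequenceError, revcomp

# ---------------------------------------------------------------------------
# fixed synthetic element sequences (not taken from any real genome)
# ---------------------------------------------------------------------------

TATA_BOX = "TATAAA"
PAS_MOTIF = "AATAAA"

#: synthetic U/T-rich triple-helix-forming motifs (5' and 3' arms of the
#: element); chosen to be AATAAA-free and distinctive enough to anchor on
HELIX_MOTIF_A = "TTTTGCTTTTTATTTTGGTTTT"
HELIX_MOTIF_B = "AGTTGCATGAAGGATT"

#: synthetic tRNA-like element: two stems with loops and a CCA-like tail;
#: the dot-bracket below records the planted base pairing (hairpin III is the
#: second stem)
TRNA_LIKE = "GCGGATGCTTCGAATGCATCCGCACTAGGGCTCACTTCGGTGAGCCACCA"
TRNA_LIKE_STRUCTURE = "((((((((.......)))))))).....((((((......))))))...."

#: synthetic high-information TF binding site planted in every promoter
TF_SITE = "GCCACGTGAC"

GU_HEXAMERS = ("GTGTGT", "TGTGTG")        # TDP-43-like GU-repeat hexamers (DNA space)
CORE_HEXAMERS = ("TCTGTG", "CTGTGT")      # core-region hexamers
CORE_CASSETTE = "TCTGTGT"                 # one cassette carries both core hexamers

#: purifying-selection substitution-rate factors for planted features
PURIFYING_FACTOR = 0.2
PROMOTER_FACTOR = 0.3
DEFAULT_BACKGROUND = {"A": 0.27, "C": 0.18, "G": 0.22, "T": 0.33}  # T-rich, C-poor

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(ValueError):
    """Raised when the requested features cannot be packed into the locus."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GuTractSpec:
    """GU-repeat tracts plus central core-hexamer cassettes."""

    n_tracts: int = 8
    tract_len: int = 24
    tract_zone: Tuple[float, float] = (0.84, 0.90)   # 3'-biased
    n_core: int = 30
    core_zone: Tuple[float, float] = (0.45, 0.55)    # central


@dataclass
class EndMotifs:
    tata: str = TATA_BOX
    helix_a: str = HELIX_MOTIF_A
    helix_b: str = HELIX_MOTIF_B
    hairpin_len: int = 29
    linker_len: int = 30
    trna_like: str = TRNA_LIKE


@dataclass
class SyntheticLocusSpec:
    """Layout of the planted two-gene locus (lengths in bp, zones as
    fractions of the divergent gene length)."""

    geneA_length: int = 21_000            # divergent gene
    geneB_length: int = 7_000             # conserved gene
    intergenic_distance: int = 36_755
    strand: str = "+"
    margin: int = 2_000
    contig_length: Optional[int] = None   # derived when None
    pas_offset: int = 3_500               # from divergent-gene start
    n_pas: int = 1                        # 2 = marsupial-like two-PAS mode
    alt_pas_separation: int = 500
    te_bins: Tuple[Tuple[float, float], ...] = ((0.30, 0.40), (0.70, 0.80))
    n_te: int = 6
    n_inverted_repeat_pairs: int = 2
    ir_arm_len: int = 150
    ir_separations: Tuple[int, ...] = (600, 4_500)   # proximal, distal
    n_g4: int = 4
    gu_tract_spec: GuTractSpec = field(default_factory=GuTractSpec)
    end_motifs: EndMotifs = field(default_factory=EndMotifs)
    background: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    plant_tf_site: bool = True

    def __post_init__(self) -> None:
        if self.pas_offset >= self.geneA_length:
            raise GenerationError("pas_offset must fall inside the divergent gene")
        for lo, hi in self.te_bins:
            if not (0.0 <= lo < hi <= 1.0):
                raise GenerationError(f"te bin ({lo}, {hi}) outside [0, 1]")
        if self.margin < 1_000:
            raise GenerationError("margin must be >= 1000 bp to hold the promoter")
        needed = (self.margin + self.geneA_length + self.intergenic_distance
                  + self.geneB_length + len(self.end_motifs.trna_like) + self.margin)
        if self.contig_length is None:
            self.contig_length = needed
        elif self.contig_length < needed:
            raise GenerationError(
                f"contig_length {self.contig_length} cannot hold the locus ({needed} bp)")


@dataclass
class EvolutionRates:
    subst_rate_scale: float = 1.0
    indel_rate: float = 0.01              # expected indels / site / unit branch length
    indel_len_geom_p: float = 1 / 3       # geometric length, mean 3
    te_insert_rate: float = 0.0           # expected insertions / unit branch length
    te_excise_rate: float = 0.0           # per present TE / unit branch length
    conserved_gene_factor: float = 0.3    # conserved gene evolves at this x rate
    forced_excisions: Tuple[Tuple[str, str], ...] = ()  # (leaf_name, te_name)

    def __post_init__(self) -> None:
        for name in ("subst_rate_scale", "indel_rate", "te_insert_rate", "te_excise_rate"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTe:
    name: str
    te_class: str
    iv: GenomicInterval


@dataclass
class GeneTruth:
    """Planted coordinates for one gene, in contig-forward coordinates."""

    gene: GenomicInterval
    tata: GenomicInterval
    promoter: GenomicInterval
    helix_a: GenomicInterval
    hairpin: GenomicInterval
    linker: GenomicInterval
    helix_b: GenomicInterval
    trna_like: GenomicInterval
    pas: List[GenomicInterval] = field(default_factory=list)
    tes: List[TruthTe] = field(default_factory=list)
    ir_pairs: List[Tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
    g4s: List[GenomicInterval] = field(default_factory=list)
    gu_tracts: List[GenomicInterval] = field(default_factory=list)
    core_motifs: List[GenomicInterval] = field(default_factory=list)
    tf_sites: List[GenomicInterval] = field(default_factory=list)

    def intervals(self) -> List[GenomicInterval]:
        out = [self.gene, self.tata, self.promoter, self.helix_a, self.hairpin,
               self.linker, self.helix_b, self.trna_like]
        out += self.pas
        out += [t.iv for t in self.tes]
        for a, b in self.ir_pairs:
            out += [a, b]
        out += self.g4s + self.gu_tracts + self.core_motifs + self.tf_sites
        return out

    def transform(self, fn) -> "GeneTruth":
        """Apply a coordinate mapping (start, end) -> (start, end) | None to
        every planted interval; destroyed features are dropped (the gene
        itself must survive)."""

        def m(iv: GenomicInterval) -> Optional[GenomicInterval]:
            r = fn(iv.start, iv.end)
            if r is None:
                return None
            s, e = r
            if e - s <= 0:
                return None
            return GenomicInterval(iv.seq_id, s, e, iv.strand)

        def m_req(iv: GenomicInterval) -> GenomicInterval:
            out = m(iv)
            if out is None:
                raise GenerationError(f"structural feature destroyed by an edit: {iv}")
            return out

        pairs = []
        for a, b in self.ir_pairs:
            na, nb = m(a), m(b)
            if na is not None and nb is not None:
                pairs.append((na, nb))
        return GeneTruth(
            gene=m_req(self.gene), tata=m_req(self.tata), promoter=m_req(self.promoter),
            helix_a=m_req(self.helix_a), hairpin=m_req(self.hairpin),
            linker=m_req(self.linker), helix_b=m_req(self.helix_b),
            trna_like=m_req(self.trna_like),
            pas=[p for p in (m(x) for x in self.pas) if p is not None],
            tes=[TruthTe(t.name, t.te_class, niv)
                 for t in self.tes if (niv := m(t.iv)) is not None],
            ir_pairs=pairs,
            g4s=[x for x in (m(g) for g in self.g4s) if x is not None],
            gu_tracts=[x for x in (m(g) for g in self.gu_tracts) if x is not None],
            core_motifs=[x for x in (m(g) for g in self.core_motifs) if x is not None],
            tf_sites=[x for x in (m(g) for g in self.tf_sites) if x is not None],
        )


@dataclass
class SyntheticTruth:
    """Recovery oracle: all planted coordinates, rates and the RNG seed."""

    contig_id: str
    contig_length: int
    strand: str
    seed: int
    genes: Dict[str, GeneTruth] = field(default_factory=dict)  # 'divergent', 'conserved'
    rates: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def empty(cls, contig_id: str, contig_length: int, seed: int = 0) -> "SyntheticTruth":
        return cls(contig_id, contig_length, "+", seed)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)

        def iv(d) -> GenomicInterval:
            return GenomicInterval(d["seq_id"], d["start"], d["end"], d["strand"])

        genes = {}
        for key, g in raw["genes"].items():
            genes[key] = GeneTruth(
                gene=iv(g["gene"]), tata=iv(g["tata"]), promoter=iv(g["promoter"]),
                helix_a=iv(g["helix_a"]), hairpin=iv(g["hairpin"]),
                linker=iv(g["linker"]), helix_b=iv(g["helix_b"]),
                trna_like=iv(g["trna_like"]),
                pas=[iv(x) for x in g["pas"]],
                tes=[TruthTe(t["name"], t["te_class"], iv(t["iv"])) for t in g["tes"]],
                ir_pairs=[(iv(a), iv(b)) for a, b in g["ir_pairs"]],
                g4s=[iv(x) for x in g["g4s"]],
                gu_tracts=[iv(x) for x in g["gu_tracts"]],
                core_motifs=[iv(x) for x in g["core_motifs"]],
                tf_sites=[iv(x) for x in g["tf_sites"]],
            )
        return cls(raw["contig_id"], raw["contig_length"], raw["strand"],
                   raw["seed"], genes, raw["rates"])

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        return cls.from_json(Path(path).read_text())

    def to_gff(self, path) -> None:
        feats = []
        for key, g in self.genes.items():
            feats.append((g.gene, "gene", f"ID={key}"))
            feats.append((g.tata, "TATA_box", f"Parent={key}"))
            for i, p in enumerate(g.pas):
                feats.append((p, "polyA_signal", f"Parent={key};rank={i}"))
            feats.append((g.helix_a, "triple_helix", f"Parent={key};part=motif_a"))
            feats.append((g.helix_b, "triple_helix", f"Parent={key};part=motif_b"))
            feats.append((g.trna_like, "tRNA_like", f"Parent={key}"))
            for t in g.tes:
                feats.append((t.iv, "repeat_region", f"Parent={key};Name={t.name};class={t.te_class}"))
            for i, (a, b) in enumerate(g.ir_pairs):
                feats.append((a, "inverted_repeat", f"Parent={key};pair={i};arm=a"))
                feats.append((b, "inverted_repeat", f"Parent={key};pair={i};arm=b"))
            for q in g.g4s:
                feats.append((q, "G_quadruplex", f"Parent={key}"))
        write_gff3(feats, path)


# ---------------------------------------------------------------------------
# TE library
# ---------------------------------------------------------------------------

_TE_LIBRARY_SEED = 202_207  # fixed: the library is shared by all cohorts

_TE_DEFS = (
    ("SINE_synth1", "SINE", 300),
    ("SINE_synth2", "SINE", 280),
    ("LINE_synth1", "LINE", 600),
    ("LTR_synth1", "LTR", 450),
    ("DNA_synth1", "DNA", 350),
)


def default_te_library() -> List[DnaSequence]:
    """Synthetic TE consensus library (fixed, AATAAA-free), DFAM-style
    '#class' tags in the description."""
    rng = np.random.default_rng(_TE_LIBRARY_SEED)
    lib = []
    for name, cls, length in _TE_DEFS:
        while True:
            res = "".join(rng.choice(list("ACGT"), size=length))
            if PAS_MOTIF not in res and PAS_MOTIF not in revcomp(res):
                break
        lib.append(DnaSequence(name, res, {"class": cls, "description": f"#{cls}"}))
    return lib


# ---------------------------------------------------------------------------
# root locus construction
# ---------------------------------------------------------------------------

class _Placer:
    """Tracks occupied intervals; places features without overlap."""

    def __init__(self) -> None:
        self.occupied: List[Tuple[int, int, str]] = []

    def reserve(self, start: int, end: int, name: str) -> None:
        for s, e, n in self.occupied:
            if start < e and s < end:
                raise GenerationError(
                    f"feature collision: {name} [{start},{end}) overlaps {n} [{s},{e})")
        self.occupied.append((start, end, name))

    def place_random(self, length: int, lo: int, hi: int, name: str,
                     rng: np.random.Generator, pad: int = 20,
                     max_tries: int = 200) -> int:
        for _ in range(max_tries):
            start = int(rng.integers(lo, max(lo + 1, hi - length)))
            end = start + length
            if all(not (start - pad < e and s < end + pad) for s, e, _ in self.occupied):
                self.occupied.append((start, end, name))
                return start
        # random placement can fragment the zone; fall back to a gap scan
        edges = sorted((max(lo, s - pad), min(hi, e + pad))
                       for s, e, _ in self.occupied if s < hi and lo < e)
        cursor = lo
        for gs, ge in edges + [(hi, hi)]:
            if gs - cursor >= length:
                slack = gs - cursor - length
                start = cursor + int(rng.integers(0, slack + 1))
                self.occupied.append((start, start + length, name))
                return start
            cursor = max(cursor, ge)
        raise GenerationError(f"cannot place {name} ({length} bp) in [{lo}, {hi})")


def _rand_seq(rng: np.random.Generator, n: int, background: Dict[str, float]) -> str:
    bases = list("ACGT")
    p = np.array([background[b] for b in bases], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(bases, size=n, p=p))


def _make_g4(rng: np.random.Generator) -> str:
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 4))
            parts.append("".join(rng.choice(list("ACT"), size=loop_len)))
    return "".join(parts)


def _stamp(seq: List[str], pos: int, payload: str) -> None:
    seq[pos:pos + len(payload)] = list(payload)


def _build_gene(seq: List[str], placer: _Placer, contig_id: str, start: int,
                length: int, spec: SyntheticLocusSpec, rng: np.random.Generator,
                divergent: bool) -> GeneTruth:
    em = spec.end_motifs
    iv = lambda s, e: GenomicInterval(contig_id, s, e)
    end = start + length

    tata = iv(start, start + len(em.tata))
    _stamp(seq, start, em.tata)
    placer.reserve(tata.start, tata.end, "tata")

    promoter = iv(start - 1000, start)
    tf_sites: List[GenomicInterval] = []
    if spec.plant_tf_site:
        tf_pos = start - 200
        _stamp(seq, tf_pos, TF_SITE)
        tf_sites.append(iv(tf_pos, tf_pos + len(TF_SITE)))
        placer.reserve(tf_pos, tf_pos + len(TF_SITE), "tf_site")

    # 3' block: helix_a + hairpin + linker + helix_b ends at the gene end;
    # the tRNA-like element follows immediately downstream of the gene.
    hairpin_len = em.hairpin_len if divergent else em.hairpin_len + 2
    linker_len = em.linker_len if divergent else em.linker_len - 7
    block_len = len(em.helix_a) + hairpin_len + linker_len + len(em.helix_b)
    b0 = end - block_len
    helix_a = iv(b0, b0 + len(em.helix_a))
    hairpin = iv(helix_a.end, helix_a.end + hairpin_len)
    linker = iv(hairpin.end, hairpin.end + linker_len)
    helix_b = iv(linker.end, linker.end + len(em.helix_b))
    trna = iv(end, end + len(em.trna_like))
    _stamp(seq, helix_a.start, em.helix_a)
    _stamp(seq, helix_b.start, em.helix_b)
    _stamp(seq, trna.start, em.trna_like)
    placer.reserve(b0, trna.end, "end_block")

    truth = GeneTruth(gene=iv(start, end), tata=tata, promoter=promoter,
                      helix_a=helix_a, hairpin=hairpin, linker=linker,
                      helix_b=helix_b, trna_like=trna, tf_sites=tf_sites)
    if not divergent:
        return truth

    # -- PAS(s) -------------------------------------------------------------
    pas_positions = [start + spec.pas_offset]
    if spec.n_pas >= 2:
        pas_positions.append(start + spec.pas_offset + spec.alt_pas_separation)
    for p in pas_positions:
        _stamp(seq, p, PAS_MOTIF)
        placer.reserve(p, p + len(PAS_MOTIF), "pas")
        truth.pas.append(iv(p, p + len(PAS_MOTIF)))

    # -- G-quadruplexes: half near the 5' end, half near the 3' end ---------
    g4_zones = [(0.03, 0.10), (0.905, 0.94)]
    for i in range(spec.n_g4):
        lo, hi = g4_zones[i % 2]
        payload = _make_g4(rng)
        pos = placer.place_random(len(payload), start + int(lo * length),
                                  start + int(hi * length), f"g4_{i}", rng)
        _stamp(seq, pos, payload)
        truth.g4s.append(iv(pos, pos + len(payload)))

    # -- GU tracts (3'-biased) and core cassettes (central) -----------------
    gu = spec.gu_tract_spec
    for i in range(gu.n_tracts):
        payload = "GT" * (gu.tract_len // 2)
        pos = placer.place_random(len(payload), start + int(gu.tract_zone[0] * length),
                                  start + int(gu.tract_zone[1] * length),
                                  f"gu_{i}", rng)
        _stamp(seq, pos, payload)
        truth.gu_tracts.append(iv(pos, pos + len(payload)))
    for i in range(gu.n_core):
        pos = placer.place_random(len(CORE_CASSETTE),
                                  start + int(gu.core_zone[0] * length),
                                  start + int(gu.core_zone[1] * length),
                                  f"core_{i}", rng, pad=6)
        _stamp(seq, pos, CORE_CASSETTE)
        truth.core_motifs.append(iv(pos, pos + len(CORE_CASSETTE)))

    # -- inverted-repeat pairs ----------------------------------------------
    ir_anchors = (0.565, 0.585)
    for i in range(spec.n_inverted_repeat_pairs):
        sep = spec.ir_separations[i % len(spec.ir_separations)]
        arm = _rand_seq(rng, spec.ir_arm_len, spec.background)
        a0 = start + int(ir_anchors[i % len(ir_anchors)] * length) + i * 40
        # keep the distal arm short of the 3' feature zones on small genes
        sep = min(sep, max(300, start + int(0.81 * length) - a0
                           - spec.ir_arm_len))
        b0_ = a0 + spec.ir_arm_len + sep
        placer.reserve(a0, a0 + spec.ir_arm_len, f"ir{i}_a")
        placer.reserve(b0_, b0_ + spec.ir_arm_len, f"ir{i}_b")
        _stamp(seq, a0, arm)
        _stamp(seq, b0_, revcomp(arm))
        truth.ir_pairs.append((iv(a0, a0 + spec.ir_arm_len),
                               iv(b0_, b0_ + spec.ir_arm_len)))

    # -- TEs, split across the permitted fractional-length bins -------------
    library = default_te_library()
    per_bin = spec.n_te // len(spec.te_bins) if spec.te_bins else 0
    extra = spec.n_te - per_bin * len(spec.te_bins)
    te_idx = 0
    for bi, (lo, hi) in enumerate(spec.te_bins):
        n_here = per_bin + (1 if bi < extra else 0)
        tes = [library[(te_idx + j) % len(library)] for j in range(n_here)]
        bin_lo, bin_hi = start + int(lo * length), start + int(hi * length)
        slack = (bin_hi - bin_lo) - sum(len(t) for t in tes)
        if slack < 20 * (n_here + 1):
            raise GenerationError(
                f"TE bin ({lo}, {hi}) too small for {n_here} elements")
        # random partition of the slack into n+1 inter-element gaps
        cuts = np.sort(rng.integers(0, slack - 20 * (n_here + 1) + 1, n_here))
        pos = bin_lo
        prev_cut = 0
        for j, te in enumerate(tes):
            gap = 20 + int(cuts[j] - prev_cut)
            prev_cut = int(cuts[j])
            pos += gap
            placer.reserve(pos, pos + len(te), f"te_{te_idx}")
            _stamp(seq, pos, te.residues)
            truth.tes.append(TruthTe(f"{te.id}.{te_idx}", te.meta["class"],
                                     iv(pos, pos + len(te))))
            pos += len(te)
            te_idx += 1
    return truth


def _scrub_guard_zone(seq: List[str], truth: GeneTruth, rng: np.random.Generator,
                      window: int = 600) -> None:
    """Remove chance AATAAA occurrences in the +-window guard zone around each
    planted PAS (the planted motifs themselves stay)."""
    planted = {p.start for p in truth.pas}
    text = "".join(seq)
    lo = min(planted) - window
    hi = max(planted) + window + len(PAS_MOTIF)
    pos = text.find(PAS_MOTIF, lo)
    guard_rounds = 0
    while 0 <= pos < hi:
        if pos not in planted and any(abs(pos - p) <= window for p in planted):
            # break the motif with a single substitution at a random offset
            off = int(rng.integers(0, len(PAS_MOTIF)))
            old = seq[pos + off]
            seq[pos + off] = str(rng.choice([c for c in "ACGT" if c != old]))
            text = "".join(seq)
            guard_rounds += 1
            if guard_rounds > 1000:
                raise GenerationError("guard-zone scrub did not converge")
            pos = text.find(PAS_MOTIF, lo)
            continue
        pos = text.find(PAS_MOTIF, pos + 1)


def build_root_locus(spec: SyntheticLocusSpec, seed: int
                     ) -> Tuple[DnaSequence, SyntheticTruth]:
    """Construct the root contig and its ground truth.

    Deterministic in (spec, seed); the same pair always yields a
    byte-identical contig.
    """
    rng = np.random.default_rng([seed, 1])
    contig_id = f"synthetic_locus_seed{seed}"
    L = spec.contig_length
    seq = list(_rand_seq(rng, L, spec.background))
    placer = _Placer()

    geneA_start = spec.margin
    geneB_start = geneA_start + spec.geneA_length + spec.intergenic_distance
    truth = SyntheticTruth(contig_id, L, spec.strand, seed)
    truth.genes["divergent"] = _build_gene(seq, placer, contig_id, geneA_start,
                                           spec.geneA_length, spec, rng, divergent=True)
    truth.genes["conserved"] = _build_gene(seq, placer, contig_id, geneB_start,
                                           spec.geneB_length, spec, rng, divergent=False)
    _scrub_guard_zone(seq, truth.genes["divergent"], rng)

    residues = "".join(seq)
    if spec.strand == "-":
        residues = revcomp(residues)
        flip = _flip_transform(L)
        truth.genes = {k: g.transform(flip) for k, g in truth.genes.items()}
        for g in truth.genes.values():
            _flip_strands(g)
    return DnaSequence(contig_id, residues), truth


def _flip_transform(L: int):
    def fn(s: int, e: int):
        return (L - e, L - s)
    return fn


def _flip_strands(g: GeneTruth) -> None:
    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.seq_id, iv.start, iv.end, "-" if iv.strand == "+" else "+")
    for name in ("gene", "tata", "promoter", "helix_a", "hairpin", "linker",
                 "helix_b", "trna_like"):
        setattr(g, name, flip(getattr(g, name)))
    g.pas = [flip(x) for x in g.pas]
    g.tes = [TruthTe(t.name, t.te_class, flip(t.iv)) for t in g.tes]
    g.ir_pairs = [(flip(a), flip(b)) for a, b in g.ir_pairs]
    g.g4s = [flip(x) for x in g.g4s]
    g.gu_tracts = [flip(x) for x in g.gu_tracts]
    g.core_motifs = [flip(x) for x in g.core_motifs]
    g.tf_sites = [flip(x) for x in g.tf_sites]


# ---------------------------------------------------------------------------
# evolution along a tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A rooted newick tree with branch lengths in expected substitutions/site."""

    newick: str

    def __post_init__(self) -> None:
        self.tree = dendropy.Tree.get(data=self.newick, schema="newick")
        self.leaf_names = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise SequenceError("duplicate leaf names in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise SequenceError("negative branch length")

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    def minimal_clade_leaves(self, leaf: str, others: Sequence[str]) -> List[str]:
        """Leaves of the smallest clade containing `leaf` and at least one of
        `others`."""
        node = next(lf for lf in self.tree.leaf_node_iter()
                    if lf.taxon.label == leaf)
        others = set(others)
        while node.parent_node is not None:
            node = node.parent_node
            leaves = [lf.taxon.label for lf in node.leaf_iter()]
            if others & set(leaves):
                return leaves
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


DEFAULT_TREE = ("(((alpha:0.05,beta:0.04):0.03,(gamma:0.08,delta:0.07):0.04):0.02,"
                "(epsilon:0.10,zeta:0.09):0.05);")


def _branch_rng(seed: int, branch_key: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(branch_key.encode())])


def _masks(truth: SyntheticTruth, L: int, rates: EvolutionRates
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site substitution-rate multiplier and indel permission."""
    mult = np.ones(L)
    indel_ok = np.ones(L, dtype=bool)
    con = truth.genes.get("conserved")
    if con is not None:
        mult[con.gene.start:con.gene.end] *= rates.conserved_gene_factor
    for g in truth.genes.values():
        mult[g.promoter.start:g.promoter.end] = np.minimum(
            mult[g.promoter.start:g.promoter.end], PROMOTER_FACTOR)
        # 3' block evolves slowly; structure-forming motifs and the planted
        # regulatory hexamers not at all
        block = (g.hairpin, g.linker, g.trna_like)
        for ivl in block:
            mult[ivl.start:ivl.end] = np.minimum(mult[ivl.start:ivl.end], PURIFYING_FACTOR)
            indel_ok[ivl.start:ivl.end] = False
        for ivl in g.g4s + g.gu_tracts + g.core_motifs:
            mult[ivl.start:ivl.end] = np.minimum(mult[ivl.start:ivl.end], PURIFYING_FACTOR)
            indel_ok[ivl.start:ivl.end] = False
        for a, b in g.ir_pairs:
            for ivl in (a, b):
                mult[ivl.start:ivl.end] = np.minimum(mult[ivl.start:ivl.end],
                                                     PURIFYING_FACTOR)
                indel_ok[ivl.start:ivl.end] = False
        for ivl in [g.tata, g.helix_a, g.helix_b] + g.pas + g.tf_sites:
            mult[ivl.start:ivl.end] = 0.0
            indel_ok[ivl.start:ivl.end] = False
    return mult, indel_ok


def _substitute(arr: np.ndarray, mult: np.ndarray, t: float,
                rng: np.random.Generator) -> np.ndarray:
    """Exact JC69: each site is redrawn uniformly with prob 1 - exp(-4 t r /3)."""
    if t <= 0:
        return arr
    p = 1.0 - np.exp(-4.0 * t * mult / 3.0)
    hit = rng.random(arr.size) < p
    hit &= arr != ord("N")
    n = int(hit.sum())
    if n:
        arr = arr.copy()
        arr[hit] = _BASES[rng.integers(0, 4, n)]
    return arr


def _apply_deletion(truth: SyntheticTruth, pos: int, dlen: int) -> SyntheticTruth:
    def fn(s: int, e: int):
        ns = s if s <= pos else max(pos, s - dlen)
        ne = e if e <= pos else max(pos, e - dlen)
        if ne - ns <= 0:
            return None
        return ns, ne
    out = replace(truth)
    out.genes = {k: g.transform(fn) for k, g in truth.genes.items()}
    out.contig_length = truth.contig_length - dlen
    return out


def _apply_insertion(truth: SyntheticTruth, pos: int, ilen: int) -> SyntheticTruth:
    def fn(s: int, e: int):
        ns = s + ilen if s >= pos else s
        ne = e + ilen if e > pos else e
        return ns, ne
    out = replace(truth)
    out.genes = {k: g.transform(fn) for k, g in truth.genes.items()}
    out.contig_length = truth.contig_length + ilen
    return out


def _indels(arr: np.ndarray, truth: SyntheticTruth, t: float,
            rates: EvolutionRates, rng: np.random.Generator,
            indel_ok: np.ndarray) -> Tuple[np.ndarray, SyntheticTruth]:
    lam = rates.indel_rate * t * arr.size
    n = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n):
        length = int(rng.geometric(rates.indel_len_geom_p))
        is_del = bool(rng.random() < 0.5)
        for _try in range(100):
            pos = int(rng.integers(0, arr.size - length))
            span = slice(pos, pos + length) if is_del else slice(pos, pos + 1)
            if indel_ok[span].all():
                break
        else:
            continue
        if is_del:
            arr = np.concatenate([arr[:pos], arr[pos + length:]])
            indel_ok = np.concatenate([indel_ok[:pos], indel_ok[pos + length:]])
            truth = _apply_deletion(truth, pos, length)
        else:
            ins = np.frombuffer(
                _rand_seq(rng, length, DEFAULT_BACKGROUND).encode(), dtype=np.uint8)
            arr = np.concatenate([arr[:pos], ins, arr[pos:]])
            indel_ok = np.concatenate([indel_ok[:pos], np.ones(length, bool),
                                       indel_ok[pos:]])
            truth = _apply_insertion(truth, pos, length)
    return arr, truth


def _scrub_cryptic_pas(arr: np.ndarray, truth: SyntheticTruth,
                       rng: np.random.Generator, window: int = 116) -> np.ndarray:
    """Remove mutation-born AATAAA motifs inside the main-PAS ambiguity
    window (purifying selection against cryptic polyadenylation next to the
    active signal; beyond the window alternative signals may arise freely)."""
    out = arr
    for g in truth.genes.values():
        if not g.pas:
            continue
        pat = PAS_MOTIF if g.gene.strand == "+" else revcomp(PAS_MOTIF)
        planted = {p.start for p in g.pas}
        protected = [(p.start, p.end) for p in g.pas]
        lo = max(0, min(p.start for p in g.pas) - window)
        hi = min(arr.size, max(p.end for p in g.pas) + window)
        text = out[lo:hi].tobytes().decode()
        pos = text.find(pat)
        while pos >= 0:
            fwd = lo + pos
            if fwd not in planted:
                if out is arr:
                    out = arr.copy()
                choices = [fwd + k for k in range(len(pat))
                           if not any(s <= fwd + k < e for s, e in protected)]
                site = int(rng.choice(choices))
                old = out[site]
                alts = [b for b in _BASES if b != old]
                out[site] = alts[int(rng.integers(0, len(alts)))]
                text = out[lo:hi].tobytes().decode()
                pos = text.find(pat)
                continue
            pos = text.find(pat, pos + 1)
    return out


def _te_turnover(arr: np.ndarray, truth: SyntheticTruth, t: float,
                 rates: EvolutionRates, rng: np.random.Generator,
                 branch_key: str, forced: Sequence[str] = ()
                 ) -> Tuple[np.ndarray, SyntheticTruth]:
    div = truth.genes.get("divergent")
    if div is None:
        return arr, truth
    # excisions: clean removal of a planted TE (junction ligation)
    doomed: List[TruthTe] = []
    for te in div.tes:
        if te.name in forced:
            doomed.append(te)
        elif rates.te_excise_rate > 0 and rng.random() < rates.te_excise_rate * t:
            doomed.append(te)
    missing = set(forced) - {te.name for te in doomed}
    for name in missing:
        import logging
        logging.getLogger(__name__).info(
            "excision of %s requested on branch %s but TE not present; skipped",
            name, branch_key)
    for te in sorted(doomed, key=lambda x: -x.iv.start):
        pos, dlen = te.iv.start, te.iv.length
        arr = np.concatenate([arr[:pos], arr[pos + dlen:]])
        truth = _apply_deletion(truth, pos, dlen)
    # insertions into the permitted bins
    lam = rates.te_insert_rate * t
    n_ins = int(rng.poisson(lam)) if lam > 0 else 0
    library = default_te_library()
    for i in range(n_ins):
        div = truth.genes["divergent"]
        g0, glen = div.gene.start, div.gene.length
        lo, hi = (0.30, 0.40) if rng.random() < 0.5 else (0.70, 0.80)
        pos = int(rng.integers(g0 + int(lo * glen), g0 + int(hi * glen)))
        te = library[int(rng.integers(0, len(library)))]
        ins = np.frombuffer(te.residues.encode(), dtype=np.uint8)
        arr = np.concatenate([arr[:pos], ins, arr[pos:]])
        truth = _apply_insertion(truth, pos, len(te))
        truth.genes["divergent"].tes.append(TruthTe(
            f"{te.id}@{branch_key}.{i}", te.meta["class"],
            GenomicInterval(div.gene.seq_id, pos, pos + len(te))))
    return arr, truth


def evolve_along_tree(root: DnaSequence, truth: SyntheticTruth, tree: PhyloTree,
                      rates: EvolutionRates, seed: int
                      ) -> Dict[str, Tuple[DnaSequence, SyntheticTruth]]:
    """Evolve the root locus along each branch of the tree.

    Substitutions follow JC69 at branch_length x subst_rate_scale per site
    (modulated by the per-feature purifying factors), indels have geometric
    lengths, and TE turnover optionally inserts library TEs into the
    permitted bins or cleanly excises planted TEs. Per-branch RNG streams are
    derived by hashing (branch leaf set, seed) so results are stable under
    tree edits elsewhere.
    """
    if truth.contig_length != len(root):
        raise GenerationError("root truth inconsistent with root sequence length")
    forced_by_leaf: Dict[str, List[str]] = {}
    for leaf, te_name in rates.forced_excisions:
        forced_by_leaf.setdefault(leaf, []).append(te_name)

    results: Dict[str, Tuple[DnaSequence, SyntheticTruth]] = {}
    root_arr = np.frombuffer(root.residues.encode(), dtype=np.uint8)

    def descend(node, arr: np.ndarray, tr: SyntheticTruth) -> None:
        for child in node.child_nodes():
            leaves_below = sorted(lf.taxon.label for lf in child.leaf_iter())
            branch_key = ",".join(leaves_below)
            rng = _branch_rng(seed, branch_key)
            t = (child.edge.length or 0.0) * rates.subst_rate_scale
            carr, ctr = arr, tr
            if t > 0 or branch_key in forced_by_leaf:
                forced = forced_by_leaf.get(branch_key, []) if child.is_leaf() else []
                carr, ctr = _te_turnover(carr, ctr, t, rates, rng, branch_key, forced)
                mult, indel_ok = _masks(ctr, carr.size, rates)
                carr = _substitute(carr, mult, t, rng)
                carr, ctr = _indels(carr, ctr, t, rates, rng, indel_ok)
                carr = _scrub_cryptic_pas(carr, ctr, rng)
            if child.is_leaf():
                name = child.taxon.label
                cid = f"{name}|{truth.contig_id}"
                leaf_truth = replace(ctr, contig_id=cid, contig_length=carr.size)
                leaf_truth.genes = {
                    k: g.transform(lambda s, e: (s, e)) for k, g in ctr.genes.items()}
                for g in leaf_truth.genes.values():
                    _rename_contig(g, cid)
                results[name] = (
                    DnaSequence(cid, carr.tobytes().decode(), {"taxon": name}),
                    leaf_truth)
            else:
                descend(child, carr, ctr)

    descend(tree.tree.seed_node, root_arr, truth)
    return results


def _rename_contig(g: GeneTruth, cid: str) -> None:
    def rn(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(cid, iv.start, iv.end, iv.strand)
    for name in ("gene", "tata", "promoter", "helix_a", "hairpin", "linker",
                 "helix_b", "trna_like"):
        setattr(g, name, rn(getattr(g, name)))
    g.pas = [rn(x) for x in g.pas]
    g.tes = [TruthTe(t.name, t.te_class, rn(t.iv)) for t in g.tes]
    g.ir_pairs = [(rn(a), rn(b)) for a, b in g.ir_pairs]
    g.g4s = [rn(x) for x in g.g4s]
    g.gu_tracts = [rn(x) for x in g.gu_tracts]
    g.core_motifs = [rn(x) for x in g.core_motifs]
    g.tf_sites = [rn(x) for x in g.tf_sites]


def simulate_cohort(spec: SyntheticLocusSpec, tree: PhyloTree,
                    rates: EvolutionRates, seed: int
                    ) -> Tuple[DnaSequence, SyntheticTruth,
                               Dict[str, Tuple[DnaSequence, SyntheticTruth]]]:
    """Convenience wrapper: build the root locus and evolve it along the tree."""
    root, truth = build_root_locus(spec, seed)
    leaves = evolve_along_tree(root, truth, tree, rates, seed)
    return root, truth, leaves
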