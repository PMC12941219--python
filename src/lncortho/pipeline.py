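"""End-to-end orchestration of the locus analyses.

Stages run in dependency order over a simulated cohort (or user FASTA):
simulate -> locate -> pas -> te -> selfcomp -> motifs -> ani -> ends ->
promoter -> summary. Every stage writes plain-text outputs (FASTA, GFF3,
BED, TSV) into the run directory, and the machine-readable ``summary.json``
carries counts, parameters and the seed but no timestamps, so identical
config + seed reproduce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .align import AlignParams
from .ani import ani_matrix, length_stats, select_archetypes
from .endstruct import ReferenceLayout, covariation, extract_end_structures, \
    align_msa, column_conservation, pairs_from_dotbracket
from .gffio import write_bed, write_gff3, write_tsv
from .locate import AnchorSet, GeneModel, NoCallError, check_synteny, \
    gene_sequence, locate_conserved_anchor, locate_gene
from .motifs import find_g4, hexamer_profile, nucleotide_usage, shared_motifs
from .pas import ProjectionError, call_main_pas, find_alternative_pas, \
    main_pas_status, project_reference_pas
from .pwm import Pwm, read_pwms, scan_many, shared_tfs, write_jaspar
from .seq import DnaSequence, GenomicInterval, write_fasta
from .selfcomp import find_self_complementary
from .simulate import (DEFAULT_TREE, EvolutionRates, PhyloTree,
                       SyntheticLocusSpec, TRNA_LIKE_STRUCTURE,
                       default_te_library, simulate_cohort)
from .te import annotate_tes, te_positional_profile, te_presence_matrix

log = logging.getLogger("lncortho.pipeline")

STAGES = ("simulate", "locate", "pas", "te", "selfcomp", "motifs", "ani",
          "ends", "promoter")

DEFAULT_QUERY_MOTIFS = ("GTGTGT", "TGTGTG", "TCTGTG", "CTGTGT")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "runs/default"
    seed: int = 1
    stages: Tuple[str, ...] = STAGES
    tree_newick: str = DEFAULT_TREE
    locus: SyntheticLocusSpec = field(default_factory=SyntheticLocusSpec)
    rates: EvolutionRates = field(default_factory=EvolutionRates)
    align: AlignParams = field(default_factory=AlignParams)
    min_hit_len: int = 100
    archetype_k: int = 3
    pas_window: int = 110
    alt_pas_window: int = 600
    te_profile_bins: int = 20
    hexamer_bins: int = 10
    query_motifs: Tuple[str, ...] = DEFAULT_QUERY_MOTIFS
    pwm_file: Optional[str] = None
    n_decoy_pwms: int = 20
    pwm_pthresh: float = 1e-4
    shared_tf_fraction: float = 0.65
    promoter_span: int = 1_000

    # -- config file round trip --------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data, ctx):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ConfigError(f"unknown config key(s) in {ctx}: {sorted(unknown)}")
            kwargs = {}
            for key, value in data.items():
                ftype = fields[key].type
                if isinstance(value, dict) and key in _NESTED:
                    kwargs[key] = build(_NESTED[key], value, key)
                elif isinstance(value, list):
                    kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                        for v in value)
                else:
                    kwargs[key] = value
            return klass(**kwargs)

        _NESTED = {"locus": SyntheticLocusSpec, "rates": EvolutionRates,
                   "align": AlignParams, "gu_tract_spec": None}
        # nested dataclasses inside locus handled by their own constructors
        data = dict(raw)
        if "locus" in data and isinstance(data["locus"], dict):
            locus_raw = dict(data["locus"])
            from .simulate import EndMotifs, GuTractSpec
            if isinstance(locus_raw.get("gu_tract_spec"), dict):
                locus_raw["gu_tract_spec"] = GuTractSpec(
                    **{k: tuple(v) if isinstance(v, list) else v
                       for k, v in locus_raw["gu_tract_spec"].items()})
            if isinstance(locus_raw.get("end_motifs"), dict):
                locus_raw["end_motifs"] = EndMotifs(**locus_raw["end_motifs"])
            data["locus"] = locus_raw
        return build(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunState:
    cfg: PipelineConfig
    out: Path
    root: Optional[DnaSequence] = None
    truth = None
    leaves: Dict[str, tuple] = field(default_factory=dict)
    anchors: Dict[str, AnchorSet] = field(default_factory=dict)
    models: Dict[str, Dict[str, GeneModel]] = field(default_factory=dict)
    genes: Dict[str, Dict[str, DnaSequence]] = field(default_factory=dict)
    te_annotations: Dict[str, list] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def divergent_genes(self) -> Dict[str, DnaSequence]:
        return {leaf: g["divergent"] for leaf, g in self.genes.items()
                if "divergent" in g}


def _stage_simulate(state: RunState) -> None:
    cfg = state.cfg
    tree = PhyloTree(cfg.tree_newick)
    root, truth, leaves = simulate_cohort(cfg.locus, tree, cfg.rates, cfg.seed)
    state.root, state.truth, state.leaves = root, truth, leaves
    write_fasta([root], state.out / "simulate" / "root.fasta")
    write_fasta([s for s, _ in leaves.values()], state.out / "simulate" / "leaves.fasta")
    (state.out / "simulate" / "tree.nwk").write_text(cfg.tree_newick + "\n")
    truth.to_gff(state.out / "simulate" / "root_truth.gff3")
    for leaf, (seq, tr) in leaves.items():
        tr.save(state.out / "simulate" / f"truth_{leaf}.json")
    sidecar = {"seed": cfg.seed, "rates": dataclasses.asdict(cfg.rates)}
    (state.out / "simulate" / "rates.json").write_text(json.dumps(sidecar, indent=1))
    state.summary["simulate"] = {"n_leaves": len(leaves),
                                 "contig_length": len(root)}


def _stage_locate(state: RunState) -> None:
    cfg = state.cfg
    state.anchors = {key: AnchorSet.from_truth(state.root, state.truth, key)
                     for key in ("divergent", "conserved")}
    feats, rows = [], []
    n_located = 0
    for leaf, (contig, _) in sorted(state.leaves.items()):
        win = GenomicInterval(contig.id, 0, len(contig))
        models: Dict[str, GeneModel] = {}
        status = {}
        for key in ("divergent", "conserved"):
            try:
                model = locate_gene(contig, win, state.anchors[key])
                models[key] = model
                status[key] = "located"
                feats.append((model.gene_iv, "gene", f"ID={leaf}.{key}"))
                feats.append((model.tata_iv, "TATA_box", f"Parent={leaf}.{key}"))
                feats.append((model.helix_iv, "triple_helix", f"Parent={leaf}.{key}"))
                feats.append((model.trna_like_iv, "tRNA_like", f"Parent={leaf}.{key}"))
            except NoCallError as exc:
                status[key] = f"no-call:{exc.reason}"
        state.models[leaf] = models
        state.genes[leaf] = {key: gene_sequence(contig, m)
                             for key, m in models.items()}
        if len(models) == 2:
            n_located += 1
            rep = check_synteny(models["divergent"], models["conserved"])
            rows.append([leaf, contig.id, models["divergent"].strand,
                         models["conserved"].strand, rep.same_contig,
                         rep.same_strand,
                         rep.intergenic_distance if rep.intergenic_distance
                         is not None else "NA"])
        state.summary.setdefault("locate", {}).setdefault("status", {})[leaf] = status
    write_gff3(feats, state.out / "locate" / "gene_models.gff3")
    write_tsv(rows, state.out / "locate" / "synteny.tsv",
              ["leaf", "contig", "strand_divergent", "strand_conserved",
               "same_contig", "same_strand", "intergenic_distance"])
    state.summary["locate"]["n_both_located"] = n_located


def _stage_pas(state: RunState) -> None:
    cfg = state.cfg
    ref_truth = state.truth.genes["divergent"]
    reference = state.root.slice(ref_truth.gene.start, ref_truth.gene.end,
                                 "reference_divergent")
    ref_pas = ref_truth.pas[0].start - ref_truth.gene.start
    rows = []
    n_called = 0
    for leaf, genes in sorted(state.genes.items()):
        gene = genes.get("divergent")
        if gene is None:
            rows.append([leaf, "NA", "NA", "NA", "NA", "no_gene", "no_gene"])
            continue
        try:
            projected = project_reference_pas(gene, reference, ref_pas)
        except ProjectionError:
            rows.append([leaf, "NA", "NA", "NA", "NA", "projection_failed",
                         "projection_failed"])
            continue
        call = call_main_pas(gene, projected, cfg.pas_window)
        if call is None:
            reason = main_pas_status(gene, projected, cfg.pas_window)
            rows.append([leaf, projected, "NA", "NA", "NA", "no_call", reason])
            continue
        n_called += 1
        model = state.models[leaf]["divergent"]
        model.pas_main = call.position
        rows.append([leaf, projected, call.position, call.kind,
                     call.offset_from_projection, "called", ""])
        for alt in find_alternative_pas(gene, call, cfg.alt_pas_window):
            model.pas_alternatives.append(alt.position)
            rows.append([leaf, projected, alt.position, alt.kind,
                         alt.offset_from_projection, "called", ""])
    write_tsv(rows, state.out / "pas" / "pas_calls.tsv",
              ["leaf", "projected", "pas_pos", "kind", "offset", "status", "reason"],
              comment="positions are transcript-frame offsets of the AATAAA start")
    state.summary["pas"] = {"n_main_called": n_called}


def _stage_te(state: RunState) -> None:
    cfg = state.cfg
    library = default_te_library()
    rows = []
    profile_sum = None
    for leaf, gene in sorted(state.divergent_genes().items()):
        anns = annotate_tes(gene, library)
        state.te_annotations[leaf] = anns
        prof = te_positional_profile(anns, len(gene), cfg.te_profile_bins)
        profile_sum = prof if profile_sum is None else profile_sum + prof
        for a in anns:
            rows.append([leaf, a.te_name, a.te_class, a.gene_iv.start,
                         a.gene_iv.end, a.gene_iv.strand, f"{a.pident:.1f}",
                         a.aln_length, f"{a.te_coverage:.2f}"])
    write_tsv(rows, state.out / "te" / "te_annotations.tsv",
              ["leaf", "te_name", "te_class", "start", "end", "strand",
               "pident", "aln_length", "te_coverage"])
    if profile_sum is not None:
        write_tsv([[i, f"{i / profile_sum.n_bins:.2f}",
                    f"{(i + 1) / profile_sum.n_bins:.2f}", c]
                   for i, c in enumerate(profile_sum.counts)],
                  state.out / "te" / "te_positional_profile.tsv",
                  ["bin", "frac_lo", "frac_hi", "count"],
                  comment="summed over leaves; bins of fractional gene length")
    tree = PhyloTree(state.cfg.tree_newick)
    loci = te_presence_matrix(state.te_annotations, state.divergent_genes(), tree)
    leaf_order = [lf for lf in tree.leaf_names if lf in state.genes]
    mrows = [[lc.locus_id, lc.te_name]
             + [lc.status.get(lf, "NA") for lf in leaf_order]
             + [";".join(lc.excised_in) or "-"] for lc in loci]
    write_tsv(mrows, state.out / "te" / "te_presence_matrix.tsv",
              ["locus", "te_name"] + leaf_order + ["excised_in"])
    state.summary["te"] = {
        "n_annotations": sum(len(v) for v in state.te_annotations.values()),
        "n_loci": len(loci),
        "n_excisions": sum(len(lc.excised_in) for lc in loci),
        "profile": profile_sum.counts if profile_sum else []}


def _stage_selfcomp(state: RunState) -> None:
    rows = []
    per_leaf = {}
    for leaf, gene in sorted(state.divergent_genes().items()):
        regions = find_self_complementary(gene)
        per_leaf[leaf] = len(regions)
        for r in regions:
            rows.append([leaf, r.iv_a.start, r.iv_a.end, r.iv_b.start, r.iv_b.end,
                         f"{r.pident:.1f}", r.separation, r.cls])
    write_tsv(rows, state.out / "selfcomp" / "self_complementary.tsv",
              ["leaf", "a_start", "a_end", "b_start", "b_end", "pident",
               "separation", "class"])
    state.summary["selfcomp"] = {"n_regions": per_leaf}


def _stage_motifs(state: RunState) -> None:
    cfg = state.cfg
    g4_rows = []
    profiles = []
    usage_rows = []
    for leaf, gene in sorted(state.divergent_genes().items()):
        for hit in find_g4(gene):
            g4_rows.append((hit.iv, f"{leaf}_G4", 500.0))
        profiles.append(hexamer_profile(gene, cfg.query_motifs, cfg.hexamer_bins))
        u = nucleotide_usage(gene)
        usage_rows.append([leaf] + [f"{u.overall[b]:.2f}" for b in "ACGT"])
    write_bed(g4_rows, state.out / "motifs" / "g4_hits.bed")
    write_tsv(usage_rows, state.out / "motifs" / "nucleotide_usage.tsv",
              ["leaf", "pct_A", "pct_C", "pct_G", "pct_T"])
    sparse = [[p.gene_id, k, c] for p in profiles
              for k, c in sorted(p.counts.items()) if c > 0]
    write_tsv(sparse, state.out / "motifs" / "hexamer_counts.tsv",
              ["gene", "hexamer", "count"],
              comment="sparse triplets over the 4096-key space")
    shared = shared_motifs(profiles) if len(profiles) >= 2 else []
    write_tsv([[k, mn, f"{mean:.1f}"] for k, mn, mean in shared[:100]],
              state.out / "motifs" / "shared_hexamers.tsv",
              ["hexamer", "min_count", "mean_count"])
    state.summary["motifs"] = {
        "n_g4": len(g4_rows),
        "top_shared_hexamers": [k for k, _, _ in shared[:4]]}


def _stage_ani(state: RunState) -> None:
    cfg = state.cfg
    genes = [g for _, g in sorted(state.divergent_genes().items())]
    for leaf, gene in sorted(state.divergent_genes().items()):
        gene.id = leaf  # matrix rows named by leaf
    if len(genes) < 2:
        state.summary["ani"] = {"skipped": "fewer than two genes"}
        return
    m = ani_matrix(genes, cfg.min_hit_len, cfg.align)
    write_tsv([[m.ids[i]] + [f"{m.values[i, j]:.2f}" for j in range(len(m.ids))]
               for i in range(len(m.ids))],
              state.out / "ani" / "ani_matrix.tsv", ["gene"] + m.ids,
              comment="percent ANI; identity-weighted local hits > "
                      f"{cfg.min_hit_len} bp")
    k = min(cfg.archetype_k, len(m.ids))
    arch = select_archetypes(m, k) if k >= 2 else list(m.ids)
    (state.out / "ani" / "archetypes.txt").write_text("\n".join(arch) + "\n")
    tree = PhyloTree(cfg.tree_newick)
    (state.out / "ani" / "leaf_order.txt").write_text(
        "\n".join(tree.leaf_names) + "\n")
    models = [mm["divergent"] for _, mm in sorted(state.models.items())
              if "divergent" in mm]
    taxonomy = {mdl.contig_id: mdl.contig_id.split("|")[0] for mdl in models}
    stats = length_stats(models, taxonomy)
    state.summary["ani"] = {
        "mean_ani_offdiag": float(np.mean(m.values[~np.eye(len(m.ids), dtype=bool)])),
        "archetypes": arch,
        "mean_gene_length": stats.overall_mean}


def _stage_ends(state: RunState) -> None:
    layout = ReferenceLayout.from_truth(state.root, state.truth, "divergent")
    rows = []
    trna_seqs = []
    for leaf, models in sorted(state.models.items()):
        model = models.get("divergent")
        if model is None:
            continue
        contig = state.leaves[leaf][0]
        esm = extract_end_structures(contig, model, layout)
        lengths = esm.lengths()
        rows.append([leaf] + [lengths[k] if lengths[k] is not None else "NA"
                              for k in ("helix_motif", "hairpin", "linker",
                                        "trna_like")])
        if esm.trna_like_iv is not None:
            iv = esm.trna_like_iv
            sub = contig.residues[iv.start:iv.end]
            from .seq import revcomp as _rc
            trna_seqs.append(sub if model.strand == "+" else _rc(sub))
    write_tsv(rows, state.out / "ends" / "end_structure_lengths.tsv",
              ["leaf", "helix_motif", "hairpin", "linker", "trna_like"])
    result = {}
    if len(trna_seqs) >= 2:
        msa = align_msa(trna_seqs)
        cons = column_conservation(msa)
        pairs = pairs_from_dotbracket(TRNA_LIKE_STRUCTURE)
        pairs = [(i, j) for i, j in pairs if j < len(msa[0])]
        cov = covariation(msa, pairs)
        write_tsv([[p.i, p.j, p.n_canonical, p.n_compensatory, p.n_inconsistent,
                    p.n_gapped, f"{p.score:.3f}"] for p in cov.pairs],
                  state.out / "ends" / "trna_covariation.tsv",
                  ["pair_i", "pair_j", "n_canonical", "n_compensatory",
                   "n_inconsistent", "n_gapped", "score"])
        write_tsv([[c] + [f"{freq.get(b, 0.0):.3f}" for b in "ACGT-"]
                   for c, freq in enumerate(cons.frequencies)],
                  state.out / "ends" / "trna_column_frequencies.tsv",
                  ["column", "A", "C", "G", "T", "gap"])
        result = {"identical_fraction": cons.identical_fraction,
                  "mean_covariation": cov.mean_score}
    state.summary["ends"] = result


def _synthetic_pwm_set(cfg: PipelineConfig) -> List[Pwm]:
    """The planted TF plus seeded random decoys (synthetic stand-ins for a
    real PWM database)."""
    from .simulate import TF_SITE

    rng = np.random.default_rng([cfg.seed, 97])
    pwms = [_consensus_pwm("PLANTED_TF", TF_SITE)]
    for i in range(cfg.n_decoy_pwms):
        counts = rng.dirichlet([0.4] * 4, size=10) * 100
        pwms.append(Pwm.from_counts(f"DECOY_{i:02d}", counts))
    return pwms


def _consensus_pwm(name: str, consensus: str, weight: float = 100.0) -> Pwm:
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.full((len(consensus), 4), 1.0)
    for w, b in enumerate(consensus):
        counts[w, idx[b]] = weight
    return Pwm.from_counts(name, counts)


def _stage_promoter(state: RunState) -> None:
    cfg = state.cfg
    if cfg.pwm_file:
        pwms = read_pwms(cfg.pwm_file)
    else:
        pwms = _synthetic_pwm_set(cfg)
        write_jaspar(pwms, state.out / "promoter" / "pwms_synthetic.jaspar")
    hit_rows = []
    tf_sets: Dict[str, set] = {}
    for leaf, models in sorted(state.models.items()):
        model = models.get("divergent")
        if model is None:
            continue
        contig = state.leaves[leaf][0]
        if model.strand == "+":
            lo = max(0, model.gene_iv.start - cfg.promoter_span)
            prom = contig.slice(lo, model.gene_iv.start, f"{leaf}_promoter")
        else:
            hi = min(len(contig), model.gene_iv.end + cfg.promoter_span)
            from .seq import reverse_complement
            prom = reverse_complement(
                contig.slice(model.gene_iv.end, hi, f"{leaf}_promoter"))
        hits = scan_many(prom, pwms, cfg.pwm_pthresh)
        tf_sets[leaf] = {h.tf_name for h in hits}
        for h in hits:
            hit_rows.append([leaf, h.tf_name, h.iv.start, h.iv.end, h.strand,
                             f"{h.score:.3f}", f"{h.pvalue:.2e}"])
    write_tsv(hit_rows, state.out / "promoter" / "tf_hits.tsv",
              ["leaf", "tf", "start", "end", "strand", "score_bits", "pvalue"],
              comment="positions within the 1 kb promoter, transcript strand")
    shared = shared_tfs(tf_sets, cfg.shared_tf_fraction) if len(tf_sets) >= 2 else []
    (state.out / "promoter" / "shared_tfs.txt").write_text(
        "\n".join(shared) + ("\n" if shared else ""))
    state.summary["promoter"] = {"n_hits": len(hit_rows), "shared_tfs": shared}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "locate": _stage_locate,
    "pas": _stage_pas,
    "te": _stage_te,
    "selfcomp": _stage_selfcomp,
    "motifs": _stage_motifs,
    "ani": _stage_ani,
    "ends": _stage_ends,
    "promoter": _stage_promoter,
}

_DEPS = {
    "simulate": (),
    "locate": ("simulate",),
    "pas": ("locate",),
    "te": ("locate",),
    "selfcomp": ("locate",),
    "motifs": ("locate",),
    "ani": ("locate",),
    "ends": ("locate",),
    "promoter": ("locate",),
}


def run_pipeline(cfg: PipelineConfig, until: Optional[str] = None) -> RunState:
    """Run the pipeline stages in dependency order.

    A stage failure is recorded in the summary and its dependents are
    skipped; the summary is always written. ``until`` limits execution to
    one stage (plus its dependencies).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    state = RunState(cfg, out)
    wanted = list(cfg.stages)
    if until is not None:
        wanted = [s for s in STAGES if s == until or _depends_on(until, s)]
    failed: set = set()
    blocked: set = set()
    for stage in STAGES:
        if stage not in wanted:
            continue
        if any(dep in failed or dep in blocked for dep in _DEPS[stage]):
            state.summary[stage] = {"skipped": "dependency failed"}
            blocked.add(stage)
            continue
        t0 = time.time()
        try:
            _STAGE_FNS[stage](state)
            log.info("stage %s done in %.2fs", stage, time.time() - t0)
        except Exception as exc:  # recorded, dependents skipped
            log.error("stage %s failed: %s", stage, exc)
            state.summary[stage] = {"failed": str(exc)}
            failed.add(stage)
    state.summary["config"] = cfg.to_dict()
    state.summary["version"] = __version__
    state.summary["failed_stages"] = sorted(failed)
    (out / "summary.json").write_text(
        json.dumps(state.summary, indent=1, sort_keys=True, default=str))
    log.removeHandler(fh)
    fh.close()
    if failed:
        raise PipelineFailure(sorted(failed), state)
    return state


def _depends_on(stage: str, candidate: str) -> bool:
    seen = set()
    frontier = [stage]
    while frontier:
        s = frontier.pop()
        for dep in _DEPS[s]:
            if dep not in seen:
                seen.add(dep)
                frontier.append(dep)
    return candidate in seen


class PipelineFailure(RuntimeError):
    def __init__(self, failed_stages: List[str], state: RunState) -> None:
        self.failed_stages = failed_stages
        self.state = state
        super().__init__(f"stages failed: {', '.join(failed_stages)}")
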