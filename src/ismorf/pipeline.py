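"""End-to-end orchestration: IG extraction through classification and synteny.

The run is a pure function of (inputs, config, seeds): every stage writes
its table to the output directory, per-stage counters are logged and
collected into a JSON report, and re-running with the same configuration
reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration_classify as cc
from . import clustering, codon_evolution, intergenic_orfs, seqprops, simulator
from . import synteny_context as sc
from .io_formats import (
    AnnotatedGenome,
    ConfigurationError,
    read_fasta,
    read_gff,
    write_tsv,
)

logger = logging.getLogger("ismorf")

_RUNCONFIG_KEYS = {
    "genomes", "simulate", "lcb_table", "hits_table", "outdir", "seed",
    "ig_min_len", "ig_max_len", "orf_min_nt", "min_containment", "min_aa",
    "max_aa", "identity", "cov_long", "len_ratio", "min_members",
    "kd_metric", "shuffle_k", "thresholds", "feature_types",
    "calibration_B", "run_synteny", "run_context", "run_props",
}


@dataclass
class RunConfig:
    outdir: str
    genomes: list[dict] = field(default_factory=list)   # {fasta, gff, genome_id?, species_label?}
    simulate: dict | None = None
    lcb_table: str | None = None
    hits_table: str | None = None
    seed: int = 0
    ig_min_len: int = intergenic_orfs.IG_MIN_LEN
    ig_max_len: int = intergenic_orfs.IG_MAX_LEN
    orf_min_nt: int = intergenic_orfs.ORF_MIN_NT
    min_containment: float = intergenic_orfs.MIN_CONTAINMENT
    min_aa: int = intergenic_orfs.PROTEIN_MIN_AA
    max_aa: int = intergenic_orfs.PROTEIN_MAX_AA
    identity: float = clustering.IDENTITY_DEFAULT
    cov_long: float = clustering.COV_LONG_DEFAULT
    len_ratio: float = clustering.LEN_RATIO_DEFAULT
    min_members: int = clustering.MIN_CLUSTER_MEMBERS
    kd_metric: str = "k2p"
    shuffle_k: int = cc.KLET_DEFAULT
    thresholds: dict = field(default_factory=dict)
    feature_types: list[str] = field(default_factory=lambda: ["gene"])
    calibration_B: int = 1000
    run_synteny: bool = True
    run_context: bool = True
    run_props: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigurationError("config must set 'outdir'")
        return cls(**raw)

    def threshold_set(self) -> cc.ThresholdSet:
        return cc.ThresholdSet(**self.thresholds) if self.thresholds else cc.ThresholdSet()


def _load_genomes(cfg: RunConfig) -> tuple[list[AnnotatedGenome], list[sc.LcbBlock] | None]:
    if cfg.simulate is not None:
        sim_cfg = simulator.SimConfig(**cfg.simulate)
        genomes, truth = simulator.simulate_genomes(sim_cfg)
        return genomes, truth.lcbs
    genomes = []
    for entry in cfg.genomes:
        fasta, gff = Path(entry["fasta"]), Path(entry["gff"])
        if not fasta.exists():
            raise ConfigurationError(f"missing FASTA: {fasta}")
        if not gff.exists():
            raise ConfigurationError(f"missing GFF: {gff}")
        genome_id = entry.get("genome_id", fasta.stem)
        contigs = read_fasta(fasta, genome_id=genome_id)
        features = read_gff(gff, feature_types=cfg.feature_types)
        genomes.append(AnnotatedGenome(
            genome_id=genome_id, contigs=contigs, features=features,
            species_label=entry.get("species_label", "")))
    lcbs = sc.read_lcb_table(cfg.lcb_table) if cfg.lcb_table else None
    return genomes, lcbs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full discovery pipeline and write every stage table.

    Returns the run report (per-stage counts and the classification
    summary), which is also written to ``report.json``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # serialize the configuration verbatim alongside the outputs
    with open(outdir / "run_config.yaml", "w") as handle:
        yaml.safe_dump(dataclasses.asdict(cfg), handle, sort_keys=True)
    report: dict = {"stages": {}}

    genomes, lcbs = _load_genomes(cfg)
    report["stages"]["inputs"] = {"n_genomes": len(genomes)}

    # --- intergenic regions -------------------------------------------------
    all_igs: list[intergenic_orfs.IntergenicRegion] = []
    for genome in genomes:
        all_igs.extend(intergenic_orfs.extract_intergenic(
            genome, min_len=cfg.ig_min_len, max_len=cfg.ig_max_len,
            feature_types=cfg.feature_types))
    write_tsv([{
        "ig_id": ig.ig_id, "genome_id": ig.genome_id, "contig_id": ig.contig_id,
        "start": ig.start, "end": ig.end,
        "left_gene": ig.left_gene.feature_id if ig.left_gene else "",
        "right_gene": ig.right_gene.feature_id if ig.right_gene else "",
    } for ig in all_igs], outdir / "ig_table.tsv", "ig_table")
    report["stages"]["extract_igs"] = {"n_igs": len(all_igs)}

    # --- ORF prediction and ismORF selection --------------------------------
    ismorfs: list[intergenic_orfs.IsmOrf] = []
    genome_by_id = {g.genome_id: g for g in genomes}
    igs_by_genome: dict[str, list] = {}
    for ig in all_igs:
        igs_by_genome.setdefault(ig.genome_id, []).append(ig)
    n_candidates = 0
    for genome in genomes:
        orfs = []
        for contig in genome.contigs:
            orfs.extend(intergenic_orfs.find_orfs(contig, min_nt=cfg.orf_min_nt))
        n_candidates += len(orfs)
        ismorfs.extend(intergenic_orfs.select_ismorfs(
            orfs, igs_by_genome.get(genome.genome_id, []),
            genome_id=genome.genome_id, min_fraction=cfg.min_containment,
            min_aa=cfg.min_aa, max_aa=cfg.max_aa))
    report["stages"]["find_orfs"] = {"n_candidate_orfs": n_candidates,
                                     "n_ismorfs": len(ismorfs)}

    if cfg.hits_table:
        hits = pd.read_csv(cfg.hits_table, sep="\t")
        ismorfs, removed = intergenic_orfs.filter_known_protein_hits(ismorfs, hits)
        report["stages"]["known_hit_filter"] = {"n_removed": int(len(removed)),
                                                "n_kept": len(ismorfs)}
    write_tsv([{
        "orf_id": o.orf_id, "ig_id": o.ig_id, "genome_id": o.genome_id,
        "contig_id": o.contig_id, "start": o.start, "end": o.end,
        "strand": o.strand, "start_codon": o.start_codon, "protein": o.protein,
        "containment": o.containment,
    } for o in ismorfs], outdir / "ismorf_table.tsv", "ismorf_table")

    # --- clustering ----------------------------------------------------------
    proteins = {o.orf_id: o.protein for o in ismorfs}
    cds_map = {o.orf_id: intergenic_orfs.extract_orf_cds(genome_by_id[o.genome_id], o)
               for o in ismorfs}
    clusters = clustering.greedy_cluster(
        proteins, identity=cfg.identity, cov_long=cfg.cov_long,
        len_ratio=cfg.len_ratio, min_members=cfg.min_members, cds=cds_map)
    cluster_rows = []
    for cl in clusters:
        for mid in cl.member_ids:
            cluster_rows.append({"cluster_id": cl.cluster_id, "member_id": mid,
                                 "is_representative": mid == cl.representative_id})
    write_tsv(cluster_rows, outdir / "cluster_table.tsv", "cluster_table")
    report["stages"]["cluster"] = {
        "n_clustered_sequences": sum(c.size for c in clusters),
        "n_clusters": len(clusters)}

    # --- alignment, back-translation, scoring --------------------------------
    scores: list[codon_evolution.EvolScores] = []
    n_align_failed = n_missing = 0
    scored_clusters = []
    for cl in clusters:
        try:
            msa = clustering.align_cluster(cl, method="builtin")
            cl.codon_msa = clustering.backtranslate_codon_alignment(msa, cl.cds)
        except ValueError:
            n_align_failed += 1
            continue
        sc_scores = codon_evolution.cluster_evolscores(cl, kd_metric=cfg.kd_metric)
        if sc_scores is None:
            n_missing += 1
            continue
        scores.append(sc_scores)
        scored_clusters.append(cl)
    _write_scores(scores, outdir / "score_table.tsv")
    report["stages"]["score"] = {"n_scored": len(scores),
                                 "n_alignment_failed": n_align_failed,
                                 "n_missing": n_missing}

    # --- shuffled null and calibration ---------------------------------------
    null_clusters = cc.build_shuffled_null(scored_clusters, seed=cfg.seed,
                                           k=cfg.shuffle_k)
    null_scores = []
    for cl in null_clusters:
        s = codon_evolution.cluster_evolscores(cl, kd_metric=cfg.kd_metric)
        if s is not None:
            null_scores.append(s)
    _write_scores(null_scores, outdir / "shuffled_score_table.tsv")
    calib_rows = []
    for label, source in (("real", scores), ("shuffled", null_scores)):
        for stat in ("dN", "dS", "Kd"):
            vals = [getattr(s, stat) for s in source]
            try:
                rep = cc.bootstrap_quantiles(vals, B=cfg.calibration_B,
                                             seed=cfg.seed, statistic=stat)
            except ValueError:
                continue
            calib_rows.append({
                "source": label, "statistic": stat,
                "q_low": rep.q_low, "q_high": rep.q_high,
                "q_low_spread_lo": rep.q_low_spread[0],
                "q_low_spread_hi": rep.q_low_spread[1],
                "q_high_spread_lo": rep.q_high_spread[0],
                "q_high_spread_hi": rep.q_high_spread[1],
                "B": rep.B, "n_values": rep.n_values})
    write_tsv(calib_rows, outdir / "calibration_table.tsv", "calibration_table")
    report["stages"]["shuffle_calibrate"] = {"n_null_scored": len(null_scores),
                                             "n_quantile_rows": len(calib_rows)}

    # --- threshold classification --------------------------------------------
    thresholds = cfg.threshold_set()
    labels = {s.cluster_id: cc.classify_thresholds(s, thresholds) for s in scores}
    write_tsv([{"cluster_id": cid, "label": lab}
               for cid, lab in sorted(labels.items())],
              outdir / "classification_table.tsv", "classification_table")
    coding_clusters = {cid for cid, lab in labels.items() if lab == "coding"}
    report["stages"]["classify"] = {
        "n_coding": len(coding_clusters),
        "n_noncoding": len(labels) - len(coding_clusters)}

    orf_clusters = {mid: cl.cluster_id for cl in clusters for mid in cl.member_ids}

    # --- synteny --------------------------------------------------------------
    if cfg.run_synteny and lcbs:
        pairs = sc.intersect_igs_lcbs(all_igs, lcbs)
        species_map = {g.genome_id: g.species_label for g in genomes}
        blocks = sc.build_syn_igs(pairs, all_igs, ismorfs, coding_clusters,
                                  orf_clusters, species_map)
        synigs_rows = []
        for b in blocks:
            for genome_id, ig_id in b.member_igs:
                for cluster in sorted(b.clusters_present):
                    synigs_rows.append({
                        "synigs_id": b.synigs_id, "block_id": b.block_id,
                        "genome_id": genome_id, "ig_id": ig_id,
                        "species_label": species_map.get(genome_id, ""),
                        "cluster_id": cluster,
                        "intact": b.intact_flags[cluster].get(genome_id, False)})
        write_tsv(synigs_rows, outdir / "synigs_table.tsv", "synigs_table")
        turnover = sc.turnover_profile(blocks)
        write_tsv(turnover.to_dict("records"), outdir / "turnover_table.tsv",
                  "turnover_table")
        all_intact = (float((turnover["fraction_intact"] == 1.0).mean())
                      if len(turnover) else None)
        report["stages"]["synteny"] = {
            "n_syn_igs": len(blocks),
            "n_turnover_rows": int(len(turnover)),
            "fraction_all_intact": all_intact}

    # --- genomic context ------------------------------------------------------
    if cfg.run_context:
        ig_by_id = {ig.ig_id: ig for ig in all_igs}
        records = [sc.classify_orientation(o, ig_by_id[o.ig_id]) for o in ismorfs]
        write_tsv([{
            "orf_id": r.orf_id, "strand": r.strand,
            "upstream_relation": r.upstream_relation,
            "downstream_relation": r.downstream_relation,
            "dist_upstream": r.dist_upstream if r.dist_upstream is not None else "",
            "dist_downstream": r.dist_downstream if r.dist_downstream is not None else "",
            "near_downstream": r.near_downstream, "overlap_1_4": r.overlap_1_4,
        } for r in records], outdir / "context_table.tsv", "context_table")
        if len(records) >= 10:
            enrich = sc.orientation_enrichment(records, seed=cfg.seed)
            with open(outdir / "orientation_enrichment.json", "w") as handle:
                json.dump(enrich, handle, indent=2, sort_keys=True)
            report["stages"]["context"] = {
                "n_records": len(records),
                "downstream_collinear_fraction":
                    enrich["downstream_collinear"]["fraction"],
                "upstream_divergent_fraction":
                    enrich["upstream_divergent"]["fraction"]}
        else:
            report["stages"]["context"] = {"n_records": len(records)}

    # --- sequence properties --------------------------------------------------
    if cfg.run_props:
        rows = []
        for o in ismorfs:
            cds = cds_map[o.orf_id]
            gc = (cds.count("G") + cds.count("C")) / len(cds)
            rows.append({"id": o.orf_id, "length": len(o.protein),
                         "gravy": seqprops.gravy(o.protein), "gc_source": gc})
        write_tsv(rows, outdir / "props_table.tsv", "props_table")
        report["stages"]["props"] = {"n_proteins": len(rows)}

    report["classification_summary"] = {
        "n_clusters_scored": len(scores),
        "n_coding": len(coding_clusters),
        "coding_fraction": len(coding_clusters) / len(scores) if scores else None,
    }
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as handle:
        for stage, counts in report["stages"].items():
            handle.write(f"{stage}: {counts}\n")
    return report


def _write_scores(scores, path: Path) -> None:
    write_tsv([{
        "cluster_id": s.cluster_id, "dN": s.dN, "dS": s.dS, "Kd": s.Kd,
        "dnds": s.dnds, "n_pairs_total": s.n_pairs_total,
        "n_pairs_used": s.n_pairs_used, "flags": ",".join(s.flags),
    } for s in scores], path, "score_table")
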