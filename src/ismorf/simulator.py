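"""Synthetic multi-species genomes and microprotein clusters with truth.

The generator emulates the statistical structure the analysis assumes:
AT-rich intergenic regions, conserved coding ismORFs evolving under
purifying selection, and neutral decoy ORFs with matched composition.

Planted clusters evolve on a star tree by acceptance-rejection: single
nucleotide changes are proposed at a rate calibrated so the expected
synonymous divergence per lineage equals ``branch_scale``; synonymous
proposals are always accepted, nonsynonymous ones with probability
``omega``, and stop-creating ones rejected.  This gives direct control of
the realized dN/dS target; it is a simulator, not an inference model.

Every genome follows the same coordinate layout (filler genes alternating
with IGs that embed the planted/decoy ORFs at homologous offsets), so the
locally-collinear-block truth table spans the homologous IGs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .calibration_classify import klet_shuffle
from .clustering import MicroproteinCluster
from .codon_evolution import CODON_AA, SENSE_CODONS, STOPS_T11
from .io_formats import (
    AnnotatedGenome,
    ConfigurationError,
    FeatureRecord,
    GenomeSequence,
    translate_cds,
    write_fasta,
    write_gff,
    write_tsv,
)
from .synteny_context import LcbBlock

GENE_LEN = 300
IG_PAD = 30
#: stop codons in all three frames; contains no start codon on either strand
FRAME_GUARD = "TAAATAAATAA"


@dataclass
class SimConfig:
    n_species: int = 6
    ig_gc: float = 0.3
    genome_len: int = 60000
    n_planted_coding: int = 30
    n_decoys: int = 30
    omega: float = 0.1
    branch_scale: float = 0.1
    orf_len_range: tuple[int, int] = (15, 70)
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 < self.ig_gc < 1.0):
            raise ConfigurationError("ig_gc must be in (0, 1)")
        if self.omega < 0:
            raise ConfigurationError("omega must be >= 0")
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _random_sense_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Sense codons drawn from the iid-nucleotide distribution at the given GC."""
    p_nt = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    weights = np.array([p_nt[c[0]] * p_nt[c[1]] * p_nt[c[2]] for c in SENSE_CODONS])
    weights /= weights.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n, p=weights)
    return [SENSE_CODONS[i] for i in idx]


def _ancestral_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random sense codons + TAA (length 3*n_codons + 3)."""
    body = _random_sense_codons(rng, n_codons - 1, gc)
    return "ATG" + "".join(body) + "TAA"


def _evolve_lineage(
    cds: str,
    omega: float,
    branch_scale: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """One star-tree lineage; returns (sequence, n_syn_accepted, n_nonsyn_accepted).

    The start codon and the terminal stop are immutable.  The number of
    proposals is Poisson with mean mutable_nt * branch_scale: a proposal
    picks a uniform position and a uniform alternative, so the chance it is
    synonymous is S/L (S = synonymous sites, L = mutable length) and the
    expected accepted synonymous changes per synonymous site equal
    ``branch_scale``.
    """
    coding = list(cds[:-3])              # excludes the stop codon
    mutable_lo, mutable_hi = 3, len(coding)
    n_mutable = mutable_hi - mutable_lo
    n_proposals = rng.poisson(n_mutable * branch_scale)
    n_syn = n_nonsyn = 0
    for _ in range(n_proposals):
        pos = int(rng.integers(mutable_lo, mutable_hi))
        current = coding[pos]
        alt = "ACGT".replace(current, "")[int(rng.integers(3))]
        codon_start = (pos // 3) * 3
        old_codon = "".join(coding[codon_start:codon_start + 3])
        new_codon = old_codon[:pos - codon_start] + alt + old_codon[pos - codon_start + 1:]
        if new_codon in STOPS_T11:
            continue
        if CODON_AA[new_codon] == CODON_AA[old_codon]:
            coding[pos] = alt
            n_syn += 1
        elif rng.random() < omega:
            coding[pos] = alt
            n_nonsyn += 1
    return "".join(coding) + cds[-3:], n_syn, n_nonsyn


def simulate_cluster(
    n_members: int,
    n_codons: int,
    omega: float,
    branch_scale: float,
    seed: int | np.random.Generator,
    gc: float = 0.5,
    cluster_id: str = "sim_cluster",
    member_prefix: str = "m",
    ancestor: str | None = None,
) -> tuple[MicroproteinCluster, dict]:
    """Simulate a microprotein cluster evolving under purifying selection.

    Members descend independently from a common ancestral CDS on a star
    tree.  ``omega`` is the acceptance probability of nonsynonymous
    proposals (the realized dN/dS target); ``omega > 1`` is rejected since
    positive selection is not representable in this acceptance scheme.
    Returns the cluster (with trivial, gap-free protein and codon
    alignments) and a truth record of realized substitution counts.
    """
    if n_members < 3:
        raise ValueError("n_members must be >= 3")
    if not (15 <= n_codons <= 70):
        raise ValueError("n_codons must be within [15, 70]")
    if omega > 1.0:
        raise ValueError("omega > 1 (positive selection) is not simulated")
    if omega < 0.0 or branch_scale < 0.0:
        raise ValueError("omega and branch_scale must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = ancestor if ancestor is not None else _ancestral_cds(rng, n_codons, gc)
    members: dict[str, str] = {}
    truth_members = {}
    for i in range(n_members):
        mid = f"{member_prefix}{i}"
        cds, n_syn, n_nonsyn = _evolve_lineage(anc, omega, branch_scale, rng)
        members[mid] = cds
        truth_members[mid] = {"n_syn": n_syn, "n_nonsyn": n_nonsyn}
    proteins = {mid: translate_cds(cds) for mid, cds in members.items()}
    codon_msa = {mid: cds[:-3] for mid, cds in members.items()}
    protein_msa = dict(proteins)
    rep = max(proteins, key=lambda m: (len(proteins[m]), m))
    cluster = MicroproteinCluster(
        cluster_id=cluster_id,
        member_ids=list(members),
        representative_id=rep,
        proteins=proteins,
        cds=members,
        protein_msa=protein_msa,
        codon_msa=codon_msa,
    )
    truth = {"cluster_id": cluster_id, "ancestor": anc, "omega": omega,
             "branch_scale": branch_scale, "members": truth_members}
    return cluster, truth


def _decoy_ancestor(planted_ancestor: str, rng: np.random.Generator) -> str:
    """Neutral decoy ancestor: a k-let (k=3) shuffle of a planted ancestor.

    The internal region is shuffled; internal stop codons arising from the
    shuffle are replaced with random sense codons so the decoy remains a
    findable ORF, and the canonical start/stop are restored.
    """
    internal = planted_ancestor[3:-3]
    shuffled = klet_shuffle(internal, k=3, seed=rng)
    codons = [shuffled[i:i + 3] for i in range(0, len(shuffled), 3)]
    for i, codon in enumerate(codons):
        if codon in STOPS_T11:
            codons[i] = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
    return "ATG" + "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# whole-genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    orfs: pd.DataFrame            # orf_id, cluster_id, kind, genome_id, contig_id, start, end, strand
    lcbs: list[LcbBlock]
    clusters: dict[str, MicroproteinCluster]


def simulate_genomes(cfg: SimConfig) -> tuple[list[AnnotatedGenome], SimTruth]:
    """Generate ``n_species`` annotated genomes with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    if (cfg.n_planted_coding > 0 or cfg.n_decoys > 0) and cfg.n_species < 3:
        raise ConfigurationError("planting clusters requires n_species >= 3")

    lo, hi = cfg.orf_len_range
    planted: list[tuple[str, MicroproteinCluster]] = []
    planted_ancestors: list[str] = []
    for i in range(cfg.n_planted_coding):
        n_codons = int(rng.integers(lo, hi + 1))
        cluster, truth_rec = simulate_cluster(
            n_members=cfg.n_species, n_codons=n_codons, omega=cfg.omega,
            branch_scale=cfg.branch_scale, seed=rng, gc=cfg.ig_gc,
            cluster_id=f"planted{i}", member_prefix="sp")
        planted.append(("planted", cluster))
        planted_ancestors.append(truth_rec["ancestor"])
    decoys: list[tuple[str, MicroproteinCluster]] = []
    for i in range(cfg.n_decoys):
        if planted_ancestors:
            anc = _decoy_ancestor(planted_ancestors[i % len(planted_ancestors)], rng)
        else:
            anc = _decoy_ancestor(
                _ancestral_cds(rng, int(rng.integers(lo, hi + 1)), cfg.ig_gc), rng)
        cluster, _truth = simulate_cluster(
            n_members=cfg.n_species, n_codons=len(anc) // 3 - 1, omega=1.0,
            branch_scale=cfg.branch_scale, seed=rng, gc=cfg.ig_gc,
            cluster_id=f"decoy{i}", member_prefix="sp", ancestor=anc)
        decoys.append(("decoy", cluster))

    slots = planted + decoys
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in slots]

    genome_ids = [f"species{g}_genome" for g in range(cfg.n_species)]
    genomes: list[AnnotatedGenome] = []
    lcbs: list[LcbBlock] = []
    orf_rows: list[dict] = []

    # layout is identical across species: per slot a filler gene then the IG
    for g, genome_id in enumerate(genome_ids):
        contig_id = f"{genome_id}_c1"
        parts: list[str] = []
        features: list[FeatureRecord] = []
        pos = 0
        gene_no = 0
        for slot_idx, (kind, cluster) in enumerate(slots):
            gene_seq = _random_nt(rng, GENE_LEN, 0.5)
            features.append(FeatureRecord(
                contig_id=contig_id, start=pos, end=pos + GENE_LEN,
                strand="+" if gene_no % 2 == 0 else "-",
                feature_id=f"{genome_id}_g{gene_no}", feature_type="gene",
                product=f"filler protein {gene_no}"))
            parts.append(gene_seq)
            pos += GENE_LEN
            gene_no += 1

            member_id = cluster.member_ids[g]
            cds = cluster.cds[member_id]
            strand = strands[slot_idx]
            ig_start = pos
            left_pad = _random_nt(rng, IG_PAD, cfg.ig_gc)
            right_pad = _random_nt(rng, IG_PAD, cfg.ig_gc)
            if strand == "+":
                insert = FRAME_GUARD + cds
                orf_start = ig_start + IG_PAD + len(FRAME_GUARD)
                orf_end = orf_start + len(cds)
            else:
                insert = str(Seq(FRAME_GUARD + cds).reverse_complement())
                orf_start = ig_start + IG_PAD
                orf_end = orf_start + len(cds)
            parts.append(left_pad + insert + right_pad)
            ig_end = ig_start + len(left_pad) + len(insert) + len(right_pad)
            pos = ig_end
            lcbs.append(LcbBlock(block_id=f"lcb{slot_idx}", genome_id=genome_id,
                                 contig_id=contig_id, start=ig_start, end=ig_end,
                                 strand="+"))
            orf_rows.append({
                "orf_id": f"{genome_id}_{cluster.cluster_id}",
                "cluster_id": cluster.cluster_id, "kind": kind,
                "genome_id": genome_id, "contig_id": contig_id,
                "start": orf_start, "end": orf_end, "strand": strand,
            })
        # closing filler gene so every IG has a right flank
        gene_seq = _random_nt(rng, GENE_LEN, 0.5)
        features.append(FeatureRecord(
            contig_id=contig_id, start=pos, end=pos + GENE_LEN, strand="+",
            feature_id=f"{genome_id}_g{gene_no}", feature_type="gene",
            product=f"filler protein {gene_no}"))
        parts.append(gene_seq)
        pos += GENE_LEN
        if pos > cfg.genome_len:
            raise ConfigurationError(
                f"requested content ({pos} nt) exceeds genome_len ({cfg.genome_len})")
        if pos < cfg.genome_len:
            # trailing filler gene absorbs the remainder (avoids a giant terminal IG)
            tail = cfg.genome_len - pos
            features.append(FeatureRecord(
                contig_id=contig_id, start=pos, end=pos + tail, strand="+",
                feature_id=f"{genome_id}_tail", feature_type="gene",
                product="filler tail"))
            parts.append(_random_nt(rng, tail, 0.5))
            pos += tail
        genomes.append(AnnotatedGenome(
            genome_id=genome_id,
            contigs=[GenomeSequence(contig_id=contig_id, sequence="".join(parts),
                                    genome_id=genome_id)],
            features=features,
            species_label=f"species{g}"))

    truth = SimTruth(
        orfs=pd.DataFrame(orf_rows, columns=["orf_id", "cluster_id", "kind",
                                             "genome_id", "contig_id", "start",
                                             "end", "strand"]),
        lcbs=lcbs,
        clusters={c.cluster_id: c for _, c in slots},
    )
    return genomes, truth


def evaluate_recovery(
    truth: SimTruth,
    ismorf_table: pd.DataFrame,
    cluster_table: pd.DataFrame,
    classification_table: pd.DataFrame,
    turnover_table: pd.DataFrame | None = None,
) -> dict:
    """Compare pipeline output tables with the planted ground truth.

    A predicted cluster matches a truth cluster when the majority of its
    members coincide (by exact genomic span and strand) with that truth
    cluster's ORFs.  Reports the fraction of planted clusters recovered as
    coding, the fraction of decoy clusters called coding, and — when a
    turnover table is given — whether every recovered planted block is
    fully intact.
    """
    from collections import Counter

    coding = set(classification_table.loc[
        classification_table["label"] == "coding", "cluster_id"])
    truth_key = {(r.genome_id, r.contig_id, r.start, r.end, r.strand): r.cluster_id
                 for r in truth.orfs.itertuples()}
    orf_truth = {
        r.orf_id: truth_key.get((r.genome_id, r.contig_id, r.start, r.end, r.strand))
        for r in ismorf_table.itertuples()}
    planted_ids = set(truth.orfs.loc[truth.orfs["kind"] == "planted", "cluster_id"])
    decoy_ids = set(truth.orfs.loc[truth.orfs["kind"] == "decoy", "cluster_id"])

    match: dict[str, str | None] = {}
    for cid, grp in cluster_table.groupby("cluster_id"):
        votes = Counter(t for m in grp["member_id"] if (t := orf_truth.get(m)))
        if votes:
            top, n_top = votes.most_common(1)[0]
            match[cid] = top if n_top >= len(grp) / 2 else None
        else:
            match[cid] = None

    planted_recovered = {match[c] for c in coding if match.get(c) in planted_ids}
    decoy_coding = {match[c] for c in coding if match.get(c) in decoy_ids}
    result = {
        "n_planted": len(planted_ids),
        "n_planted_recovered": len(planted_recovered),
        "planted_recovery": (len(planted_recovered) / len(planted_ids)
                             if planted_ids else None),
        "n_decoys": len(decoy_ids),
        "n_decoys_coding": len(decoy_coding),
        "decoy_coding_fraction": (len(decoy_coding) / len(decoy_ids)
                                  if decoy_ids else None),
    }
    if turnover_table is not None:
        planted_clusters = {c for c, t in match.items() if t in planted_ids}
        rows = turnover_table[turnover_table["cluster_id"].isin(planted_clusters)]
        result["n_planted_turnover_rows"] = int(len(rows))
        result["planted_all_intact"] = (bool((rows["fraction_intact"] == 1.0).all())
                                        if len(rows) else None)
    return result


def write_simulated(genomes: list[AnnotatedGenome], truth: SimTruth,
                    outdir: str | Path) -> dict[str, Path]:
    """Write the simulated corpus in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome in genomes:
        fasta = outdir / f"{genome.genome_id}.fasta"
        gff = outdir / f"{genome.genome_id}.gff3"
        write_fasta([(c.contig_id, c.sequence) for c in genome.contigs], fasta)
        write_gff(genome.features, gff)
        paths[f"{genome.genome_id}.fasta"] = fasta
        paths[f"{genome.genome_id}.gff3"] = gff
    lcb_path = outdir / "lcbs.tsv"
    write_tsv([vars(b) for b in truth.lcbs], lcb_path, "lcb_table")
    paths["lcbs.tsv"] = lcb_path
    truth_path = outdir / "truth_orfs.tsv"
    truth.orfs.to_csv(truth_path, sep="\t", index=False)
    paths["truth_orfs.tsv"] = truth_path
    return paths
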