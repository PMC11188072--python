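"""Syntenic intergenic blocks (Syn-IGS), turnover, and genomic context.

Locally-collinear blocks (LCBs) are consumed as tabular input (block_id,
genome_id, contig_id, start, end, strand).  Intergenic regions sharing an
LCB define a Syn-IGS when (1) each intersects the LCB by at least 50% of
its length, (2) at least two distinct species are represented, and (3) at
least one member IG contains a coding-classified ismORF.  Turnover is the
fraction of member genomes with an intact ismORF of the same cluster.

Genomic context classifies each ismORF's orientation against its flanking
genes (collinear / convergent downstream; collinear / divergent upstream)
and measures the strand-aware gaps, flagging stop-to-start proximity
(gap <= 10 nt) and short 1-4 nt overlaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intergenic_orfs import IntergenicRegion, IsmOrf
from .io_formats import FeatureRecord

logger = logging.getLogger("ismorf")

LCB_MIN_FRACTION = 0.5
NEAR_GAP_MAX = 10
OVERLAP_RANGE = (-4, -1)


@dataclass
class LcbBlock:
    block_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"LCB {self.block_id}: start >= end")


def read_lcb_table(path: str | Path) -> list[LcbBlock]:
    """Read a tabular LCB file (block_id, genome_id, contig_id, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    return [LcbBlock(str(r.block_id), str(r.genome_id), str(r.contig_id),
                     int(r.start), int(r.end), str(r.strand))
            for r in df.itertuples(index=False)]


@dataclass
class SynIgsBlock:
    synigs_id: str
    block_id: str
    member_igs: list[tuple[str, str]]              # (genome_id, ig_id)
    species_set: set[str]
    clusters_present: set[str]
    intact_flags: dict[str, dict[str, bool]]       # cluster_id -> genome_id -> intact


@dataclass
class ContextRecord:
    orf_id: str
    strand: str
    upstream_relation: str      # collinear | divergent | none
    downstream_relation: str    # collinear | convergent | none
    dist_upstream: int | None
    dist_downstream: int | None
    near_downstream: bool
    overlap_1_4: bool


# ---------------------------------------------------------------------------
# Syn-IGS construction
# ---------------------------------------------------------------------------

def intersect_igs_lcbs(
    igs: list[IntergenicRegion],
    lcbs: list[LcbBlock],
    min_fraction: float = LCB_MIN_FRACTION,
) -> list[tuple[str, str, float]]:
    """(ig_id, block_id, fraction) pairs with overlap/IG length >= min_fraction.

    An IG may match multiple blocks; all matches are reported.
    """
    known_contigs = {(ig.genome_id, ig.contig_id) for ig in igs}
    by_contig: dict[tuple[str, str], list[IntergenicRegion]] = {}
    for ig in igs:
        by_contig.setdefault((ig.genome_id, ig.contig_id), []).append(ig)
    out = []
    for lcb in lcbs:
        key = (lcb.genome_id, lcb.contig_id)
        if key not in known_contigs:
            logger.warning("intersect_igs_lcbs: LCB %s references unknown contig %s/%s",
                           lcb.block_id, lcb.genome_id, lcb.contig_id)
            continue
        for ig in by_contig.get(key, []):
            ov = min(ig.end, lcb.end) - max(ig.start, lcb.start)
            if ov <= 0:
                continue
            frac = ov / ig.length
            if frac >= min_fraction:
                out.append((ig.ig_id, lcb.block_id, frac))
    return out


def build_syn_igs(
    pairs: list[tuple[str, str, float]],
    igs: list[IntergenicRegion],
    ismorfs: list[IsmOrf],
    coding_clusters: set[str],
    orf_clusters: dict[str, str],
    species_of_genome: dict[str, str] | None = None,
) -> list[SynIgsBlock]:
    """Group IGs by LCB and keep blocks passing the Syn-IGS filters.

    ``orf_clusters`` maps orf_id -> cluster_id for clustered ismORFs;
    ``coding_clusters`` is the set of coding-classified cluster ids.  A
    genome's intact flag for a cluster is set when one of its member IGs
    fully contains an ismORF of that cluster.
    """
    ig_by_id = {ig.ig_id: ig for ig in igs}
    species_of_genome = species_of_genome or {}
    # orfs fully contained in their parent IG, by IG
    orfs_by_ig: dict[str, list[IsmOrf]] = {}
    for orf in ismorfs:
        orfs_by_ig.setdefault(orf.ig_id, []).append(orf)

    members_by_block: dict[str, list[str]] = {}
    for ig_id, block_id, _frac in pairs:
        members_by_block.setdefault(block_id, [])
        if ig_id not in members_by_block[block_id]:
            members_by_block[block_id].append(ig_id)

    blocks: list[SynIgsBlock] = []
    counter = 0
    for block_id in sorted(members_by_block):
        member_ids = members_by_block[block_id]
        member_igs = [(ig_by_id[i].genome_id, i) for i in member_ids]
        species = {species_of_genome.get(g, g.split("_")[0]) for g, _ in member_igs}
        if len(species) < 2:
            continue
        clusters_present: set[str] = set()
        intact: dict[str, dict[str, bool]] = {}
        has_coding = False
        for genome_id, ig_id in member_igs:
            ig = ig_by_id[ig_id]
            for orf in orfs_by_ig.get(ig_id, []):
                cluster = orf_clusters.get(orf.orf_id)
                if cluster is None:
                    continue
                fully_inside = orf.start >= ig.start and orf.end <= ig.end
                if cluster in coding_clusters:
                    has_coding = True
                    clusters_present.add(cluster)
                    if fully_inside:
                        intact.setdefault(cluster, {})[genome_id] = True
        if not has_coding:
            continue
        for cluster in clusters_present:
            flags = intact.setdefault(cluster, {})
            for genome_id, _ in member_igs:
                flags.setdefault(genome_id, False)
        counter += 1
        blocks.append(SynIgsBlock(
            synigs_id=f"synigs{counter}",
            block_id=block_id,
            member_igs=member_igs,
            species_set=species,
            clusters_present=clusters_present,
            intact_flags=intact,
        ))
    return blocks


def turnover_profile(blocks: list[SynIgsBlock]) -> pd.DataFrame:
    """Per (Syn-IGS, cluster) fraction of member genomes with an intact ismORF.

    Multi-cluster blocks are reported once per cluster.  The summary
    fraction of rows with fraction_intact == 1.0 is available from the
    returned frame.
    """
    rows = []
    for block in blocks:
        genomes = sorted({g for g, _ in block.member_igs})
        for cluster in sorted(block.clusters_present):
            flags = block.intact_flags.get(cluster, {})
            n_intact = sum(1 for g in genomes if flags.get(g, False))
            rows.append({
                "synigs_id": block.synigs_id,
                "cluster_id": cluster,
                "n_genomes": len(genomes),
                "n_intact": n_intact,
                "fraction_intact": n_intact / len(genomes) if genomes else 0.0,
            })
    return pd.DataFrame(rows, columns=["synigs_id", "cluster_id", "n_genomes",
                                       "n_intact", "fraction_intact"])


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------

def classify_orientation(orf: IsmOrf, ig: IntergenicRegion) -> ContextRecord:
    """Orientation and strand-aware distances of an ismORF to its flanks.

    For a '+' ismORF the upstream gene is the left flank and downstream the
    right flank; reversed for '-'.  Gaps are measured along the ismORF's
    reading direction (negative = overlap).  ``near_downstream`` flags a
    stop-to-downstream-start gap of 0..10 nt; ``overlap_1_4`` a 1-4 nt
    overlap with the downstream gene.
    """
    if orf.strand == "+":
        up_gene, down_gene = ig.left_gene, ig.right_gene
        dist_up = orf.start - up_gene.end if up_gene else None
        dist_down = down_gene.start - orf.end if down_gene else None
    else:
        up_gene, down_gene = ig.right_gene, ig.left_gene
        dist_up = up_gene.start - orf.end if up_gene else None
        dist_down = orf.start - down_gene.end if down_gene else None

    if up_gene is None:
        up_rel = "none"
    else:
        up_rel = "collinear" if up_gene.strand == orf.strand else "divergent"
    if down_gene is None:
        down_rel = "none"
    else:
        down_rel = "collinear" if down_gene.strand == orf.strand else "convergent"

    near = dist_down is not None and 0 <= dist_down <= NEAR_GAP_MAX
    overlap = dist_down is not None and OVERLAP_RANGE[0] <= dist_down <= OVERLAP_RANGE[1]
    return ContextRecord(
        orf_id=orf.orf_id,
        strand=orf.strand,
        upstream_relation=up_rel,
        downstream_relation=down_rel,
        dist_upstream=dist_up,
        dist_downstream=dist_down,
        near_downstream=near,
        overlap_1_4=overlap,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def orientation_enrichment(
    records: list[ContextRecord],
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Enrichment of orientation classes against chance expectation.

    For each relation class (downstream collinear, upstream divergent) the
    observed count among records with a defined relation is compared with a
    fair-coin expectation (the flanking gene strand carries no information
    about the ismORF strand): an exact two-sided binomial p, a Fisher
    exact p on the observed-vs-expected 2x2, and a strand-permutation p
    from ``n_perm`` resamples.  Also reports the fraction co-directed with
    both neighbors ("head-to-tail").
    """
    if len(records) < 10:
        raise ValueError("need >= 10 context records")
    rng = np.random.default_rng(seed)
    report: dict = {}

    def one_class(n_hit: int, n_tot: int) -> dict:
        entry = {"observed": n_hit, "n": n_tot, "expected": n_tot / 2.0}
        if n_tot == 0:
            entry.update({"fraction": None, "binom_p": None,
                          "fisher_p": None, "perm_p": None})
            return entry
        entry["fraction"] = n_hit / n_tot
        entry["binom_p"] = float(stats.binomtest(n_hit, n_tot, 0.5).pvalue)
        exp_hi = n_tot // 2
        entry["fisher_p"] = fisher_exact_2x2(
            [[n_hit, n_tot - n_hit], [exp_hi, n_tot - exp_hi]])
        draws = rng.binomial(n_tot, 0.5, size=n_perm)
        obs_dev = abs(n_hit - n_tot / 2.0)
        entry["perm_p"] = float(
            (1 + np.sum(np.abs(draws - n_tot / 2.0) >= obs_dev)) / (1 + n_perm))
        return entry

    down_defined = [r for r in records if r.downstream_relation != "none"]
    up_defined = [r for r in records if r.upstream_relation != "none"]
    report["downstream_collinear"] = one_class(
        sum(1 for r in down_defined if r.downstream_relation == "collinear"),
        len(down_defined))
    report["upstream_divergent"] = one_class(
        sum(1 for r in up_defined if r.upstream_relation == "divergent"),
        len(up_defined))
    both = [r for r in records
            if r.downstream_relation != "none" and r.upstream_relation != "none"]
    report["head_to_tail_fraction"] = (
        sum(1 for r in both if r.downstream_relation == "collinear"
            and r.upstream_relation == "collinear") / len(both) if both else None)
    return report
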