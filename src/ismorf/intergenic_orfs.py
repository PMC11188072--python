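"""Intergenic region extraction and intergenic smORF (ismORF) prediction.

An intergenic region (IG) is a maximal interval of a contig not covered by
any annotated gene (strand-agnostic union).  Candidate ORFs are scanned on
both strands with bacterial start codons ATG/GTG/TTG; an ismORF is an ORF
lying at least 80% within a single IG and encoding a 15-70 aa protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import (
    START_CODONS,
    STOP_CODONS,
    AnnotatedGenome,
    FeatureRecord,
    GenomeSequence,
    translate_cds,
)

logger = logging.getLogger("ismorf")

IG_MIN_LEN = 33
IG_MAX_LEN = 1500
ORF_MIN_NT = 45          # coding length excluding the stop codon
PROTEIN_MIN_AA = 15
PROTEIN_MAX_AA = 70
MIN_CONTAINMENT = 0.8


@dataclass
class IntergenicRegion:
    ig_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    left_gene: FeatureRecord | None = None
    right_gene: FeatureRecord | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateOrf:
    contig_id: str
    start: int           # genomic, 0-based; span includes the stop codon
    end: int
    strand: str
    start_codon: str
    protein: str


@dataclass
class IsmOrf:
    orf_id: str
    ig_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    start_codon: str
    protein: str
    containment: float

    def __post_init__(self) -> None:
        assert (self.end - self.start) % 3 == 0
        assert len(self.protein) == (self.end - self.start) // 3 - 1
        assert self.protein[0] == "M"

    @property
    def cds_length(self) -> int:
        return self.end - self.start - 3


# ---------------------------------------------------------------------------
# intergenic extraction
# ---------------------------------------------------------------------------

def _merged_gene_intervals(features: Iterable[FeatureRecord]) -> list[tuple[int, int]]:
    ivals = sorted((f.start, f.end) for f in features)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def complement_intervals(gene_intervals: Sequence[tuple[int, int]], contig_len: int) -> list[tuple[int, int]]:
    """Maximal intervals of [0, contig_len) not covered by the gene union."""
    gaps = []
    cursor = 0
    for s, e in gene_intervals:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < contig_len:
        gaps.append((cursor, contig_len))
    return gaps


def extract_intergenic(
    genome: AnnotatedGenome,
    min_len: int = IG_MIN_LEN,
    max_len: int = IG_MAX_LEN,
    feature_types: Iterable[str] = ("gene",),
) -> list[IntergenicRegion]:
    """Intergenic regions of every contig, length-filtered to [min_len, max_len].

    Overlapping gene features are unioned.  Terminal intervals are kept for
    linear contigs; on circular contigs the wrap-around segment is joined
    into one region (recorded with start > end handled by concatenation at
    sequence-extraction time is avoided here: the joined region is reported
    with the linear start of the tail segment and end = tail + head length,
    coordinates taken modulo contig length by consumers).
    """
    wanted = set(feature_types)
    igs: list[IntergenicRegion] = []
    counter = 0
    for contig in genome.contigs:
        feats = [f for f in genome.features
                 if f.contig_id == contig.contig_id and f.feature_type in wanted]
        feats.sort(key=lambda f: (f.start, f.end))
        merged = _merged_gene_intervals(feats)
        gaps = complement_intervals(merged, len(contig))
        # join wrap-around gap on circular contigs
        if (contig.circular and len(gaps) >= 2 and gaps[0][0] == 0
                and gaps[-1][1] == len(contig) and merged):
            head, tail = gaps[0], gaps[-1]
            gaps = gaps[1:-1] + [(tail[0], tail[1] + (head[1] - head[0]))]

        def flank(pos: int, side: str) -> FeatureRecord | None:
            if side == "left":
                cands = [f for f in feats if f.end <= pos]
                return max(cands, key=lambda f: f.end) if cands else None
            cands = [f for f in feats if f.start >= pos]
            return min(cands, key=lambda f: f.start) if cands else None

        for s, e in gaps:
            if not (min_len <= e - s <= max_len):
                continue
            counter += 1
            right_pos = e if e <= len(contig) else e % len(contig)
            igs.append(
                IntergenicRegion(
                    ig_id=f"{genome.genome_id}_ig{counter}",
                    genome_id=genome.genome_id,
                    contig_id=contig.contig_id,
                    start=s,
                    end=e,
                    left_gene=flank(s, "left"),
                    right_gene=flank(right_pos, "right"),
                )
            )
    return igs


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def _scan_forward(seq: str, min_nt: int, starts: set[str], stops: set[str],
                  all_starts: bool) -> list[tuple[int, int, str]]:
    """ORFs on the forward strand of ``seq`` as (start, end, start_codon)."""
    out = []
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" in codon:
                open_starts.clear()
                continue
            if codon in stops:
                for i, s in enumerate(open_starts):
                    if pos - s >= min_nt:
                        out.append((s, pos + 3, seq[s:s + 3]))
                    if not all_starts:
                        break
                open_starts.clear()
            elif codon in starts:
                open_starts.append(pos)
    return out


def find_orfs(
    seq: GenomeSequence,
    min_nt: int = ORF_MIN_NT,
    starts: Iterable[str] = START_CODONS,
    stops: Iterable[str] = STOP_CODONS,
    all_starts: bool = False,
) -> list[CandidateOrf]:
    """Scan both strands for start->in-frame-stop ORFs.

    The reported span includes the stop codon; ``min_nt`` applies to the
    coding length (span - 3).  By default only the longest ORF per stop is
    emitted (nested starts suppressed); ``all_starts=True`` emits every
    start.  Codons containing N break the scan.
    """
    starts, stops = set(starts), set(stops)
    s = seq.sequence
    results: list[CandidateOrf] = []
    for g_start, g_end, codon in _scan_forward(s, min_nt, starts, stops, all_starts):
        protein = translate_cds(s[g_start:g_end])
        results.append(CandidateOrf(seq.contig_id, g_start, g_end, "+", codon, protein))
    rc = str(Seq(s).reverse_complement())
    n = len(s)
    for r_start, r_end, codon in _scan_forward(rc, min_nt, starts, stops, all_starts):
        protein = translate_cds(rc[r_start:r_end])
        results.append(CandidateOrf(seq.contig_id, n - r_end, n - r_start, "-", codon, protein))
    results.sort(key=lambda o: (o.start, o.end, o.strand))
    return results


# ---------------------------------------------------------------------------
# ismORF selection
# ---------------------------------------------------------------------------

def select_ismorfs(
    orfs: Sequence[CandidateOrf],
    igs: Sequence[IntergenicRegion],
    genome_id: str = "",
    min_fraction: float = MIN_CONTAINMENT,
    min_aa: int = PROTEIN_MIN_AA,
    max_aa: int = PROTEIN_MAX_AA,
) -> list[IsmOrf]:
    """ORFs contained >= ``min_fraction`` in a single IG, 15-70 aa.

    Each kept ORF is linked to the IG of maximal overlap; an ORF matching
    several IGs is reported once (the ``-u`` semantics).
    """
    trees: dict[str, IntervalTree] = {}
    for ig in igs:
        trees.setdefault(ig.contig_id, IntervalTree()).addi(ig.start, ig.end, ig)
    kept: list[IsmOrf] = []
    counter = 0
    for orf in orfs:
        if not (min_aa <= len(orf.protein) <= max_aa):
            continue
        tree = trees.get(orf.contig_id)
        if tree is None:
            continue
        best: tuple[int, IntergenicRegion] | None = None
        for hit in tree.overlap(orf.start, orf.end):
            ig: IntergenicRegion = hit.data
            ov = min(orf.end, ig.end) - max(orf.start, ig.start)
            if best is None or ov > best[0] or (ov == best[0] and ig.ig_id < best[1].ig_id):
                best = (ov, ig)
        if best is None:
            continue
        frac = best[0] / (orf.end - orf.start)
        if frac < min_fraction:
            continue
        counter += 1
        kept.append(
            IsmOrf(
                orf_id=f"{genome_id or best[1].genome_id}_orf{counter}",
                ig_id=best[1].ig_id,
                genome_id=genome_id or best[1].genome_id,
                contig_id=orf.contig_id,
                start=orf.start,
                end=orf.end,
                strand=orf.strand,
                start_codon=orf.start_codon,
                protein=orf.protein,
                containment=frac,
            )
        )
    return kept


def filter_known_protein_hits(
    ismorfs: Sequence[IsmOrf],
    hits: pd.DataFrame,
    evalue_max: float = 1e-5,
    identity_min: float = 50.0,
    aln_frac_min: float = 0.5,
) -> tuple[list[IsmOrf], pd.DataFrame]:
    """Drop ismORFs with a strong hit to an annotated protein.

    A hit removes its ismORF when evalue < ``evalue_max`` AND percent
    identity > ``identity_min`` AND alignment length > ``aln_frac_min`` x
    protein length (all three conditions jointly).  Returns survivors and a
    removal report.
    """
    by_id = {o.orf_id: o for o in ismorfs}
    removed: set[str] = set()
    rows = []
    if len(hits):
        for _, hit in hits.iterrows():
            orf = by_id.get(hit["orf_id"])
            if orf is None:
                logger.warning("filter_known_protein_hits: unknown orf_id %r ignored",
                               hit["orf_id"])
                continue
            if (hit["evalue"] < evalue_max
                    and hit["pct_identity"] > identity_min
                    and hit["aln_len"] > aln_frac_min * len(orf.protein)):
                if orf.orf_id not in removed:
                    removed.add(orf.orf_id)
                    rows.append({"orf_id": orf.orf_id, "evalue": hit["evalue"],
                                 "pct_identity": hit["pct_identity"],
                                 "aln_len": hit["aln_len"]})
    survivors = [o for o in ismorfs if o.orf_id not in removed]
    report = pd.DataFrame(rows, columns=["orf_id", "evalue", "pct_identity", "aln_len"])
    return survivors, report


def extract_orf_cds(genome: AnnotatedGenome, orf: IsmOrf) -> str:
    """Nucleotide CDS of an ismORF including its stop codon."""
    seq = genome.contig(orf.contig_id).sequence[orf.start:orf.end]
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
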