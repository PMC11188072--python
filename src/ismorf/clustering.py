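"""Greedy identity clustering of microproteins and codon-alignment building.

The clustering emulates the acceptance rules of greedy incremental
clustering at 50% identity / 95% coverage / 0.95 length ratio (CD-HIT-style
semantics): sequences are processed longest-first, each joining the
best-identity existing cluster whose representative it matches, otherwise
founding a new cluster.  It is a behavioral emulation of those thresholds,
not a bit-compatible CD-HIT reimplementation — no short-word prefilter is
used and the full pairwise alignment is always computed.

Identity is defined as identical aligned residues divided by the length of
the shorter sequence; coverage as the aligned core (first to last aligned
pair) over the longer sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

from .io_formats import translate_cds

logger = logging.getLogger("ismorf")

MIN_CLUSTER_MEMBERS = 3
MIN_SEQ_AA = 6           # sequences shorter than this are rejected (-l 5)
IDENTITY_DEFAULT = 0.5
COV_LONG_DEFAULT = 0.95
LEN_RATIO_DEFAULT = 0.95

GAP_OPEN = 10
GAP_EXTEND = 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    # free end gaps: global alignment without penalizing terminal overhangs
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, coverage_of_longer) from a global protein alignment.

    identity = identical residues / len(shorter);
    coverage  = span from first to last aligned residue pair, measured on
    the longer sequence, / len(longer).
    """
    if not seq_a or not seq_b:
        return 0.0, 0.0
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    identities = 0
    for (ta, tb), (qa, qb) in zip(aln.aligned[0], aln.aligned[1]):
        identities += sum(1 for x, y in zip(seq_a[ta:tb], seq_b[qa:qb]) if x == y)
    shorter = min(len(seq_a), len(seq_b))
    longer = max(len(seq_a), len(seq_b))
    if not len(aln.aligned[0]):
        return 0.0, 0.0
    # aligned core on the longer sequence
    if len(seq_a) >= len(seq_b):
        core = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    else:
        core = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    return identities / shorter, core / longer


@dataclass
class MicroproteinCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    proteins: dict[str, str]
    cds: dict[str, str] = field(default_factory=dict)
    protein_msa: dict[str, str] | None = None
    codon_msa: dict[str, str] | None = None
    genus_label: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    proteins: dict[str, str],
    identity: float = IDENTITY_DEFAULT,
    cov_long: float = COV_LONG_DEFAULT,
    len_ratio: float = LEN_RATIO_DEFAULT,
    min_members: int = MIN_CLUSTER_MEMBERS,
    genus_label: str = "",
    cds: dict[str, str] | None = None,
) -> list[MicroproteinCluster]:
    """Greedy incremental clustering against cluster representatives.

    Sequences are sorted by length descending (ties by id) and each joins
    the best-identity existing cluster whose representative satisfies all
    three acceptance rules; ties on identity go to the earliest-founded
    cluster.  Clusters with fewer than ``min_members`` members are
    discarded.  Sequences shorter than 6 aa are rejected with a warning.
    """
    order = sorted(proteins, key=lambda i: (-len(proteins[i]), i))
    reps: list[str] = []          # representative id per cluster, founding order
    members: list[list[str]] = []
    n_rejected = 0
    for seq_id in order:
        seq = proteins[seq_id]
        if len(seq) < MIN_SEQ_AA:
            n_rejected += 1
            continue
        best_idx, best_ident = -1, -1.0
        for idx, rep_id in enumerate(reps):
            rep = proteins[rep_id]
            # representative is never shorter (length-descending order)
            if len(seq) / len(rep) < len_ratio:
                continue
            ident, cov = pairwise_identity(rep, seq)
            if ident >= identity and cov >= cov_long and ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx >= 0:
            members[best_idx].append(seq_id)
        else:
            reps.append(seq_id)
            members.append([seq_id])
    if n_rejected:
        logger.warning("greedy_cluster: rejected %d sequences shorter than %d aa",
                       n_rejected, MIN_SEQ_AA)
    clusters = []
    counter = 0
    for rep_id, mem in zip(reps, members):
        if len(mem) < min_members:
            continue
        counter += 1
        prefix = f"{genus_label}_" if genus_label else ""
        clusters.append(
            MicroproteinCluster(
                cluster_id=f"{prefix}cluster{counter}",
                member_ids=list(mem),
                representative_id=rep_id,
                proteins={i: proteins[i] for i in mem},
                cds={i: cds[i] for i in mem} if cds else {},
                genus_label=genus_label,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _pairwise_align(ref: str, seq: str) -> tuple[str, str]:
    aln = _ALIGNER.align(ref, seq)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def center_star_align(proteins: dict[str, str], center_id: str) -> dict[str, str]:
    """Center-star progressive MSA seeded on ``center_id``.

    Every member is pairwise-aligned to the center; gaps inserted into the
    center by any pairwise alignment are propagated to all rows
    ("once a gap, always a gap").
    """
    center = proteins[center_id]
    others = [i for i in proteins if i != center_id]
    # master gapped center and per-member gapped rows, iteratively merged
    master = center
    rows: dict[str, str] = {}
    pair_alns: dict[str, tuple[str, str]] = {}
    for mid in others:
        pair_alns[mid] = _pairwise_align(center, proteins[mid])

    def merge(master_row: str, ref_gapped: str) -> tuple[str, list[str]]:
        """Merge two gapped versions of the center into a common gapping.

        Returns the merged center and per-input expansion maps encoded as
        operation strings ('B' both advance, 'M' only master, 'R' only ref).
        """
        ops = []
        merged = []
        i = j = 0
        while i < len(master_row) or j < len(ref_gapped):
            a = master_row[i] if i < len(master_row) else None
            b = ref_gapped[j] if j < len(ref_gapped) else None
            if a is not None and a != "-" and b is not None and b != "-":
                ops.append("B")
                merged.append(a)
                i += 1
                j += 1
            elif a == "-":
                ops.append("M")
                merged.append("-")
                i += 1
            else:
                ops.append("R")
                merged.append(b if b is not None else "-")
                j += 1
        return "".join(merged), ops

    for mid in others:
        ref_gapped, _seq_gapped = pair_alns[mid]
        master, ops = merge(master, ref_gapped)
        # rows already in the master frame gain gaps wherever 'R' inserted;
        # the new row gains gaps wherever 'M' inserted
        for prev in list(rows):
            rows[prev] = _apply_ops(rows[prev], ops, consume="M")
        rows[mid] = _apply_ops(pair_alns[mid][1], ops, consume="R")
    result = {center_id: master}
    result.update(rows)
    # sanity: equal lengths, no all-gap columns
    width = len(master)
    assert all(len(r) == width for r in result.values())
    return {i: result[i] for i in proteins}


def _apply_ops(row: str, ops: list[str], consume: str) -> str:
    """Expand ``row`` to the merged gapping.

    ``consume``: which op letter consumes a character of ``row`` besides 'B'
    ('M' for rows already in the master frame, 'R' for the new pairwise row).
    """
    out = []
    i = 0
    for op in ops:
        if op == "B" or op == consume:
            out.append(row[i] if i < len(row) else "-")
            i += 1
        else:
            out.append("-")
    return "".join(out)


def align_cluster(
    cluster: MicroproteinCluster,
    method: str = "builtin",
    external_path: str | Path | None = None,
) -> dict[str, str]:
    """Protein MSA for a cluster.

    ``builtin``: center-star progressive alignment seeded on the
    representative (BLOSUM62, gap open 10 / extend 1).  ``external``:
    ingest a user-supplied aligned FASTA and validate that every member is
    present with a matching ungapped sequence.
    """
    if cluster.size < 2:
        raise ValueError("align_cluster requires >= 2 members")
    if method == "builtin":
        msa = center_star_align(cluster.proteins, cluster.representative_id)
        msa = _drop_allgap_columns(msa)
    elif method == "external":
        if external_path is None:
            raise ValueError("external method requires external_path")
        msa = {}
        for rec in SeqIO.parse(str(external_path), "fasta"):
            msa[rec.id] = str(rec.seq).upper()
        for mid, protein in cluster.proteins.items():
            if mid not in msa:
                raise ValueError(f"external alignment missing member {mid!r}")
            if msa[mid].replace("-", "") != protein:
                raise ValueError(f"external alignment sequence mismatch for member {mid!r}")
        widths = {len(r) for r in msa.values()}
        if len(widths) != 1:
            raise ValueError("external alignment rows have unequal lengths")
        msa = {mid: msa[mid] for mid in cluster.proteins}
        msa = _drop_allgap_columns(msa)
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    cluster.protein_msa = msa
    return msa


def _drop_allgap_columns(msa: dict[str, str]) -> dict[str, str]:
    rows = list(msa.values())
    keep = [k for k in range(len(rows[0])) if any(r[k] != "-" for r in rows)]
    return {i: "".join(r[k] for k in keep) for i, r in msa.items()}


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def backtranslate_codon_alignment(
    protein_msa: dict[str, str],
    cds_map: dict[str, str],
) -> dict[str, str]:
    """Expand each protein MSA row to its source codons (pal2nal-style).

    Each residue column becomes its codon; each protein gap becomes '---'.
    A trailing stop codon on the CDS is stripped before mapping.  The CDS
    must translate (table 11, initiator as M) to the stored protein.
    """
    codon_msa: dict[str, str] = {}
    for mid, row in protein_msa.items():
        if mid not in cds_map:
            raise ValueError(f"no CDS for member {mid!r}")
        cds = cds_map[mid]
        protein = row.replace("-", "")
        if len(cds) == 3 * len(protein) + 3:
            cds = cds[:-3]
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"member {mid!r}: CDS length {len(cds_map[mid])} does not match "
                f"protein length {len(protein)}"
            )
        translated = translate_cds(cds)
        for k, (aa_obs, aa_exp) in enumerate(zip(translated, protein)):
            if aa_obs != aa_exp:
                raise ValueError(
                    f"member {mid!r}: codon {cds[3 * k:3 * k + 3]} at position {k} "
                    f"translates to {aa_obs!r}, protein has {aa_exp!r}"
                )
        out = []
        pos = 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos:3 * pos + 3])
                pos += 1
        codon_msa[mid] = "".join(out)
    return codon_msa
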