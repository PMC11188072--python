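"""Pairwise and cluster-level evolutionary rates on codon alignments.

Implements the statistics behind the coding-potential score:

* ``p``-distance and the Kimura two-parameter (K2P) distance, separating
  transition (P) and transversion (Q) proportions:
  ``k2p = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]``.
* Nei-Gojobori (1986) synonymous/nonsynonymous counting with the
  Jukes-Cantor correction ``d = -3/4 * ln(1 - 4/3 * p)``.  Synonymous site
  fractions enumerate the three single-nucleotide changes at each codon
  position (changes creating stop codons count as nonsynonymous); between
  codons differing at d positions, differences are averaged over all d!
  substitution pathways, excluding pathways passing through stop codons
  (when every pathway passes through a stop, the changes are counted as
  nonsynonymous).

Gapped or ambiguous positions/codons are excluded pairwise (pairwise
deletion); saturated distances are flagged non-finite (+inf) and excluded
from cluster means with counts reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOPS_T11 = frozenset({"TAA", "TAG", "TGA"})
ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOPS_T11)
CODON_AA = {c: str(Seq(c).translate(table=11)) for c in ALL_CODONS}


class UndefinedPairError(ValueError):
    """A pair with zero comparable sites/codons."""


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


# ---------------------------------------------------------------------------
# nucleotide distances
# ---------------------------------------------------------------------------

@dataclass
class PairwiseRates:
    id_a: str
    id_b: str
    sites_nt: int = 0
    P: float = 0.0
    Q: float = 0.0
    p_dist: float = 0.0
    k2p: float = 0.0
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    pS: float = 0.0
    pN: float = 0.0
    dS: float = 0.0
    dN: float = 0.0


def pairwise_nt_distance(row_a: str, row_b: str) -> tuple[float, float, float, float]:
    """(P, Q, p_dist, k2p) between two equal-length aligned rows.

    Positions where either row has a gap or N are excluded.  k2p is +inf
    when the K2P logarithm arguments are non-positive (saturation).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    sites = transitions = transversions = 0
    for a, b in zip(row_a, row_b):
        if a not in NUCLEOTIDES or b not in NUCLEOTIDES:
            continue
        sites += 1
        if a != b:
            if _is_transition(a, b):
                transitions += 1
            else:
                transversions += 1
    if sites == 0:
        raise UndefinedPairError("zero comparable sites")
    P = transitions / sites
    Q = transversions / sites
    p_dist = P + Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        k2p = math.inf
    else:
        k2p = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, p_dist, k2p


# ---------------------------------------------------------------------------
# Nei-Gojobori counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3).

    At each position the three single-nucleotide changes are enumerated;
    the synonymous fraction of the position contributes to the total.
    Changes creating stop codons are counted as nonsynonymous.
    """
    aa = CODON_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in STOPS_T11 and CODON_AA[mutant] == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over substitution pathways.

    Pathways passing through stop codons are excluded; if all pathways do,
    the differences are counted as nonsynonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    d = len(diff_positions)
    if d == 0:
        return 0.0, 0.0
    pathway_counts: list[tuple[int, int]] = []
    for perm in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in perm:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOPS_T11:
                valid = False
                break
            if CODON_AA[nxt] == CODON_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            pathway_counts.append((sd, nd))
    if not pathway_counts:
        return 0.0, float(d)
    sd_mean = sum(x[0] for x in pathway_counts) / len(pathway_counts)
    nd_mean = sum(x[1] for x in pathway_counts) / len(pathway_counts)
    return sd_mean, nd_mean


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _iter_codon_pairs(row_a: str, row_b: str):
    if len(row_a) != len(row_b) or len(row_a) % 3 != 0:
        raise ValueError("rows must be codon-aligned and equal-length")
    for k in range(0, len(row_a), 3):
        ca, cb = row_a[k:k + 3], row_b[k:k + 3]
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            continue
        if ca in STOPS_T11 or cb in STOPS_T11:
            continue
        yield ca, cb


def ng86_pair(row_a: str, row_b: str) -> tuple[float, float, float, float, float, float, float, float]:
    """(S, N, Sd, Nd, pS, pN, dS, dN) between two aligned codon rows."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for ca, cb in _iter_codon_pairs(row_a, row_b):
        n_codons += 1
        s_a += syn_sites(ca)
        s_b += syn_sites(cb)
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise UndefinedPairError("zero comparable codons")
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else (0.0 if sd == 0 else math.inf)
    pN = nd / N if N > 0 else (0.0 if nd == 0 else math.inf)
    dS = _jc_correct(pS) if math.isfinite(pS) else math.inf
    dN = _jc_correct(pN) if math.isfinite(pN) else math.inf
    return S, N, sd, nd, pS, pN, dS, dN


def pairwise_rates(id_a: str, id_b: str, row_a: str, row_b: str) -> PairwiseRates:
    """All pairwise statistics for a codon-aligned pair."""
    P, Q, p_dist, k2p = pairwise_nt_distance(row_a, row_b)
    sites = sum(1 for a, b in zip(row_a, row_b)
                if a in NUCLEOTIDES and b in NUCLEOTIDES)
    S, N, Sd, Nd, pS, pN, dS, dN = ng86_pair(row_a, row_b)
    return PairwiseRates(id_a=id_a, id_b=id_b, sites_nt=sites, P=P, Q=Q,
                         p_dist=p_dist, k2p=k2p, S=S, N=N, Sd=Sd, Nd=Nd,
                         pS=pS, pN=pN, dS=dS, dN=dN)


# ---------------------------------------------------------------------------
# cluster-level scores
# ---------------------------------------------------------------------------

@dataclass
class EvolScores:
    cluster_id: str
    dN: float
    dS: float
    Kd: float
    dnds: float
    n_pairs_total: int
    n_pairs_used: int
    flags: list[str] = field(default_factory=list)

    def is_finite(self) -> bool:
        return all(math.isfinite(v) for v in (self.dN, self.dS, self.Kd, self.dnds))


def cluster_evolscores(cluster, kd_metric: str = "k2p") -> EvolScores | None:
    """Cluster means of the finite pairwise dN, dS and Kd over unique pairs.

    ``dnds`` is the ratio of cluster means (0 when both are 0, +inf when
    only dS is 0).  ``kd_metric`` binds Kd to the K2P-corrected distance
    (default) or the raw p-distance.  Returns None when every pair is
    undefined (cluster scored as missing).
    """
    if kd_metric not in ("k2p", "p"):
        raise ValueError(f"kd_metric must be 'k2p' or 'p', got {kd_metric!r}")
    msa = cluster.codon_msa
    if msa is None or len(msa) < 2:
        raise ValueError("cluster has no codon alignment with >= 2 rows")
    ids = list(msa)
    dn_vals: list[float] = []
    ds_vals: list[float] = []
    kd_vals: list[float] = []
    n_total = 0
    n_used = 0
    n_undefined = 0
    for i, j in itertools.combinations(range(len(ids)), 2):
        n_total += 1
        try:
            rates = pairwise_rates(ids[i], ids[j], msa[ids[i]], msa[ids[j]])
        except UndefinedPairError:
            n_undefined += 1
            continue
        kd = rates.k2p if kd_metric == "k2p" else rates.p_dist
        if math.isfinite(rates.dN):
            dn_vals.append(rates.dN)
        if math.isfinite(rates.dS):
            ds_vals.append(rates.dS)
        if math.isfinite(kd):
            kd_vals.append(kd)
        if math.isfinite(rates.dN) and math.isfinite(rates.dS) and math.isfinite(kd):
            n_used += 1
    if n_undefined == n_total:
        return None
    flags = []
    dn = sum(dn_vals) / len(dn_vals) if dn_vals else math.inf
    ds = sum(ds_vals) / len(ds_vals) if ds_vals else math.inf
    kd = sum(kd_vals) / len(kd_vals) if kd_vals else math.inf
    if not dn_vals:
        flags.append("dN_saturated")
    if not ds_vals:
        flags.append("dS_saturated")
    if not kd_vals:
        flags.append("Kd_saturated")
    if math.isfinite(dn) and math.isfinite(ds):
        if ds == 0.0:
            dnds = 0.0 if dn == 0.0 else math.inf
            if dn > 0.0:
                flags.append("dnds_undefined")
        else:
            dnds = dn / ds
    else:
        dnds = math.inf
        flags.append("dnds_undefined")
    return EvolScores(cluster_id=cluster.cluster_id, dN=dn, dS=ds, Kd=kd,
                      dnds=dnds, n_pairs_total=n_total, n_pairs_used=n_used,
                      flags=flags)
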