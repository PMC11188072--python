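"""Shuffled null construction, threshold calibration, and classification.

The null model preserves local sequence composition exactly: each member
CDS is shuffled preserving its k-mer counts (k=3 by default) via
Euler-path sampling on the (k-1)-mer multigraph, so the shuffled corpus
retains codon-composition biases while destroying homology-driven
substitution structure.  Thresholds on the cluster-level rates are
calibrated with bootstrap 1%/99% quantiles of positive (annotated small
protein) and shuffled-null score distributions; the fixed default
thresholds are dN<0.2, dS<0.7, Kd<0.2 and dN/dS<0.5 (all strict).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .clustering import MicroproteinCluster
from .codon_evolution import EvolScores, cluster_evolscores

logger = logging.getLogger("ismorf")

#: feature encoding for non-finite rate statistics fed to the forest
NONFINITE_SENTINEL = 100.0
RF_N_TREES = 500
KLET_DEFAULT = 3


@dataclass
class ThresholdSet:
    dn_max: float = 0.2
    ds_max: float = 0.7
    kd_max: float = 0.2
    dnds_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("dn_max", "ds_max", "kd_max", "dnds_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# k-let-preserving shuffle
# ---------------------------------------------------------------------------

def klet_shuffle(seq: str, k: int = KLET_DEFAULT, seed: int | np.random.Generator = 0) -> str:
    """Uniform sample from the sequences with the same k-mer counts as ``seq``.

    Euler-path sampling on the (k-1)-mer multigraph: a uniformly random
    arborescence rooted at the terminal (k-1)-mer designates each vertex's
    last exit edge, the remaining out-edges are randomly ordered, and the
    Eulerian walk from the initial (k-1)-mer spells the shuffle.  The first
    and last (k-1)-mers are preserved.  Sequences shorter than k are
    returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(seq)
    if n < k or n == 0:
        return seq
    if k == 1:
        chars = list(seq)
        rng.shuffle(chars)
        return "".join(chars)

    # multigraph of (k-1)-mers; one edge per k-mer occurrence
    edges: dict[str, list[str]] = {}
    for i in range(n - k + 1):
        u, v = seq[i:i + k - 1], seq[i + 1:i + k]
        edges.setdefault(u, []).append(v)
    start = seq[: k - 1]
    terminal = seq[n - k + 1:]

    vertices = [v for v in edges if v != terminal]
    # rejection-sample a uniform arborescence toward the terminal vertex:
    # each non-terminal vertex picks a uniformly random out-edge as its
    # designated last exit; accept when all picks chain to the terminal
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != terminal:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    # dead end (vertex with no out-edges other than terminal
                    # reached) or cycle -> reject unless terminal reached
                    ok = cur == terminal
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    pools: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last_edge:
            rest.remove(last_edge[v])
        order = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        if v in last_edge:
            order.append(last_edge[v])
        pools[v] = order

    out = [start]
    cur = start
    for _ in range(n - k + 1):
        nxt = pools[cur].pop(0)
        out.append(nxt[-1])
        cur = nxt
    return "".join(out)


def build_shuffled_null(
    clusters: list[MicroproteinCluster],
    seed: int,
    k: int = KLET_DEFAULT,
    realign: bool = False,
) -> list[MicroproteinCluster]:
    """Shuffled-null clusters: each member CDS independently k-let-shuffled.

    By default the shuffled nucleotide rows are treated as codon rows
    aligned by the original codon-MSA gap pattern, preserving pairability
    without re-invoking the aligner.  With ``realign=True`` the shuffled
    sequences are translated where possible and re-aligned (falling back
    to the gap-pattern route for untranslatable shuffles).
    """
    rng = np.random.default_rng(seed)
    null_clusters: list[MicroproteinCluster] = []
    for cluster in clusters:
        if cluster.codon_msa is None:
            raise ValueError(f"cluster {cluster.cluster_id} has no codon alignment")
        shuffled_cds = {mid: klet_shuffle(cds, k=k, seed=rng)
                        for mid, cds in cluster.cds.items()}
        codon_msa = {}
        for mid, row in cluster.codon_msa.items():
            src = shuffled_cds[mid]
            if len(src) == len(row.replace("-", "")) + 3:
                src = src[:-3]     # strip (shuffled) stop-codon worth of tail
            out = []
            pos = 0
            for ch in row:
                if ch == "-":
                    out.append("-")
                else:
                    out.append(src[pos])
                    pos += 1
            codon_msa[mid] = "".join(out)
        null = copy.copy(cluster)
        null.cluster_id = f"{cluster.cluster_id}_shuffled"
        null.cds = shuffled_cds
        null.proteins = dict(cluster.proteins)
        null.codon_msa = codon_msa
        null.protein_msa = None
        null_clusters.append(null)
    return null_clusters


# ---------------------------------------------------------------------------
# bootstrap calibration
# ---------------------------------------------------------------------------

@dataclass
class QuantileReport:
    statistic: str
    q_low: float
    q_high: float
    B: int
    n_values: int
    q_low_spread: tuple[float, float] = (0.0, 0.0)
    q_high_spread: tuple[float, float] = (0.0, 0.0)


def bootstrap_quantiles(
    values: list[float],
    q_low: float = 0.01,
    q_high: float = 0.99,
    B: int = 1000,
    seed: int = 0,
    statistic: str = "",
) -> QuantileReport:
    """Bootstrap estimates of extreme quantiles.

    ``B`` resamples with replacement; per-resample empirical quantiles with
    linear interpolation; reports the mean of each quantile and its central
    95% spread across resamples.  Requires at least 20 finite values.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    finite = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if finite.size < 20:
        raise ValueError(f"need >= 20 finite values, got {finite.size}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, finite.size, size=(B, finite.size))
    samples = finite[idx]
    lows = np.quantile(samples, q_low, axis=1)
    highs = np.quantile(samples, q_high, axis=1)
    return QuantileReport(
        statistic=statistic,
        q_low=float(lows.mean()),
        q_high=float(highs.mean()),
        B=B,
        n_values=int(finite.size),
        q_low_spread=(float(np.quantile(lows, 0.025)), float(np.quantile(lows, 0.975))),
        q_high_spread=(float(np.quantile(highs, 0.025)), float(np.quantile(highs, 0.975))),
    )


def calibration_report(
    positive_scores: list[EvolScores],
    shuffled_scores: list[EvolScores],
    B: int = 1000,
    seed: int = 0,
) -> list[QuantileReport]:
    """Bootstrap 1%/99% quantiles of dN, dS, Kd for both score sources."""
    reports = []
    for label, scores in (("positives", positive_scores), ("shuffled", shuffled_scores)):
        for stat in ("dN", "dS", "Kd"):
            vals = [getattr(s, stat) for s in scores]
            reports.append(
                bootstrap_quantiles(vals, B=B, seed=seed, statistic=f"{label}:{stat}")
            )
    return reports


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_thresholds(scores: EvolScores, thresholds: ThresholdSet | None = None) -> str:
    """'coding' iff all four statistics fall strictly below their cutoffs.

    Any non-finite statistic makes the cluster noncoding.
    """
    t = thresholds or ThresholdSet()
    if not scores.is_finite():
        return "noncoding"
    if (scores.dN < t.dn_max and scores.dS < t.ds_max
            and scores.Kd < t.kd_max and scores.dnds < t.dnds_max):
        return "coding"
    return "noncoding"


def score_features(scores: EvolScores, include_dnds: bool = True) -> list[float]:
    """Feature vector [dN, dS, Kd, dnds] with non-finite values encoded
    as the documented sentinel."""
    feats = [scores.dN, scores.dS, scores.Kd]
    if include_dnds:
        feats.append(scores.dnds)
    return [v if math.isfinite(v) else NONFINITE_SENTINEL for v in feats]


@dataclass
class RateClassifier:
    model: RandomForestClassifier
    feature_names: list[str]
    seed: int
    split: float
    include_dnds: bool = True

    def predict(self, scores: list[EvolScores]) -> list[str]:
        X = np.asarray([score_features(s, self.include_dnds) for s in scores])
        return ["coding" if y == 1 else "noncoding" for y in self.model.predict(X)]


def train_rate_classifier(
    positives: list[EvolScores],
    negatives: list[EvolScores],
    split: float = 0.7,
    seed: int = 0,
    include_dnds: bool = True,
) -> tuple[RateClassifier, dict[str, float]]:
    """Random forest on rate features with a train/test split.

    Features are [dN, dS, Kd] plus optionally the dN/dS ratio; 500 trees;
    metrics (precision, recall, AUROC) evaluated on the held-out split.
    """
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("each class needs >= 10 members")
    X = np.asarray([score_features(s, include_dnds) for s in positives + negatives])
    y = np.asarray([1] * len(positives) + [0] * len(negatives))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y)
    model = RandomForestClassifier(n_estimators=RF_N_TREES, random_state=seed)
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    y_prob = model.predict_proba(X_te)[:, 1]
    metrics = {
        "precision": float(precision_score(y_te, y_pred, zero_division=0)),
        "recall": float(recall_score(y_te, y_pred, zero_division=0)),
        "auroc": float(roc_auc_score(y_te, y_prob)),
        "n_test": int(len(y_te)),
    }
    feature_names = ["dN", "dS", "Kd"] + (["dnds"] if include_dnds else [])
    clf = RateClassifier(model=model, feature_names=feature_names, seed=seed,
                         split=split, include_dnds=include_dnds)
    return clf, metrics


def evaluate_agreement(labels_a: dict[str, str], labels_b: dict[str, str]) -> tuple[float, dict]:
    """Overlap of 'coding' calls between two labelings of the same ids.

    Returns |coding in both| / |coding in either| and a confusion table.
    Two empty coding sets agree at 1.0 (warned).
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("labelings cover different id sets")
    coding_a = {i for i, v in labels_a.items() if v == "coding"}
    coding_b = {i for i, v in labels_b.items() if v == "coding"}
    union = coding_a | coding_b
    confusion = {
        "both_coding": len(coding_a & coding_b),
        "only_a": len(coding_a - coding_b),
        "only_b": len(coding_b - coding_a),
        "neither": len(labels_a) - len(union),
    }
    if not union:
        logger.warning("evaluate_agreement: both coding sets empty; overlap defined as 1.0")
        return 1.0, confusion
    return len(coding_a & coding_b) / len(union), confusion


def apply_rnacode_table(
    table,
    p_max: float = 0.05,
    identity_max: float = 90.0,
) -> set[str]:
    """Select cluster ids from an externally produced coding-potential table.

    Applies P < ``p_max`` and the sequence-diversity filter (pairwise
    identity < ``identity_max`` percent) to a DataFrame with columns
    (cluster_id, p_value, pct_identity).  The external tool itself is not
    re-implemented.
    """
    mask = (table["p_value"] < p_max) & (table["pct_identity"] < identity_max)
    return set(table.loc[mask, "cluster_id"])
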