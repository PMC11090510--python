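"""Iterative cluster-align-merge of homolog families.

Candidate McrB/McrC homologs are clustered greedily at a fractional-identity
threshold, each cluster is aligned around its centroid (center-star), column
frequency profiles are built, and clusters whose profile-to-profile score to
self-score ratio exceeds the merge threshold are merged by single linkage.
The procedure runs for a fixed number of iterations (default three) with
early stop once a round merges nothing. Representatives for tree building
come from a second greedy clustering at a higher identity threshold, and a
neighbor-joining tree over 1 - identity distances is the desk-scale stand-in
for external maximum-likelihood tree builders (adapter seam).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core import AA_ALPHABET, ProteinRecord

PROFILE_ALPHABET = AA_ALPHABET + "-"
_AA_INDEX = {a: i for i, a in enumerate(PROFILE_ALPHABET)}

SeqMapping = Mapping[str, Union[str, ProteinRecord]]


def _as_seqs(seqs: SeqMapping) -> dict[str, str]:
    return {
        k: (v.sequence if isinstance(v, ProteinRecord) else str(v))
        for k, v in seqs.items()
    }


def make_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def _align_pair(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None):
    aligner = aligner or _DEFAULT_ALIGNER
    alignment = aligner.align(a, b)[0]
    return alignment[0], alignment[1]


def pairwise_identity(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Fraction of identical columns under BLOSUM62 global alignment
    (gap open 11, extend 1)."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    row_a, row_b = _align_pair(a, b, aligner)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return matches / len(row_a)


@dataclass(frozen=True)
class Profile:
    """Per-column residue frequencies (20 aa + gap) of an alignment."""

    columns: np.ndarray  # shape (length, 21), rows sum to 1

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != len(PROFILE_ALPHABET):
            raise ValueError("profile columns must be (length, 21)")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.columns.shape[0]


@dataclass
class SeqCluster:
    """A cluster of homologs: members, centroid, and (once computed) the
    center-star alignment and its column-frequency profile."""

    members: list[str]
    centroid: str
    alignment: Optional[list[str]] = None
    profile: Optional[Profile] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.centroid not in self.members:
            raise ValueError("centroid must be a member of the cluster")
        if self.alignment is not None:
            if len(self.alignment) != len(self.members):
                raise ValueError("alignment rows must parallel members")
            lengths = {len(r) for r in self.alignment}
            if len(lengths) > 1:
                raise ValueError("alignment rows must have equal length")


def greedy_cluster(seqs: SeqMapping, threshold: float) -> list[SeqCluster]:
    """Incremental greedy clustering at a fractional-identity threshold.

    Sequences are processed longest-first (ties by ID) for determinism;
    each joins the first existing cluster whose centroid identity is at
    least the threshold, otherwise it founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    plain = _as_seqs(seqs)
    order = sorted(plain, key=lambda k: (-len(plain[k]), k))
    clusters: list[SeqCluster] = []
    for sid in order:
        joined = False
        for cluster in clusters:
            if pairwise_identity(plain[cluster.centroid], plain[sid]) >= threshold:
                cluster.members.append(sid)
                joined = True
                break
        if not joined:
            clusters.append(SeqCluster(members=[sid], centroid=sid))
    return clusters


def align_cluster(cluster: SeqCluster, seqs: SeqMapping) -> SeqCluster:
    """Center-star progressive alignment around the cluster centroid.

    De-aligning any row reproduces the member's input sequence exactly.
    """
    plain = _as_seqs(seqs)
    centroid_seq = plain[cluster.centroid]
    L = len(centroid_seq)
    per_member: list[tuple[list[str], list[str]]] = []  # (ins[0..L], char[0..L-1])
    for member in cluster.members:
        if member == cluster.centroid:
            per_member.append(([""] * (L + 1), list(centroid_seq)))
            continue
        row_c, row_m = _align_pair(centroid_seq, plain[member])
        ins: list[str] = [""] * (L + 1)
        chars: list[str] = []
        ci = 0
        for cc, mc in zip(row_c, row_m):
            if cc == "-":
                ins[ci] += mc
            else:
                chars.append(mc)
                ci += 1
        per_member.append((ins, chars))
    master_ins = [max(len(pm[0][i]) for pm in per_member) for i in range(L + 1)]
    rows: list[str] = []
    for ins, chars in per_member:
        parts: list[str] = []
        for i in range(L):
            parts.append(ins[i].ljust(master_ins[i], "-"))
            parts.append(chars[i])
        parts.append(ins[L].ljust(master_ins[L], "-"))
        rows.append("".join(parts))
    return replace(cluster, alignment=rows, profile=None)


def build_profile(alignment: list[str], pseudocount: float = 0.01) -> Profile:
    """Column frequency vectors over 20 aa + gap with additive pseudocounts.
    'X' residues contribute uniformly to the 20 amino-acid bins."""
    if not alignment:
        raise ValueError("empty alignment")
    L = len(alignment[0])
    counts = np.full((L, len(PROFILE_ALPHABET)), pseudocount, dtype=float)
    for row in alignment:
        for i, ch in enumerate(row):
            if ch == "X":
                counts[i, :20] += 1.0 / 20.0
            else:
                counts[i, _AA_INDEX[ch]] += 1.0
    counts /= counts.sum(axis=1, keepdims=True)
    return Profile(columns=counts)


def cross_score(p: Profile, q: Profile) -> float:
    """Best ungapped sliding-offset sum of column dot products."""
    a, b = p.columns, q.columns
    la, lb = len(a), len(b)
    best = -np.inf
    for offset in range(-(lb - 1), la):
        lo_a = max(0, offset)
        hi_a = min(la, offset + lb)
        if hi_a <= lo_a:
            continue
        seg_a = a[lo_a:hi_a]
        seg_b = b[lo_a - offset : hi_a - offset]
        best = max(best, float(np.einsum("ij,ij->", seg_a, seg_b)))
    return best


def self_score(p: Profile) -> float:
    return cross_score(p, p)


def _ensure_profiled(cluster: SeqCluster, seqs: SeqMapping) -> SeqCluster:
    if cluster.alignment is None:
        cluster = align_cluster(cluster, seqs)
    if cluster.profile is None:
        cluster = replace(cluster, profile=build_profile(cluster.alignment))
    return cluster


def merge_round(
    clusters: list[SeqCluster],
    seqs: SeqMapping,
    ratio_threshold: float = 0.1,
    denominator: str = "max",
) -> list[SeqCluster]:
    """Merge clusters whose pairwise score to self-score ratio is strictly
    greater than the threshold, by single linkage over the pair graph.

    The ratio denominator is the max of the two self-scores by default
    (conservative: avoids absorption of short profiles); ``min`` is the
    permissive alternative. Merged clusters are re-aligned and re-profiled.
    The cluster count never increases.
    """
    if denominator not in ("max", "min"):
        raise ValueError("denominator must be 'max' or 'min'")
    plain = _as_seqs(seqs)
    clusters = [_ensure_profiled(c, plain) for c in clusters]
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    selves = [self_score(c.profile) for c in clusters]
    for i in range(n):
        for j in range(i + 1, n):
            denom = (
                max(selves[i], selves[j])
                if denominator == "max"
                else min(selves[i], selves[j])
            )
            ratio = cross_score(clusters[i].profile, clusters[j].profile) / denom
            if ratio > ratio_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[SeqCluster] = []
    for indices in groups.values():
        if len(indices) == 1:
            merged.append(clusters[indices[0]])
            continue
        members: list[str] = []
        for i in indices:
            members.extend(clusters[i].members)
        centroid = sorted(members, key=lambda m: (-len(plain[m]), m))[0]
        cluster = SeqCluster(members=members, centroid=centroid)
        merged.append(_ensure_profiled(cluster, plain))
    merged.sort(key=lambda c: c.centroid)
    return merged


def iterate_clustering(
    seqs: SeqMapping,
    threshold: float = 0.5,
    iterations: int = 3,
    ratio_threshold: float = 0.1,
    denominator: str = "max",
    return_history: bool = False,
):
    """Cluster, align, profile, then merge — repeated ``iterations`` times,
    stopping early once a round merges nothing. Deterministic."""
    plain = _as_seqs(seqs)
    if not plain:
        return ([], []) if return_history else []
    clusters = [_ensure_profiled(c, plain) for c in greedy_cluster(plain, threshold)]
    history = [len(clusters)]
    for _ in range(iterations):
        merged = merge_round(
            clusters, plain, ratio_threshold=ratio_threshold, denominator=denominator
        )
        history.append(len(merged))
        if len(merged) == len(clusters):
            clusters = merged
            break
        clusters = merged
    return (clusters, history) if return_history else clusters


def select_representatives(seqs: SeqMapping, threshold: float = 0.9) -> list[str]:
    """Cluster at a high identity threshold and return the sorted centroid
    of each cluster."""
    return sorted(c.centroid for c in greedy_cluster(seqs, threshold))


def identity_distance_matrix(seqs: SeqMapping, ids: Optional[list[str]] = None):
    """Symmetric 1 - identity distance matrix over the given sequences."""
    from skbio import DistanceMatrix

    plain = _as_seqs(seqs)
    ids = ids or sorted(plain)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(plain[ids[i]], plain[ids[j]])
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids)


def nj_tree_from_distances(dm):
    """Unrooted neighbor-joining tree from a distance matrix. Exact on
    additive matrices. The 2-leaf base case splits the single distance."""
    from skbio import TreeNode
    from skbio.tree import nj

    if dm.shape[0] < 2:
        raise ValueError("a tree requires at least 2 leaves")
    if dm.shape[0] == 2:
        a, b = dm.ids
        d = float(dm[0, 1])
        root = TreeNode()
        root.extend([TreeNode(name=a, length=d / 2), TreeNode(name=b, length=d / 2)])
        return root
    return nj(dm)


def nj_tree(representatives: SeqMapping):
    """Neighbor-joining tree over representatives with 1 - identity
    distances."""
    plain = _as_seqs(representatives)
    if len(plain) < 2:
        raise ValueError("a tree requires at least 2 representatives")
    return nj_tree_from_distances(identity_distance_matrix(plain))
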