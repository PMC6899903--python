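"""Effective sequence count (Meff) by greedy 62%-identity clustering.

Meff is the number of clusters obtained when the alignment rows are
clustered greedily at a 62% sequence-identity threshold, in the style of
CD-HIT: sequences are sorted by descending non-gap length (ties broken by
input order), the longest founds the first cluster, and each subsequent
sequence joins the first existing representative it is at least
``threshold`` identical to, otherwise it founds a new cluster.

Identity between two aligned rows is the number of identical non-gap
matches divided by the smaller of the two rows' non-gap lengths (the CD-HIT
convention); it is 0 if either row is all gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import GAP, Msa

DEFAULT_IDENTITY = 0.62


@dataclass
class ClusterResult:
    """Greedy clustering assignment.

    ``assignment[s]`` is the cluster index of sequence ``s`` (input order);
    ``representatives`` holds the founding row index of each cluster.
    """

    assignment: np.ndarray
    representatives: list[int]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of identical non-gap positions over the shorter non-gap length."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"aligned rows differ in length: {a.shape} vs {b.shape}")
    na = int(np.sum(a != GAP))
    nb = int(np.sum(b != GAP))
    denom = min(na, nb)
    if denom == 0:
        return 0.0
    matches = int(np.sum((a == b) & (a != GAP)))
    return matches / denom


def _identity_matrix(codes: np.ndarray) -> np.ndarray:
    """All-pairs identity fractions for the rows of an encoded alignment."""
    nongap = codes != GAP
    lengths = nongap.sum(axis=1)
    # matches[s,t] = #{i : codes[s,i] == codes[t,i] != gap}
    oh = np.stack([(codes == a) for a in range(GAP)]).astype(np.float64)  # 20,N,L
    matches = np.einsum("anl,aml->nm", oh, oh)
    denom = np.minimum.outer(lengths, lengths).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / denom, 0.0)
    return ident


def greedy_cluster(msa: Msa, threshold: float = DEFAULT_IDENTITY) -> ClusterResult:
    """CD-HIT-style greedy incremental clustering of alignment rows."""
    codes = msa.codes
    n = codes.shape[0]
    nongap_len = (codes != GAP).sum(axis=1)
    # descending non-gap length, ties by input order
    order = np.lexsort((np.arange(n), -nongap_len))
    ident = _identity_matrix(codes)

    assignment = np.full(n, -1, dtype=np.int64)
    reps: list[int] = []
    for s in order:
        placed = False
        for ci, r in enumerate(reps):
            if ident[s, r] >= threshold:
                assignment[s] = ci
                placed = True
                break
        if not placed:
            assignment[s] = len(reps)
            reps.append(int(s))
    return ClusterResult(assignment=assignment, representatives=reps, threshold=threshold)


def compute_meff(msa: Msa, threshold: float = DEFAULT_IDENTITY) -> int:
    """Number of greedy identity clusters; always in [1, N]."""
    return greedy_cluster(msa, threshold).n_clusters
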