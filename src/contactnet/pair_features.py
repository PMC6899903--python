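"""Column and pair substitution statistics from an alignment.

Given an MSA, this module computes sequence weights (inverse 62%-identity
neighbourhood sizes), weighted single-column frequencies f_i(a), weighted
pair frequencies f_ij(a,b), the 441-channel raw covariance tensor

    cov[(a,b), i, j] = f_ij(a,b) - f_i(a) f_j(b),

plug-in mutual information in nats with its average-product correction
(APC), and the joint column entropy.  The gap is a first-class 21st state
throughout, so there are 21 x 21 = 441 residue-type pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meff import DEFAULT_IDENTITY, _identity_matrix
from .msa_io import N_STATES, Msa, one_hot

N_COV_CHANNELS = N_STATES * N_STATES  # 441


@dataclass
class ColumnStats:
    """Weighted column statistics of an alignment.

    weights : (N,) per-sequence weights, 1 / neighbourhood size
    f1 : (L, 21) weighted single-column frequencies; rows sum to 1
    f2 : (L, L, 21, 21) weighted pair frequencies; each [i, j] sums to 1
    """

    weights: np.ndarray
    f1: np.ndarray
    f2: np.ndarray


@dataclass
class PairMatrices:
    """Pairwise coupling statistics derived from :class:`ColumnStats`."""

    cov: np.ndarray  # (441, L, L)
    mi: np.ndarray  # (L, L), nats
    mi_apc: np.ndarray  # (L, L)
    joint_entropy: np.ndarray  # (L, L), nats


def sequence_weights(msa: Msa, ident_threshold: float = DEFAULT_IDENTITY) -> np.ndarray:
    """Inverse neighbourhood-size weights.

    ``weight_s = 1 / #{t : identity(s, t) >= threshold}`` (self included),
    so duplicated sequences share one unit of weight between them.
    """
    ident = _identity_matrix(msa.codes)
    neighbours = (ident >= ident_threshold).sum(axis=1)
    return 1.0 / neighbours


def column_stats(msa: Msa, weights: np.ndarray | None = None) -> ColumnStats:
    """Weighted, normalized single and pair column frequencies.

    With ``weights=None`` every sequence counts equally (unweighted
    statistics); pass :func:`sequence_weights` output for the weighted
    convention used in the assembled features.
    """
    if weights is None:
        weights = np.ones(msa.N)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (msa.N,):
        raise ValueError(f"expected {msa.N} weights, got shape {weights.shape}")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total sequence weight must be positive")

    oh = one_hot(msa)  # (N, L, 21)
    L = msa.L
    f1 = np.einsum("n,nla->la", weights, oh) / total
    flat = oh.reshape(msa.N, L * N_STATES)
    f2 = (flat * weights[:, None]).T @ flat / total  # (L*21, L*21)
    f2 = f2.reshape(L, N_STATES, L, N_STATES).transpose(0, 2, 1, 3)
    return ColumnStats(weights=weights, f1=f1, f2=f2)


def covariance_features(stats: ColumnStats) -> np.ndarray:
    """Raw covariance tensor of shape (441, L, L).

    Channel ``a * 21 + b`` holds ``f2[i,j,a,b] - f1[i,a] * f1[j,b]``, so
    channel (a, b) at (i, j) equals channel (b, a) at (j, i).
    """
    L = stats.f1.shape[0]
    outer = stats.f1[:, None, :, None] * stats.f1[None, :, None, :]
    cov = stats.f2 - outer  # (L, L, 21, 21)
    return np.ascontiguousarray(cov.transpose(2, 3, 0, 1).reshape(N_COV_CHANNELS, L, L))


def mutual_information(stats: ColumnStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plug-in MI, APC-corrected MI and joint entropy, all in nats.

    ``mi[i,j] = sum_ab f2 * ln(f2 / (f1_i(a) f1_j(b)))`` over cells with
    ``f2 > 0`` (the marginals of a positive cell are automatically
    positive, so no flooring is required).  The diagonal ``mi[i,i]`` is the
    single-column entropy.  APC subtracts ``mean_i * mean_j / mean_all``
    with the means taken over off-diagonal entries.
    """
    f1, f2 = stats.f1, stats.f2
    L = f1.shape[0]
    prod = f1[:, None, :, None] * f1[None, :, None, :]
    pos = f2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(pos, np.log(np.where(pos, f2, 1.0) / np.where(pos, prod, 1.0)), 0.0)
        log_f2 = np.where(pos, np.log(np.where(pos, f2, 1.0)), 0.0)
    mi = np.einsum("ijab,ijab->ij", f2, log_ratio)
    joint_entropy = -np.einsum("ijab,ijab->ij", f2, log_f2)
    mi = np.maximum(mi, 0.0)  # clip -1e-16-scale rounding noise

    mi_apc = _apc(mi)
    return mi, mi_apc, joint_entropy


def _apc(mi: np.ndarray) -> np.ndarray:
    """Average product correction with off-diagonal means."""
    L = mi.shape[0]
    if L < 2:
        return mi.copy()
    off = ~np.eye(L, dtype=bool)
    row_mean = (mi * off).sum(axis=1) / (L - 1)
    mean_all = mi[off].mean()
    if mean_all == 0:
        return mi.copy()
    return mi - np.outer(row_mean, row_mean) / mean_all


def pair_matrices(msa: Msa, weighted: bool = True) -> PairMatrices:
    """One-call pipeline: weights -> column stats -> covariance + MI maps."""
    w = sequence_weights(msa) if weighted else None
    stats = column_stats(msa, w)
    cov = covariance_features(stats)
    mi, mi_apc, joint_entropy = mutual_information(stats)
    return PairMatrices(cov=cov, mi=mi, mi_apc=mi_apc, joint_entropy=joint_entropy)


def write_matrix(mat: np.ndarray, path) -> None:
    """Write an L x L map as whitespace-separated text, row-major."""
    np.savetxt(path, np.asarray(mat), fmt="%.6f")


def read_matrix(path) -> np.ndarray:
    """Read a flat whitespace-separated L x L map."""
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    return mat
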