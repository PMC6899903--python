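"""Assembly of the 501-channel network input tensor.

The input to the contact network combines, for a protein of length L:

* 58 channels of alignment- and residue-level statistics: per-residue
  features (sequence profile, 3-state secondary structure, solvent
  accessibility, profile column entropy) striped horizontally and
  vertically into L x L maps, plus pairwise maps (mutual information, its
  APC-corrected form, a mean contact-potential map, and three optional
  externally computed coupling maps);
* 441 channels of raw residue-type-pair covariances;
* a sequence-separation channel and an all-ones sequence-bounds channel
  that lets the first convolution distinguish genuine zeros from zero
  padding.

The exact 58-channel layout is centralized in :func:`channel_manifest` so
consumers never hard-code channel positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_io import AMINO_ACIDS, GAP, Msa, N_STATES
from .pair_features import N_COV_CHANNELS, PairMatrices

EXTERNAL_MAPS = ("psicov", "ccmpred", "freecontact")
N_CHANNELS = 501
SEPARATION_CAP = 100

# Kyte-Doolittle hydropathy, alphabet order ARNDCQEGHILKMFPSTWYV.
_HYDROPATHY = np.array(
    [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
     3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2]
)

# Synthetic stand-in for a statistical contact-potential table: the outer
# product of normalized hydropathies, negated so that hydrophobic pairs
# (which pack in protein cores) score favourably (negative).  It is NOT a
# published knowledge-based potential; it only has to behave like one
# (symmetric, hydrophobic-pair favouring) for feature-assembly purposes.
SYNTHETIC_CONTACT_POTENTIAL = -np.outer(_HYDROPATHY, _HYDROPATHY) / (4.5 ** 2)


class FeatureError(ValueError):
    pass


@dataclass
class ResidueFeatures:
    """Per-residue (1D) features for one protein.

    profile : (L, 21) sequence profile, rows sum to 1
    ss3 : (L, 3) predicted probabilities in the order (helix, strand, coil)
    solv : (L,) predicted relative solvent accessibility in [0, 1]
    loop_mask : (L,) booleans, True where the residue is a loop
    """

    profile: np.ndarray
    ss3: np.ndarray
    solv: np.ndarray
    loop_mask: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        self.ss3 = np.asarray(self.ss3, dtype=np.float64)
        self.solv = np.asarray(self.solv, dtype=np.float64).reshape(-1)
        self.loop_mask = np.asarray(self.loop_mask, dtype=bool).reshape(-1)
        L = self.profile.shape[0]
        if self.profile.shape != (L, N_STATES):
            raise FeatureError(f"profile must be (L, {N_STATES})")
        for name, arr, shape in (
            ("ss3", self.ss3, (L, 3)),
            ("solv", self.solv, (L,)),
            ("loop_mask", self.loop_mask, (L,)),
        ):
            if arr.shape != shape:
                raise FeatureError(f"{name} has shape {arr.shape}, expected {shape}")
        if not np.allclose(self.profile.sum(axis=1), 1.0, atol=1e-6):
            raise FeatureError("profile rows must sum to 1")
        if not np.allclose(self.ss3.sum(axis=1), 1.0, atol=1e-6):
            raise FeatureError("ss3 rows must sum to 1")
        if self.solv.min() < -1e-9 or self.solv.max() > 1 + 1e-9:
            raise FeatureError("solv must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.profile.shape[0]

    def take(self, keep: np.ndarray) -> "ResidueFeatures":
        """Restriction to a subset of residues (used by loop sampling)."""
        return ResidueFeatures(
            profile=self.profile[keep],
            ss3=self.ss3[keep],
            solv=self.solv[keep],
            loop_mask=self.loop_mask[keep],
        )


@dataclass
class FeatureTensor:
    """A named-channel C x L x L input tensor."""

    data: np.ndarray
    channel_map: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise FeatureError(f"expected (C, L, L), got {self.data.shape}")
        if len(self.channel_map) != self.data.shape[0]:
            raise FeatureError("channel_map length must equal channel count")
        if len(set(self.channel_map)) != len(self.channel_map):
            raise FeatureError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise FeatureError("feature tensor contains non-finite values")

    @property
    def C(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_map.index(name)]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            data=self.data,
            channel_map=np.array(self.channel_map),
            metadata_keys=np.array(sorted(self.metadata)),
            metadata_vals=np.array([str(self.metadata[k]) for k in sorted(self.metadata)]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTensor":
        with np.load(path) as z:
            meta = dict(zip(z["metadata_keys"].tolist(), z["metadata_vals"].tolist()))
            return cls(z["data"], [str(c) for c in z["channel_map"]], meta)


def stripe_1d(values: np.ndarray) -> np.ndarray:
    """Stripe per-residue features into 2D maps.

    For an (L, k) input, returns a (2k, L, L) tensor where channel 2c is
    the horizontal stripe out[i, j] = values[i, c] and channel 2c+1 is the
    vertical stripe out[i, j] = values[j, c].
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    L, k = values.shape
    out = np.empty((2 * k, L, L))
    for c in range(k):
        out[2 * c] = np.broadcast_to(values[:, c][:, None], (L, L))
        out[2 * c + 1] = np.broadcast_to(values[:, c][None, :], (L, L))
    return out


def separation_channel(L: int, cap: int = SEPARATION_CAP) -> np.ndarray:
    """min(|i-j|, cap)/cap — symmetric, zero diagonal, saturating at cap."""
    idx = np.arange(L)
    return np.minimum(np.abs(idx[:, None] - idx[None, :]), cap) / cap


def bounds_channel(L: int) -> np.ndarray:
    """All-ones frame marking real sequence positions (vs zero padding)."""
    return np.ones((L, L))


def contact_potential_map(msa: Msa, table: np.ndarray | None = None) -> np.ndarray:
    """Profile-weighted mean contact potential for every residue pair.

    out[i, j] = sum_ab p_i(a) p_j(b) T[a, b] where p_i is the column's
    amino-acid frequency profile (gaps excluded, renormalized; all-gap
    columns contribute zero) and T is a fixed symmetric 20 x 20 table
    (default: the synthetic hydropathy-product stand-in).
    """
    if table is None:
        table = SYNTHETIC_CONTACT_POTENTIAL
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (20, 20):
        raise FeatureError("contact-potential table must be 20 x 20")
    counts = np.stack([(msa.codes == a).sum(axis=0) for a in range(GAP)], axis=1).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
    return p @ table @ p.T


def msa_profile(msa: Msa) -> np.ndarray:
    """Unweighted 21-state column frequency profile of an alignment."""
    counts = np.stack([(msa.codes == a).sum(axis=0) for a in range(N_STATES)], axis=1)
    return counts / msa.N


def profile_entropy(profile: np.ndarray) -> np.ndarray:
    """Per-column Shannon entropy of the profile, in nats."""
    p = np.asarray(profile, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def channel_manifest() -> list[str]:
    """Ordered names of all 501 channels."""
    names: list[str] = []
    for a in AMINO_ACIDS + "-":
        names += [f"profile_{a}_h", f"profile_{a}_v"]
    for s in ("H", "E", "C"):
        names += [f"ss3_{s}_h", f"ss3_{s}_v"]
    names += ["solv_h", "solv_v", "colent_h", "colent_v"]
    names += ["mi", "mi_apc", "contact_potential"]
    names += list(EXTERNAL_MAPS)
    for a in AMINO_ACIDS + "-":
        for b in AMINO_ACIDS + "-":
            names.append(f"cov_{a}{b}")
    names += ["separation", "bounds"]
    return names


def assemble_features(
    msa: Msa,
    res: ResidueFeatures,
    pm: PairMatrices,
    external: dict[str, np.ndarray] | None = None,
) -> FeatureTensor:
    """Build the full 501-channel input tensor.

    ``external`` may supply precomputed coupling maps under the keys
    ``psicov``, ``ccmpred`` and ``freecontact``; absent maps are zero-filled
    (with a warning) and recorded in the tensor metadata.
    """
    external = dict(external or {})
    unknown = set(external) - set(EXTERNAL_MAPS)
    if unknown:
        raise FeatureError(f"unknown external map(s): {sorted(unknown)}")
    L = msa.L
    if res.L != L:
        raise FeatureError(f"residue features have L={res.L}, alignment has L={L}")
    for name, mat in external.items():
        if np.asarray(mat).shape != (L, L):
            raise FeatureError(f"external map {name!r} must be {L} x {L}")
    if pm.cov.shape != (N_COV_CHANNELS, L, L):
        raise FeatureError(f"covariance block must be ({N_COV_CHANNELS}, L, L)")

    blocks = [
        stripe_1d(res.profile),
        stripe_1d(res.ss3),
        stripe_1d(res.solv),
        stripe_1d(profile_entropy(res.profile)),
        pm.mi[None],
        pm.mi_apc[None],
        contact_potential_map(msa)[None],
    ]
    missing = []
    for name in EXTERNAL_MAPS:
        if name in external:
            blocks.append(np.asarray(external[name], dtype=np.float64)[None])
        else:
            missing.append(name)
            blocks.append(np.zeros((1, L, L)))
    if missing:
        warnings.warn(
            f"external coupling map(s) {missing} not provided; zero-filled",
            stacklevel=2,
        )
    blocks += [pm.cov, separation_channel(L)[None], bounds_channel(L)[None]]
    data = np.concatenate(blocks, axis=0)
    names = channel_manifest()
    assert data.shape[0] == len(names) == N_CHANNELS
    return FeatureTensor(
        data=data,
        channel_map=names,
        metadata={"missing_external": ",".join(missing), "L": L},
    )


def read_ss2(path: str | Path) -> np.ndarray:
    """Read a PSIPRED-style ss2 file into an (L, 3) array ordered (H, E, C).

    ss2 data lines are ``index residue state pC pH pE``; header and blank
    lines are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 or not parts[0].isdigit():
                continue
            c, h, e = (float(x) for x in parts[3:6])
            rows.append((h, e, c))
    if not rows:
        raise FeatureError(f"no ss2 records found in {path}")
    ss3 = np.array(rows)
    return ss3 / ss3.sum(axis=1, keepdims=True)
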