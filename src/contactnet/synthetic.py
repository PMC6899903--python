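"""Desk-scale synthetic fixtures with the statistical structure the
predictor assumes.

Three generators:

* :func:`generate_toy_structure` — an idealized helix-bundle "protein":
  alternating helix and loop segments, helical Cβ-like coordinates packed
  around a bundle axis circle, self-avoiding, with genuine long-range
  contacts between helices.
* :func:`sample_coupled_msa` — sequence families drawn from a pairwise
  Potts-like model by Gibbs sampling: per-column fields plus a favoured
  residue pair at every contact with |i-j| >= 5, so column covariation is
  elevated exactly at contact positions; gaps are injected at rate 0.05 in
  loop columns.
* :func:`make_family` — a deep MSA plus a shallow subsample of it for the
  same protein, standing in for paired deep/shallow alignments of
  differing quality used by feature interpolation.

These fixtures are statistical stand-ins: they reproduce the
covariation-at-contacts signal, not protein energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import CONTACT_CUTOFF, contacts_from_coords
from .features import ResidueFeatures, msa_profile
from .msa_io import GAP, Msa, N_STATES

MIN_SELF_DISTANCE = 3.5  # Å, enforced for |i-j| >= 3
GAP_RATE = 0.05
COUPLING_MIN_SEP = 5


@dataclass
class ToyProtein:
    """An idealized structure with contact map and loop annotations."""

    length: int
    cb_coords: np.ndarray  # (L, 3)
    contact_map: np.ndarray  # (L, L) binary
    ss_labels: np.ndarray  # (L,) of 'H' | 'E' | 'C' (C = loop)
    loop_mask: np.ndarray  # (L,) bool


@dataclass
class SyntheticFamily:
    protein: ToyProtein
    msa_deep: Msa
    msa_shallow: Msa
    coupling_strength: float


class PackingError(RuntimeError):
    pass


def _segment_plan(L: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Alternating helix/loop lengths summing to L, starting and ending in helix."""
    segments: list[tuple[str, int]] = []
    remaining = L
    while remaining > 0:
        kind = "H" if not segments or segments[-1][0] == "C" else "C"
        if kind == "H":
            n = int(rng.integers(10, 17))
        else:
            n = int(rng.integers(3, 7))
        if kind == "H" and remaining - n < 9:
            n = remaining  # absorb the tail into the final helix
        if kind == "C" and remaining - n < 10:
            # not enough left for another helix: extend the previous helix
            prev = segments.pop()
            segments.append((prev[0], prev[1] + remaining))
            remaining = 0
            break
        n = min(n, remaining)
        segments.append((kind, n))
        remaining -= n
    return segments


def _helix_coords(n: int, origin: np.ndarray, direction: float, phase: float) -> np.ndarray:
    """Idealized helix: 1.5 Å rise per residue, 100 deg turn, side-chain radius 2.9 Å."""
    t = np.arange(n)
    ang = phase + np.deg2rad(100.0) * t
    coords = np.empty((n, 3))
    coords[:, 0] = origin[0] + 2.9 * np.cos(ang)
    coords[:, 1] = origin[1] + 2.9 * np.sin(ang)
    coords[:, 2] = origin[2] + direction * 1.5 * t
    return coords


def _loop_coords(n: int, a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n residues arcing from just after a to just before b, bowed outward."""
    ts = np.linspace(0, 1, n + 2)[1:-1]
    base = a[None, :] + ts[:, None] * (b - a)[None, :]
    # bow perpendicular to the a->b chord, magnitude peaking mid-loop
    chord = b - a
    perp = np.cross(chord, np.array([0.0, 0.0, 1.0]))
    nrm = np.linalg.norm(perp)
    if nrm < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
        nrm = 1.0
    perp = perp / nrm
    bow = 3.0 + 2.0 * rng.random()
    base += np.sin(np.pi * ts)[:, None] * bow * perp[None, :]
    base += rng.normal(0, 0.2, size=base.shape)
    return base


def generate_toy_structure(L: int, rng: np.random.Generator, max_retries: int = 50) -> ToyProtein:
    """Build a self-avoiding helix-bundle toy protein of length L >= 20."""
    if L < 20:
        raise ValueError("toy structures need L >= 20")
    for attempt in range(max_retries):
        segments = _segment_plan(L, rng)
        helices = [s for s in segments if s[0] == "H"]
        n_h = len(helices)
        if n_h < 2:
            continue
        # bundle axis positions on a circle with 10.5 Å between neighbours
        radius = 10.5 / (2 * np.sin(np.pi / n_h)) if n_h > 2 else 5.25
        axis_xy = [
            radius * np.array([np.cos(2 * np.pi * k / n_h), np.sin(2 * np.pi * k / n_h)])
            for k in range(n_h)
        ]
        coords = np.zeros((L, 3))
        ss = np.empty(L, dtype="<U1")
        pos = 0
        h_idx = 0
        z_end = 0.0
        prev_end: np.ndarray | None = None
        pending_loop: tuple[int, int] | None = None
        for kind, n in segments:
            if kind == "H":
                direction = 1.0 if h_idx % 2 == 0 else -1.0
                z0 = 0.0 if direction > 0 else z_end
                origin = np.array([axis_xy[h_idx][0], axis_xy[h_idx][1], z0])
                hc = _helix_coords(n, origin, direction, phase=2 * np.pi * rng.random())
                hc += rng.normal(0, 0.15, size=hc.shape)
                coords[pos : pos + n] = hc
                ss[pos : pos + n] = "H"
                if pending_loop is not None:
                    ls, ln = pending_loop
                    coords[ls : ls + ln] = _loop_coords(ln, prev_end, hc[0], rng)
                    ss[ls : ls + ln] = "C"
                    pending_loop = None
                prev_end = hc[-1]
                z_end = hc[-1, 2]
                h_idx += 1
            else:
                pending_loop = (pos, n)
            pos += n
        if pending_loop is not None:  # plan never ends in a loop, but be safe
            ls, ln = pending_loop
            coords[ls : ls + ln] = prev_end[None, :] + rng.normal(0, 1.0, size=(ln, 3))
            ss[ls : ls + ln] = "C"

        # self-avoidance for |i-j| >= 3
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        idx = np.arange(L)
        far = np.abs(idx[:, None] - idx[None, :]) >= 3
        if dist[far].min() < MIN_SELF_DISTANCE:
            continue
        cmap = contacts_from_coords(coords, CONTACT_CUTOFF)
        sep = np.abs(idx[:, None] - idx[None, :])
        if not (cmap & (sep >= 24)).any():
            continue
        loop_mask = ss == "C"
        return ToyProtein(
            length=L, cb_coords=coords, contact_map=cmap, ss_labels=ss, loop_mask=loop_mask
        )
    raise PackingError(
        f"failed to build a self-avoiding L={L} bundle after {max_retries} attempts "
        f"(rng state {rng.bit_generator.state['state']})"
    )


def sample_coupled_msa(
    protein: ToyProtein,
    n_seqs: int,
    coupling_strength: float,
    rng: np.random.Generator,
    n_sweeps: int = 4,
) -> Msa:
    """Gibbs-sample an alignment whose covariation is elevated at contacts.

    Energy: per-column fields plus, for every contact (i, j) with
    |i-j| >= 5, a compatibility bonus of ``coupling_strength`` whenever the
    residue pair (a, b) satisfies b == perm_ij(a) for that contact's random
    one-to-one compatibility permutation (so every state has a favoured
    partner state, the way covarying contact columns behave).
    """
    L = protein.length
    fields = rng.normal(0.0, 1.0, size=(L, 20))
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    ci, cj = np.nonzero(np.triu(protein.contact_map, 1) & (sep >= COUPLING_MIN_SEP))
    # partners[i]: (j, perm, forward); forward means favoured pair is
    # (a at i, perm[a] at j); the reverse direction uses the inverse map.
    # partners[i]: (j, mapping) with mapping[s_j] = the favoured state at i
    partners: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(L)}
    for i, j in zip(ci, cj):
        perm = rng.permutation(20)  # favoured pairs are (a, perm[a])
        partners[int(i)].append((int(j), np.argsort(perm)))
        partners[int(j)].append((int(i), perm))

    # independent initialization from the fields
    logits = fields - fields.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    seqs = np.empty((n_seqs, L), dtype=np.int8)
    for i in range(L):
        seqs[:, i] = rng.choice(20, size=n_seqs, p=probs[i])

    if coupling_strength != 0:
        for _ in range(n_sweeps):
            for i in range(L):
                lg = np.broadcast_to(fields[i], (n_seqs, 20)).copy()
                rows = np.arange(n_seqs)
                for j, mapping in partners[i]:
                    lg[rows, mapping[seqs[:, j]]] += coupling_strength
                lg -= lg.max(axis=1, keepdims=True)
                p = np.exp(lg)
                p /= p.sum(axis=1, keepdims=True)
                u = rng.random((n_seqs, 1))
                seqs[:, i] = (p.cumsum(axis=1) < u).sum(axis=1).clip(0, 19)

    # gaps in loop columns (never in the query row)
    loop_cols = np.nonzero(protein.loop_mask)[0]
    if loop_cols.size and n_seqs > 1:
        gap_draw = rng.random((n_seqs, loop_cols.size)) < GAP_RATE
        gap_draw[0] = False
        sub = seqs[:, loop_cols]
        sub[gap_draw] = GAP
        seqs[:, loop_cols] = sub

    ids = ["query"] + [f"synth{i}" for i in range(1, n_seqs)]
    return Msa(ids=ids, codes=seqs)


def make_family(
    L: int,
    n_deep: int,
    n_shallow: int,
    rng: np.random.Generator,
    coupling_strength: float = 2.0,
) -> SyntheticFamily:
    """A toy protein with paired deep and shallow alignments.

    The shallow MSA is a random row subsample of the deep MSA (query always
    retained as the first row).
    """
    if n_shallow > n_deep:
        raise ValueError("n_shallow must not exceed n_deep")
    protein = generate_toy_structure(L, rng)
    msa_deep = sample_coupled_msa(protein, n_deep, coupling_strength, rng)
    if n_shallow == n_deep:
        msa_shallow = Msa(ids=list(msa_deep.ids), codes=msa_deep.codes.copy())
    else:
        picked = rng.choice(np.arange(1, n_deep), size=n_shallow - 1, replace=False)
        rows = np.concatenate([[0], np.sort(picked)])
        msa_shallow = Msa(
            ids=[msa_deep.ids[r] for r in rows], codes=msa_deep.codes[rows].copy()
        )
    return SyntheticFamily(
        protein=protein,
        msa_deep=msa_deep,
        msa_shallow=msa_shallow,
        coupling_strength=coupling_strength,
    )


def residue_features(protein: ToyProtein, msa: Msa) -> ResidueFeatures:
    """Ground-truth-derived per-residue features for a synthetic family.

    Profile = empirical column frequencies; ss3 = one-hot true labels
    smoothed 0.9/0.05/0.05; solvent accessibility = distance-from-centroid
    burial proxy rescaled to [0, 1].
    """
    profile = msa_profile(msa)
    ss_index = {"H": 0, "E": 1, "C": 2}
    ss3 = np.full((protein.length, 3), 0.05)
    for i, lab in enumerate(protein.ss_labels):
        ss3[i, ss_index[lab]] = 0.9
    centroid = protein.cb_coords.mean(axis=0)
    d = np.linalg.norm(protein.cb_coords - centroid, axis=1)
    rng_d = d.max() - d.min()
    solv = (d - d.min()) / rng_d if rng_d > 0 else np.zeros_like(d)
    return ResidueFeatures(profile=profile, ss3=ss3, solv=solv, loop_mask=protein.loop_mask)
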