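"""CASP-style contact assessment and benchmark-table aggregation.

Contacts are residue pairs whose Cβ atoms (Cα for glycine) lie within 8 Å.
Sequence-separation ranges follow the CASP convention: long-range
|i-j| >= 24, medium-range 12 <= |i-j| <= 23.  Top-L/k precision is the
percentage of true contacts among the floor(L/k) highest-scoring eligible
pairs (at least 1 pair; ties broken by descending score then ascending
(i, j) for determinism).

The module also ships a benchmark table of CASP13 FM and FM/TBM domain
results (id, classification, length, top-L/5 long-range precision, Meff)
used for aggregation statistics, a CASP RR format reader/writer, and the
domain-score splicing step that copies contact scores predicted for a
putative domain back into the full-length score map.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

CONTACT_CUTOFF = 8.0
RANGES = {
    "long": (24, None),
    "medium": (12, 23),
    "medium+long": (12, None),
}


class EvaluationError(ValueError):
    pass


def _range_mask(L: int, range: str) -> np.ndarray:
    try:
        lo, hi = RANGES[range]
    except KeyError:
        raise EvaluationError(f"unknown range {range!r}; expected one of {sorted(RANGES)}")
    idx = np.arange(L)
    sep = idx[None, :] - idx[:, None]  # upper triangle positive
    mask = sep >= lo
    if hi is not None:
        mask &= sep <= hi
    return mask


def topk_precision(
    scores: np.ndarray,
    truth: np.ndarray,
    k_divisor: int = 5,
    range: str = "long",
) -> float:
    """Range-stratified top-L/k precision, in percent."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if scores.shape != truth.shape or scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise EvaluationError(f"score/truth shapes do not match: {scores.shape} vs {truth.shape}")
    L = scores.shape[0]
    mask = _range_mask(L, range)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise EvaluationError(f"no eligible {range}-range pairs for L={L}")
    n_sel = max(1, L // k_divisor)
    n_sel = min(n_sel, ii.size)
    order = np.lexsort((jj, ii, -scores[ii, jj]))
    sel = order[:n_sel]
    tp = int(truth[ii[sel], jj[sel]].sum())
    return 100.0 * tp / n_sel


def contacts_from_coords(cb_coords: np.ndarray, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Binary contact map from Cβ coordinates: distance <= cutoff, i != j."""
    coords = np.asarray(cb_coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise EvaluationError(f"expected (L, 3) coordinates, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise EvaluationError("coordinates must be finite")
    dist = squareform(pdist(coords))
    cmap = (dist <= cutoff).astype(np.int8)
    np.fill_diagonal(cmap, 0)
    return cmap


# -- benchmark-table aggregation -------------------------------------------

TABLE_COLUMNS = ["domain", "classification", "length", "precision", "meff"]


def load_domain_table() -> pd.DataFrame:
    """The packaged CASP13 FM/FM-TBM domain benchmark table."""
    with resources.files("contactnet.data").joinpath("casp13_fm_domains.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def aggregate_table(
    table: pd.DataFrame,
    meff_max: float | None = None,
    precision_min: float | None = None,
) -> dict:
    """Filtered mean precision over a domain table.

    Returns ``{"mean_precision": <rounded to 2 dp or None>, "n_rows": int}``.
    """
    df = table
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise EvaluationError(f"domain table lacks columns: {sorted(missing)}")
    if df.empty:
        raise EvaluationError("domain table is empty")
    if meff_max is not None:
        df = df[df["meff"] <= meff_max]
    if precision_min is not None:
        df = df[df["precision"] >= precision_min]
    if df.empty:
        return {"mean_precision": None, "n_rows": 0}
    return {"mean_precision": round(float(df["precision"].mean()), 2), "n_rows": int(len(df))}


# -- domain splicing --------------------------------------------------------

@dataclass
class DomainSegment:
    """A 0-based half-open residue interval in the full-length sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise EvaluationError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def splice_domain_scores(
    full: np.ndarray, domain: np.ndarray, seg: DomainSegment
) -> np.ndarray:
    """Copy domain-level contact scores back into the full-length map.

    Only entries with both residues inside the segment are overwritten.
    """
    full = np.asarray(full, dtype=np.float64)
    domain = np.asarray(domain, dtype=np.float64)
    if seg.end > full.shape[0]:
        raise EvaluationError(
            f"segment [{seg.start}, {seg.end}) exceeds map size {full.shape[0]}"
        )
    if domain.shape != (seg.length, seg.length):
        raise EvaluationError(
            f"domain map shape {domain.shape} != segment length {seg.length}"
        )
    out = full.copy()
    out[seg.start : seg.end, seg.start : seg.end] = domain
    return out


# -- CASP RR format ---------------------------------------------------------

def write_rr(
    scores: np.ndarray,
    path: str | Path,
    target: str = "T0000",
    sequence: str | None = None,
    model_number: int = 1,
    min_sep: int = 1,
) -> None:
    """Write a score map as a CASP RR contact file.

    Records are ``i j 0 8 p`` with 1-based indices, upper triangle only,
    sorted by descending probability (ties by ascending (i, j)).
    """
    scores = np.asarray(scores)
    L = scores.shape[0]
    ii, jj = np.nonzero(pair_upper(L, min_sep))
    order = np.lexsort((jj, ii, -scores[ii, jj]))
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"TARGET {target}\n")
        fh.write(f"MODEL {model_number}\n")
        if sequence:
            for k in range(0, len(sequence), 50):
                fh.write(sequence[k : k + 50] + "\n")
        for idx in order:
            i, j = ii[idx], jj[idx]
            fh.write(f"{i + 1} {j + 1} 0 8 {scores[i, j]:.6f}\n")
        fh.write("END\n")


def pair_upper(L: int, min_sep: int = 1) -> np.ndarray:
    idx = np.arange(L)
    return (idx[None, :] - idx[:, None]) >= min_sep


def read_rr(path: str | Path, L: int | None = None) -> np.ndarray:
    """Read a CASP RR file into a symmetric L x L score matrix.

    When ``L`` is None it is taken from the sequence lines if present,
    else from the largest residue index.
    """
    records: list[tuple[int, int, float]] = []
    seq_len = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].upper()
            if key in ("PFRMAT", "TARGET", "MODEL", "REMARK", "METHOD", "AUTHOR", "END"):
                continue
            if len(parts) == 1 and parts[0].isalpha():
                seq_len += len(parts[0])
                continue
            if len(parts) == 5:
                i, j = int(parts[0]), int(parts[1])
                records.append((i - 1, j - 1, float(parts[4])))
            else:
                raise EvaluationError(f"unparseable RR line: {line.rstrip()!r}")
    if not records:
        raise EvaluationError(f"no contact records in {path}")
    if L is None:
        L = seq_len if seq_len else max(max(i, j) for i, j, _ in records) + 1
    scores = np.zeros((L, L))
    for i, j, p in records:
        if not (0 <= i < L and 0 <= j < L):
            raise EvaluationError(f"residue index out of range in {path}: {i + 1}, {j + 1}")
        scores[i, j] = p
        scores[j, i] = p
    return scores
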