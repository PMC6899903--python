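"""Reading, validation and integer encoding of multiple sequence alignments.

Three flat-text dialects are supported:

* ``fasta``  — standard FASTA records; rows must share one aligned length.
* ``a3m``    — FASTA-like, where lowercase letters mark insert states
  relative to the query; lowercase columns are deleted before encoding so
  every row lives in the query's column frame.
* ``psicov`` — one aligned sequence per line, no headers.

The alphabet is fixed as the 20 standard amino acids in the order
``ARNDCQEGHILKMFPSTWYV`` followed by the gap state (code 20).  Nonstandard
letters (B, Z, X, U, O) and ``.`` map to the gap state.  The first row is
taken to be the query/target sequence by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = 20
N_STATES = 21  # 20 amino acids + gap

_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ENCODE = np.full(128, GAP, dtype=np.int8)
for _aa, _i in _CODE_OF.items():
    _ENCODE[ord(_aa)] = _i


class MsaFormatError(ValueError):
    """Raised for ragged alignments or unparseable files."""


@dataclass
class Msa:
    """An integer-encoded multiple sequence alignment.

    Attributes
    ----------
    ids : list of str
        One identifier per row (synthesized for the psicov dialect).
    codes : ndarray of shape (N, L), dtype int8
        Residue codes in ``[0, 20]``; 20 is the gap state.
    """

    ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise MsaFormatError("alignment must be a nonempty N x L matrix")
        if len(self.ids) != self.codes.shape[0]:
            raise MsaFormatError("number of ids must match number of rows")
        if self.codes.min() < 0 or self.codes.max() > GAP:
            raise MsaFormatError("residue codes must lie in [0, 20]")

    @property
    def N(self) -> int:
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    @property
    def query(self) -> np.ndarray:
        """Codes of the first (query) row."""
        return self.codes[0]


def encode_sequence(seq: str) -> np.ndarray:
    """Map an upper-case residue string to integer codes in [0, 20]."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr].copy()


def decode_sequence(codes: Sequence[int]) -> str:
    alphabet = AMINO_ACIDS + "-"
    return "".join(alphabet[c] for c in codes)


def _from_rows(ids: list[str], rows: list[str], *, what: str) -> Msa:
    if not rows:
        raise MsaFormatError(f"empty input: no sequences found in {what}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MsaFormatError(
            f"ragged alignment in {what}: row lengths {sorted(lengths)}"
        )
    if lengths == {0}:
        raise MsaFormatError(f"empty input: zero-length rows in {what}")
    codes = np.stack([encode_sequence(r) for r in rows])
    return Msa(ids=ids, codes=codes)


def _strip_inserts(seq: str) -> str:
    # a3m semantics: lowercase letters are insert states relative to the
    # query column frame and are removed, not realigned.
    return "".join(c for c in seq if not c.islower())


def read_msa(path: str | Path, format: str = "fasta") -> Msa:
    """Read an alignment file into an integer-encoded :class:`Msa`.

    Parameters
    ----------
    path : path-like
        Alignment file.
    format : {"fasta", "a3m", "psicov"}
        File dialect; see module docstring.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt in ("fasta", "a3m"):
        records = list(SeqIO.parse(str(path), "fasta"))
        ids = [r.id for r in records]
        rows = [str(r.seq) for r in records]
        if fmt == "a3m":
            rows = [_strip_inserts(r) for r in rows]
        rows = [r.upper() for r in rows]
        return _from_rows(ids, rows, what=str(path))
    if fmt == "psicov":
        with open(path) as fh:
            rows = [line.strip().upper() for line in fh if line.strip()]
        ids = [f"seq{i}" for i in range(len(rows))]
        return _from_rows(ids, rows, what=str(path))
    raise ValueError(f"unsupported alignment format: {format!r}")


def write_msa(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment in the fasta or psicov dialect (gap written as '-')."""
    fmt = format.lower()
    with open(path, "w") as fh:
        if fmt == "fasta":
            for name, row in zip(msa.ids, msa.codes):
                fh.write(f">{name}\n{decode_sequence(row)}\n")
        elif fmt == "psicov":
            for row in msa.codes:
                fh.write(decode_sequence(row) + "\n")
        else:
            raise ValueError(f"unsupported alignment format: {format!r}")


def one_hot(msa: Msa) -> np.ndarray:
    """Indicator encoding of shape (N, L, 21); channel index == residue code."""
    eye = np.eye(N_STATES, dtype=np.float64)
    return eye[msa.codes]


def msa_from_strings(rows: Iterable[str], ids: list[str] | None = None) -> Msa:
    """Build an Msa directly from aligned residue strings (testing/synthetic use)."""
    rows = [r.upper() for r in rows]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(rows))]
    return _from_rows(ids, rows, what="<strings>")
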