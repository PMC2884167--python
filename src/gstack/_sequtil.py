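"""Shared helpers for encoding 25-mer probe sequences."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PROBE_LENGTH = 25
MIDDLE_POSITION = 13  # 1-based position of the mismatch substitution

_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_CODE[c] for c in sequence], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from exc


def encode_many(sequences) -> np.ndarray:
    """Encode an iterable of equal-length sequences as an (n, L) uint8 matrix."""
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        raise ValueError("non-ACGT character in sequence batch")
    n = len(sequences)
    return codes.reshape(n, -1)


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    # A<->T (0<->3), C<->G (1<->2)
    return (3 - codes.astype(np.int64)).astype(np.uint8)


def motif_codes(codes: np.ndarray, rank: int) -> np.ndarray:
    """Base-4 code of the length-``rank`` motif starting at every position.

    ``codes`` is an (n, L) matrix; the result is (n, L - rank + 1) with values
    in ``[0, 4**rank)`` ordered lexicographically over A<C<G<T.
    """
    n_pos = codes.shape[1] - rank + 1
    out = np.zeros((codes.shape[0], n_pos), dtype=np.int64)
    for i in range(rank):
        out = out * 4 + codes[:, i : i + n_pos].astype(np.int64)
    return out
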