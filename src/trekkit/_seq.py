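"""Low-level sequence codecs shared across the package.

Bases are encoded A=0, C=1, G=2, T=3 (lexicographic, so base-4 digit
strings give the lexicological index of a k-mer directly) and N=4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODES = {b: i for i, b in enumerate(BASES)}
N_CODE = 4

_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)

_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c
_LUT[ord("N")] = N_CODE
_LUT[ord("n")] = N_CODE

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes; raises on non-ACGTN characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def kmer_index(kmer: str) -> int:
    """Lexicological index of a k-mer (A<C<G<T), first base most significant."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASE_CODES[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All length-k windows of a code array, shape (L-k+1, k)."""
    return np.lib.stride_tricks.sliding_window_view(codes, k)


def window_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Lexicological indices of every k-window plus a no-N validity mask."""
    win = window_codes(codes, k)
    valid = (win != N_CODE).all(axis=1)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = (win.astype(np.int64) * pow4).sum(axis=1)
    idx[~valid] = 0
    return idx, valid
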