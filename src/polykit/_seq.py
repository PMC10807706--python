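"""Low-level DNA encoding, k-mer codes and i.i.d. substitution machinery.

Bases are coded A,C,G,T -> 0..3; any other character (N, IUPAC ambiguity)
becomes 255 and is excluded from k-mer windows and mutation.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[codes == i] = ord(b)
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each valid site with probability ``rate`` to a uniformly
    chosen *different* base (Jukes-Cantor-like single round)."""
    out = codes.copy()
    if rate <= 0 or out.size == 0:
        return out
    hit = (out <= 3) & (rng.random(out.size) < rate)
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def kmer_codes(codes: np.ndarray, k: int):
    """Integer codes of every k-window free of non-ACGT characters.

    Returns ``(starts, fwd, rc)``: window start offsets, forward 2-bit codes
    and reverse-complement codes (both uint64).
    """
    L = int(codes.size)
    n = L - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return np.zeros(0, dtype=np.int64), z, z
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    ok = (cs[k:] - cs[:-k]) == 0
    c = np.where(codes > 3, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd += c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rc += (np.uint64(3) - c[j : j + n]) << np.uint64(2 * j)
    starts = np.nonzero(ok)[0]
    return starts, fwd[ok], rc[ok]


def canonical_codes(fwd: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Canonical k-mer code: lexicographic minimum of a k-mer and its
    reverse complement (2-bit encoding preserves lexicographic order)."""
    return np.minimum(fwd, rc)


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append(BASES[(int(code) >> (2 * (k - 1 - j))) & 3])
    return "".join(out)
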