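"""2-bit packed k-mer encoding, canonicalization and Hamming distance.

A k-mer (k <= 32) is packed into a single 64-bit word with the fixed code
A=00, C=01, G=10, T=11; base 0 of the k-mer occupies the two lowest-order
bits. All matching downstream (LSH hashing, distance computation) operates
on these words. Bulk paths work on ``numpy.uint64`` arrays; the scalar API
wraps values in :class:`EncodedKmer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AmbiguousBaseError",
    "EncodedKmer",
    "encode_kmer",
    "decode_kmer",
    "canonical_kmer",
    "hamming_distance",
    "reverse_complement",
    "read_to_kmers",
    "canonical_window_values",
    "hamming_distance_values",
]

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> 2-bit code; 255 marks anything that is not A/C/G/T (case-folded)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c

_ODD_BITS = np.uint64(0x5555555555555555)


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a non-ACGT base; callers skip the k-mer."""


@dataclass(frozen=True)
class EncodedKmer:
    """A k-length DNA word packed 2 bits/base into one 64-bit value.

    ``value`` holds base 0 in its two lowest-order bits; every bit position
    at or above ``2*k`` is zero.
    """

    value: int
    k: int = 32

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.value < 0 or (self.k < 32 and self.value >> (2 * self.k)):
            raise ValueError("encoded value has bits set above 2k")


def _seq_codes(seq: str) -> np.ndarray:
    """Map a DNA string to an array of 2-bit codes (255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def encode_kmer(seq: str, k: int | None = None) -> EncodedKmer:
    """Pack a k-length ACGT string into an :class:`EncodedKmer`.

    Lowercase (soft-masked) bases are accepted and uppercased. Any other
    character raises :class:`AmbiguousBaseError`.
    """
    if k is None:
        k = len(seq)
    if len(seq) != k:
        raise ValueError(f"sequence length {len(seq)} != k={k}")
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    codes = _seq_codes(seq)
    if (codes > 3).any():
        raise AmbiguousBaseError(f"ambiguous base in k-mer {seq!r}")
    value = 0
    for i in range(k):
        value |= int(codes[i]) << (2 * i)
    return EncodedKmer(value, k)


def decode_kmer(kmer: EncodedKmer) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join(_BASES[(kmer.value >> (2 * i)) & 3] for i in range(kmer.k))


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    try:
        return "".join(comp[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise AmbiguousBaseError(f"ambiguous base {exc.args[0]!r}") from exc


def canonical_kmer(seq: str, k: int | None = None) -> EncodedKmer:
    """Encode the lexicographically smaller of ``seq`` and its reverse
    complement (string order), making matching strand-independent."""
    seq = seq.upper()
    rc = reverse_complement(seq)
    return encode_kmer(min(seq, rc), k)


def hamming_distance(x: EncodedKmer, y: EncodedKmer) -> int:
    """Number of base positions at which two equal-length k-mers differ.

    A base differing in either or both of its 2 bits counts once: the XOR
    of the words is collapsed so each 2-bit symbol contributes one flag bit,
    then flags are popcounted.
    """
    if x.k != y.k:
        raise ValueError(f"k mismatch: {x.k} != {y.k}")
    diff = np.uint64(x.value) ^ np.uint64(y.value)
    flags = (diff | (diff >> np.uint64(1))) & _ODD_BITS
    return int(np.bitwise_count(flags))


def hamming_distance_values(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized base-level Hamming distance between packed uint64 words."""
    diff = np.bitwise_xor(a, b)
    flags = (diff | (diff >> np.uint64(1))) & _ODD_BITS
    return np.bitwise_count(flags)


def _window_encodings(codes: np.ndarray, k: int):
    """Little-endian (storage) and big-endian (lexicographic key) encodings
    of every k-window of a code array, plus a validity mask."""
    n = codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty, np.empty(0, dtype=bool)
    codes64 = codes.astype(np.uint64)
    le = np.zeros(n, dtype=np.uint64)
    be = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        window = codes64[i : i + n] & np.uint64(3)  # invalid bytes masked later
        le |= window << np.uint64(2 * i)
        be |= window << np.uint64(2 * (k - 1 - i))
    invalid = codes > 3
    bad = np.zeros(n, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(invalid)])
    bad = cum[k:] - cum[:-k]
    return le, be, bad == 0


def canonical_window_values(seq: str, k: int = 32) -> np.ndarray:
    """Canonical packed values of every valid k-window of ``seq``.

    Windows containing a non-ACGT base are skipped. This is the bulk
    engine behind :func:`read_to_kmers` and the library builder; the
    reverse complement's encodings fall out of the forward ones because
    complementing flips every 2-bit symbol to its 3-complement:
    ``rc_be == ~le`` and ``rc_le == ~be`` within the 2k-bit mask.
    """
    codes = _seq_codes(seq)
    le, be, valid = _window_encodings(codes, k)
    if le.size == 0:
        return le
    mask = np.uint64(0xFFFFFFFFFFFFFFFF) if k == 32 else np.uint64((1 << (2 * k)) - 1)
    rc_le = mask - be
    rc_be = mask - le
    canon = np.where(be <= rc_be, le, rc_le)
    return canon[valid]


def _minimize_35mers(seq: str, k: int) -> list[EncodedKmer]:
    # Each valid 35-window is canonicalized as a string, reduced to its
    # lexicographically smallest k-substring, and consecutive duplicates
    # are collapsed.
    w = 35
    out: list[EncodedKmer] = []
    prev = None
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        try:
            canon = min(window, reverse_complement(window))
        except AmbiguousBaseError:
            continue
        mini = min(canon[j : j + k] for j in range(w - k + 1))
        if mini != prev:
            out.append(encode_kmer(mini, k))
            prev = mini
    return out


def read_to_kmers(
    read: str, k: int = 32, minimizer_window: int | None = None
) -> list[EncodedKmer]:
    """Sliding-window canonical k-mers of a read.

    Windows containing a non-ACGT base are skipped (not substituted);
    lowercase bases are uppercased. A read shorter than ``k`` yields an
    empty list. With ``minimizer_window=35`` each canonical 35-mer is
    reduced to its lexicographically smallest 32-mer substring and
    consecutive duplicates are collapsed (off by default).
    """
    read = read.upper()
    if minimizer_window is not None:
        if minimizer_window != 35 or k != 32:
            raise ValueError("minimizer mode supports only window=35 with k=32")
        return _minimize_35mers(read, k)
    values = canonical_window_values(read, k)
    return [EncodedKmer(int(v), k) for v in values]
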