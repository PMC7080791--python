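"""Vectorized 2-bit k-mer arithmetic.

K-mers over ACGT are packed into uint64 codes (A=0, C=1, G=2, T=3, most
significant 2 bits = first base), which keeps exact canonical k-mer counting
and Hamming-neighbor search tractable at tens of millions of k-mers in pure
numpy. Supports k <= 31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i

_M_NIBBLE = np.uint64(0x0F0F0F0F0F0F0F0F)
_M_PAIR = np.uint64(0x3333333333333333)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0 .. T=3).

    Raises ValueError on characters outside ACGT (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _BASE_TO_CODE[raw]
    if (out == 255).any():
        bad = chr(raw[int(np.argmax(out == 255))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def kmer_mask(k: int) -> np.uint64:
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    return np.uint64((1 << (2 * k)) - 1)


def encode_kmer(kmer: str) -> int:
    """Pack one k-mer string into an integer code."""
    codes = seq_to_codes(kmer)
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(int(code) >> shift) & 3])
    return "".join(out)


def rolling_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer codes of a base-code array.

    Accepts a 1D array (one sequence) or a 2D array (rows = equal-length
    reads); returns codes with one entry per k-mer position.
    """
    mask = kmer_mask(k)
    two = np.uint64(2)
    arr = np.asarray(base_codes, dtype=np.uint64)
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    else:
        squeeze = False
    n, L = arr.shape
    if L < k:
        raise ValueError("sequence shorter than k")
    out = np.empty((n, L - k + 1), dtype=np.uint64)
    col = np.zeros(n, dtype=np.uint64)
    for j in range(L):
        col = ((col << two) | arr[:, j]) & mask
        if j >= k - 1:
            out[:, j - k + 1] = col
    return out[0] if squeeze else out


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes, vectorized."""
    x = np.asarray(codes, dtype=np.uint64) ^ kmer_mask(k)  # complement: b -> 3-b
    x = x.byteswap()                                       # reverse bytes
    x = ((x & _M_NIBBLE) << np.uint64(4)) | ((x >> np.uint64(4)) & _M_NIBBLE)
    x = ((x & _M_PAIR) << np.uint64(2)) | ((x >> np.uint64(2)) & _M_PAIR)
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic minimum of each code and its reverse complement."""
    return np.minimum(np.asarray(codes, dtype=np.uint64), revcomp_codes(codes, k))


def canonical_kmer(kmer: str) -> str:
    """Canonical form of a k-mer string (min of itself and its revcomp)."""
    comp = kmer.upper().translate(str.maketrans("ACGT", "TGCA"))
    rc = comp[::-1]
    return min(kmer.upper(), rc)


@dataclass
class KmerCounts:
    """Distinct canonical k-mers with their multiplicities.

    The array-backed counterpart of a text k-mer dump; `codes` are sorted
    unique canonical packed k-mers and `counts` their occurrence counts.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(coverage, frequency) arrays of the k-mer spectrum, zero bins removed."""
        freq = np.bincount(self.counts.astype(np.int64))
        cov = np.nonzero(freq)[0]
        cov = cov[cov > 0]
        return cov, freq[cov]

    def to_dict(self) -> dict[str, int]:
        return {
            decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    @classmethod
    def from_dict(cls, records: dict[str, int], k: int) -> "KmerCounts":
        codes = np.fromiter(
            (encode_kmer(s) for s in records), dtype=np.uint64, count=len(records)
        )
        counts = np.fromiter(records.values(), dtype=np.int64, count=len(records))
        codes = canonical_codes(codes, k)
        order = np.argsort(codes, kind="stable")
        codes, counts = codes[order], counts[order]
        uniq, start = np.unique(codes, return_index=True)
        summed = np.add.reduceat(counts, start)
        return cls(k=k, codes=uniq, counts=summed)


def count_canonical(all_codes: np.ndarray, k: int) -> KmerCounts:
    """Aggregate raw (possibly repeated) k-mer codes into canonical counts."""
    canon = canonical_codes(np.ravel(all_codes), k)
    uniq, counts = np.unique(canon, return_counts=True)
    return KmerCounts(k=k, codes=uniq, counts=counts.astype(np.int64))
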