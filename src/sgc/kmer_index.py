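"""K-mer hash index over a reference base stream.

Every overlapping k-mer of the reference is 2-bit packed into an integer
key (A=0, C=1, G=2, T=3) and stored with its start position.  Packing is
exact for k <= 31, so two k-mers share a key iff they are the same string;
there are no key collisions to resolve.  Internally the index is a pair of
parallel sorted arrays (key, position) queried by binary search, which is
compact and cache-friendly for references up to chromosome scale.

The index exists only in memory during compression; decompression never
needs it and archives never contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

MAX_K = 31

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASE_FOR_CODE = b"ACGT"


def pack_kmers(seq: bytes, k: int) -> np.ndarray:
    """2-bit pack every overlapping k-mer of an ACGT stream.

    Returns an int64 array of length ``len(seq) - k + 1`` (empty when the
    stream is shorter than k).
    """
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64)
    vals = _CODE[np.frombuffer(seq, dtype=np.uint8)]
    if vals.max(initial=0) > 3:
        raise ValueError("stream contains symbols outside ACGT")
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes <<= 2
        codes += vals[j : j + m]
    return codes


def encode_kmer(kmer: bytes) -> int:
    """2-bit pack a single k-mer."""
    code = 0
    for b in kmer:
        v = _CODE[b]
        if v > 3:
            raise ValueError("k-mer contains symbols outside ACGT")
        code = (code << 2) | int(v)
    return code


@dataclass
class KmerIndex:
    """Occurrence index of all k-mers of one reference stream."""

    k: int
    ref_length: int
    sorted_codes: np.ndarray = field(repr=False)
    sorted_positions: np.ndarray = field(repr=False)
    max_occ: int | None = None

    @property
    def size(self) -> int:
        """Total number of stored (k-mer, position) entries."""
        return int(self.sorted_codes.size)

    def occurrence_bounds(self, code: int) -> tuple[int, int]:
        lo = int(np.searchsorted(self.sorted_codes, code, side="left"))
        hi = int(np.searchsorted(self.sorted_codes, code, side="right"))
        return lo, hi

    def lookup_code(self, code: int) -> np.ndarray:
        """Occurrence positions of a packed k-mer, ascending; possibly empty."""
        lo, hi = self.occurrence_bounds(code)
        pos = self.sorted_positions[lo:hi]
        if self.max_occ is not None and pos.size > self.max_occ:
            pos = pos[: self.max_occ]
        return pos

    def lookup(self, kmer: bytes) -> list[int]:
        """Occurrence positions of a k-mer string, ascending; possibly empty."""
        if len(kmer) != self.k:
            raise ConfigurationError(
                f"query length {len(kmer)} != index k {self.k}"
            )
        return [int(p) for p in self.lookup_code(encode_kmer(kmer))]

    def to_dict(self) -> dict[bytes, list[int]]:
        """Materialize the mapping kmer -> positions (small references only)."""
        out: dict[bytes, list[int]] = {}
        for code, pos in zip(self.sorted_codes, self.sorted_positions):
            kmer = bytes(
                _BASE_FOR_CODE[(int(code) >> (2 * (self.k - 1 - j))) & 3]
                for j in range(self.k)
            )
            out.setdefault(kmer, []).append(int(pos))
        return out


def build_index(ref_base: bytes, k: int, max_occ: int | None = None) -> KmerIndex:
    """Index every k-mer occurrence of a reference ACGT stream.

    A reference shorter than k yields a valid empty index (matching then
    degenerates to all-literal output).  ``max_occ`` caps the number of
    positions returned per k-mer at lookup time, keeping the earliest ones;
    this bounds extension work in massive repeats.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > MAX_K:
        raise ConfigurationError(f"k must be <= {MAX_K}")
    codes = pack_kmers(ref_base, k)
    # stable sort keeps positions ascending within each k-mer
    order = np.argsort(codes, kind="stable")
    return KmerIndex(
        k=k,
        ref_length=len(ref_base),
        sorted_codes=codes[order],
        sorted_positions=order.astype(np.int64),
        max_occ=max_occ,
    )
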