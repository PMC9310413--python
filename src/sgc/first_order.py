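"""First-order compression: greedy longest-match of a target base stream
against the reference via the k-mer index.

At cursor c the k-mer ``target[c:c+k]`` is looked up; every occurrence in
the reference is extended forward as far as the exact match holds
(a maximal exact match anchored at the cursor), and the longest extension
wins.  Matched spans become ``Match(position, length)`` tokens, unmatched
symbols accumulate into ``Literal`` tokens; adjacent literals are merged.
A cursor with no anchor advances by one symbol, which maximizes the chance
of recovering a match immediately after an isolated mismatch.

Tie-break among equally long candidates: the position whose delta to the
previous match's end has the smallest absolute value, then the smallest
position.  Small deltas keep the archive's delta-coded positions cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorruptionError
from .kmer_index import KmerIndex, pack_kmers

_CHUNK = 4096


@dataclass(frozen=True)
class Match:
    """An exact copy of ``length`` bases from ``position`` in the reference."""

    position: int
    length: int


@dataclass(frozen=True)
class Literal:
    """Verbatim bases with no accepted reference match."""

    data: bytes


FirstOrderToken = Match | Literal


@dataclass
class FirstOrderStream:
    """Ordered token stream reproducing one target base stream."""

    seq_id: int
    tokens: list[FirstOrderToken]


def common_prefix_length(a: bytes, b: bytes, i: int, j: int) -> int:
    """Length of the longest common prefix of a[i:] and b[j:]."""
    n = min(len(a) - i, len(b) - j)
    done = 0
    while done < n:
        step = min(_CHUNK, n - done)
        if a[i + done : i + done + step] == b[j + done : j + done + step]:
            done += step
            continue
        ca = a[i + done : i + done + step]
        cb = b[j + done : j + done + step]
        for x in range(step):
            if ca[x] != cb[x]:
                return done + x
    return n


def compress_first_order(
    target: bytes, ref: bytes, idx: KmerIndex, seq_id: int = 0
) -> FirstOrderStream:
    """Greedy MEM factorization of ``target`` against ``ref``.

    ``idx`` must have been built from ``ref``.  Inputs with no shared
    k-mer compress to a single literal.
    """
    k = idx.k
    n = len(target)
    tokens: list[FirstOrderToken] = []
    lit = bytearray()

    def flush() -> None:
        if lit:
            tokens.append(Literal(bytes(lit)))
            lit.clear()

    if n == 0:
        return FirstOrderStream(seq_id, tokens)
    if n < k or idx.size == 0:
        tokens.append(Literal(target))
        return FirstOrderStream(seq_id, tokens)

    codes = pack_kmers(target, k)
    lo = np.searchsorted(idx.sorted_codes, codes, side="left")
    hi = np.searchsorted(idx.sorted_codes, codes, side="right")
    anchors = np.flatnonzero(lo < hi)
    positions = idx.sorted_positions
    max_occ = idx.max_occ

    c = 0
    prev_end = 0
    last = n - k  # last cursor that can host an anchor
    while c <= last:
        a = int(np.searchsorted(anchors, c, side="left"))
        if a >= anchors.size:
            break
        nxt = int(anchors[a])
        if nxt > c:
            lit += target[c:nxt]
            c = nxt
        cands = positions[lo[c] : hi[c]]
        if max_occ is not None and cands.size > max_occ:
            cands = cands[:max_occ]
        best_len = -1
        best_pos = -1
        best_delta = 0
        for p in cands:
            p = int(p)
            length = k + common_prefix_length(target, ref, c + k, p + k)
            delta = abs(p - prev_end)
            if length > best_len or (
                length == best_len
                and (delta < best_delta or (delta == best_delta and p < best_pos))
            ):
                best_len, best_pos, best_delta = length, p, delta
        flush()
        tokens.append(Match(best_pos, best_len))
        prev_end = best_pos + best_len
        c += best_len
    if c < n:
        lit += target[c:]
    flush()
    return FirstOrderStream(seq_id, tokens)


def decompress_first_order(stream: FirstOrderStream, ref: bytes) -> bytes:
    """Exact inverse of :func:`compress_first_order`."""
    parts: list[bytes] = []
    for tok in stream.tokens:
        if isinstance(tok, Match):
            if tok.position < 0 or tok.length < 0 or tok.position + tok.length > len(ref):
                raise CorruptionError(
                    f"match ({tok.position},{tok.length}) outside reference "
                    f"of length {len(ref)}"
                )
            parts.append(ref[tok.position : tok.position + tok.length])
        else:
            parts.append(tok.data)
    return b"".join(parts)


def stream_length(stream: FirstOrderStream) -> int:
    """Number of target bases the stream reproduces."""
    total = 0
    for tok in stream.tokens:
        total += tok.length if isinstance(tok, Match) else len(tok.data)
    return total
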