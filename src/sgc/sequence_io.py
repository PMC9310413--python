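"""Lossless decomposition of FASTA records into base and auxiliary data.

A FASTA record carries more than its four-letter base stream: the header
line, the line-wrapping layout, soft-masked (lowercase) stretches, runs of
the unknown symbol ``N``, and occasional other symbols (IUPAC ambiguity
codes, gap characters, stray bytes).  Reference-based matching only makes
sense over a pure uppercase-ACGT stream, so each record is split into

* ``base`` — the uppercase A/C/G/T symbols only, and
* :class:`AuxiliaryData` — everything required to rebuild the original
  record byte-for-byte.

The extraction order is fixed (and therefore part of the archive format):

1. record the line layout and unwrap the sequence lines into one stream;
2. fold lowercase to uppercase, recording maximal lowercase intervals;
3. remove symbols outside {A,C,G,T,N}, recording (position, symbol) pairs;
4. remove runs of ``N``, recording intervals.

Each auxiliary sub-stream records positions in the coordinate frame that
exists at its own extraction step, so reconstruction simply applies the
steps in reverse without any coordinate remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._varint import ByteReader, encode_uvarint
from .errors import CorruptionError, ParseError

_A, _C, _G, _T, _N = 65, 67, 71, 84, 78
_ACGTN = np.array([_A, _C, _G, _T, _N], dtype=np.uint8)

_FLAG_TRAILING_NEWLINE = 1
_FLAG_CRLF = 2


@dataclass
class AuxiliaryData:
    """Everything in a FASTA record besides the uppercase-ACGT stream."""

    identifier: bytes = b""          # header line without the leading '>'
    num_lines: int = 0               # number of sequence lines
    line_width: int = 0              # dominant bases-per-line
    line_exceptions: list[tuple[int, int]] = field(default_factory=list)
    lowercase_intervals: list[tuple[int, int]] = field(default_factory=list)
    n_intervals: list[tuple[int, int]] = field(default_factory=list)
    special_chars: list[tuple[int, int]] = field(default_factory=list)
    trailing_newline: bool = True
    crlf: bool = False


@dataclass
class SequenceRecord:
    """One FASTA record split into base data and auxiliary data."""

    seq_id: int
    base: bytes
    aux: AuxiliaryData


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array as (start, length) pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.concatenate(([0], brk + 1))]
    ends = idx[np.concatenate((brk, [idx.size - 1]))]
    return [(int(s), int(e - s + 1)) for s, e in zip(starts, ends)]


def split_fasta(data: bytes) -> list[bytes]:
    """Split a FASTA file into raw per-record byte slices, order preserved."""
    if not data:
        return []
    if data[0:1] != b">":
        raise ParseError("FASTA input does not start with '>'", offset=0)
    starts = [0]
    pos = 0
    while True:
        pos = data.find(b"\n>", pos)
        if pos < 0:
            break
        starts.append(pos + 1)
        pos += 1
    starts.append(len(data))
    return [data[a:b] for a, b in zip(starts[:-1], starts[1:])]


def split_record(raw_record: bytes, seq_id: int = 0) -> SequenceRecord:
    """Split one raw FASTA record into base and auxiliary data.

    The inverse is :func:`reconstruct_record`; the pair is byte-exact for
    any record whose lines contain no bare ``\\n``.
    """
    if raw_record[0:1] != b">":
        raise ParseError("record does not start with '>'", offset=0)

    n_lf = raw_record.count(b"\n")
    n_crlf = raw_record.count(b"\r\n")
    crlf = n_lf > 0 and n_crlf == n_lf and raw_record.count(b"\r") == n_crlf
    work = raw_record.replace(b"\r\n", b"\n") if crlf else raw_record

    trailing = work.endswith(b"\n")
    body = work[:-1] if trailing else work
    lines = body.split(b"\n")
    identifier = lines[0][1:]
    seq_lines = lines[1:]

    lengths = [len(ln) for ln in seq_lines]
    if lengths:
        counts: dict[int, int] = {}
        first_seen: dict[int, int] = {}
        for i, ln in enumerate(lengths):
            counts[ln] = counts.get(ln, 0) + 1
            first_seen.setdefault(ln, i)
        # ties go to the earliest-seen length, so a short final line is the
        # exception rather than the rule
        width = max(counts, key=lambda w: (counts[w], -first_seen[w]))
    else:
        width = 0
    exceptions = [(i, ln) for i, ln in enumerate(lengths) if ln != width]

    stream = b"".join(seq_lines)
    arr = np.frombuffer(stream, dtype=np.uint8).copy()

    lower = (arr >= 97) & (arr <= 122)
    lowercase_intervals = _runs(lower)
    arr[lower] -= 32

    special = ~np.isin(arr, _ACGTN)
    special_pos = np.flatnonzero(special)
    special_chars = [(int(p), int(arr[p])) for p in special_pos]
    arr = arr[~special]

    n_mask = arr == _N
    n_intervals = _runs(n_mask)
    base = arr[~n_mask].tobytes()

    aux = AuxiliaryData(
        identifier=identifier,
        num_lines=len(seq_lines),
        line_width=width,
        line_exceptions=exceptions,
        lowercase_intervals=lowercase_intervals,
        n_intervals=n_intervals,
        special_chars=special_chars,
        trailing_newline=trailing,
        crlf=crlf,
    )
    return SequenceRecord(seq_id=seq_id, base=base, aux=aux)


def _insert_runs(arr: np.ndarray, intervals: list[tuple[int, int]],
                 fill: int) -> np.ndarray:
    """Insert runs of a fill byte so each (start, length) lands at start in
    the output frame."""
    total = sum(l for _, l in intervals)
    out_len = arr.size + total
    mask = np.zeros(out_len, dtype=bool)
    for s, l in intervals:
        if s < 0 or l < 1 or s + l > out_len:
            raise CorruptionError("interval out of range in auxiliary data")
        mask[s : s + l] = True
    if int(mask.sum()) != total:
        raise CorruptionError("overlapping intervals in auxiliary data")
    out = np.empty(out_len, dtype=np.uint8)
    out[mask] = fill
    out[~mask] = arr
    return out


def reconstruct_record(rec: SequenceRecord) -> bytes:
    """Rebuild the original FASTA record bytes from a split record."""
    aux = rec.aux
    arr = np.frombuffer(rec.base, dtype=np.uint8)

    arr = _insert_runs(arr, aux.n_intervals, _N)

    n_spec = len(aux.special_chars)
    out_len = arr.size + n_spec
    if n_spec:
        pos = np.array([p for p, _ in aux.special_chars], dtype=np.int64)
        sym = np.array([s for _, s in aux.special_chars], dtype=np.uint8)
        if np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] >= out_len:
            raise CorruptionError("special-character positions out of order")
        mask = np.zeros(out_len, dtype=bool)
        mask[pos] = True
        out = np.empty(out_len, dtype=np.uint8)
        out[mask] = sym
        out[~mask] = arr
        arr = out

    arr = arr.copy()
    for s, l in aux.lowercase_intervals:
        if s < 0 or l < 1 or s + l > arr.size:
            raise CorruptionError("lowercase interval out of range")
        seg = arr[s : s + l]
        letters = (seg >= 65) & (seg <= 90)
        seg[letters] += 32

    lengths = [aux.line_width] * aux.num_lines
    for i, ln in aux.line_exceptions:
        if i < 0 or i >= aux.num_lines:
            raise CorruptionError("line exception out of range")
        lengths[i] = ln
    if sum(lengths) != arr.size:
        raise CorruptionError("line layout does not cover the symbol stream")

    stream = arr.tobytes()
    pieces = [b">" + aux.identifier]
    off = 0
    for ln in lengths:
        pieces.append(stream[off : off + ln])
        off += ln
    text = b"\n".join(pieces)
    if aux.trailing_newline:
        text += b"\n"
    if aux.crlf:
        text = text.replace(b"\n", b"\r\n")
    return text


def _encode_intervals(out: bytearray, intervals: list[tuple[int, int]]) -> None:
    out += encode_uvarint(len(intervals))
    prev_end = 0
    for s, l in intervals:
        out += encode_uvarint(s - prev_end)
        out += encode_uvarint(l - 1)
        prev_end = s + l


def _decode_intervals(r: ByteReader) -> list[tuple[int, int]]:
    n = r.uvarint()
    out = []
    prev_end = 0
    for _ in range(n):
        s = prev_end + r.uvarint()
        l = r.uvarint() + 1
        out.append((s, l))
        prev_end = s + l
    return out


def encode_auxiliary(aux: AuxiliaryData) -> bytes:
    """Serialize auxiliary data; intervals are delta-coded varints."""
    out = bytearray()
    flags = (_FLAG_TRAILING_NEWLINE if aux.trailing_newline else 0) | (
        _FLAG_CRLF if aux.crlf else 0
    )
    out.append(flags)
    out += encode_uvarint(len(aux.identifier))
    out += aux.identifier
    out += encode_uvarint(aux.num_lines)
    out += encode_uvarint(aux.line_width)
    out += encode_uvarint(len(aux.line_exceptions))
    prev = 0
    for i, ln in aux.line_exceptions:
        out += encode_uvarint(i - prev)
        out += encode_uvarint(ln)
        prev = i
    _encode_intervals(out, aux.lowercase_intervals)
    _encode_intervals(out, aux.n_intervals)
    out += encode_uvarint(len(aux.special_chars))
    prev = -1
    for p, s in aux.special_chars:
        out += encode_uvarint(p - prev - 1)
        out.append(s)
        prev = p
    return bytes(out)


def decode_auxiliary(data: bytes) -> AuxiliaryData:
    """Inverse of :func:`encode_auxiliary`."""
    r = ByteReader(data)
    flags = r.byte()
    identifier = r.take(r.uvarint())
    num_lines = r.uvarint()
    width = r.uvarint()
    exceptions = []
    prev = 0
    for _ in range(r.uvarint()):
        i = prev + r.uvarint()
        exceptions.append((i, r.uvarint()))
        prev = i
    lowercase = _decode_intervals(r)
    n_intervals = _decode_intervals(r)
    specials = []
    prev = -1
    for _ in range(r.uvarint()):
        p = prev + 1 + r.uvarint()
        specials.append((p, r.byte()))
        prev = p
    return AuxiliaryData(
        identifier=identifier,
        num_lines=num_lines,
        line_width=width,
        line_exceptions=exceptions,
        lowercase_intervals=lowercase,
        n_intervals=n_intervals,
        special_chars=specials,
        trailing_newline=bool(flags & _FLAG_TRAILING_NEWLINE),
        crlf=bool(flags & _FLAG_CRLF),
    )


def read_fasta_records(data: bytes, first_seq_id: int = 0) -> list[SequenceRecord]:
    """Parse a whole FASTA file into split records with sequential ids."""
    return [
        split_record(raw, seq_id=first_seq_id + i)
        for i, raw in enumerate(split_fasta(data))
    ]
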