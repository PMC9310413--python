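"""Single-file indexed archive container.

Layout::

    magic "SGCA" | version | header | block index | blocks...

The header stores the compression parameters (k, number of second-order
references, minimum token run), the entropy backend identifier, a content
fingerprint of the reference genome's base stream, and the table mapping
sequence ids back to their source FASTA files.  The index holds one
(length, crc32) entry per sequence, so any block can be located in O(1)
and extracted on its own: per-sequence blocks are compressed independently,
which is what makes selective decompression possible.

Inside a block, token tags are packed as 2-bit codes ahead of the
payloads; match positions are delta-coded against the previous match's end
and zigzag-varint encoded; literal bases are 2-bit packed.

The final entropy stage is pluggable.  The default is bz2 — like the
block-sorting coder the scheme was designed around, it is a BWT-family
compressor — with zlib, lzma and store registered as alternatives and
:func:`register_backend` available for an external coder pass-through.
"""

from __future__ import annotations

import bz2
import io
import lzma
import zlib
from dataclasses import dataclass, field
from typing import BinaryIO, Callable

import numpy as np

from ._varint import ByteReader, encode_svarint, encode_uvarint
from .errors import ConfigurationError, CorruptionError
from .first_order import Literal, Match
from .second_order import Passthrough, RefMatch, SecondOrderStream, SecondOrderToken

MAGIC = b"SGCA"
VERSION = 1
FINGERPRINT_LEN = 16

_TAG_LITERAL = 0
_TAG_MATCH = 1
_TAG_REFMATCH = 2

DEFAULT_BACKEND = "bz2"

_BACKENDS: dict[str, tuple[Callable[[bytes], bytes], Callable[[bytes], bytes]]] = {
    "store": (lambda b: b, lambda b: b),
    "zlib": (lambda b: zlib.compress(b, 9), zlib.decompress),
    "bz2": (lambda b: bz2.compress(b, 9), bz2.decompress),
    "lzma": (lambda b: lzma.compress(b, preset=6), lzma.decompress),
}


def register_backend(
    name: str,
    compress: Callable[[bytes], bytes],
    decompress: Callable[[bytes], bytes],
) -> None:
    """Register an external entropy-coding backend (e.g. a BSC wrapper)."""
    _BACKENDS[name] = (compress, decompress)


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def entropy_compress(payload: bytes, backend: str) -> bytes:
    try:
        return _BACKENDS[backend][0](payload)
    except KeyError:
        raise ConfigurationError(f"unknown entropy backend {backend!r}") from None


def entropy_decompress(payload: bytes, backend: str) -> bytes:
    try:
        fn = _BACKENDS[backend][1]
    except KeyError:
        raise ConfigurationError(f"unknown entropy backend {backend!r}") from None
    try:
        return fn(payload)
    except Exception as exc:
        raise CorruptionError(f"entropy decoding failed: {exc}") from exc


# --- varint re-exports (public names of this module's wire primitives) ---

def encode_varint(n: int) -> bytes:
    """Standard 7-bit continuation varint of a non-negative integer."""
    return encode_uvarint(n)


def decode_varint(data: bytes, offset: int = 0) -> tuple[int, int]:
    """Decode one varint; returns (value, next offset)."""
    r = ByteReader(data, offset)
    return r.uvarint(), r.pos


# --- 2-bit base packing -------------------------------------------------

_PACK_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _PACK_CODE[_b] = _i
_UNPACK = np.frombuffer(b"ACGT", dtype=np.uint8)


def pack_bases(seq: bytes) -> bytes:
    """Pack an ACGT stream at 2 bits per base (zero-padded to a byte)."""
    vals = _PACK_CODE[np.frombuffer(seq, dtype=np.uint8)]
    if vals.size and vals.max() > 3:
        raise ValueError("cannot pack symbols outside ACGT")
    pad = (-vals.size) % 4
    if pad:
        vals = np.concatenate([vals, np.zeros(pad, dtype=np.uint8)])
    quads = vals.reshape(-1, 4)
    packed = quads[:, 0] << 6 | quads[:, 1] << 4 | quads[:, 2] << 2 | quads[:, 3]
    return packed.astype(np.uint8).tobytes()


def unpack_bases(data: bytes, n: int) -> bytes:
    """Inverse of :func:`pack_bases` for a stream of n bases."""
    if len(data) * 4 < n:
        raise CorruptionError("packed base stream shorter than declared")
    arr = np.frombuffer(data, dtype=np.uint8)
    vals = np.empty(arr.size * 4, dtype=np.uint8)
    vals[0::4] = arr >> 6
    vals[1::4] = (arr >> 4) & 3
    vals[2::4] = (arr >> 2) & 3
    vals[3::4] = arr & 3
    return _UNPACK[vals[:n]].tobytes()


# --- block payload ------------------------------------------------------

def serialize_block(stream: SecondOrderStream, aux_bytes: bytes) -> bytes:
    """Serialize one sequence's auxiliary bytes + second-order tokens."""
    out = bytearray()
    out += encode_uvarint(len(aux_bytes))
    out += aux_bytes
    toks = stream.tokens
    out += encode_uvarint(len(toks))
    tags = bytearray((len(toks) + 3) // 4)
    for i, tok in enumerate(toks):
        if isinstance(tok, RefMatch):
            tag = _TAG_REFMATCH
        elif isinstance(tok.token, Match):
            tag = _TAG_MATCH
        else:
            tag = _TAG_LITERAL
        tags[i >> 2] |= tag << ((i & 3) * 2)
    out += tags
    prev_end = 0
    for tok in toks:
        if isinstance(tok, RefMatch):
            out += encode_uvarint(tok.ref_seq_id)
            out += encode_uvarint(tok.token_position)
            out += encode_uvarint(tok.token_count)
        elif isinstance(tok.token, Match):
            m = tok.token
            out += encode_svarint(m.position - prev_end)
            out += encode_uvarint(m.length)
            prev_end = m.position + m.length
        else:
            data = tok.token.data
            out += encode_uvarint(len(data))
            out += pack_bases(data)
    return bytes(out)


def deserialize_block_payload(
    payload: bytes, seq_id: int, is_reference: bool = False
) -> tuple[SecondOrderStream, bytes]:
    """Inverse of :func:`serialize_block`; returns (stream, aux bytes)."""
    r = ByteReader(payload)
    aux_bytes = r.take(r.uvarint())
    ntok = r.uvarint()
    tags = r.take((ntok + 3) // 4)
    toks: list[SecondOrderToken] = []
    prev_end = 0
    for i in range(ntok):
        tag = (tags[i >> 2] >> ((i & 3) * 2)) & 3
        if tag == _TAG_REFMATCH:
            toks.append(RefMatch(r.uvarint(), r.uvarint(), r.uvarint()))
        elif tag == _TAG_MATCH:
            pos = prev_end + r.svarint()
            length = r.uvarint()
            if pos < 0:
                raise CorruptionError("negative match position")
            toks.append(Passthrough(Match(pos, length)))
            prev_end = pos + length
        elif tag == _TAG_LITERAL:
            n = r.uvarint()
            toks.append(Passthrough(Literal(unpack_bases(r.take((n + 3) // 4), n))))
        else:
            raise CorruptionError(f"invalid token tag at token {i}")
    if not r.exhausted:
        raise CorruptionError("trailing bytes after token payloads")
    return SecondOrderStream(seq_id, toks, is_reference=is_reference), aux_bytes


# --- archive container --------------------------------------------------

@dataclass
class ArchiveParams:
    k: int
    num_references: int
    min_run: int
    backend: str
    fingerprint: bytes
    file_table: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class Archive:
    """In-memory indexed container: header, per-sequence blocks, index."""

    params: ArchiveParams
    blocks: list[bytes]           # entropy-coded payloads
    crcs: list[int]

    @property
    def sequence_count(self) -> int:
        return len(self.blocks)

    @property
    def num_references_effective(self) -> int:
        return min(self.params.num_references, self.sequence_count)

    def _header_bytes(self) -> bytes:
        p = self.params
        h = bytearray()
        h += encode_uvarint(p.k)
        h += encode_uvarint(p.num_references)
        h += encode_uvarint(p.min_run)
        backend = p.backend.encode()
        h += encode_uvarint(len(backend))
        h += backend
        if len(p.fingerprint) != FINGERPRINT_LEN:
            raise ConfigurationError("fingerprint must be 16 bytes")
        h += p.fingerprint
        h += encode_uvarint(self.sequence_count)
        h += encode_uvarint(len(p.file_table))
        for name, count in p.file_table:
            nb = name.encode()
            h += encode_uvarint(len(nb))
            h += nb
            h += encode_uvarint(count)
        return bytes(h)

    def write(self, path_or_file) -> int:
        """Write the archive; returns the number of bytes written."""
        out = bytearray()
        out += MAGIC
        out.append(VERSION)
        header = self._header_bytes()
        out += encode_uvarint(len(header))
        out += header
        for block, crc in zip(self.blocks, self.crcs):
            out += encode_uvarint(len(block))
            out += encode_uvarint(crc)
        for block in self.blocks:
            out += block
        data = bytes(out)
        if hasattr(path_or_file, "write"):
            path_or_file.write(data)
        else:
            with open(path_or_file, "wb") as fh:
                fh.write(data)
        return len(data)

    def block_payload(self, seq_id: int) -> bytes:
        if not 0 <= seq_id < self.sequence_count:
            raise CorruptionError(f"sequence id {seq_id} out of range")
        block = self.blocks[seq_id]
        if zlib.crc32(block) != self.crcs[seq_id]:
            raise CorruptionError(f"block {seq_id} failed its checksum")
        return entropy_decompress(block, self.params.backend)


def serialize_streams(
    second_order: list[SecondOrderStream],
    aux_bytes: list[bytes],
    params: ArchiveParams,
) -> Archive:
    """Entropy-code one block per sequence into an in-memory archive."""
    if len(second_order) != len(aux_bytes):
        raise ValueError("stream and auxiliary lists differ in length")
    blocks = []
    crcs = []
    for stream, aux in zip(second_order, aux_bytes):
        payload = serialize_block(stream, aux)
        block = entropy_compress(payload, params.backend)
        blocks.append(block)
        crcs.append(zlib.crc32(block))
    return Archive(params=params, blocks=blocks, crcs=crcs)


def deserialize_block(
    archive: "Archive | ArchiveReader", seq_id: int
) -> tuple[SecondOrderStream, bytes]:
    """Decode one sequence's block into (SecondOrderStream, aux bytes)."""
    if isinstance(archive, ArchiveReader):
        return archive.read_block(seq_id)
    payload = archive.block_payload(seq_id)
    return deserialize_block_payload(
        payload, seq_id, is_reference=seq_id < archive.num_references_effective
    )


class _CountingFile:
    """Wrap a binary file, counting bytes actually read."""

    def __init__(self, fh: BinaryIO):
        self._fh = fh
        self.bytes_read = 0

    def read(self, n: int = -1) -> bytes:
        data = self._fh.read(n)
        self.bytes_read += len(data)
        return data

    def seek(self, pos: int, whence: int = io.SEEK_SET) -> int:
        return self._fh.seek(pos, whence)

    def close(self) -> None:
        self._fh.close()


class ArchiveReader:
    """Random-access reader with per-block extraction.

    Only the header and index are read at open; each block is read, checked
    against its crc32 and decoded on demand.  ``bytes_read`` and
    ``blocks_accessed`` expose the I/O footprint, which the selective
    decompression contract is stated (and tested) in terms of.
    """

    def __init__(self, path):
        self._fh = _CountingFile(open(path, "rb"))
        magic = self._fh.read(4)
        if magic != MAGIC:
            raise CorruptionError("not an sgc archive (bad magic)")
        version = self._fh.read(1)
        if not version or version[0] != VERSION:
            raise CorruptionError(f"unsupported archive version {version!r}")
        header_len, hdr_prefix = self._read_uvarint()
        header = self._fh.read(header_len)
        if len(header) != header_len:
            raise CorruptionError("truncated archive header")
        r = ByteReader(header)
        k = r.uvarint()
        num_refs = r.uvarint()
        min_run = r.uvarint()
        backend = r.take(r.uvarint()).decode()
        fingerprint = r.take(FINGERPRINT_LEN)
        self.sequence_count = r.uvarint()
        file_table = []
        for _ in range(r.uvarint()):
            name = r.take(r.uvarint()).decode()
            file_table.append((name, r.uvarint()))
        self.params = ArchiveParams(
            k=k,
            num_references=num_refs,
            min_run=min_run,
            backend=backend,
            fingerprint=fingerprint,
            file_table=file_table,
        )
        self.block_lengths: list[int] = []
        self.block_crcs: list[int] = []
        for _ in range(self.sequence_count):
            n, _ = self._read_uvarint()
            crc, _ = self._read_uvarint()
            self.block_lengths.append(n)
            self.block_crcs.append(crc)
        self._blocks_start = 4 + 1 + hdr_prefix + header_len + self._index_bytes()
        self._offsets = [0] * self.sequence_count
        off = self._blocks_start
        for i, n in enumerate(self.block_lengths):
            self._offsets[i] = off
            off += n
        self.blocks_accessed: set[int] = set()

    def _read_uvarint(self) -> tuple[int, int]:
        result = 0
        shift = 0
        nbytes = 0
        while True:
            b = self._fh.read(1)
            if not b:
                raise CorruptionError("truncated varint in archive")
            nbytes += 1
            result |= (b[0] & 0x7F) << shift
            if not b[0] & 0x80:
                return result, nbytes
            shift += 7

    def _index_bytes(self) -> int:
        total = 0
        for n, crc in zip(self.block_lengths, self.block_crcs):
            total += len(encode_uvarint(n)) + len(encode_uvarint(crc))
        return total

    @property
    def bytes_read(self) -> int:
        return self._fh.bytes_read

    @property
    def num_references_effective(self) -> int:
        return min(self.params.num_references, self.sequence_count)

    def read_block(self, seq_id: int) -> tuple[SecondOrderStream, bytes]:
        if not 0 <= seq_id < self.sequence_count:
            raise CorruptionError(f"sequence id {seq_id} out of range")
        self._fh.seek(self._offsets[seq_id])
        block = self._fh.read(self.block_lengths[seq_id])
        if len(block) != self.block_lengths[seq_id]:
            raise CorruptionError(f"block {seq_id} truncated")
        if zlib.crc32(block) != self.block_crcs[seq_id]:
            raise CorruptionError(f"block {seq_id} failed its checksum")
        self.blocks_accessed.add(seq_id)
        payload = entropy_decompress(block, self.params.backend)
        return deserialize_block_payload(
            payload, seq_id, is_reference=seq_id < self.num_references_effective
        )

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "ArchiveReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
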