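"""Variable-length integer coding (7-bit continuation form) with zigzag
mapping for signed values.

All multi-byte integers in auxiliary streams and token payloads go through
these helpers; deltas that may be negative are zigzag-mapped first.
"""

from __future__ import annotations

from .errors import CorruptionError


def encode_uvarint(n: int) -> bytes:
    """Encode a non-negative integer as a 7-bit continuation varint."""
    if n < 0:
        raise ValueError("uvarint requires a non-negative integer")
    out = bytearray()
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def zigzag(n: int) -> int:
    """Map a signed integer to an unsigned one (0,-1,1,-2,... -> 0,1,2,3,...)."""
    return (n << 1) if n >= 0 else ((-n << 1) - 1)


def unzigzag(u: int) -> int:
    return (u >> 1) ^ -(u & 1)


def encode_svarint(n: int) -> bytes:
    return encode_uvarint(zigzag(n))


class ByteReader:
    """Sequential reader over a bytes buffer with varint decoding.

    Raises :class:`CorruptionError` on truncation.
    """

    __slots__ = ("buf", "pos")

    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def uvarint(self) -> int:
        buf, pos = self.buf, self.pos
        shift = 0
        result = 0
        while True:
            if pos >= len(buf):
                raise CorruptionError("truncated varint")
            b = buf[pos]
            pos += 1
            result |= (b & 0x7F) << shift
            if not b & 0x80:
                self.pos = pos
                return result
            shift += 7
            if shift > 70:
                raise CorruptionError("varint too long")

    def svarint(self) -> int:
        return unzigzag(self.uvarint())

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise CorruptionError("truncated byte field")
        out = self.buf[self.pos : self.pos + n]
        self.pos += n
        return out

    def byte(self) -> int:
        if self.pos >= len(self.buf):
            raise CorruptionError("truncated byte field")
        b = self.buf[self.pos]
        self.pos += 1
        return b

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.buf)
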