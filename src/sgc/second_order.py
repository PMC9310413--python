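"""Second-order compression: matching first-order token streams against a
set of second-order references.

After first-order compression, sequences from the same collection still
share long identical stretches of *tokens* (the same matches against the
genome reference, the same literal fragments).  The first S compressed
sequences become second-order references: their token streams are indexed,
every other stream is greedily matched against them, and the references
themselves are chain-compressed — reference i may only match into
references 0..i-1, so the chain unrolls losslessly front to back.

Matching granularity is the whole first-order token: a ``Match`` token
matches only an identical (position, length) pair and a ``Literal`` only an
identical string.  A run of at least ``min_run`` consecutive equal tokens
is replaced by ``RefMatch(ref_seq_id, token_position, token_count)``;
everything else passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._varint import encode_svarint, encode_uvarint
from .errors import CorruptionError
from .first_order import FirstOrderStream, FirstOrderToken, Match

DEFAULT_NUM_REFERENCES = 40
DEFAULT_MIN_RUN = 2


@dataclass(frozen=True)
class RefMatch:
    """A run of tokens copied from a second-order reference's stream."""

    ref_seq_id: int
    token_position: int
    token_count: int


@dataclass(frozen=True)
class Passthrough:
    """A first-order token carried through unchanged."""

    token: FirstOrderToken


SecondOrderToken = RefMatch | Passthrough


@dataclass
class SecondOrderStream:
    seq_id: int
    tokens: list[SecondOrderToken]
    is_reference: bool = False


class TokenIndex:
    """Occurrence index over the tokens of the second-order references.

    ``locations(token)`` returns every (ref_seq_id, token_position) holding
    an equal token, in (id, position) order.  A token-pair table is kept
    alongside as a search accelerator: under the default ``min_run >= 2``
    any acceptable run must agree on its first two tokens, so candidate
    enumeration can start from the much sparser pair table without changing
    which run the greedy search selects.
    """

    def __init__(self) -> None:
        self._single: dict[FirstOrderToken, list[tuple[int, int]]] = {}
        self._pairs: dict[
            tuple[FirstOrderToken, FirstOrderToken], list[tuple[int, int]]
        ] = {}
        self.streams: dict[int, list[FirstOrderToken]] = {}

    def add_reference(self, stream: FirstOrderStream) -> None:
        toks = stream.tokens
        rid = stream.seq_id
        self.streams[rid] = toks
        for i, tok in enumerate(toks):
            self._single.setdefault(tok, []).append((rid, i))
            if i + 1 < len(toks):
                self._pairs.setdefault((tok, toks[i + 1]), []).append((rid, i))

    def locations(self, token: FirstOrderToken) -> list[tuple[int, int]]:
        return self._single.get(token, [])

    def pair_locations(
        self, first: FirstOrderToken, second: FirstOrderToken
    ) -> list[tuple[int, int]]:
        return self._pairs.get((first, second), [])

    @property
    def num_tokens(self) -> int:
        return sum(len(v) for v in self._single.values())


def select_second_order_references(
    streams: list[FirstOrderStream], num_references: int
) -> tuple[list[FirstOrderStream], list[FirstOrderStream]]:
    """Split a seq_id-ordered collection into (references, non-references).

    The references are simply the first ``num_references`` streams; the
    count is clamped to the collection size.
    """
    if num_references < 0:
        raise ValueError("number of second-order references must be >= 0")
    s = min(num_references, len(streams))
    return streams[:s], streams[s:]


def build_token_index(references: list[FirstOrderStream]) -> TokenIndex:
    """Index every token of every reference exactly once."""
    idx = TokenIndex()
    for ref in references:
        idx.add_reference(ref)
    return idx


def _extend_run(
    target: list[FirstOrderToken],
    t: int,
    ref_tokens: list[FirstOrderToken],
    tp: int,
) -> int:
    run = 0
    nt, nr = len(target), len(ref_tokens)
    while t + run < nt and tp + run < nr and target[t + run] == ref_tokens[tp + run]:
        run += 1
    return run


def compress_second_order(
    target: FirstOrderStream,
    idx: TokenIndex,
    min_run: int = DEFAULT_MIN_RUN,
    is_reference: bool = False,
) -> SecondOrderStream:
    """Greedy run-matching of one first-order stream against the indexed
    references.

    At token cursor t every candidate location of the current token is
    extended to its maximal run of consecutive equal tokens; the longest
    run wins (ties: lowest reference id, then lowest token position).  The
    run is accepted if it spans at least ``min_run`` tokens *and* its
    serialized form is strictly smaller than the passthrough encoding of
    the tokens it replaces — substituting a reference pointer that does not
    shrink the archive would only cost bytes.  Otherwise the token passes
    through and the cursor advances by one.
    """
    toks = target.tokens
    out: list[SecondOrderToken] = []
    t = 0
    nt = len(toks)
    use_pairs = min_run >= 2
    prev_end = 0  # end of the last passed-through Match (the delta chain)
    while t < nt:
        if use_pairs:
            cands = (
                idx.pair_locations(toks[t], toks[t + 1]) if t + 1 < nt else []
            )
        else:
            cands = idx.locations(toks[t])
        best_run = 0
        best_loc: tuple[int, int] | None = None
        for rid, tp in cands:
            run = _extend_run(toks, t, idx.streams[rid], tp)
            if run > best_run:
                best_run, best_loc = run, (rid, tp)
        if (
            best_loc is not None
            and best_run >= min_run
            and _refmatch_cost(best_loc, best_run)
            < _passthrough_cost(toks, t, best_run, prev_end)
        ):
            out.append(RefMatch(best_loc[0], best_loc[1], best_run))
            t += best_run
        else:
            tok = toks[t]
            out.append(Passthrough(tok))
            if isinstance(tok, Match):
                prev_end = tok.position + tok.length
            t += 1
    return SecondOrderStream(target.seq_id, out, is_reference=is_reference)


def _refmatch_cost(loc: tuple[int, int], run: int) -> int:
    """Serialized payload bytes of a RefMatch token."""
    return (
        len(encode_uvarint(loc[0]))
        + len(encode_uvarint(loc[1]))
        + len(encode_uvarint(run))
    )


def _passthrough_cost(
    toks: list[FirstOrderToken], t: int, run: int, prev_end: int
) -> int:
    """Serialized payload bytes of tokens t..t+run-1 if passed through,
    continuing the current match-position delta chain."""
    total = 0
    for tok in toks[t : t + run]:
        if isinstance(tok, Match):
            total += len(encode_svarint(tok.position - prev_end))
            total += len(encode_uvarint(tok.length))
            prev_end = tok.position + tok.length
        else:
            n = len(tok.data)
            total += len(encode_uvarint(n)) + (n + 3) // 4
    return total


def chain_compress_references(
    references: list[FirstOrderStream], min_run: int = DEFAULT_MIN_RUN
) -> list[SecondOrderStream]:
    """Compress each reference against its predecessors only.

    Reference 0 comes out all-passthrough; reference i may RefMatch only
    into ids < i, so expansion can proceed front to back.
    """
    idx = TokenIndex()
    out: list[SecondOrderStream] = []
    for ref in references:
        out.append(compress_second_order(ref, idx, min_run, is_reference=True))
        idx.add_reference(ref)
    return out


def decompress_second_order(
    stream: SecondOrderStream, expanded_references: list[FirstOrderStream]
) -> FirstOrderStream:
    """Exact inverse of second-order compression.

    ``expanded_references`` must already be plain first-order streams (use
    :func:`expand_references` for the chained reference group).
    """
    by_id = {r.seq_id: r.tokens for r in expanded_references}
    toks: list[FirstOrderToken] = []
    for tok in stream.tokens:
        if isinstance(tok, RefMatch):
            ref_toks = by_id.get(tok.ref_seq_id)
            if ref_toks is None:
                raise CorruptionError(
                    f"reference stream {tok.ref_seq_id} is not available"
                )
            end = tok.token_position + tok.token_count
            if tok.token_position < 0 or end > len(ref_toks):
                raise CorruptionError(
                    f"token run [{tok.token_position},{end}) outside "
                    f"reference stream {tok.ref_seq_id}"
                )
            toks.extend(ref_toks[tok.token_position : end])
        else:
            toks.append(tok.token)
    return FirstOrderStream(stream.seq_id, toks)


def expand_references(
    chained: list[SecondOrderStream],
) -> list[FirstOrderStream]:
    """Unroll the chained second-order reference group front to back.

    A RefMatch pointing at a reference not yet expanded (a forward
    reference) is corruption.
    """
    expanded: list[FirstOrderStream] = []
    seen: set[int] = set()
    for so in chained:
        for tok in so.tokens:
            if isinstance(tok, RefMatch) and tok.ref_seq_id not in seen:
                raise CorruptionError(
                    f"forward reference to stream {tok.ref_seq_id} "
                    f"while expanding stream {so.seq_id}"
                )
        expanded.append(decompress_second_order(so, expanded))
        seen.add(so.seq_id)
    return expanded
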