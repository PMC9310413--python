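"""Second-order (cross-sequence) token stream compression."""

from __future__ import annotations

import numpy as np
import pytest

from sgc import (
    FirstOrderStream,
    Literal,
    Match,
    Passthrough,
    RefMatch,
    build_index,
    build_token_index,
    chain_compress_references,
    compress_first_order,
    compress_second_order,
    decompress_second_order,
    expand_references,
    select_second_order_references,
)
from sgc.errors import CorruptionError

from conftest import random_base_stream


def fo(seq_id, *tokens):
    return FirstOrderStream(seq_id, list(tokens))


def test_reference_selection_takes_first_s_by_id():
    streams = [fo(i) for i in range(100)]
    refs, others = select_second_order_references(streams, 40)
    assert [r.seq_id for r in refs] == list(range(40))
    assert [o.seq_id for o in others] == list(range(40, 100))


def test_reference_selection_clamps_to_collection_size():
    streams = [fo(i) for i in range(10)]
    refs, others = select_second_order_references(streams, 40)
    assert len(refs) == 10 and others == []


def test_zero_references_degenerates_to_identity():
    streams = [fo(0, Match(0, 20), Literal(b"AC"))]
    refs, others = select_second_order_references(streams, 0)
    assert refs == [] and others == streams
    idx = build_token_index(refs)
    so = compress_second_order(streams[0], idx)
    assert all(isinstance(t, Passthrough) for t in so.tokens)
    assert decompress_second_order(so, []).tokens == streams[0].tokens


def test_token_index_counts_and_verifies():
    ref = fo(0, Match(0, 10), Literal(b"AC"), Match(11, 5))
    idx = build_token_index([ref])
    assert idx.num_tokens == 3
    assert idx.locations(Match(0, 10)) == [(0, 0)]
    assert idx.locations(Literal(b"AC")) == [(0, 1)]
    assert idx.locations(Match(99, 1)) == []


def test_token_index_pairs_locations_in_id_order():
    a = fo(0, Match(0, 10), Literal(b"AC"))
    b = fo(1, Match(0, 10), Literal(b"AC"))
    idx = build_token_index([a, b])
    assert idx.locations(Match(0, 10)) == [(0, 0), (1, 0)]


def test_identical_target_collapses_to_one_refmatch():
    ref = fo(0, Match(0, 10), Literal(b"AC"), Match(11, 5))
    idx = build_token_index([ref])
    target = fo(7, Match(0, 10), Literal(b"AC"), Match(11, 5))
    so = compress_second_order(target, idx)
    assert so.tokens == [RefMatch(0, 0, 3)]
    assert decompress_second_order(so, [ref]).tokens == target.tokens


def test_disjoint_target_is_all_passthrough():
    ref = fo(0, Match(0, 10), Literal(b"AC"))
    idx = build_token_index([ref])
    target = fo(1, Match(5, 10), Literal(b"GT"))
    so = compress_second_order(target, idx)
    assert all(isinstance(t, Passthrough) for t in so.tokens)


def test_run_below_min_run_passes_through():
    big_literal = Literal(b"ACGT" * 20)
    ref = fo(0, big_literal, Match(0, 10))
    idx = build_token_index([ref])
    # only one shared token in a row: stays a passthrough under min_run=2
    target = fo(1, big_literal, Literal(b"GT"))
    so = compress_second_order(target, idx, min_run=2)
    assert all(isinstance(t, Passthrough) for t in so.tokens)
    so1 = compress_second_order(target, idx, min_run=1)
    assert so1.tokens[0] == RefMatch(0, 0, 1)


def test_refmatch_rejected_when_not_cheaper_than_passthrough():
    # the shared pair sits at token position 600 of the reference stream,
    # so the pointer costs 1+2+1 bytes; the same tokens passed through cost
    # only 2+2 bytes because the preceding match makes the delta zero —
    # the substitution would not shrink the archive and must not happen
    fillers = [Match(i * 2000 + 5, 7) for i in range(600)]
    ref = fo(0, *fillers, Match(100_050, 98), Literal(b"A"))
    idx = build_token_index([ref])
    target = fo(1, Match(100_000, 50), Match(100_050, 98), Literal(b"A"))
    so = compress_second_order(target, idx)
    assert all(isinstance(t, Passthrough) for t in so.tokens)
    # the identical pair early in the reference stream is cheaper as a
    # pointer when the delta chain does not favour passthrough
    ref2 = fo(0, Match(100_050, 98), Literal(b"A"))
    idx2 = build_token_index([ref2])
    target2 = fo(1, Match(100_050, 98), Literal(b"A"))
    so2 = compress_second_order(target2, idx2)
    assert so2.tokens == [RefMatch(0, 0, 2)]


def test_single_reference_chain_is_all_passthrough():
    ref = fo(0, Match(0, 10), Literal(b"AC"))
    [so] = chain_compress_references([ref])
    assert all(isinstance(t, Passthrough) for t in so.tokens)
    assert so.is_reference


def test_two_identical_references_chain_to_one_refmatch():
    a = fo(0, Match(0, 10), Literal(b"AC"), Match(11, 5))
    b = fo(1, Match(0, 10), Literal(b"AC"), Match(11, 5))
    chained = chain_compress_references([a, b])
    assert chained[1].tokens == [RefMatch(0, 0, 3)]
    expanded = expand_references(chained)
    assert [e.tokens for e in expanded] == [a.tokens, b.tokens]


def test_dangling_reference_id_is_corruption():
    so = compress_second_order(
        fo(1, Match(0, 10), Literal(b"AC")),
        build_token_index([fo(0, Match(0, 10), Literal(b"AC"))]),
    )
    with pytest.raises(CorruptionError, match="0"):
        decompress_second_order(so, [])


def test_forward_reference_detected_on_expansion():
    from sgc import SecondOrderStream

    chained = [SecondOrderStream(0, [RefMatch(1, 0, 2)], is_reference=True)]
    with pytest.raises(CorruptionError):
        expand_references(chained)


def _mutant_streams(rng, n_seqs, ref_len=20_000, snp=0.001, k=12):
    ref = random_base_stream(rng, ref_len)
    idx = build_index(ref, k)
    streams = []
    for i in range(n_seqs):
        t = bytearray(ref)
        for p in rng.integers(0, ref_len, size=int(ref_len * snp)):
            t[p] = b"ACGT"[int(rng.integers(0, 4))]
        streams.append(compress_first_order(bytes(t), ref, idx, seq_id=i))
    return ref, streams


def test_full_two_order_round_trip_on_mutant_collection(rng):
    _, streams = _mutant_streams(rng, 12)
    refs, others = select_second_order_references(streams, 5)
    chained = chain_compress_references(refs)
    idx = build_token_index(refs)
    expanded = expand_references(chained)
    assert [e.tokens for e in expanded] == [r.tokens for r in refs]
    for s in others:
        so = compress_second_order(s, idx)
        back = decompress_second_order(so, expanded)
        assert back.tokens == s.tokens
        assert back.seq_id == s.seq_id


def test_identical_collection_collapses_to_single_tokens():
    # identical multi-token streams: every non-reference collapses to one token
    toks = [Match(0, 100), Literal(b"ACGT"), Match(200, 50)]
    streams = [fo(i, *toks) for i in range(6)]
    refs, others = select_second_order_references(streams, 2)
    tindex = build_token_index(refs)
    for s in others:
        so = compress_second_order(s, tindex)
        assert len(so.tokens) == 1
        assert so.tokens[0] == RefMatch(0, 0, 3)


def test_tie_break_prefers_lowest_reference_id():
    a = fo(0, Match(0, 10), Literal(b"AC"))
    b = fo(1, Match(0, 10), Literal(b"AC"))
    idx = build_token_index([a, b])
    so = compress_second_order(fo(2, Match(0, 10), Literal(b"AC")), idx)
    assert so.tokens == [RefMatch(0, 0, 2)]
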