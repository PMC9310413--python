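# Methods

## The compression scheme

`sgc` is a lossless, reference-based compressor for collections of highly
similar genome sequences in FASTA format. It exploits redundancy at two
levels.

**Pre-processing.** Each FASTA record is split into *base data* — the
uppercase A/C/G/T stream — and *auxiliary data*: the header line, the
line-wrapping layout (dominant width plus exceptions), soft-masked
(lowercase) intervals, runs of `N`, and any other symbol (IUPAC ambiguity
codes, gaps, stray bytes) as explicit (position, symbol) pairs. The
extraction order is frozen as: line layout → case folding → special-symbol
removal → `N`-run removal. Each auxiliary sub-stream records positions in
the coordinate frame existing at its own extraction step, so
reconstruction applies the steps in reverse with no coordinate remapping.
The pair split/reconstruct is byte-exact, including trailing-newline state
and (per-record) CRLF line endings; a record mixing line-ending
conventions degrades gracefully by storing stray `\r` bytes as special
symbols.

**First order (target vs. genome reference).** All overlapping k-mers of
the reference base stream are 2-bit packed (exact for k ≤ 31, so keys
collide only for equal strings) and held as parallel sorted
(key, position) arrays queried by binary search. Compression is greedy
maximal-exact-match factorization: at cursor *c* the k-mer
`target[c:c+k]` is looked up, every occurrence is extended forward while
the exact match holds, and the longest extension is emitted as
`Match(position, length)`; unmatched symbols accumulate into `Literal`
tokens and a cursor with no anchor advances by one symbol. Ties among
equally long candidates go to the position whose delta from the previous
match's end is smallest in absolute value (then the smallest position),
which keeps the archive's delta-coded positions short. There is no
lookahead and no match shortening; the factorization is deliberately plain
greedy.

**Second order (target vs. target).** After first-order compression,
sequences of one collection still share identical stretches of *tokens*.
The first S compressed sequences become second-order references: their
token streams are indexed (one entry per token; a `Match` token is equal
only to an identical (position, length) pair, a `Literal` only to an
identical string) and every other stream is greedily matched against
them, replacing runs of at least `min_run` consecutive equal tokens by
`RefMatch(ref_seq_id, token_position, token_count)`. The references
themselves are chain-compressed — reference *i* may match only into
references 0..i−1 — so the whole group unrolls losslessly front to back,
and a non-reference depends only on the reference group. A substitution
is additionally required to serialize strictly smaller than the
passthrough encoding of the tokens it covers (continuing the
match-position delta chain); a reference pointer that does not shrink the
block would only cost bytes, so it is never emitted. Under the default
`min_run ≥ 2` the candidate search runs off an internal token-*pair*
table; any acceptable run must agree on its first two tokens, so this
prunes the ubiquitous one-base-literal fingerprints without changing
which run the greedy search selects.

**Archive.** One entropy-coded block per sequence (auxiliary bytes +
second-order tokens), an index of (length, crc32) entries for O(1) block
location, and a header carrying k, S, `min_run`, the backend identifier,
the source-file table, and a SHA-256/128-bit fingerprint of the reference
base stream so decompression fails fast with the wrong reference. Token
tags are 2-bit codes packed ahead of the payloads; match positions are
zigzag-varint deltas against the previous passthrough match's end;
literal bases are 2-bit packed; intervals are delta-coded varints.
Because blocks are compressed independently, selective extraction of
sequence *j* reads only header + index + the reference block group +
block *j* (for a reference *i*: only blocks 0..i). Decompression needs no
k-mer index at all and is single-threaded by design — it is I/O-bound.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 14 | anchor k-mer length (bases). Large enough that anchors in a ~1 Mb–1 Gb reference are near-unique, small enough to re-anchor quickly after a mismatch. Matches shorter than k are undetectable by the index and become literals. |
| `S` (`-S`) | 40 | number of second-order references. More references raise the chance of cross-sequence token matches and the per-lookup work; the sweep reported by the acceptance script measures this trade-off. |
| `min_run` | 2 | minimum token run for a RefMatch; a 1-token pointer rarely beats the token it replaces (and the byte-cost guard enforces the cases where it does not). |
| `backend` | `bz2` | final entropy stage. bz2 is a BWT block-sorting coder of the same family as the scheme's original final stage; `zlib`, `lzma`, `store` are registered, and `register_backend()` accepts an external coder pass-through. |
| `workers` | 1 | thread count for the first/second-order matching stages. Tasks share the reference and index read-only and results are collected in sequence-id order, so archive bytes are invariant under the worker count. |
| `max_occ` | unlimited | cap on index occurrences considered per anchor (earliest kept); bounds extension work inside massive repeats. |

## Synthetic data

The fixture generator emulates a resequencing collection: a uniform-random
ACGT reference and *n* independently mutated copies (star phylogeny) with
per-base SNP rate, insertion/deletion rates with geometric(p) lengths,
soft-masked runs, `N` runs, rare ambiguity symbols, and fixed-width line
wrapping. The standard conditions used throughout the test suite are
1 Mb reference, 50 sequences, SNP 1e-3, indels 1e-4 each with
geometric(0.5) lengths, 5 % soft-masked in mean-300 bp runs, `N` runs at
1e-5 per base of mean length 50, specials at 1e-6, width 60, seed 42.
Every derived sequence ships with a plain-text mutation log; a scalar
replay of the log (independent of the vectorized generation path) must
reproduce the emitted FASTA byte-for-byte.

What the generator does *not* model: shared variants between sequences
(real cohorts share haplotypes, so real collections give the second order
far more to chew on than independent mutants do), structural variants,
GC bias, and compositional repeats. Passing tests therefore demonstrate
losslessness, selectivity and determinism on realistic *structure*, but
the absolute ratios on real cohorts will differ — in the second order's
favour.

## Numerical and design choices

- **Coordinate frames.** All positions and intervals are 0-based,
  intervals half-open at serialization; auxiliary streams use the frame of
  their own extraction step (see above) to avoid quadratic remapping.
- **Dominant line width.** Most frequent line length, ties to the
  earliest-seen length, so the conventional short final line is the
  exception rather than the rule.
- **Lowercase `n`.** Recorded in both the lowercase intervals and the `N`
  intervals; reconstruction restores case after `N` insertion, keeping
  each stream single-purpose.
- **Anchor failure.** A cursor with no index hit advances by one symbol
  (not by k): this maximizes match recovery right after an isolated
  mismatch. Literal stretches are skipped in bulk using a precomputed
  anchor table, so the advance-by-1 policy has no quadratic cost.
- **Tie-breaks** are total and deterministic everywhere (first order:
  smallest |position delta| then smallest position; second order: longest
  run, then lowest reference id, then lowest token position), which makes
  archives reproducible bit-for-bit across runs and worker counts.
- **Degenerate inputs.** Empty records, header-only records, all-`N` or
  all-lowercase records, targets shorter than k, empty collections and
  S = 0 (second order degenerates to the identity) are all well-defined
  and round-trip.
- **Integrity.** Each block carries a crc32; corruption is detected and
  confined to the damaged block, and a wrong reference genome is rejected
  via the header fingerprint before any block is decoded.

## Problem sizes used in the tests

The suite exercises the standard conditions above (50 × ~1 Mb) for the
end-to-end properties, 2 kb pairs for brute-force oracle comparisons of
the matcher, and 50 identical 1 Mb copies against an unrelated reference
for the second-order collapse experiment. On one CPU the full suite runs
in a few minutes; the acceptance script re-generates everything from its
`--seed` and finishes in under five.

## Known limitations

- Absolute compression ratios depend on the entropy backend; the default
  bz2 stage is not the original external block-sorting coder, so archive
  sizes are not comparable to tools built on it, and archives are not
  interchangeable with any other implementation's format.
- Greedy matching is suboptimal by construction (no lookahead); repeats
  can trap the cursor into shorter-than-optimal factorizations.
- The second-order unit is the whole token: a single-base difference
  inside a long literal breaks the run. Sub-token matching is out of
  scope.
- One sequence must fit in memory uncompressed; the first-order stage
  additionally holds the reference and its index (~16 bytes/base).
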