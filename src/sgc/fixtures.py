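"""Synthetic reference genomes and mutated collections.

The compressor exploits two layers of redundancy: target-vs-reference
similarity (first order) and target-vs-target similarity (second order).
This module generates data with exactly that structure — a uniform-random
reference plus independently mutated copies (a star phylogeny, which is a
reasonable stand-in for the intra-species similarity of a resequencing
collection without modelling haplotype structure) — decorated with the
messy parts of real FASTA: soft-masked (lowercase) intervals, runs of
``N``, rare ambiguity symbols, and line wrapping.

Every derived sequence is emitted together with a plain-text mutation log
sufficient to rebuild it from the reference; :func:`replay_mutation_log`
is a deliberately simple scalar re-implementation used as a self-check
oracle against the vectorized generation path.

All sampling is driven by ``numpy`` generators seeded from the profile, so
a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_SPECIALS = b"RYSWKMBDHV"


@dataclass(frozen=True)
class MutationProfile:
    """Per-base event rates and decoration parameters for one collection.

    Defaults are the frozen standard fixture of the test suite: SNPs at
    1e-3 per base, indels at 1e-4 each with geometric(0.5) lengths
    (mean 2 bp), ~5% of each sequence soft-masked in runs of mean 300 bp,
    N runs at 1e-5 per base of mean length 50, ambiguity symbols at 1e-6,
    60-column wrapping, seed 42.
    """

    snp_rate: float = 1e-3
    ins_rate: float = 1e-4
    del_rate: float = 1e-4
    indel_geom_p: float = 0.5
    softmask_fraction: float = 0.05
    softmask_mean_run: float = 300.0
    n_run_rate: float = 1e-5
    n_mean_length: float = 50.0
    special_rate: float = 1e-6
    line_width: int = 60
    seed: int = 42

    def validate(self) -> None:
        for name in ("snp_rate", "ins_rate", "del_rate", "indel_geom_p",
                     "softmask_fraction", "n_run_rate", "special_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.line_width < 1:
            raise ConfigurationError("line_width must be >= 1")


STANDARD_PROFILE = MutationProfile()
STANDARD_REFERENCE_LENGTH = 1_000_000
STANDARD_COLLECTION_SIZE = 50


def _wrap(stream: bytes, width: int) -> bytes:
    return b"\n".join(stream[i : i + width] for i in range(0, len(stream), width))


def generate_reference(
    length: int, seed: int, width: int = 60, identifier: str = "reference"
) -> bytes:
    """Uniform-ACGT reference genome as FASTA bytes, deterministic per seed."""
    if length < 0:
        raise ConfigurationError("length must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    stream = _ACGT[rng.integers(0, 4, size=length)].tobytes()
    header = f">{identifier}\n".encode()
    if length == 0:
        return header
    return header + _wrap(stream, width) + b"\n"


def _child_seed(seed: int, i: int) -> int:
    return (seed * 1_000_003 + 2_654_435_761 * (i + 1)) % (2**31 - 1)


def derive_sequence(
    ref_base: bytes, profile: MutationProfile, seed: int, identifier: str
) -> tuple[bytes, str]:
    """One mutated, decorated FASTA record plus its mutation log."""
    profile.validate()
    rng = np.random.Generator(np.random.PCG64(seed))
    arr = np.frombuffer(ref_base, dtype=np.uint8).copy()
    L = arr.size
    log: list[str] = [f"# mutation log, seed {seed}", f"H {identifier}"]

    # substitutions: new base always differs from the old one
    sub_pos = np.flatnonzero(rng.random(L) < profile.snp_rate)
    if sub_pos.size:
        old = _CODE[arr[sub_pos]]
        new = (old + rng.integers(1, 4, size=sub_pos.size)) % 4
        for p, o, v in zip(sub_pos, old, new):
            log.append(f"S {int(p)} {chr(_ACGT[o])} {chr(_ACGT[v])}")
        arr[sub_pos] = _ACGT[new]

    # deletions: drop runs, skipping starts inside an earlier deletion
    del_starts = np.flatnonzero(rng.random(L) < profile.del_rate)
    del_lens = rng.geometric(profile.indel_geom_p, size=del_starts.size)
    keep = np.ones(L, dtype=bool)
    prev_end = 0
    for s, l in zip(del_starts, del_lens):
        s, l = int(s), int(min(l, L - s))
        if s < prev_end:
            continue
        keep[s : s + l] = False
        log.append(f"D {s} {l}")
        prev_end = s + l

    # insertions: random bases inserted before a reference position
    ins_pos = np.flatnonzero(rng.random(L) < profile.ins_rate)
    ins_lens = rng.geometric(profile.indel_geom_p, size=ins_pos.size)
    ins_chunks = []
    for p, l in zip(ins_pos, ins_lens):
        bases = _ACGT[rng.integers(0, 4, size=int(l))].tobytes()
        ins_chunks.append((int(p), bases))
        log.append(f"I {int(p)} {bases.decode()}")

    kept = arr[keep]
    if ins_chunks:
        kept_before = np.cumsum(keep) - keep  # ref pos -> post-deletion index
        idx = np.concatenate(
            [np.full(len(b), kept_before[p], dtype=np.int64) for p, b in ins_chunks]
        )
        vals = np.frombuffer(b"".join(b for _, b in ins_chunks), dtype=np.uint8)
        kept = np.insert(kept, idx, vals)
    arr = kept
    L2 = arr.size

    # N runs overwrite bases (clipped at the end of the sequence)
    n_starts = np.flatnonzero(rng.random(L2) < profile.n_run_rate)
    n_lens = rng.geometric(1.0 / max(profile.n_mean_length, 1.0), size=n_starts.size)
    for s, l in zip(n_starts, n_lens):
        s, l = int(s), int(min(l, L2 - s))
        arr[s : s + l] = ord("N")
        log.append(f"N {s} {l}")

    # rare ambiguity symbols
    sp_pos = np.flatnonzero(rng.random(L2) < profile.special_rate)
    sp_sym = rng.integers(0, len(_SPECIALS), size=sp_pos.size)
    for p, s in zip(sp_pos, sp_sym):
        arr[int(p)] = _SPECIALS[int(s)]
        log.append(f"X {int(p)} {chr(_SPECIALS[int(s)])}")

    # soft-masking: lowercase runs covering ~softmask_fraction of the stream
    if profile.softmask_fraction > 0 and L2 > 0:
        n_runs = int(round(L2 * profile.softmask_fraction / profile.softmask_mean_run))
        m_starts = np.sort(rng.integers(0, L2, size=n_runs))
        m_lens = rng.geometric(1.0 / max(profile.softmask_mean_run, 1.0),
                               size=n_runs)
        mask = np.zeros(L2, dtype=bool)
        for s, l in zip(m_starts, m_lens):
            s, l = int(s), int(min(l, L2 - s))
            mask[s : s + l] = True
            log.append(f"M {s} {l}")
        upper = (arr >= 65) & (arr <= 90)
        arr[mask & upper] += 32

    log.append(f"W {profile.line_width}")
    record = f">{identifier}\n".encode()
    if L2:
        record += _wrap(arr.tobytes(), profile.line_width) + b"\n"
    return record, "\n".join(log) + "\n"


def replay_mutation_log(ref_base: bytes, log_text: str) -> bytes:
    """Rebuild a derived record from the reference and its log.

    Scalar reference implementation, independent of the vectorized
    generation path; used as a self-check oracle.
    """
    subs: dict[int, int] = {}
    dels: dict[int, int] = {}
    ins: dict[int, bytes] = {}
    n_runs: list[tuple[int, int]] = []
    specials: list[tuple[int, int]] = []
    masks: list[tuple[int, int]] = []
    width = 60
    identifier = "seq"
    for line in log_text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split(" ", 1)
        op, rest = parts[0], parts[1]
        if op == "H":
            identifier = rest
        elif op == "S":
            p, _old, new = rest.split()
            subs[int(p)] = ord(new)
        elif op == "D":
            p, l = rest.split()
            dels[int(p)] = int(l)
        elif op == "I":
            p, bases = rest.split()
            ins[int(p)] = bases.encode()
        elif op == "N":
            s, l = rest.split()
            n_runs.append((int(s), int(l)))
        elif op == "X":
            p, sym = rest.split()
            specials.append((int(p), ord(sym)))
        elif op == "M":
            s, l = rest.split()
            masks.append((int(s), int(l)))
        elif op == "W":
            width = int(rest)

    out = bytearray()
    skip_until = 0
    for p in range(len(ref_base)):
        if p in ins:
            out += ins[p]
        if p in dels:
            skip_until = max(skip_until, p + dels[p])
        if p < skip_until:
            continue
        out.append(subs.get(p, ref_base[p]))

    for s, l in n_runs:
        out[s : s + l] = b"N" * l
    for p, sym in specials:
        out[p] = sym
    for s, l in masks:
        for i in range(s, min(s + l, len(out))):
            if 65 <= out[i] <= 90:
                out[i] += 32

    record = f">{identifier}\n".encode()
    if out:
        record += _wrap(bytes(out), width) + b"\n"
    return record


def generate_collection(
    ref_fasta: bytes | str | Path,
    n: int,
    profile: MutationProfile,
    outdir: str | Path,
    self_check: bool = True,
) -> list[Path]:
    """Write n mutated FASTA files plus mutation logs; returns FASTA paths.

    ``ref_fasta`` may be FASTA bytes or a path.  Each sequence gets an
    independent generator seeded from the profile seed and its index.
    """
    from .sequence_io import read_fasta_records

    if isinstance(ref_fasta, (str, Path)):
        ref_fasta = Path(ref_fasta).read_bytes()
    # mutate the uppercase base stream of the (possibly multi-record) reference
    ref_base = b"".join(r.base for r in read_fasta_records(ref_fasta))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        ident = f"seq_{i:03d} mutant of reference"
        record, log = derive_sequence(
            ref_base, profile, _child_seed(profile.seed, i), ident
        )
        if self_check and replay_mutation_log(ref_base, log) != record:
            raise AssertionError(f"mutation-log replay mismatch for sequence {i}")
        fasta_path = outdir / f"seq_{i:03d}.fa"
        fasta_path.write_bytes(record)
        (outdir / f"seq_{i:03d}.log").write_text(log)
        paths.append(fasta_path)
    return paths
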