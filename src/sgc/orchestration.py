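"""End-to-end compression and decompression of FASTA collections.

Compression runs in four fixed stages:

1. pre-processing — read the reference, split it, build the k-mer index;
2. first-order — match every target record against the reference, one
   record per task, concurrently over a read-only shared index;
3. second-order — select the first S compressed sequences as second-order
   references, chain-compress them serially, then match the remaining
   sequences against the reference set concurrently;
4. post-processing — serialize auxiliary and token streams and entropy-code
   one block per sequence into the archive.

Tasks share the reference and its index read-only and results are
collected in sequence-id order regardless of completion order, so the
archive bytes are invariant under the worker count.

Decompression is single-threaded by design (it is I/O-bound and needs no
index) and supports selective extraction: a non-reference sequence needs
only the header, the index, the reference block group and its own block;
reference i needs only blocks 0..i.
"""

from __future__ import annotations

import hashlib
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .archive import (
    Archive,
    ArchiveParams,
    ArchiveReader,
    DEFAULT_BACKEND,
    FINGERPRINT_LEN,
    serialize_streams,
)
from .errors import ConfigurationError, SgcError, WrongReferenceError
from .first_order import FirstOrderStream, compress_first_order, decompress_first_order
from .kmer_index import build_index
from .second_order import (
    DEFAULT_MIN_RUN,
    DEFAULT_NUM_REFERENCES,
    build_token_index,
    chain_compress_references,
    compress_second_order,
    decompress_second_order,
    expand_references,
    select_second_order_references,
)
from .sequence_io import (
    encode_auxiliary,
    decode_auxiliary,
    read_fasta_records,
    reconstruct_record,
    SequenceRecord,
)

logger = logging.getLogger("sgc")

DEFAULT_K = 14


@dataclass
class CompressionConfig:
    """Parameters of one compression run."""

    reference: Path
    targets: list[Path]
    output: Path
    k: int = DEFAULT_K
    num_references: int = DEFAULT_NUM_REFERENCES
    min_run: int = DEFAULT_MIN_RUN
    backend: str = DEFAULT_BACKEND
    workers: int = 1
    max_occ: int | None = None
    force: bool = False

    def validate(self) -> None:
        if self.k < 4:
            raise ConfigurationError("k must be >= 4")
        if self.num_references < 0:
            raise ConfigurationError("number of second-order references must be >= 0")
        if self.min_run < 1:
            raise ConfigurationError("min_run must be >= 1")
        if self.workers < 1:
            raise ConfigurationError("worker count must be >= 1")
        if not self.targets:
            raise ConfigurationError("no target FASTA files given")


@dataclass
class CompressionReport:
    input_bytes: int
    output_bytes: int
    sequence_count: int
    stage_seconds: dict[str, float] = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        return self.input_bytes / self.output_bytes if self.output_bytes else 0.0


def reference_base_stream(ref_fasta: bytes) -> bytes:
    """Uppercase-ACGT stream of a (possibly multi-record) reference FASTA."""
    return b"".join(r.base for r in read_fasta_records(ref_fasta))


def reference_fingerprint(ref_base: bytes) -> bytes:
    return hashlib.sha256(ref_base).digest()[:FINGERPRINT_LEN]


def _read_file(path: Path) -> bytes:
    try:
        return Path(path).read_bytes()
    except OSError as exc:
        raise SgcError(f"cannot read {path}: {exc}") from exc


def build_archive(config: CompressionConfig) -> tuple[Archive, CompressionReport]:
    """Run the whole pipeline and return the in-memory archive + report."""
    config.validate()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    ref_fasta = _read_file(config.reference)
    ref_base = reference_base_stream(ref_fasta)
    fingerprint = reference_fingerprint(ref_base)
    idx = build_index(ref_base, config.k, max_occ=config.max_occ)
    timings["pre-processing"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    input_bytes = 0
    records: list[SequenceRecord] = []
    file_table: list[tuple[str, int]] = []
    for path in config.targets:
        data = _read_file(path)
        input_bytes += len(data)
        recs = read_fasta_records(data, first_seq_id=len(records))
        file_table.append((Path(path).name, len(recs)))
        records.extend(recs)
    if not records:
        raise ConfigurationError("target files contain no FASTA records")

    def first_order_task(rec: SequenceRecord) -> FirstOrderStream:
        return compress_first_order(rec.base, ref_base, idx, seq_id=rec.seq_id)

    with ThreadPoolExecutor(max_workers=config.workers) as pool:
        fo_streams = list(pool.map(first_order_task, records))
    timings["first-order"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    refs, others = select_second_order_references(fo_streams, config.num_references)
    chained = chain_compress_references(refs, config.min_run)
    token_idx = build_token_index(refs)

    def second_order_task(stream: FirstOrderStream):
        return compress_second_order(stream, token_idx, config.min_run)

    with ThreadPoolExecutor(max_workers=config.workers) as pool:
        so_others = list(pool.map(second_order_task, others))
    so_streams = chained + so_others
    timings["second-order"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    aux_bytes = [encode_auxiliary(rec.aux) for rec in records]
    params = ArchiveParams(
        k=config.k,
        num_references=config.num_references,
        min_run=config.min_run,
        backend=config.backend,
        fingerprint=fingerprint,
        file_table=file_table,
    )
    archive = serialize_streams(so_streams, aux_bytes, params)
    timings["post-processing"] = time.perf_counter() - t0

    report = CompressionReport(
        input_bytes=input_bytes,
        output_bytes=0,
        sequence_count=len(records),
        stage_seconds=timings,
    )
    return archive, report


def compress_collection(config: CompressionConfig) -> CompressionReport:
    """Compress a collection to ``config.output`` and report sizes/timings."""
    output = Path(config.output)
    if output.exists() and not config.force:
        raise ConfigurationError(
            f"output {output} exists; pass force=True / --force to overwrite"
        )
    archive, report = build_archive(config)
    t0 = time.perf_counter()
    report.output_bytes = archive.write(output)
    report.stage_seconds["post-processing"] += time.perf_counter() - t0
    logger.info(
        "compressed %d sequences: %d -> %d bytes (%.1f:1)",
        report.sequence_count, report.input_bytes, report.output_bytes,
        report.ratio,
    )
    return report


def _expand_reference_group(
    reader: ArchiveReader, upto: int
) -> tuple[list[FirstOrderStream], list[bytes]]:
    """Read and chain-expand reference blocks 0..upto-1 (plus their aux)."""
    chained = []
    aux = []
    for i in range(upto):
        so, aux_raw = reader.read_block(i)
        chained.append(so)
        aux.append(aux_raw)
    return expand_references(chained), aux


def decompress_collection(
    archive_path: Path,
    reference_path: Path,
    output_dir: Path,
    seq_ids: list[int] | None = None,
    reader: ArchiveReader | None = None,
) -> list[Path]:
    """Reconstruct FASTA files from an archive; returns written paths.

    With ``seq_ids`` given, only those records are decoded and written
    (grouped into their source files); otherwise every file of the
    collection is rebuilt byte-identically.  A pre-opened ``reader`` may be
    supplied to observe the I/O footprint; it is left open for the caller.
    """
    ref_base = reference_base_stream(_read_file(Path(reference_path)))
    own_reader = reader is None
    reader = reader if reader is not None else ArchiveReader(archive_path)
    try:
        if reader.params.fingerprint != reference_fingerprint(ref_base):
            raise WrongReferenceError(
                "reference genome does not match the archive fingerprint"
            )
        n = reader.sequence_count
        s_eff = reader.num_references_effective
        if seq_ids is None:
            wanted = list(range(n))
        else:
            wanted = sorted(set(seq_ids))
            for i in wanted:
                if not 0 <= i < n:
                    raise ConfigurationError(
                        f"sequence id {i} out of range (archive holds {n})"
                    )
        # a non-reference needs the whole reference group; reference i
        # needs only its predecessors
        if any(i >= s_eff for i in wanted):
            upto = s_eff
        else:
            upto = max(wanted) + 1 if wanted else 0
        expanded, ref_aux = _expand_reference_group(reader, upto)

        pieces: dict[int, bytes] = {}
        for i in wanted:
            if i < s_eff:
                fo = expanded[i]
                aux_raw = ref_aux[i]
            else:
                so, aux_raw = reader.read_block(i)
                fo = decompress_second_order(so, expanded)
            base = decompress_first_order(fo, ref_base)
            aux = decode_auxiliary(aux_raw)
            pieces[i] = reconstruct_record(SequenceRecord(i, base, aux))

        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        first = 0
        for name, count in reader.params.file_table:
            ids_here = [i for i in wanted if first <= i < first + count]
            if ids_here:
                path = output_dir / name
                path.write_bytes(b"".join(pieces[i] for i in ids_here))
                written.append(path)
            first += count
        return written
    finally:
        if own_reader:
            reader.close()


def list_archive(archive_path: Path) -> dict:
    """Header fields and per-sequence compressed block sizes."""
    with ArchiveReader(archive_path) as reader:
        p = reader.params
        return {
            "k": p.k,
            "num_references": p.num_references,
            "min_run": p.min_run,
            "backend": p.backend,
            "fingerprint": p.fingerprint.hex(),
            "sequence_count": reader.sequence_count,
            "files": list(p.file_table),
            "block_sizes": list(reader.block_lengths),
        }
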