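"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from sgc import MutationProfile, generate_collection, generate_reference
from sgc.fixtures import (
    STANDARD_COLLECTION_SIZE,
    STANDARD_PROFILE,
    STANDARD_REFERENCE_LENGTH,
)


@pytest.fixture(scope="session")
def small_collection(tmp_path_factory) -> dict:
    """A 50 kb reference with 10 mutated sequences, for fast unit tests."""
    d = tmp_path_factory.mktemp("small")
    ref_path = d / "reference.fa"
    ref_path.write_bytes(generate_reference(50_000, seed=11))
    profile = MutationProfile(seed=13)
    paths = generate_collection(ref_path, 10, profile, d / "coll")
    return {"dir": d, "reference": ref_path, "targets": paths}


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory) -> dict:
    """The frozen standard fixture: 1 Mb reference, 50 mutated sequences,
    mixed case / N runs / ambiguity symbols / ragged lines, seed 42."""
    d = tmp_path_factory.mktemp("standard")
    ref_path = d / "reference.fa"
    ref_path.write_bytes(
        generate_reference(STANDARD_REFERENCE_LENGTH, seed=STANDARD_PROFILE.seed)
    )
    paths = generate_collection(
        ref_path, STANDARD_COLLECTION_SIZE, STANDARD_PROFILE, d / "coll",
        self_check=False,
    )
    return {"dir": d, "reference": ref_path, "targets": paths}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))


def random_base_stream(rng: np.random.Generator, n: int) -> bytes:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=n)
    ].tobytes()
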