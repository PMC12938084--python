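"""Shared fixtures: tiny alignments and synthetic targets, generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from coevodist.msa import Alignment
from coevodist.pipeline import featurize_protein
from coevodist.synthetic import GeneratorParams, generate_protein


@pytest.fixture()
def toy_alignment() -> Alignment:
    """6-row, 8-column mixed alignment exercising gaps and redundancy."""
    rows = [
        "ACDEFGHI",
        "ACDEFGHI",
        "ACDEYGHI",
        "AC-EFGHL",
        "GHIKLMNP",
        "GHIKLMNP",
    ]
    return Alignment(ids=[f"s{i}" for i in range(len(rows))], rows=rows)


@pytest.fixture(scope="session")
def small_protein():
    """One deterministic synthetic target (L=40, shallow MSA)."""
    params = GeneratorParams(
        length_range=(40, 40), n_sequences=40, coupling_strength=5.0, seed=11
    )
    return generate_protein(params, index=0)


@pytest.fixture(scope="session")
def small_record(small_protein):
    return featurize_protein(small_protein)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
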