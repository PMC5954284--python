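"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: bin
membership by Python substring search, accumulation sums by per-occurrence
``str.count``-style scanning, and edit distance by a full quadratic DP
matrix.  They are the ground truth the packed-bit implementations are
checked against.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedfilter.filter_core import ReadSequence
from seedfilter.genome_index import (
    BinningConfig,
    GenomeSequence,
    TokenCodec,
    build_index,
    decode_token,
    make_binning,
)
from seedfilter.synthetic_data import random_genome


# ---------------------------------------------------------------------------
# oracle functions (exposed as fixtures returning plain callables)
# ---------------------------------------------------------------------------


def _naive_bin_tokens(genome: GenomeSequence, binning: BinningConfig, n: int) -> list[set[str]]:
    """Per bin, the set of ACGT tokens occurring in the bin's sequence."""
    out = []
    acgt = set("ACGT")
    for i in range(binning.num_bins):
        start, end = binning.bin_interval(i)
        seq = genome.seq[start:end]
        toks = {
            seq[p : p + n]
            for p in range(len(seq) - n + 1)
            if set(seq[p : p + n]) <= acgt
        }
        out.append(toks)
    return out


def _naive_accumulation(
    read: ReadSequence, genome: GenomeSequence, binning: BinningConfig, bin: int, n: int
) -> int:
    """Count of read token occurrences present in the bin sequence."""
    start, end = binning.bin_interval(bin)
    bin_seq = genome.seq[start:end]
    acgt = set("ACGT")
    total = 0
    for p in range(read.length - n + 1):
        tok = read.seq[p : p + n]
        if set(tok) <= acgt and tok in bin_seq:
            total += 1
    return total


def _dp_edit_distance_semiglobal(query: str, target: str) -> int:
    """Full quadratic DP, free target ends: min edits to fit the whole
    query anywhere inside the target."""
    m, n = len(query), len(target)
    prev = np.zeros(n + 1, dtype=np.int64)  # row 0: free start in target
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = i
        qc = query[i - 1]
        sub = prev[:-1] + np.array([0 if qc == target[j] else 1 for j in range(n)])
        for j in range(1, n + 1):
            cur[j] = min(sub[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


@pytest.fixture(scope="session")
def naive_bin_tokens():
    return _naive_bin_tokens


@pytest.fixture(scope="session")
def naive_accumulation():
    return _naive_accumulation


@pytest.fixture(scope="session")
def dp_semiglobal():
    return _dp_edit_distance_semiglobal


# ---------------------------------------------------------------------------
# data fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def codec5() -> TokenCodec:
    return TokenCodec(5)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    return random_genome(3000, seed=7, name="g3k")


@pytest.fixture(scope="session")
def small_binning(small_genome) -> BinningConfig:
    return make_binning(small_genome.length, 12, overlap=104)


@pytest.fixture(scope="session")
def small_index(small_genome, small_binning, codec5):
    return build_index(small_genome, small_binning, codec5)


@pytest.fixture(scope="session")
def all_g_index():
    genome = GenomeSequence(name="allG", seq="G" * 400)
    binning = make_binning(400, 4, overlap=10)
    return build_index(genome, binning, TokenCodec(5))


def random_token(rng, n: int) -> str:
    return decode_token(int(rng.integers(0, 4**n)), TokenCodec(n))
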