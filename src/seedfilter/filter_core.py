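"""Accumulation-sum seed-location filtering.

For a read r and a candidate location z, the filter counts how many of the
read's overlapping tokens (length n, counted per occurrence, duplicates
included) exist in the bin containing z.  This count, the accumulation sum
Sum_z, is compared against a threshold chosen so that any location whose bin
holds a match within the alignment error tolerance e is guaranteed to pass:

    threshold = (L - (n - 1)) - ceil(L * e) * n      (clamped at 0)

where L - (n - 1) is the total number of tokens in the read and each of the
ceil(L * e) allowable edit errors can, in the worst case (a substitution or
deletion), destroy n consecutive tokens.  Locations with Sum_z below the
threshold therefore cannot align within tolerance and are discarded before
the expensive verification step; locations at or above it are kept.  The
construction makes false positives (wrongly discarded true locations)
impossible, while false negatives (kept locations that fail verification)
are possible and are what the evaluation harness measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_index import (
    TokenBitvectorIndex,
    bin_of_location,
    fetch_token_row,
    token_codes,
)

__all__ = [
    "ReadSequence",
    "FilterConfig",
    "TokenOccurrence",
    "AccumulationResult",
    "SeedLocationFilterBitmask",
    "extract_tokens",
    "allowable_errors",
    "compute_threshold",
    "accumulation_sum",
    "accumulation_sums_all_bins",
    "filter_read_locations",
    "filter_bin_window",
    "write_bitmask_tsv",
    "write_bitmask_bed",
]

logger = logging.getLogger(__name__)

# ceil() guard: e is a binary float, so L*e can land a few ulps above the
# exact product (e.g. 0.05 is stored slightly high); without the guard that
# would overcount allowable errors by one at exact-integer products.
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class ReadSequence:
    read_id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FilterConfig:
    """Token size n and alignment error tolerance e (fraction of read length)."""

    token_size: int = 5
    error_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.token_size < 1:
            raise ValueError("token_size must be >= 1")
        if not 0.0 <= self.error_tolerance < 1.0:
            raise ValueError("error_tolerance must be in [0, 1)")


@dataclass(frozen=True)
class TokenOccurrence:
    position: int
    token: str
    code: int  # -1 when ambiguous

    @property
    def ambiguous(self) -> bool:
        return self.code < 0


@dataclass(frozen=True)
class AccumulationResult:
    bin: int
    sum: int
    threshold: int

    @property
    def passed(self) -> bool:
        return self.sum >= self.threshold


@dataclass
class SeedLocationFilterBitmask:
    """Per-candidate pass/fail decisions for one read.

    ``entries`` holds one (location, bin, AccumulationResult) triple per
    submitted candidate location, in submission order; candidates sharing a
    bin share one evaluation.
    """

    read_id: str
    entries: list[tuple[int, int, AccumulationResult]] = field(default_factory=list)

    def pass_bits(self) -> list[int]:
        return [int(res.passed) for _, _, res in self.entries]

    def passing_locations(self) -> list[int]:
        return [z for z, _, res in self.entries if res.passed]


def extract_tokens(read: ReadSequence, n: int) -> list[TokenOccurrence]:
    """All L - n + 1 overlapping token occurrences of the read, in order.

    Duplicate tokens appear once per occurrence.  Occurrences containing a
    non-ACGT character are tagged ambiguous (code -1).
    """
    if read.length < n:
        raise ValueError(f"read {read.read_id!r} shorter than token size {n}")
    codes = token_codes(read.seq, n)
    return [
        TokenOccurrence(p, read.seq[p : p + n], int(c)) for p, c in enumerate(codes)
    ]


def allowable_errors(L: int, e: float) -> int:
    """Maximum tolerated edit errors: ceil(L * e)."""
    if L < 1:
        raise ValueError("read length must be >= 1")
    if not 0.0 <= e < 1.0:
        raise ValueError("error tolerance must be in [0, 1)")
    return math.ceil(L * e - _CEIL_EPS)


def compute_threshold(L: int, n: int, e: float, extra_errors: int = 0) -> int:
    """Accumulation-sum threshold for a read of length L.

    Each tolerated error destroys at most n tokens (worst case: substitution
    or deletion at positions whose damaged token sets are disjoint), so the
    minimum surviving sum of a true match is the token count L - (n - 1)
    minus n per error.  ``extra_errors`` charges additional worst-case
    substitutions, e.g. one per ambiguous read base.  A result clamped to 0
    means pass-all; a warning is logged because the filter then rejects
    nothing.
    """
    if L < n:
        raise ValueError(f"read length {L} < token size {n}")
    raw = (L - (n - 1)) - (allowable_errors(L, e) + extra_errors) * n
    if raw <= 0:
        logger.warning(
            "threshold clamped to 0 (raw %d) for L=%d n=%d e=%g: filter passes all",
            raw, L, n, e,
        )
        return 0
    return raw


def _read_codes_and_threshold(
    read: ReadSequence, cfg: FilterConfig
) -> tuple[np.ndarray, int]:
    n = cfg.token_size
    codes = token_codes(read.seq, n)
    # every ambiguous base is charged as one worst-case substitution, which
    # keeps true locations of N-containing reads impossible to reject
    n_ambiguous_bases = sum(1 for ch in read.seq if ch not in "ACGT")
    threshold = compute_threshold(
        read.length, n, cfg.error_tolerance, extra_errors=n_ambiguous_bases
    )
    return codes, threshold


def accumulation_sum(
    read: ReadSequence,
    index: TokenBitvectorIndex,
    bin: int,
    cfg: FilterConfig,
) -> AccumulationResult:
    """Sum of the bin's existence bits over the read's token occurrences."""
    if not 0 <= bin < index.num_bins:
        raise ValueError(f"bin {bin} out of range [0, {index.num_bins})")
    codes, threshold = _read_codes_and_threshold(read, cfg)
    valid = codes[codes >= 0]
    if valid.size:
        byte = index.bits[valid, bin >> 3]
        total = int(((byte >> (7 - (bin & 7))) & 1).sum())
    else:
        total = 0
    return AccumulationResult(bin=bin, sum=total, threshold=threshold)


def accumulation_sums_all_bins(
    read: ReadSequence, index: TokenBitvectorIndex, cfg: FilterConfig
) -> tuple[np.ndarray, int]:
    """Vector of Sum_z over every bin of the index, plus the threshold.

    Equivalent to calling :func:`accumulation_sum` per bin; used where the
    whole genome is scanned (average read existence).
    """
    codes, threshold = _read_codes_and_threshold(read, cfg)
    valid = codes[codes >= 0]
    t = index.num_bins
    if not valid.size:
        return np.zeros(t, dtype=np.int64), threshold
    rows = np.unpackbits(index.bits[valid], axis=1, count=t)
    return rows.sum(axis=0, dtype=np.int64), threshold


def filter_read_locations(
    read: ReadSequence,
    locations: list[int],
    index: TokenBitvectorIndex,
    cfg: FilterConfig,
) -> SeedLocationFilterBitmask:
    """Pass/fail decision for each candidate location of one read.

    Each distinct bin is evaluated once and its result shared by all of the
    bin's locations; output order matches input order.
    """
    glen = index.binning.genome_length
    bins = []
    for z in locations:
        if not 0 <= z < glen:
            raise ValueError(f"candidate location {z} out of range [0, {glen})")
        bins.append(bin_of_location(z, index.binning))
    cache: dict[int, AccumulationResult] = {}
    mask = SeedLocationFilterBitmask(read_id=read.read_id)
    for z, b in zip(locations, bins):
        if b not in cache:
            cache[b] = accumulation_sum(read, index, b, cfg)
        mask.entries.append((z, b, cache[b]))
    return mask


def filter_bin_window(
    read: ReadSequence,
    index: TokenBitvectorIndex,
    bin_start: int,
    w: int,
    cfg: FilterConfig,
) -> list[AccumulationResult]:
    """Evaluate w consecutive bins in lockstep, token by token.

    Functional model of the in-memory hardware path: for each read token one
    row fetch supplies that token's existence bits for the whole window, and
    every bin's accumulator is updated in the same step.  Results are
    identical to per-bin :func:`accumulation_sum` for any w.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    if not (0 <= bin_start and bin_start + w <= index.num_bins):
        raise ValueError(
            f"window [{bin_start}, {bin_start + w}) out of range"
        )
    codes, threshold = _read_codes_and_threshold(read, cfg)
    sums = np.zeros(w, dtype=np.int64)
    for c in codes:
        if c >= 0:
            sums += fetch_token_row(index, int(c), bin_start, w)
    return [
        AccumulationResult(bin=bin_start + i, sum=int(s), threshold=threshold)
        for i, s in enumerate(sums)
    ]


# ---------------------------------------------------------------------------
# bitmask export
# ---------------------------------------------------------------------------


def write_bitmask_tsv(masks: list[SeedLocationFilterBitmask], path: str) -> None:
    """TSV: read_id, location (0-based), bin, sum, threshold, pass{0,1}."""
    with open(path, "w") as fh:
        fh.write("read_id\tlocation\tbin\tsum\tthreshold\tpass\n")
        for m in masks:
            for z, b, res in m.entries:
                fh.write(
                    f"{m.read_id}\t{z}\t{b}\t{res.sum}\t{res.threshold}\t{int(res.passed)}\n"
                )


def write_bitmask_bed(
    masks: list[SeedLocationFilterBitmask],
    read_lengths: dict[str, int],
    chrom: str,
    path: str,
) -> None:
    """BED intervals [z, z + L) of passing candidate locations."""
    with open(path, "w") as fh:
        for m in masks:
            L = read_lengths[m.read_id]
            for z in m.passing_locations():
                fh.write(f"{chrom}\t{z}\t{z + L}\t{m.read_id}\n")
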