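"""Per-bin token-existence bitvector index over a reference genome.

The reference is divided into ``num_bins`` overlapping bins of uniform
stride.  For every bin, a bitvector of length ``4**n`` records which DNA
tokens (substrings of fixed length ``n`` over ACGT) occur anywhere inside
the bin.  The whole index is a packed bit matrix with one row per token
code and one column per bin, so fetching the existence bits of one token
across a window of consecutive bins is a contiguous slice — the same
layout a column-major DRAM row holds in the in-memory realisation of the
filter.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import io
import json
import struct
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "BinningConfig",
    "TokenCodec",
    "TokenBitvectorIndex",
    "AmbiguousTokenError",
    "CorruptIndexError",
    "encode_token",
    "decode_token",
    "token_codes",
    "make_binning",
    "bin_of_location",
    "build_index",
    "existence_bit",
    "fetch_token_row",
    "save_index",
    "load_index",
    "footprint_bytes",
    "load_fasta",
    "concat_genome",
]

_BASE_TO_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_DIGIT_TO_BASE = "ACGT"

# 256-entry lookup: ASCII byte -> base-4 digit, or -1 for anything not ACGT.
_DIGIT_LUT = np.full(256, -1, dtype=np.int8)
for _b, _d in _BASE_TO_DIGIT.items():
    _DIGIT_LUT[ord(_b)] = _d


class AmbiguousTokenError(ValueError):
    """Token contains a character outside {A, C, G, T}."""


class CorruptIndexError(IOError):
    """Index file fails magic/version/size validation."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence; uppercased on construction."""

    name: str
    seq: str
    #: half-open (name, start) boundaries of the records concatenated into
    #: ``seq``; a single plain sequence has one entry at offset 0.
    records: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise ValueError("genome sequence must be non-empty")
        if not self.records:
            object.__setattr__(self, "records", ((self.name, 0),))

    @property
    def length(self) -> int:
        return len(self.seq)

    def record_boundaries(self) -> list[int]:
        """Start offsets of the concatenated records (first is always 0)."""
        return [off for _, off in self.records]


@dataclass(frozen=True)
class TokenCodec:
    """Fixed big-endian base-4 encoding of ACGT tokens (A=0 C=1 G=2 T=3)."""

    token_size: int

    def __post_init__(self) -> None:
        if self.token_size < 1:
            raise ValueError("token_size must be >= 1")

    @property
    def num_tokens(self) -> int:
        return 4**self.token_size

    def encode(self, token: str) -> int:
        return encode_token(token, self)

    def decode(self, code: int) -> str:
        return decode_token(code, self)


def encode_token(token: str, codec: TokenCodec) -> int:
    """Map an ACGT token of length n to its big-endian base-4 code."""
    if len(token) != codec.token_size:
        raise ValueError(
            f"token length {len(token)} != token_size {codec.token_size}"
        )
    code = 0
    for ch in token.upper():
        try:
            code = code * 4 + _BASE_TO_DIGIT[ch]
        except KeyError:
            raise AmbiguousTokenError(f"non-ACGT character {ch!r} in token") from None
    return code


def decode_token(code: int, codec: TokenCodec) -> str:
    if not 0 <= code < codec.num_tokens:
        raise ValueError(f"token code {code} out of range [0, 4^{codec.token_size})")
    out = []
    for _ in range(codec.token_size):
        out.append(_DIGIT_TO_BASE[code % 4])
        code //= 4
    return "".join(reversed(out))


def token_codes(
    seq: str, token_size: int, boundaries: list[int] | None = None
) -> np.ndarray:
    """Codes of all overlapping tokens of ``seq``, -1 where ambiguous.

    Returns an int64 array of length ``len(seq) - token_size + 1`` whose
    entry p is the code of ``seq[p:p+n]``, or -1 if that window contains a
    non-ACGT character or (when ``boundaries`` of a concatenated genome are
    given) would straddle a record boundary.
    """
    n = token_size
    if len(seq) < n:
        raise ValueError(f"sequence length {len(seq)} < token size {n}")
    digits = _DIGIT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(digits, n)
    powers = 4 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    codes = windows.astype(np.int64) @ powers
    codes[(windows < 0).any(axis=1)] = -1
    if boundaries:
        for off in boundaries:
            if off > 0:  # kill tokens spanning the junction at `off`
                lo = max(0, off - n + 1)
                codes[lo:off] = -1
    return codes


@dataclass(frozen=True)
class BinningConfig:
    """Uniform overlapping binning of a genome coordinate space.

    Bin i covers [i*stride, min(i*stride + bin_width, genome_length)) where
    bin_width = stride + overlap.  Any window of length <= overlap + 1
    starting at z is fully contained in bin floor(z / stride), which is the
    containment property the filter relies on.
    """

    num_bins: int
    stride: int
    overlap: int
    genome_length: int

    @property
    def bin_width(self) -> int:
        return self.stride + self.overlap

    def bin_interval(self, i: int) -> tuple[int, int]:
        if not 0 <= i < self.num_bins:
            raise IndexError(f"bin {i} out of range [0, {self.num_bins})")
        start = i * self.stride
        end = min(start + self.bin_width, self.genome_length)
        return start, max(start, end)


def make_binning(genome_length: int, num_bins: int, overlap: int) -> BinningConfig:
    """Binning with stride ceil(genome_length / num_bins) and given overlap."""
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if genome_length < num_bins:
        raise ValueError(
            f"genome_length {genome_length} < num_bins {num_bins}: "
            "cannot give every bin at least one base"
        )
    stride = -(-genome_length // num_bins)
    return BinningConfig(
        num_bins=num_bins,
        stride=stride,
        overlap=overlap,
        genome_length=genome_length,
    )


def default_overlap(max_read_length: int, max_error_tolerance: float) -> int:
    """Weakest overlap guaranteeing a read (plus worst-case insertions
    extending its reference span) fits inside the bin of its start location."""
    import math

    span = max_read_length + math.ceil(max_read_length * max_error_tolerance)
    return span - 1


def bin_of_location(z: int, binning: BinningConfig) -> int:
    """Number of the bin that contains location z (and the window
    [z, z + overlap + 1) clipped to the genome)."""
    if not 0 <= z < binning.genome_length:
        raise ValueError(f"location {z} out of range [0, {binning.genome_length})")
    return z // binning.stride


@dataclass
class TokenBitvectorIndex:
    """Packed per-bin token-existence bit matrix.

    ``bits`` has shape (4**n, ceil(t/8)) dtype uint8; bit x of row k (MSB
    first within each byte) is 1 iff the token with code k occurs as a
    substring of bin x's sequence.
    """

    binning: BinningConfig
    codec: TokenCodec
    bits: np.ndarray
    genome_name: str = ""
    records: tuple[tuple[str, int], ...] = ()
    version: int = 1

    row_bytes: int = field(init=False)

    def __post_init__(self) -> None:
        self.row_bytes = -(-self.binning.num_bins // 8)
        expect = (self.codec.num_tokens, self.row_bytes)
        if self.bits.shape != expect:
            raise ValueError(f"bit matrix shape {self.bits.shape} != {expect}")

    @property
    def num_bins(self) -> int:
        return self.binning.num_bins

    def bin_sequence(self, genome: GenomeSequence, i: int) -> str:
        start, end = self.binning.bin_interval(i)
        return genome.seq[start:end]


def build_index(
    genome: GenomeSequence, binning: BinningConfig, codec: TokenCodec
) -> TokenBitvectorIndex:
    """Scan the genome once and set, for every bin, the existence bit of
    every ACGT token occurring inside the bin.

    Tokens overlapping non-ACGT characters or record boundaries set no bits.
    """
    if binning.bin_width < codec.token_size:
        raise ValueError(
            f"bin_width {binning.bin_width} < token_size {codec.token_size}"
        )
    if binning.genome_length != genome.length:
        raise ValueError("binning.genome_length does not match genome")
    n = codec.token_size
    codes = token_codes(genome.seq, n, boundaries=genome.record_boundaries())
    bits = np.zeros((codec.num_tokens, -(-binning.num_bins // 8)), dtype=np.uint8)
    masks = (np.uint8(1) << np.uint8(7 - (np.arange(binning.num_bins) & 7))).astype(
        np.uint8
    )
    for x in range(binning.num_bins):
        start, end = binning.bin_interval(x)
        if end - start < n:
            continue
        window = codes[start : end - n + 1]
        present = np.unique(window[window >= 0])
        bits[present, x >> 3] |= masks[x]
    return TokenBitvectorIndex(
        binning=binning,
        codec=codec,
        bits=bits,
        genome_name=genome.name,
        records=genome.records,
    )


def existence_bit(index: TokenBitvectorIndex, token_code: int, bin: int) -> int:
    """Stored existence bit of one token in one bin."""
    if not 0 <= token_code < index.codec.num_tokens:
        raise ValueError(f"token code {token_code} out of range")
    if not 0 <= bin < index.num_bins:
        raise ValueError(f"bin {bin} out of range [0, {index.num_bins})")
    return int((index.bits[token_code, bin >> 3] >> (7 - (bin & 7))) & 1)


def fetch_token_row(
    index: TokenBitvectorIndex, token_code: int, bin_start: int, w: int
) -> np.ndarray:
    """Existence bits of one token across bins [bin_start, bin_start + w).

    This is the software analogue of one DRAM row fetch: a contiguous slice
    of the token's packed row.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    if not (0 <= bin_start and bin_start + w <= index.num_bins):
        raise ValueError(
            f"window [{bin_start}, {bin_start + w}) out of range [0, {index.num_bins})"
        )
    if not 0 <= token_code < index.codec.num_tokens:
        raise ValueError(f"token code {token_code} out of range")
    row = np.unpackbits(index.bits[token_code], count=index.num_bins)
    return row[bin_start : bin_start + w]


# ---------------------------------------------------------------------------
# serialization
#
# Byte-exact layout (all integers little-endian):
#   magic   4 bytes   b"SBVI"
#   version u16
#   n       u16       token size
#   t       u64       number of bins
#   stride  u64
#   overlap u64
#   glen    u64       genome length
#   mlen    u32       length of UTF-8 JSON metadata {"name":…, "records":…}
#   meta    mlen bytes
#   bits    4**n * ceil(t/8) bytes, token-major rows, each row byte-padded
# ---------------------------------------------------------------------------

_MAGIC = b"SBVI"
_HEADER = struct.Struct("<4sHHQQQQI")


def save_index(index: TokenBitvectorIndex, path: str) -> None:
    meta = json.dumps(
        {"name": index.genome_name, "records": list(index.records)}
    ).encode("utf-8")
    b = index.binning
    header = _HEADER.pack(
        _MAGIC,
        index.version,
        index.codec.token_size,
        b.num_bins,
        b.stride,
        b.overlap,
        b.genome_length,
        len(meta),
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(meta)
        fh.write(index.bits.tobytes())


def load_index(path: str) -> TokenBitvectorIndex:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size:
        raise CorruptIndexError("file shorter than index header")
    magic, version, n, t, stride, overlap, glen, mlen = _HEADER.unpack_from(raw)
    if magic != _MAGIC:
        raise CorruptIndexError(f"bad magic {magic!r}")
    if version != 1:
        raise CorruptIndexError(f"unsupported index version {version}")
    off = _HEADER.size
    if len(raw) < off + mlen:
        raise CorruptIndexError("truncated metadata")
    meta = json.loads(raw[off : off + mlen].decode("utf-8"))
    off += mlen
    row_bytes = -(-t // 8)
    payload = 4**n * row_bytes
    if len(raw) != off + payload:
        raise CorruptIndexError(
            f"payload size {len(raw) - off} != expected {payload}"
        )
    bits = np.frombuffer(raw[off:], dtype=np.uint8).reshape(4**n, row_bytes).copy()
    return TokenBitvectorIndex(
        binning=BinningConfig(t, stride, overlap, glen),
        codec=TokenCodec(n),
        bits=bits,
        genome_name=meta["name"],
        records=tuple((r[0], r[1]) for r in meta["records"]),
        version=version,
    )


def footprint_bytes(num_bins: int, token_size: int) -> float:
    """Raw index footprint: num_bins bitvectors of 4**token_size bits each,
    before per-row byte padding and header."""
    if num_bins < 1 or token_size < 1:
        raise ValueError("num_bins and token_size must be >= 1")
    return num_bins * 4**token_size / 8


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def load_fasta(path: str) -> list[GenomeSequence]:
    """Load all records of a FASTA file as individual sequences."""
    seqs = [
        GenomeSequence(name=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def concat_genome(seqs: list[GenomeSequence], name: str | None = None) -> GenomeSequence:
    """Concatenate records into one coordinate space with an offset table.

    Tokens spanning record junctions are suppressed at index-build time, so
    no phantom cross-record tokens can enter the index.
    """
    if len(seqs) == 1 and len(seqs[0].records) == 1:
        return seqs[0]
    records: list[tuple[str, int]] = []
    parts: list[str] = []
    off = 0
    for s in seqs:
        records.append((s.name, off))
        parts.append(s.seq)
        off += s.length
    return GenomeSequence(
        name=name or "+".join(s.name for s in seqs),
        seq="".join(parts),
        records=tuple(records),
    )


def record_of_location(genome: GenomeSequence, z: int) -> tuple[str, int]:
    """(record name, offset within record) of a concatenated-space location."""
    offsets = genome.record_boundaries()
    i = bisect_right(offsets, z) - 1
    return genome.records[i][0], z - offsets[i]
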