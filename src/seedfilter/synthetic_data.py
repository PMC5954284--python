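"""Synthetic references and planted reads with controlled errors.

Every experiment in this package runs on data generated here: uniform
random ACGT references, reads sampled from known positions with exact
per-read counts of substitutions, insertions and deletions (so the true
location of every read is known and false positives / negatives of the
filter can be counted without re-deriving ground truth), and a tiny
deterministic worked-example genome used in the documentation.

Read length stays fixed under indels: a read with i insertions and d
deletions is built from a reference window of length L - i + d, so the
final read is always L bases.  The truth table records the window start
and span for each read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filter_core import ReadSequence
from .genome_index import GenomeSequence

__all__ = [
    "ReadSimConfig",
    "random_genome",
    "plant_reads",
    "plant_reads_error_sweep",
    "worked_example_fixture",
    "write_fasta",
    "write_fastq",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSimConfig:
    """Exact per-read error counts for planted-read simulation."""

    read_length: int = 100
    n_reads: int = 100
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.n_reads < 1:
            raise ValueError("read_length and n_reads must be >= 1")
        if min(self.substitutions, self.insertions, self.deletions) < 0:
            raise ValueError("error counts must be >= 0")
        if self.insertions >= self.read_length:
            raise ValueError("insertions must be < read_length")

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions

    @property
    def ref_span(self) -> int:
        """Reference window length consumed by one read."""
        return self.read_length - self.insertions + self.deletions


def random_genome(length: int, seed: int, name: str = "synthetic") -> GenomeSequence:
    """I.i.d. uniform ACGT sequence; deterministic given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)]
    return GenomeSequence(name=name, seq=arr.tobytes().decode("ascii"))


def _mutate(window: str, n_sub: int, n_ins: int, n_del: int, rng) -> str:
    """Apply exact error counts to a reference window of length L - i + d,
    returning a read of length L.  Order: deletions, insertions, then
    substitutions at positions untouched by insertions."""
    seq = list(window)
    if n_del:
        for p in sorted(rng.choice(len(seq), size=n_del, replace=False), reverse=True):
            del seq[int(p)]
    inserted: set[int] = set()
    for _ in range(n_ins):
        p = int(rng.integers(0, len(seq) + 1))
        seq.insert(p, "ACGT"[rng.integers(0, 4)])
        inserted = {q + 1 if q >= p else q for q in inserted} | {p}
    if n_sub:
        candidates = [p for p in range(len(seq)) if p not in inserted]
        for p in rng.choice(len(candidates), size=n_sub, replace=False):
            pos = candidates[int(p)]
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)


def plant_reads(
    genome: GenomeSequence, cfg: ReadSimConfig
) -> tuple[list[ReadSequence], pd.DataFrame]:
    """Sample reads at uniform positions and mutate with exact error counts.

    Returns the reads and a truth table with one row per read:
    read_id, position (0-based start of the source window), ref_span,
    substitutions, insertions, deletions.
    """
    span = cfg.ref_span
    if span > genome.length:
        raise ValueError(
            f"reference span {span} exceeds genome length {genome.length}"
        )
    rng = np.random.default_rng(cfg.seed)
    positions = rng.integers(0, genome.length - span + 1, size=cfg.n_reads)
    reads, rows = [], []
    for i, pos in enumerate(positions):
        window = genome.seq[pos : pos + span]
        seq = _mutate(window, cfg.substitutions, cfg.insertions, cfg.deletions, rng)
        rid = f"read{i:05d}"
        reads.append(ReadSequence(read_id=rid, seq=seq))
        rows.append(
            (rid, int(pos), span, cfg.substitutions, cfg.insertions, cfg.deletions)
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "position", "ref_span",
            "substitutions", "insertions", "deletions",
        ],
    )
    return reads, truth


def plant_reads_error_sweep(
    genome: GenomeSequence,
    n_reads: int,
    read_length: int,
    max_errors: int,
    seed: int,
) -> tuple[list[ReadSequence], pd.DataFrame]:
    """Planted reads with k = 0..max_errors total errors, cycling over k,
    each error independently typed substitution/insertion/deletion."""
    rng = np.random.default_rng(seed)
    reads, frames = [], []
    for i in range(n_reads):
        k = i % (max_errors + 1)
        types = rng.integers(0, 3, size=k)
        n_sub, n_ins, n_del = (
            int((types == 0).sum()), int((types == 1).sum()), int((types == 2).sum())
        )
        cfg = ReadSimConfig(
            read_length=read_length,
            n_reads=1,
            substitutions=n_sub,
            insertions=n_ins,
            deletions=n_del,
            seed=int(rng.integers(0, 2**31)),
        )
        rs, tr = plant_reads(genome, cfg)
        rid = f"read{i:05d}"
        reads.append(ReadSequence(read_id=rid, seq=rs[0].seq))
        tr["read_id"] = rid
        tr["total_errors"] = k
        frames.append(tr)
    truth = pd.concat(frames, ignore_index=True)
    return reads, truth


@dataclass(frozen=True)
class WorkedExample:
    """Tiny deterministic fixture: a genome whose bin 2 contains the token
    GACAG but not TTTTT, with token size 5 — the toy setting used in the
    documentation's walkthrough of the existence-bit lookup."""

    genome: GenomeSequence
    num_bins: int
    overlap: int
    token_size: int
    read: ReadSequence


def worked_example_fixture() -> WorkedExample:
    rng = np.random.default_rng(42)
    # draw an 80 bp genome free of TTTTT and of GACAG, then splice GACAG
    # into bin 2 ([40, 64) with stride 20, overlap 4)
    while True:
        g = _BASES[rng.integers(0, 4, size=80)].tobytes().decode("ascii")
        if "TTTTT" not in g and "GACAG" not in g:
            break
    g = g[:45] + "GACAG" + g[50:]
    assert "TTTTT" not in g and g.count("GACAG") == 1
    genome = GenomeSequence(name="toy", seq=g)
    read = ReadSequence(read_id="toy_read", seq=g[42:58])
    return WorkedExample(
        genome=genome, num_bins=4, overlap=4, token_size=5, read=read
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_fasta(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, off in genome.records:
            nxt = next(
                (o for n, o in genome.records if o > off), genome.length
            )
            fh.write(f">{name}\n")
            seq = genome.seq[off:nxt]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[ReadSequence], path: str, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{quality * r.length}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)
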