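"""Minimal seed-and-extend mapping loop for evaluating the seed-location filter.

The loop mirrors a hash-table read mapper: non-overlapping exact-match
seeds from each read (and its reverse complement) are looked up in a k-mer
index of the reference, seed hits are projected back to candidate read
start locations, the candidates are run through the accumulation-sum
filter, and surviving candidates are verified by semi-global edit distance
(read end-to-end, reference window ends free) with acceptance at edit
distance <= ceil(L * e).

Because the filter's threshold is constructed so a true within-tolerance
match can never fall below it, mapping with the filter on and off must
produce identical accepted locations; the harness tallies what the filter
kept and discarded so the false-negative rate (kept candidates that fail
verification) and the false-positive count (discarded candidates that
would have verified — provably zero) can be measured.
"""

from __future__ import annotations

import itertools
import json
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .filter_core import (
    FilterConfig,
    ReadSequence,
    accumulation_sums_all_bins,
    allowable_errors,
    filter_read_locations,
)
from .genome_index import (
    BinningConfig,
    GenomeSequence,
    TokenBitvectorIndex,
    TokenCodec,
    build_index,
    footprint_bytes,
    make_binning,
)

__all__ = [
    "SeedIndex",
    "Candidate",
    "AlignmentResult",
    "FilterEvaluation",
    "build_seed_index",
    "candidate_locations",
    "reverse_complement",
    "verify_alignment",
    "map_reads",
    "evaluate_filter",
    "average_read_existence",
    "parameter_sweep",
    "load_reads",
    "load_candidates_tsv",
    "write_mappings_tsv",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    if set(seq) <= set("ACGTN"):
        return seq.translate(_RC)[::-1]
    return str(Seq(seq).reverse_complement())


@dataclass
class SeedIndex:
    """Exact-match k-mer index over the forward strand of the reference."""

    seed_length: int
    locations: dict[str, np.ndarray]

    def lookup(self, seed: str) -> np.ndarray:
        return self.locations.get(seed, np.empty(0, dtype=np.int64))


def build_seed_index(genome: GenomeSequence, seed_length: int) -> SeedIndex:
    if seed_length < 1:
        raise ValueError("seed_length must be >= 1")
    table: dict[str, list[int]] = defaultdict(list)
    s = genome.seq
    for p in range(genome.length - seed_length + 1):
        table[s[p : p + seed_length]].append(p)
    return SeedIndex(
        seed_length=seed_length,
        locations={k: np.asarray(v, dtype=np.int64) for k, v in table.items()},
    )


@dataclass(frozen=True)
class Candidate:
    """Candidate read-start location: z = seed hit - seed offset in the read."""

    z: int
    strand: str  # '+' or '-'
    seed_offset: int


def candidate_locations(
    read: ReadSequence,
    seed_index: SeedIndex,
    genome_length: int,
    num_seeds: int | None = None,
) -> list[Candidate]:
    """Candidates from fixed-offset non-overlapping seeds, both strands.

    Seeds are taken at offsets 0, s, 2s, ... (s = seed length); each hit is
    projected to the read start and (z, strand) pairs are deduplicated,
    keeping the first proposing seed.  Hits whose projected read span falls
    outside the genome are dropped.
    """
    s = seed_index.seed_length
    L = read.length
    if num_seeds is None:
        num_seeds = L // s
    if num_seeds < 1 or L < num_seeds * s:
        raise ValueError(
            f"read {read.read_id!r} (length {L}) too short for "
            f"{num_seeds} seeds of length {s}"
        )
    out: list[Candidate] = []
    seen: set[tuple[int, str]] = set()
    for strand, qseq in (("+", read.seq), ("-", reverse_complement(read.seq))):
        for k in range(num_seeds):
            off = k * s
            for hit in seed_index.lookup(qseq[off : off + s]):
                z = int(hit) - off
                if z < 0 or z + L > genome_length:
                    continue
                key = (z, strand)
                if key not in seen:
                    seen.add(key)
                    out.append(Candidate(z=z, strand=strand, seed_offset=off))
    return out


def _guard_locations(z: int, k: int, genome_length: int) -> list[int]:
    """Locations whose bins cover every match start the verifier can accept.

    The semi-global verifier scans [z - k, z + L + k), so an accepted match
    can start anywhere in [z - k, z + 2k] (a match needs at least L - k
    reference bases).  That range is shorter than one stride for any sane
    binning, so the bins of its clamped endpoints (plus z itself) cover it;
    a candidate is kept if any of those bins passes.  Without the guard, a
    true match starting just left of z's bin boundary could lose its leading
    tokens to the neighbouring bin and be wrongly discarded.
    """
    return sorted({min(max(p, 0), genome_length - 1) for p in (z - k, z, z + 2 * k)})


@dataclass(frozen=True)
class AlignmentResult:
    z: int
    edit_distance: int
    accepted: bool


def verify_alignment(
    read_seq: str, genome: GenomeSequence, z: int, e: float
) -> AlignmentResult:
    """Semi-global unit-cost edit distance of the read against the reference
    window [z - k, z + L + k) clipped to the genome, k = ceil(L * e);
    accepted iff the distance is <= k."""
    L = len(read_seq)
    if not 0 <= z < genome.length:
        raise ValueError(f"location {z} out of range [0, {genome.length})")
    k = allowable_errors(L, e)
    lo = max(0, z - k)
    hi = min(genome.length, z + L + k)
    dist = edlib.align(read_seq, genome.seq[lo:hi], mode="HW", task="distance")[
        "editDistance"
    ]
    return AlignmentResult(z=z, edit_distance=int(dist), accepted=dist <= k)


@dataclass
class FilterEvaluation:
    """Filter quality tallies over a mapping run.

    false_negative_rate = (n_pass - n_pass_and_map) / n_pass: the fraction
    of filter-passing candidates that fail verification (wasted alignments).
    false_positive_count = n_reject_but_map: rejected candidates that would
    have verified — the construction guarantees zero.
    """

    n_pass: int = 0
    n_pass_and_map: int = 0
    n_reject: int = 0
    n_reject_but_map: int = 0
    fn_rate_defined: bool = True

    @property
    def false_negative_rate(self) -> float:
        if self.n_pass == 0:
            return 0.0
        return (self.n_pass - self.n_pass_and_map) / self.n_pass

    @property
    def false_positive_count(self) -> int:
        return self.n_reject_but_map

    def to_dict(self) -> dict:
        return {
            "n_pass": self.n_pass,
            "n_pass_and_map": self.n_pass_and_map,
            "n_reject": self.n_reject,
            "n_reject_but_map": self.n_reject_but_map,
            "false_negative_rate": self.false_negative_rate,
            "false_negative_rate_defined": self.fn_rate_defined,
            "false_positive_count": self.false_positive_count,
        }


def evaluate_filter(
    n_pass: int, n_pass_and_map: int, n_reject: int, n_reject_but_map: int
) -> FilterEvaluation:
    ev = FilterEvaluation(
        n_pass=n_pass,
        n_pass_and_map=n_pass_and_map,
        n_reject=n_reject,
        n_reject_but_map=n_reject_but_map,
        fn_rate_defined=n_pass > 0,
    )
    return ev


@dataclass
class MappingRun:
    """Outcome of :func:`map_reads`."""

    mappings: pd.DataFrame  # read_id, z, strand, edit_distance
    evaluation: FilterEvaluation
    n_candidates: int = 0
    n_verifications: int = 0  # alignments the mapper performed


def map_reads(
    reads: list[ReadSequence],
    genome: GenomeSequence,
    index: TokenBitvectorIndex,
    cfg: FilterConfig,
    seed_index: SeedIndex | None = None,
    seed_length: int = 12,
    use_filter: bool = True,
    candidates: dict[str, list[Candidate]] | None = None,
) -> MappingRun:
    """Seed, filter, and verify a read set; tally filter quality.

    With ``use_filter`` off every candidate is verified; with it on only
    passing candidates are.  For the evaluation tallies rejected candidates
    are verified as well (they never reach the mapper's output), so the
    false-positive count is measured, not assumed.  The reverse-strand copy
    of a read is filtered as its own query string against the same index.
    """
    if index.binning.genome_length != genome.length:
        raise ValueError("index was built for a different genome length")
    if cfg.token_size != index.codec.token_size:
        raise ValueError(
            "filter token size differs from index token size: "
            f"{cfg.token_size} != {index.codec.token_size}"
        )
    if seed_index is None and candidates is None:
        seed_index = build_seed_index(genome, seed_length)

    ev = FilterEvaluation()
    rows = []
    n_candidates = 0
    n_verifications = 0
    for read in reads:
        if candidates is not None:
            cand = candidates.get(read.read_id, [])
        else:
            cand = candidate_locations(read, seed_index, genome.length)
        n_candidates += len(cand)
        by_strand: dict[str, list[Candidate]] = {"+": [], "-": []}
        for c in cand:
            by_strand[c.strand].append(c)
        k = allowable_errors(read.length, cfg.error_tolerance)
        if index.binning.overlap + 1 < read.length + k:
            raise ValueError(
                f"index overlap {index.binning.overlap} too small for read "
                f"length {read.length} at tolerance {cfg.error_tolerance}: "
                f"need overlap >= {read.length + k - 1}"
            )
        for strand, group in by_strand.items():
            if not group:
                continue
            qseq = read.seq if strand == "+" else reverse_complement(read.seq)
            query = ReadSequence(read_id=read.read_id, seq=qseq)
            if use_filter:
                guards = {c.z: _guard_locations(c.z, k, genome.length) for c in group}
                all_locs = sorted({g for gs in guards.values() for g in gs})
                mask = filter_read_locations(query, all_locs, index, cfg)
                passed_at = {z: res.passed for z, _, res in mask.entries}
                passes = [any(passed_at[g] for g in guards[c.z]) for c in group]
            else:
                passes = [True] * len(group)
            for c, passed in zip(group, passes):
                aln = verify_alignment(qseq, genome, c.z, cfg.error_tolerance)
                if use_filter and passed:
                    n_verifications += 1
                elif not use_filter:
                    n_verifications += 1
                if passed:
                    ev.n_pass += 1
                    if aln.accepted:
                        ev.n_pass_and_map += 1
                        rows.append(
                            (read.read_id, c.z, strand, aln.edit_distance)
                        )
                else:
                    ev.n_reject += 1
                    if aln.accepted:
                        ev.n_reject_but_map += 1
    ev.fn_rate_defined = ev.n_pass > 0
    mappings = pd.DataFrame(
        rows, columns=["read_id", "z", "strand", "edit_distance"]
    )
    return MappingRun(
        mappings=mappings,
        evaluation=ev,
        n_candidates=n_candidates,
        n_verifications=n_verifications,
    )


def average_read_existence(
    reads: list[ReadSequence], index: TokenBitvectorIndex, cfg: FilterConfig
) -> float:
    """Mean over reads of (bins passing the filter) / (all bins).

    Lower is better: it is the fraction of the genome's bins a typical read
    cannot be excluded from by the filter alone.
    """
    if not reads:
        raise ValueError("read set must be nonempty")
    t = index.num_bins
    total = 0.0
    for read in reads:
        sums, threshold = accumulation_sums_all_bins(read, index, cfg)
        total += float((sums >= threshold).sum()) / t
    return total / len(reads)


def parameter_sweep(
    genome: GenomeSequence,
    reads: list[ReadSequence],
    token_sizes: list[int],
    bin_counts: list[int],
    tolerances: list[float],
    overlap: int | None = None,
    seed_length: int = 12,
) -> pd.DataFrame:
    """Grid sweep over (n, num_bins, e): average read existence, FN rate,
    footprint.  One index build per (n, num_bins); deterministic."""
    if not (token_sizes and bin_counts and tolerances):
        raise ValueError("sweep grid must be nonempty")
    if overlap is None:
        L = max(r.length for r in reads)
        emax = max(tolerances)
        overlap = L + allowable_errors(L, emax) - 1
    seed_index = build_seed_index(genome, seed_length)
    rows = []
    for n, t in itertools.product(token_sizes, bin_counts):
        binning = make_binning(genome.length, t, overlap)
        index = build_index(genome, binning, TokenCodec(n))
        for e in tolerances:
            cfg = FilterConfig(token_size=n, error_tolerance=e)
            are = average_read_existence(reads, index, cfg)
            run = map_reads(
                reads, genome, index, cfg, seed_index=seed_index, use_filter=True
            )
            rows.append(
                {
                    "token_size": n,
                    "num_bins": t,
                    "error_tolerance": e,
                    "average_read_existence": are,
                    "false_negative_rate": run.evaluation.false_negative_rate,
                    "false_positive_count": run.evaluation.false_positive_count,
                    "footprint_bytes": footprint_bytes(t, n),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------


def load_reads(path: str) -> list[ReadSequence]:
    """Load reads from FASTQ or FASTA (sniffed from the first character)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [
        ReadSequence(read_id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(path, fmt)
    ]


def load_candidates_tsv(path: str) -> dict[str, list[Candidate]]:
    """External candidate lists: TSV columns read_id, location, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    need = {"read_id", "location", "strand"}
    if not need <= set(df.columns):
        raise ValueError(f"candidate TSV must have columns {sorted(need)}")
    out: dict[str, list[Candidate]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[row.read_id].append(
            Candidate(z=int(row.location), strand=str(row.strand), seed_offset=0)
        )
    return dict(out)


def write_mappings_tsv(run: MappingRun, path: str) -> None:
    run.mappings.to_csv(path, sep="\t", index=False)


def write_metrics_json(run: MappingRun, path: str) -> None:
    payload = dict(run.evaluation.to_dict())
    payload["n_candidates"] = run.n_candidates
    payload["n_verifications"] = run.n_verifications
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
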