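# Methods

## Model

The filter answers, per candidate location `z`, a one-sided question: *can
read `r` align within edit distance `k = ⌈L·e⌉` to some segment of the bin
containing `z`?* It does so by counting token evidence. A read of length
`L` contains `L − (n − 1)` overlapping tokens of length `n`. If the bin
holds a match with at most `k` edits, then in the worst case each edit (a
substitution or deletion) destroys the `n` tokens that cover it, and the
worst case places the edits so their destroyed token sets are disjoint; an
insertion destroys at most `n − 1` (one covering token survives shifted).
Hence at least

    threshold(L, n, e) = (L − (n − 1)) − ⌈L·e⌉·n

read tokens must still occur in the bin, and the accumulation sum
`Sum_z` (per-occurrence count of the read's tokens present in the bin) of
a true location can never be below the threshold. Rejection is therefore
always safe (no false positives); acceptance is heuristic (false
negatives happen when unrelated bin content supplies tokens, the
homopolymer example being the extreme case: a 104-A read scores 100
against a bin holding a single AAAAA).

Ties pass (`Sum_z ≥ threshold`). When the expression is non-positive
(large `e`, small `L`) the threshold clamps to 0 and the filter passes
everything; a warning is logged since the filter then does no work.

## Binning geometry

`make_binning(G, t, overlap)` uses stride `s = ⌈G/t⌉`; bin `i` covers
`[i·s, min(i·s + s + overlap, G))` (0-based, half-open everywhere). The
containment property the guarantee needs is that the window
`[z, z + overlap + 1)` lies inside bin `⌊z/s⌋`; the default overlap for
mapping is `L + ⌈L·e⌉ − 1`, the weakest value for which a read plus its
worst-case reference-span growth (all tolerated errors being deletions
from the read's perspective) fits in one bin. At `L = 100`, `e = 0.05`
this gives overlap 104 — the value used throughout the experiments. The
last bin may be truncated at the genome end; a genome shorter than one
stride gets `t = 1`.

Multi-record FASTA references are concatenated into one coordinate space
with a stored per-record offset table. Tokens whose window would straddle
a record junction are treated as ambiguous and never marked present, so
the index can hold no phantom cross-chromosome tokens; per-record bin
ranges were considered and rejected as needless bookkeeping once junction
tokens are suppressed, since a read spanning a junction cannot truly map
anyway.

## Ambiguity and numerical choices

* Reference tokens containing non-ACGT characters set no existence bits
  (conservative: absence can only cause false negatives, never false
  positives).
* Read tokens containing a non-ACGT base contribute 0 to `Sum_z`, and each
  ambiguous **base** is charged as one extra worst-case substitution,
  lowering the threshold by `n`. An all-N read degenerates to threshold 0
  (pass-all), which is the only safe answer.
* `⌈L·e⌉` is computed as `ceil(L·e − 1e−9)`: `e` is a binary float, so the
  product can land a few ulps above an exact integer (e.g. `60·0.1`), and
  overcounting allowable errors by one would silently loosen the filter.
* Token codes are big-endian base-4 with A=0, C=1, G=2, T=3; the bit
  matrix is token-major with byte-padded rows, so the existence bits of
  one token across a window of bins are a contiguous slice (the software
  image of one DRAM row).
* Reads shorter than `n` are rejected with an error rather than silently
  passed.

## Mapping harness

The harness is deliberately minimal, not a production mapper. Seeds are
non-overlapping 12-mers at fixed read offsets 0, 12, 24, … (`⌊L/12⌋` of
them), looked up in an exact hash index of the forward strand; the
reverse-complemented read is processed symmetrically and filtered as its
own query string. Seed hits are projected to read-start candidates
(`z = hit − offset`), deduplicated per `(z, strand)`.

Verification is semi-global unit-cost edit distance (read end-to-end,
window ends free) of the read against `[z − k, z + L + k)` clipped to the
genome, computed by edlib's infix mode; acceptance at distance `≤ k`
keeps the verifier's tolerance identical to the filter's. The test suite
checks this path against an independent full-DP quadratic oracle.

One subtlety makes the filter-on/filter-off equivalence exact rather than
approximate. A seed-projected `z` can be offset from the true match start
by up to the indel count, and the verifier window even admits matches
starting anywhere in `[z − k, z + 2k]`. A match starting just left of the
bin boundary of `z` would lose its leading tokens to the neighbouring bin
and could be wrongly discarded. The harness therefore queries the filter
at the guard locations `{z − k, z, z + 2k}` (clamped to the genome) and
keeps the candidate if any of their bins passes; since that range is far
shorter than one stride, at most two distinct bins are ever involved. The
guarantee is then provable for every candidate the verifier can accept.
The per-bin filter API itself (`filter_read_locations`) is untouched by
this and maps each location to exactly its own bin.

Metrics: `false_negative_rate` = (passed − passed∧mapped) / passed,
reported as 0 with a flag when nothing passes; `false_positive_count` =
rejected∧would-map, measured (not assumed) by verifying rejected
candidates during evaluation; `average_read_existence` = mean over reads
of the fraction of **all** bins the read passes in, computed with a
vectorised all-bins accumulation.

## Synthetic data

The generator emulates the study conditions: uniform i.i.d. ACGT
references, 100 bp reads sampled at uniform positions with exact per-read
error counts, error tolerance 0.05, token size 5, stride-150 bins with
overlap 104. Read length stays fixed under indels: a read with `i`
insertions and `d` deletions consumes a reference window of
`L − i + d` bases. The error-sweep generator cycles `k = 0…5` total
errors per read with uniformly random error types, the regime the
zero-false-positive experiment exercises. All generators are deterministic
given their seed, and truth tables carry the planted position, window
span and error counts, so filter quality is computable without
re-alignment.

What the generator does **not** emulate: real base-composition bias,
repeat structure, platform error profiles or quality values. Passing
tests therefore demonstrate the construction's guarantees and trends, not
absolute false-negative rates on real genomes — on a uniform random
reference far fewer seed hits share tokens by chance than in repeat-rich
human sequence, so measured false-negative rates here are near zero and
should not be compared to real-data figures.

## Cost model

`pim_model` counts abstract work units of the in-memory schedule: per bin
window of `w` consecutive bins containing at least one candidate, one row
activation per read token (a row holds one token's bits for the whole
window, `w ≤ 4096` row bits per cycle), one lockstep cycle per activation
plus one per window for the threshold compare and bitmask write-back, and
`⌈bins-in-window/8⌉` bitmask bytes. Empty windows cost nothing. The model
is schedule-only — filter results are independent of `w` by construction,
which the tests assert — and deliberately excludes DRAM timing, energy and
area figures, which are hardware-dependent.

## Problem sizes

The shipped experiments run on a 1 Mbp reference with 1000 planted reads
for the guarantee suite, 50 × 10 kb genomes for exhaustive oracle
equivalence, 500 read/window pairs for the verifier oracle, and a
300 kb / 60-read grid over `n ∈ {4,5}`, `t ∈ {64,256,1024}`,
`e ∈ {0…0.05}` for the sensitivity trends — sizes chosen so the whole
suite completes in minutes on one core while every qualitative claim
remains measurable.

## Known limitations

* The seed index is a plain Python hash table; it is the harness's
  stand-in for a mapper's index, not a scalable implementation.
* Absolute false-negative rates depend on the candidate generator and on
  genome repeat content; only their parameter trends are meaningful here.
* No paired-end logic, base qualities, or SAM semantics beyond plain TSV
  output.
* The cost model treats a bin window as a single lockstep unit and does
  not split it across memory vaults.
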