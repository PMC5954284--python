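# seedfilter

Bin-based token-existence seed-location filtering for seed-and-extend DNA
read mapping, with an analytic cost model of the filter's
processing-in-memory hardware realisation.

## The problem

Hash-based read mappers look up short exact seeds from each read and obtain
long lists of candidate genome locations, most of which fail the expensive
edit-distance verification that follows. A *seed location filter* sits
between seeding and verification and discards candidates that provably
cannot align within the error tolerance, without ever discarding one that
can.

`seedfilter` implements such a filter. The reference genome is divided into
`t` overlapping bins of uniform stride. Each bin `x` carries a bitvector
`b_x` of length `4^n` whose bit `k` records whether the token (DNA
substring of length `n`, default 5) with code `k` occurs anywhere in the
bin. For a read `r` of length `L` and a candidate location `z`, the
*accumulation sum*

    Sum_z = Σ over the L − n + 1 token occurrences of r of b_bin(z)[token]

counts how many of the read's tokens exist in the bin containing `z`
(duplicates counted per occurrence). The candidate is kept iff

    Sum_z ≥ (L − (n − 1)) − ⌈L·e⌉·n

where `e` is the alignment error tolerance. Each of the `⌈L·e⌉` tolerated
edit errors can destroy at most `n` tokens (worst case: a substitution or
deletion, hitting `n` disjoint tokens), so a true within-tolerance match
can never fall below the threshold: the filter has **zero false
positives** by construction. False negatives — kept candidates that still
fail verification — are possible and are what the evaluation harness
measures, together with *average read existence*: the fraction of all bins
a read passes in, averaged over reads (lower = better filtering).

Because each token's existence bits for consecutive bins are stored
contiguously, one memory row fetch serves one token across thousands of
bins at once; `seedfilter.pim_model` counts row activations and lockstep
cycles of that schedule for a 3D-stacked-DRAM realisation of the filter.

## Worked example

```python
from seedfilter import *
from seedfilter.synthetic_data import random_genome, plant_reads_error_sweep

genome = random_genome(100_000, seed=11)
reads, truth = plant_reads_error_sweep(genome, 100, read_length=100,
                                       max_errors=5, seed=12)

binning = make_binning(genome.length, num_bins=667, overlap=104)  # stride 150
index = build_index(genome, binning, TokenCodec(5))
cfg = FilterConfig(token_size=5, error_tolerance=0.05)

run_on  = map_reads(reads, genome, index, cfg, use_filter=True)
run_off = map_reads(reads, genome, index, cfg, use_filter=False)
```

prints (via the summary fields):

```
candidates:             173
verifications (on/off): 167 / 173
false positives:        0
false negative rate:    0.0000
mapped locations:       167
identical to no-filter: True
```

100 planted reads (0–5 mixed substitutions/indels each) yield 173 seed
candidates; the filter discards 6 of them, every discarded candidate fails
verification (zero false positives), and the accepted mappings are
identical with and without the filter. The threshold at `L=100`, `n=5`,
`e=0.05` is `(100−4) − 5·5 = 71` of 96 tokens.

The same pipeline is available from the shell:

```sh
seedfilter simulate --genome-length 100000 --n-reads 100 --seed 11 --out-prefix sim
seedfilter build-index sim.fasta -n 5 -t 667 --overlap 104 -o sim.sbvi
seedfilter map sim.sbvi sim.fasta sim.fastq -e 0.05 -o mappings.tsv
seedfilter sweep --genome-length 100000 -o sweep.tsv
seedfilter pim-estimate sim.sbvi candidates.tsv -o cost.json
```

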