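"""Simplified analytic cost model of the in-memory filter.

The hardware realisation stores each token's existence bits for many
consecutive bins in one DRAM row, and attaches one small logic module
(incrementer + accumulator + comparator) per bin of a *bin window* of w
consecutive bins.  The modules run in lockstep: one row fetch per read
token delivers the token's bits for the whole window, and every module
updates its accumulator in the same cycle.  Only windows containing at
least one candidate seed location are processed at all.

This module counts abstract row fetches and lockstep cycles under that
schedule — no DRAM timing, energy, or area is modelled.  The schedule
never changes filter *results* (those are pinned by filter_core for any
w); it only changes how much work the hardware does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .genome_index import BinningConfig, bin_of_location

__all__ = ["PimConfig", "CostReport", "windows_touched", "estimate_cost", "accumulator_bits"]


@dataclass(frozen=True)
class PimConfig:
    """Hardware-shape parameters.

    row_bits_per_cycle: bits one row fetch delivers to the logic layer per
    cycle (4096 matches the TSV count of current 3D-stacked parts).
    bin_window: number of bins processed in lockstep (w <= row bits).
    bitmask_buffer_bytes: capacity of the seed-location-filter bitmask
    buffer in the logic layer (512 KiB default).
    """

    row_bits_per_cycle: int = 4096
    bin_window: int = 4096
    bitmask_buffer_bytes: int = 524288

    def __post_init__(self) -> None:
        if min(self.row_bits_per_cycle, self.bin_window, self.bitmask_buffer_bytes) < 1:
            raise ValueError("all PIM parameters must be >= 1")
        if self.bin_window > self.row_bits_per_cycle:
            raise ValueError(
                f"bin_window {self.bin_window} exceeds row bits per cycle "
                f"{self.row_bits_per_cycle}"
            )


@dataclass(frozen=True)
class CostReport:
    row_activations: int
    lockstep_cycles: int
    windows_processed: int
    bitmask_bytes: int

    def to_dict(self) -> dict:
        return {
            "row_activations": self.row_activations,
            "lockstep_cycles": self.lockstep_cycles,
            "windows_processed": self.windows_processed,
            "bitmask_bytes": self.bitmask_bytes,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def accumulator_bits(read_length: int) -> int:
    """Width of each per-bin accumulator: it must hold sums up to the
    read's token count, so ceil(log2(read_length)) bits suffice."""
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    return math.ceil(math.log2(read_length))


def windows_touched(
    locations: list[int], binning: BinningConfig, w: int
) -> list[int]:
    """Sorted indices of bin windows holding >= 1 candidate location.

    Window i covers bins [i*w, (i+1)*w).  Windows with no candidates are
    skipped entirely by the hardware.
    """
    if w < 1:
        raise ValueError("bin window must be >= 1")
    return sorted({bin_of_location(z, binning) // w for z in locations})


def estimate_cost(
    read_length: int,
    token_size: int,
    locations: list[int],
    binning: BinningConfig,
    pim: PimConfig,
) -> CostReport:
    """Abstract cost of filtering one read's candidate locations.

    Per touched window: one row activation per read token (the row holds
    the token's bits for all w bins), one lockstep cycle per activation,
    plus one cycle for the threshold compare and bitmask write-back.  The
    bitmask written per window is its bin count rounded up to whole bytes.
    """
    if read_length < token_size:
        raise ValueError("read_length must be >= token_size")
    touched = windows_touched(locations, binning, pim.bin_window)
    tokens = read_length - token_size + 1
    activations = tokens * len(touched)
    bitmask = 0
    for i in touched:
        bins_in_window = min(pim.bin_window, binning.num_bins - i * pim.bin_window)
        bitmask += -(-bins_in_window // 8)
    return CostReport(
        row_activations=activations,
        lockstep_cycles=activations + len(touched),
        windows_processed=len(touched),
        bitmask_bytes=bitmask,
    )
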