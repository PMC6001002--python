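"""Runs-of-homozygosity detection from windowed SNP counts.

A single genome is tiled into fixed windows (10 kb by default, anchored at
position 1; a trailing partial window is flagged non-evaluable). Per window
the heterozygous call count of the focal sample and the mean site depth are
collected. Against genome-wide averages, an autozygous stretch is a run of
consecutive evaluable windows that

* starts and ends at a *seed* window (count < ``seed_fraction`` x average),
* never contains an evaluable window above ``window_cap_fraction`` x average
  (the relaxed per-window bound that bridges local assembly/alignment
  artifacts inside a stretch),
* spans at least ``min_windows`` evaluable windows, and
* keeps its mean count at or below ``stretch_mean_fraction`` x average.

Windows whose depth falls outside ``depth_band`` x average depth (or that
have no covered sites) are non-evaluable: they neither count toward the run
nor break it, up to ``max_gap`` consecutive such windows.

Counting heterozygous calls (rather than all variant sites) is the default:
an ROH estimates autozygosity and a homozygous-alt site carries no evidence
against it; ``count_mode="all"`` is available for the alternative reading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

from .errors import DegenerateInputError, ValidationError
from .io_formats import VariantTable

__all__ = [
    "RohParams",
    "WindowStat",
    "RohInterval",
    "Baseline",
    "window_stats",
    "genome_baseline",
    "call_roh",
]


@dataclass
class RohParams:
    """Thresholds of the windowed autozygosity caller (defaults per the
    published criteria: 10 kb windows, 0.25x seed, >=10 windows, 0.5-2x
    depth band, 2x per-window cap, 1/4 stretch mean)."""

    window_size: int = 10_000
    seed_fraction: float = 0.25
    min_windows: int = 10
    depth_band: Tuple[float, float] = (0.5, 2.0)
    window_cap_fraction: float = 2.0
    stretch_mean_fraction: float = 0.25
    max_gap: int = 2

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValidationError("window_size must be >= 1")
        if self.min_windows < 1:
            raise ValidationError("min_windows must be >= 1")
        if not self.depth_band[0] < self.depth_band[1]:
            raise ValidationError("depth_band low must be < high")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


@dataclass
class WindowStat:
    """Counts for one tiling window (1-based closed genomic interval)."""

    index: int
    start: int
    end: int
    snp_count: int
    mean_depth: float  # NaN when the window has no covered sites
    evaluable: bool


@dataclass
class RohInterval:
    """One called autozygous tract (window-aligned, 1-based closed)."""

    chrom: str
    start: int
    end: int
    n_windows: int  # evaluable windows in the stretch
    mean_snp_fraction: float  # stretch mean count / genome average


@dataclass
class Baseline:
    avg_snp_count: float
    avg_depth: float


def window_stats(
    table: VariantTable,
    sample: str,
    segment_length: int,
    params: RohParams,
    count_mode: Literal["het", "all"] = "het",
    chrom: Optional[str] = None,
) -> List[WindowStat]:
    """Tile the segment and count the focal sample's SNPs per window.

    ``snp_count`` counts heterozygous calls of ``sample`` (``count_mode
    ="het"``, the autozygosity semantics) or all non-reference non-missing
    calls (``"all"``). ``mean_depth`` averages the site depths of every
    record in the window regardless of genotype, so homozygous sites still
    anchor coverage. Evaluability (depth band relative to the average depth
    of fully covered windows) is pre-computed here; a trailing partial
    window is always non-evaluable.
    """
    si = table.sample_index(sample)
    w = params.window_size
    n_windows = math.ceil(segment_length / w)
    counts = [0] * n_windows
    depth_sums = [0.0] * n_windows
    depth_ns = [0] * n_windows
    for rec in table.records:
        if chrom is not None and rec.chrom != chrom:
            continue
        if rec.pos > segment_length:
            continue
        wi = (rec.pos - 1) // w
        depth_sums[wi] += rec.mean_depth
        depth_ns[wi] += 1
        if count_mode == "het":
            if rec.is_het(si):
                counts[wi] += 1
        else:
            a, b = rec.genotype(si)
            if a is not None and b is not None and (a > 0 or b > 0):
                counts[wi] += 1

    full = [segment_length >= (i + 1) * w for i in range(n_windows)]
    depths = [
        depth_sums[i] / depth_ns[i] if depth_ns[i] else float("nan")
        for i in range(n_windows)
    ]
    covered = [
        depths[i] for i in range(n_windows) if full[i] and depth_ns[i] > 0
    ]
    avg_depth = sum(covered) / len(covered) if covered else float("nan")
    lo, hi = params.depth_band
    stats = []
    for i in range(n_windows):
        evaluable = (
            full[i]
            and depth_ns[i] > 0
            and lo * avg_depth <= depths[i] <= hi * avg_depth
        )
        stats.append(
            WindowStat(
                index=i,
                start=i * w + 1,
                end=min((i + 1) * w, segment_length),
                snp_count=counts[i],
                mean_depth=depths[i],
                evaluable=evaluable,
            )
        )
    return stats


def genome_baseline(stats: Sequence[WindowStat]) -> Baseline:
    """Genome-average window SNP count and depth over evaluable windows."""
    ev = [s for s in stats if s.evaluable]
    if not ev:
        raise DegenerateInputError("no evaluable windows; cannot form a baseline")
    return Baseline(
        avg_snp_count=sum(s.snp_count for s in ev) / len(ev),
        avg_depth=sum(s.mean_depth for s in ev) / len(ev),
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _qualifies(
    stats: Sequence[WindowStat],
    i: int,
    j: int,
    seed_thr: float,
    cap: float,
    mean_thr: float,
    min_windows: int,
    max_gap: int,
) -> bool:
    """Test run [i..j] (window indices, inclusive) against all criteria."""
    if not (stats[i].evaluable and stats[j].evaluable):
        return False
    if not (stats[i].snp_count < seed_thr and stats[j].snp_count < seed_thr):
        return False
    n_ev = 0
    total = 0
    gap = 0
    for k in range(i, j + 1):
        s = stats[k]
        if not s.evaluable:
            gap += 1
            if gap > max_gap:
                return False
            continue
        gap = 0
        if s.snp_count > cap:
            return False
        n_ev += 1
        total += s.snp_count
    if n_ev < min_windows:
        return False
    return total / n_ev <= mean_thr


def call_roh(
    stats: Sequence[WindowStat],
    baseline: Baseline,
    params: RohParams,
    chrom: str = "1",
) -> List[RohInterval]:
    """Call maximal qualifying autozygous stretches.

    Qualifying runs (see module docstring) are enumerated, inclusion-maximal
    ones kept, and overlapping candidates merged to the maximal qualifying
    extent — the union when the union itself qualifies, otherwise the run
    spanning more evaluable windows (leftmost on ties). Output is sorted and
    non-overlapping.
    """
    if not baseline.avg_snp_count > 0:
        raise DegenerateInputError("baseline average SNP count must be > 0")
    avg = baseline.avg_snp_count
    seed_thr = params.seed_fraction * avg
    cap = params.window_cap_fraction * avg
    mean_thr = params.stretch_mean_fraction * avg

    seeds = [
        s.index for s in stats if s.evaluable and s.snp_count < seed_thr
    ]

    def ok(i: int, j: int) -> bool:
        return _qualifies(
            stats, i, j, seed_thr, cap, mean_thr, params.min_windows, params.max_gap
        )

    runs: List[Tuple[int, int]] = []
    for a, i in enumerate(seeds):
        for j in reversed(seeds[a:]):
            if ok(i, j):
                runs.append((i, j))
                break  # longest run starting at i; shorter ones are contained

    # inclusion-maximal
    runs = [
        r
        for r in runs
        if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)
    ]
    runs.sort()

    def n_ev(i: int, j: int) -> int:
        return sum(1 for k in range(i, j + 1) if stats[k].evaluable)

    merged: List[Tuple[int, int]] = []
    for run in runs:
        if merged and run[0] <= merged[-1][1]:
            prev = merged[-1]
            union = (prev[0], max(prev[1], run[1]))
            if ok(*union):
                merged[-1] = union
            elif n_ev(*run) > n_ev(*prev):
                merged[-1] = run
            # else keep prev (more windows, or leftmost on tie)
        else:
            merged.append(run)

    out = []
    for i, j in merged:
        ev = [stats[k] for k in range(i, j + 1) if stats[k].evaluable]
        mean_count = sum(s.snp_count for s in ev) / len(ev)
        out.append(
            RohInterval(
                chrom=chrom,
                start=stats[i].start,
                end=stats[j].end,
                n_windows=len(ev),
                mean_snp_fraction=mean_count / avg,
            )
        )
    return out
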