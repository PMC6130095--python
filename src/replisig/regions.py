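"""Replication-domain geometry: domains, origin bins, timing quartiles, masks.

Coordinates are 0-based half-open (BED convention) throughout; 1-based input
positions are converted at the reader boundary.

Replication direction is encoded as ``"left"`` / ``"right"``: in a
left-replicating region the fork moves leftward along the reference, so the
reference (plus/Watson) strand is the template of the leading strand; in a
right-replicating region the complementary strand is.

Replication timing is carried in rtu (replication timing units).  The package
default orientation is *larger rtu = later replication* (an origin is a local
timing minimum), which makes the slope sign convention below self-consistent:
timing rises left-to-right while the fork travels rightward, so a positive
slope marks a right-replicating transition region.  The opposite orientation
(larger rtu = earlier, common for raw Repli-seq scores) is selected with
``higher_rtu_is_earlier=True`` where quartiles are assigned, and with
``invert_direction=True`` where direction is inferred from slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pyranges as pr

LEFT = "left"
RIGHT = "right"
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReplicationDomain:
    """Fixed-width region annotated with replication direction and timing."""

    interval: GenomicInterval
    direction: str
    timing: float

    def __post_init__(self):
        if self.direction not in (LEFT, RIGHT):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")


@dataclass(frozen=True)
class OriginBin:
    """One fixed-width bin on one side of a replication origin.

    ``index`` is the 1-based distance rank from the origin midpoint;
    ``inferred_direction`` follows outward bidirectional replication: bins
    left of the origin replicate leftward, bins right of it rightward.
    """

    interval: GenomicInterval
    side: str  # "left_of_origin" | "right_of_origin"
    index: int
    inferred_direction: str

    def __post_init__(self):
        if self.side not in ("left_of_origin", "right_of_origin"):
            raise ValueError(f"bad side {self.side!r}")
        if self.index < 1:
            raise ValueError("index is 1-based")


@dataclass
class TimingProfile:
    """Binned replication-timing track (bedGraph-like).

    ``bins`` maps chromosome -> (starts, ends, values) with per-chromosome
    bins sorted and non-overlapping.
    """

    bins: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimingProfile":
        """Build from a frame with columns chrom, start, end, timing."""
        bins = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or non-monotone timing bins on {chrom}")
            bins[str(chrom)] = (starts, ends, sub["timing"].to_numpy(float))
        return cls(bins)

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"chrom": c, "start": s, "end": e, "timing": v})
            for c, (s, e, v) in sorted(self.bins.items())
        ]
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["chrom", "start", "end", "timing"]
        )


def derive_domains_from_timing(
    profile: TimingProfile,
    domain_width: int = 20_000,
    slope_threshold: float = 250.0,
    invert_direction: bool = False,
) -> list[ReplicationDomain]:
    """Cut the timing track into fixed-width domains classified by slope.

    Each ``domain_width`` window gets an ordinary-least-squares slope of
    timing (rtu) versus position, in rtu per Mb, using the midpoints of the
    profile bins inside it.  Windows with ``|slope| < slope_threshold`` are
    the flat peaks/valleys around origins and termini and are discarded.
    Remaining windows become domains: positive slope -> right-replicating,
    negative -> left (inverted by ``invert_direction``), each annotated with
    its mean timing.
    """
    domains: list[ReplicationDomain] = []
    for chrom in sorted(profile.bins):
        starts, ends, values = profile.bins[chrom]
        if len(starts) < 2:
            warnings.warn(f"chromosome {chrom} has <2 timing bins; skipped")
            continue
        mids = (starts + ends) / 2.0
        lo, hi = int(starts[0]), int(ends[-1])
        for w0 in range(lo, hi - domain_width + 1, domain_width):
            w1 = w0 + domain_width
            sel = (mids >= w0) & (mids < w1)
            if sel.sum() < 2:
                continue
            x = mids[sel] / 1e6  # Mb
            y = values[sel]
            slope = np.polyfit(x, y, 1)[0]  # rtu per Mb
            if abs(slope) < slope_threshold:
                continue
            is_right = slope > 0
            if invert_direction:
                is_right = not is_right
            domains.append(
                ReplicationDomain(
                    GenomicInterval(chrom, w0, w1),
                    RIGHT if is_right else LEFT,
                    float(np.mean(y)),
                )
            )
    return domains


def _merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def build_origin_bins(
    origins: list[GenomicInterval],
    bin_width: int = 1_000,
    max_bins: int = 1_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[OriginBin]:
    """Tile fixed-width bins outward from each origin midpoint.

    Up to ``max_bins`` bins are laid on each side of the midpoint; a bin is
    emitted only while it stays entirely within half the distance to the
    adjacent origin midpoint (so no bin is shared between origins) and
    within the chromosome.  Overlapping origin intervals are merged first.
    """
    merged = _merge_intervals(origins)
    if len(merged) < len(origins):
        warnings.warn("overlapping origin intervals merged")
    bins: list[OriginBin] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in sorted(by_chrom.items()):
        mids = [(iv.start + iv.end) // 2 for iv in ivs]
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        for i, mid in enumerate(mids):
            left_lim = 0 if i == 0 else (mids[i - 1] + mid + 1) // 2
            right_lim = (mid + mids[i + 1]) // 2 if i + 1 < len(mids) else (
                size if size is not None else None
            )
            for k in range(1, max_bins + 1):
                b0, b1 = mid - k * bin_width, mid - (k - 1) * bin_width
                if b0 < left_lim:
                    break
                bins.append(
                    OriginBin(GenomicInterval(chrom, b0, b1), "left_of_origin", k, LEFT)
                )
            for k in range(1, max_bins + 1):
                b0, b1 = mid + (k - 1) * bin_width, mid + k * bin_width
                if right_lim is not None and b1 > right_lim:
                    break
                bins.append(
                    OriginBin(GenomicInterval(chrom, b0, b1), "right_of_origin", k, RIGHT)
                )
    return bins


def assign_timing_quartiles(
    domains: list[ReplicationDomain],
    higher_rtu_is_earlier: bool = False,
) -> dict[ReplicationDomain, str]:
    """Rank domains by mean timing and split into four near-equal quartiles.

    Q1 is the earliest-replicating quarter, Q4 the latest.  With the default
    orientation (larger rtu = later) Q1 holds the lowest timings; with
    ``higher_rtu_is_earlier=True`` it holds the highest.  Ties are broken by
    (chrom, start) so the assignment is deterministic.
    """
    n = len(domains)
    if n < 4:
        raise ValueError("need at least 4 domains for quartiles")
    timings = np.array([d.timing for d in domains])
    if np.all(timings == timings[0]):
        warnings.warn("all domain timings identical; quartiles assigned by position rank")
    sign = -1.0 if higher_rtu_is_earlier else 1.0
    order = sorted(
        range(n),
        key=lambda i: (sign * domains[i].timing, domains[i].interval.chrom,
                       domains[i].interval.start),
    )
    # earliest first; quartile sizes differ by at most one (larger ones first)
    bounds = [round(n * k / 4) for k in range(5)]
    assignment: dict[ReplicationDomain, str] = {}
    for q in range(4):
        for i in order[bounds[q]:bounds[q + 1]]:
            assignment[domains[i]] = QUARTILE_LABELS[q]
    return assignment


def _to_pyranges(intervals: list[GenomicInterval]) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in intervals],
                "Start": [iv.start for iv in intervals],
                "End": [iv.end for iv in intervals],
            }
        )
    )


def apply_exclusions(
    intervals: list[GenomicInterval], masks: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Subtract mask intervals (low-mappability, coding genes, blacklists).

    Returns the maximal sub-intervals of the input not covered by any mask;
    total returned length equals input length minus overlap length.
    """
    if not intervals:
        return []
    if not masks:
        return list(intervals)
    result = _to_pyranges(intervals).subtract(_to_pyranges(masks))
    df = result.df
    out = [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in df.itertuples()
    ]
    return sorted(out)


def mask_domains(
    domains: list[ReplicationDomain], masks: list[GenomicInterval]
) -> list[ReplicationDomain]:
    """Subtract masks from each domain, keeping direction/timing annotations.

    A masked domain may split into several sub-domains (or vanish)."""
    out: list[ReplicationDomain] = []
    for d in domains:
        for iv in apply_exclusions([d.interval], masks):
            out.append(replace(d, interval=iv))
    return out


def origin_bins_as_domains(bins: list[OriginBin]) -> list[ReplicationDomain]:
    """View origin bins as direction-annotated domains (timing is NaN).

    Lets the catalog builder stratify mutation counts by origin-relative
    bin through the same interface as replication domains."""
    return [
        ReplicationDomain(b.interval, b.inferred_direction, float("nan"))
        for b in bins
    ]


def randomize_domains(
    domains: list[ReplicationDomain],
    chrom_sizes: dict[str, int],
    seed: int,
) -> list[ReplicationDomain]:
    """Place the same domain widths uniformly at random, without overlap.

    Used as a negative control: catalogs built on randomized domains should
    carry no replication-strand signal.  Widths stay on their original
    chromosome; directions and timings are shuffled among all domains.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[ReplicationDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    annotations = [(d.direction, d.timing) for d in domains]
    rng.shuffle(annotations)
    out: list[ReplicationDomain] = []
    ai = 0
    for chrom in sorted(by_chrom):
        widths = [d.interval.width for d in by_chrom[chrom]]
        slack = chrom_sizes[chrom] - sum(widths)
        if slack < 0:
            raise ValueError(f"domains do not fit on {chrom}")
        # distribute the free space as random gaps before each domain
        cuts = np.sort(rng.integers(0, slack + 1, size=len(widths)))
        pos = 0
        for w, cut, prev in zip(widths, cuts, np.concatenate([[0], cuts[:-1]])):
            pos += int(cut - prev)
            direction, timing = annotations[ai]
            ai += 1
            out.append(
                ReplicationDomain(GenomicInterval(chrom, pos, pos + w), direction, timing)
            )
            pos += w
    return out
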