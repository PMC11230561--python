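"""Bar / interbar calling on a 1-D intensity profile.

A vertical melanic bar is a region darker than the individual's own average
gray value.  Two run-length criteria suppress pixel-to-pixel noise: a bar
only opens on a run of at least ``min_run`` consecutive below-average pixels,
and only closes on a run of at least ``min_run`` consecutive at-or-above-
average pixels (shorter bright interruptions stay inside the bar).  The bar's
recorded end is the last below-average pixel before the closing run.  All
remaining pixels — including leading and trailing stretches — are interbars.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

Interval = tuple[int, int]  # half-open [start, end) in pixels

DEFAULT_MIN_RUN = 5


@dataclass
class BarSegmentation:
    """Ordered, disjoint bar and interbar intervals covering a profile.

    ``threshold`` is the profile's mean gray value; ``bars`` and
    ``interbars`` are half-open pixel intervals that together partition
    ``[0, length_px)`` and alternate.
    """

    threshold: float
    length_px: int
    bars: list[Interval] = field(default_factory=list)
    interbars: list[Interval] = field(default_factory=list)
    min_run: int = DEFAULT_MIN_RUN

    def __post_init__(self) -> None:
        segs = sorted(
            [(s, e, "bar") for s, e in self.bars]
            + [(s, e, "interbar") for s, e in self.interbars]
        )
        cursor = 0
        prev_kind = None
        for s, e, kind in segs:
            if s != cursor or e <= s:
                raise ValueError("segments must tile [0, length_px) without gaps")
            if kind == prev_kind:
                raise ValueError("bar/interbar segments must alternate")
            cursor = e
            prev_kind = kind
        if cursor != self.length_px:
            raise ValueError("segments must cover the full profile")

    @property
    def n_bars(self) -> int:
        return len(self.bars)

    def bar_mask(self) -> np.ndarray:
        """Boolean mask, True where a pixel belongs to a bar."""
        mask = np.zeros(self.length_px, dtype=bool)
        for s, e in self.bars:
            mask[s:e] = True
        return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean mask into (start, end, value) triples."""
    n = mask.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(mask.view(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    return [(int(s), int(e), bool(mask[s])) for s, e in zip(starts, ends)]


def segment_bars(profile, min_run: int = DEFAULT_MIN_RUN) -> BarSegmentation:
    """Call bars and interbars on ``profile`` (an array or IntensityProfile).

    The threshold is the arithmetic mean of the profile's own values; pixels
    strictly below it are "dark".  Scanning anterior to posterior, a bar
    opens at the first pixel of a run of >= ``min_run`` dark pixels, closes
    on the first subsequent run of >= ``min_run`` not-dark pixels (its end is
    the last dark pixel before that run), and a bar still open at the end of
    the profile runs to the final pixel.
    """
    values = np.asarray(getattr(profile, "values", profile), dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("profile must be a non-empty 1-D series")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    n = values.size
    threshold = float(values.mean())
    below = values < threshold  # equality counts as interbar

    runs = _runs(below)
    bars: list[Interval] = []
    i = 0
    while i < len(runs):
        s, e, dark = runs[i]
        if not dark or e - s < min_run:
            i += 1
            continue
        # Bar opens at s; absorb runs until a closing bright run or profile end.
        bar_start, bar_end, closed = s, e, False
        j = i + 1
        while j < len(runs):
            rs, re, rdark = runs[j]
            if rdark:
                bar_end = re
            elif re - rs >= min_run:
                closed = True
                break
            j += 1
        if not closed:
            bar_end = n  # open at profile end: bar runs to the last pixel
        bars.append((bar_start, bar_end))
        i = j + 1

    interbars: list[Interval] = []
    cursor = 0
    for s, e in bars:
        if s > cursor:
            interbars.append((cursor, s))
        cursor = e
    if cursor < n:
        interbars.append((cursor, n))

    return BarSegmentation(
        threshold=threshold, length_px=n, bars=bars, interbars=interbars, min_run=min_run
    )


def write_segmentation_csv(
    seg: BarSegmentation, path: str | Path, individual_id: str = ""
) -> None:
    """Export segments as BED-like CSV: id, type, start_px, end_px (half-open)."""
    rows = sorted(
        [(s, e, "bar") for s, e in seg.bars]
        + [(s, e, "interbar") for s, e in seg.interbars]
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual_id", "segment_type", "start_px", "end_px"])
        for s, e, kind in rows:
            w.writerow([individual_id, kind, s, e])
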