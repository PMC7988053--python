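"""Point-in-interval queries between CpG probes and genomic intervals.

Probes are 1-based points; interval tables are BED-style 0-based
half-open, so a probe at position ``p`` hits ``[start, end)`` iff
``start <= p - 1 < end``.  All converters live here so the convention is
fixed in exactly one place.

Both query directions are needed downstream: "which probes fall in any
interval" (resampling null, external DMC overlap) and "which intervals
contain at least one probe" (per-DMR hit counting).  Both are answered
with sorted arrays and ``numpy.searchsorted`` — O((n+m) log(n+m)) and
fully vectorised, which matters because the biomarker Monte Carlo runs
these queries thousands of times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def probe_points(manifest: pd.DataFrame) -> pd.DataFrame:
    """0-based point coordinates for the probes of a manifest."""
    return pd.DataFrame(
        {"chrom": manifest["chrom"].to_numpy(), "point": manifest["pos"].to_numpy() - 1},
        index=manifest.index,
    )


def validate_intervals(intervals: pd.DataFrame) -> None:
    for col in INTERVAL_COLUMNS:
        if col not in intervals.columns:
            raise ValueError(f"interval table lacks required column {col!r}")
    if len(intervals) and not (intervals["start"] < intervals["end"]).all():
        bad = intervals.loc[~(intervals["start"] < intervals["end"])]
        raise ValueError(f"malformed intervals (start >= end): {len(bad)} rows")


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly overlapping half-open intervals, sorted."""
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def points_in_any(
    chroms: np.ndarray, points: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each 0-based point fall inside any interval?"""
    validate_intervals(intervals)
    chroms = np.asarray(chroms)
    points = np.asarray(points)
    hit = np.zeros(len(points), dtype=bool)
    if not len(intervals):
        return hit
    for chrom, sub in intervals.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        pts = points[mask]
        idx = np.searchsorted(ms, pts, side="right") - 1
        inside = (idx >= 0) & (pts < me[np.clip(idx, 0, len(me) - 1)])
        hit[mask] = inside
    return hit


def intervals_containing_any(
    intervals: pd.DataFrame, chroms: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Boolean mask over intervals: does each contain >= 1 of the points?"""
    validate_intervals(intervals)
    chroms = np.asarray(chroms)
    points = np.asarray(points)
    hit = np.zeros(len(intervals), dtype=bool)
    if not len(points) or not len(intervals):
        return hit
    positions = np.arange(len(intervals))
    for chrom, sub in intervals.groupby("chrom", sort=False):
        pts = np.sort(points[chroms == chrom])
        if not len(pts):
            continue
        lo = np.searchsorted(pts, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pts, sub["end"].to_numpy(), side="left")
        hit[positions[intervals["chrom"].to_numpy() == chrom]] = hi > lo
    return hit
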