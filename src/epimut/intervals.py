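"""Light interval utilities over BED-like frames.

Scales are desk-sized (<=10^5 intervals, <=10^6 points), so the index is a
per-chromosome sorted-start array with a running maximum of ends — O(log n)
stabbing without an external interval-tree dependency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class IntervalIndex:
    """Point-in-interval queries over a (chrom, start, end) frame."""

    def __init__(self, features: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        if len(features) == 0:
            return
        for chrom, grp in features.groupby("chrom", sort=False):
            order = np.argsort(grp["start"].to_numpy(), kind="mergesort")
            starts = grp["start"].to_numpy()[order]
            ends = grp["end"].to_numpy()[order]
            rows = grp.index.to_numpy()[order]
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends), rows)

    def covers(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: is each (chrom, pos) point inside any interval?"""
        out = np.zeros(len(positions), dtype=bool)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom, (starts, _ends, cummax, _rows) in self._by_chrom.items():
            m = chroms == chrom
            if not m.any():
                continue
            pos = positions[m]
            idx = np.searchsorted(starts, pos, side="right")
            hit = (idx > 0) & (cummax[np.maximum(idx - 1, 0)] > pos)
            out[m] = hit
        return out

    def overlaps_any(self, chrom: str, qstart: int, qend: int) -> bool:
        """Does [qstart, qend) overlap any indexed interval by >= 1 bp?"""
        if chrom not in self._by_chrom:
            return False
        starts, _ends, cummax, _rows = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, qend, side="left"))
        return i > 0 and cummax[i - 1] > qstart

    def stab(self, chrom: str, pos: int) -> list[int]:
        """Row labels of all intervals containing ``pos`` (may be several)."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, cummax, rows = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right"))
        hits = []
        j = i - 1
        while j >= 0 and cummax[j] > pos:
            if ends[j] > pos:
                hits.append(int(rows[j]))
            j -= 1
        return hits


def position_index(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted mutation positions per chromosome (events pooled over samples)."""
    return {chrom: np.sort(grp["pos"].to_numpy())
            for chrom, grp in df.groupby("chrom", sort=False)}


def count_in_intervals(positions: dict[str, np.ndarray],
                       regions: pd.DataFrame) -> np.ndarray:
    """Number of events with start <= pos < end, per region, in input order."""
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.itertuples(index=False)):
        pos = positions.get(row.chrom)
        if pos is None:
            continue
        counts[i] = (np.searchsorted(pos, row.end, side="left")
                     - np.searchsorted(pos, row.start, side="left"))
    return counts
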