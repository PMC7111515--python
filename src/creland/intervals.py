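"""Half-open genomic interval arithmetic on plain numpy arrays.

All interval sets are pandas DataFrames with columns ``chrom``, ``start``,
``end`` and 0-based, half-open coordinates.  Intervals that merely touch
(``a.end == b.start``) are *not* considered overlapping: the half-open
convention makes "touching" unambiguous, and merging is restricted to
overlaps of at least one base.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

COLUMNS = ["chrom", "start", "end"]


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an interval frame (sorted, typed, 3 columns)."""
    if df is None or len(df) == 0:
        return empty_intervals()
    out = df[COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] < 0).any():
        raise FormatError("negative interval coordinates")
    if (out["start"] >= out["end"]).any():
        raise FormatError("interval with start >= end")
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return out


def merge_intervals(df: pd.DataFrame, touching: bool = False) -> pd.DataFrame:
    """Merge intervals overlapping by >= 1 base into maximal intervals.

    With ``touching=True``, book-ended intervals (``a.end == b.start``) are
    fused as well; this is the right semantics when the intervals describe
    base-level coverage rather than discrete elements.
    """
    df = as_intervals(df)
    if len(df) == 0:
        return df
    pieces = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # sorted by start: a new merged block begins where start >= running max end
        run_max = np.maximum.accumulate(ends)
        new_block = np.ones(len(starts), dtype=bool)
        if touching:
            new_block[1:] = starts[1:] > run_max[:-1]
        else:
            new_block[1:] = starts[1:] >= run_max[:-1]
        block = np.cumsum(new_block) - 1
        n_blocks = block[-1] + 1
        m_start = np.zeros(n_blocks, dtype=np.int64)
        m_end = np.zeros(n_blocks, dtype=np.int64)
        m_start[block[new_block]] = starts[new_block]
        np.maximum.at(m_end, block, ends)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": m_start, "end": m_end}))
    return pd.concat(pieces, ignore_index=True)


def intersect_all(sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Base-level intersection across all interval sets, as maximal intervals."""
    if len(sets) == 0:
        raise ValueError("intersect_all needs at least one interval set")
    sets = [merge_intervals(s) for s in sets]
    n = len(sets)
    if n == 1:
        return sets[0]
    chroms = set(sets[0]["chrom"])
    for s in sets[1:]:
        chroms &= set(s["chrom"])
    pieces = []
    for chrom in sorted(chroms):
        events = []
        for s in sets:
            grp = s[s["chrom"] == chrom]
            events.append(np.stack([grp["start"].to_numpy(), np.ones(len(grp), dtype=np.int64)], axis=1))
            events.append(np.stack([grp["end"].to_numpy(), -np.ones(len(grp), dtype=np.int64)], axis=1))
        ev = np.concatenate(events, axis=0)
        order = np.lexsort((ev[:, 1], ev[:, 0]))  # ends (-1) before starts (+1) at same pos
        ev = ev[order]
        depth = np.cumsum(ev[:, 1])
        pos = ev[:, 0]
        covered = depth == n
        # maximal runs where coverage depth equals n
        starts = pos[covered]
        nxt = np.empty(len(pos), dtype=np.int64)
        nxt[:-1] = pos[1:]
        if len(pos):
            nxt[-1] = pos[-1]
        ends = nxt[covered]
        keep = ends > starts
        if keep.any():
            pieces.append(pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]}))
    if not pieces:
        return empty_intervals()
    return merge_intervals(pd.concat(pieces, ignore_index=True), touching=True)


def overlaps_any(query: pd.DataFrame, catalog: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap >= 1 base of any catalog interval?

    The result is aligned with ``query``'s row order as given.
    """
    if len(query) == 0:
        return np.zeros(0, dtype=bool)
    out = np.zeros(len(query), dtype=bool)
    if catalog is None or len(catalog) == 0:
        return out
    cat = merge_intervals(catalog)
    by_chrom = {c: g for c, g in cat.groupby("chrom", sort=False)}
    q = query.reset_index(drop=True)
    for chrom, grp in q.groupby("chrom", sort=False):
        g = by_chrom.get(chrom)
        if g is None:
            continue
        cs = g["start"].to_numpy()
        ce = g["end"].to_numpy()
        run_max_end = np.maximum.accumulate(ce)
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        # any catalog interval with start < query end and end > query start
        idx = np.searchsorted(cs, qe, side="left")
        hit = np.zeros(len(grp), dtype=bool)
        nz = idx > 0
        hit[nz] = run_max_end[idx[nz] - 1] > qs[nz]
        out[grp.index.to_numpy()] = hit
    return out


def total_bases(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def midpoints(df: pd.DataFrame) -> np.ndarray:
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
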