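"""Chromatin-state segmentations and landscape statistics.

A :class:`StateSegmentation` is one cell type's tiling of the genome by
integer epigenetic state ids (state 0 is the quiescent state by convention).
On top of it this module computes the statistics used to describe a
regulatory landscape: per-state genome coverage, the fraction of the genome
quiescent in *every* cell type, pairwise state-transition matrices (per bin
or per region), and aggregated signal meta-profiles around interval classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, GenomeMismatchError

log = logging.getLogger(__name__)

ChromArrays = Tuple[np.ndarray, np.ndarray, np.ndarray]  # starts, ends, states


class StateSegmentation:
    """One cell type's genome tiling by epigenetic state.

    Segments are stored per chromosome as sorted, non-overlapping
    ``(starts, ends, states)`` arrays in 0-based half-open coordinates.
    Adjacent segments with equal state are merged on construction.
    """

    def __init__(self, cell_type: str, data: Mapping[str, ChromArrays], n_states: int):
        self.cell_type = cell_type
        self.n_states = int(n_states)
        self.data: Dict[str, ChromArrays] = {}
        for chrom in sorted(data):
            starts, ends, states = (np.asarray(a, dtype=np.int64) for a in data[chrom])
            if len(starts) == 0:
                continue
            order = np.argsort(starts, kind="mergesort")
            starts, ends, states = starts[order], ends[order], states[order]
            if (starts < 0).any():
                raise FormatError(f"{chrom}: negative coordinates")
            if (starts >= ends).any():
                raise FormatError(f"{chrom}: segment with start >= end")
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"{chrom}: overlapping segments")
            if (states < 0).any() or (states >= self.n_states).any():
                raise FormatError(f"{chrom}: state id outside [0, {self.n_states})")
            # merge adjacent same-state segments
            brk = np.ones(len(starts), dtype=bool)
            brk[1:] = (states[1:] != states[:-1]) | (starts[1:] != ends[:-1])
            block = np.cumsum(brk) - 1
            nb = block[-1] + 1
            ms = np.zeros(nb, dtype=np.int64)
            me = np.zeros(nb, dtype=np.int64)
            ms[block[brk]] = starts[brk]
            np.maximum.at(me, block, ends)
            self.data[chrom] = (ms, me, states[brk])
        self._cum: Dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ basics
    @property
    def chroms(self) -> Sequence[str]:
        return list(self.data)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: int(self.data[c][1][-1]) for c in self.data}

    @property
    def total_bases(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self.data.values()))

    def n_segments(self) -> int:
        return sum(len(s) for s, _, _ in self.data.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in self.data:
            s, e, st = self.data[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "state": st}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "state"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_type: str, n_states: Optional[int] = None) -> "StateSegmentation":
        if n_states is None:
            n_states = int(df["state"].max()) + 1 if len(df) else 1
        data = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            data[chrom] = (grp["start"].to_numpy(np.int64),
                           grp["end"].to_numpy(np.int64),
                           grp["state"].to_numpy(np.int64))
        return cls(cell_type, data, n_states)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StateSegmentation):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self.data[c], other.data[c]))
            for c in self.data
        )

    # --------------------------------------------------------- base accounting
    def _cum_states(self, chrom: str) -> np.ndarray:
        """(n_seg + 1, n_states) cumulative bases per state over segments."""
        cached = self._cum.get(chrom)
        if cached is not None:
            return cached
        s, e, st = self.data[chrom]
        per = np.zeros((len(s), self.n_states), dtype=np.int64)
        per[np.arange(len(s)), st] = e - s
        cum = np.zeros((len(s) + 1, self.n_states), dtype=np.int64)
        np.cumsum(per, axis=0, out=cum[1:])
        self._cum[chrom] = cum
        return cum

    def state_base_counts(self, chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Bases per state inside each query interval ``[a_i, b_i)``.

        Coordinates outside the segmented span contribute nothing.
        Returns an (n_query, n_states) integer matrix.
        """
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        if chrom not in self.data:
            return np.zeros((len(a), self.n_states), dtype=np.int64)
        starts, ends, states = self.data[chrom]
        cum = self._cum_states(chrom)

        def upto(x: np.ndarray) -> np.ndarray:
            j = np.searchsorted(starts, x, side="right")
            out = cum[j].astype(np.int64).copy()
            nz = j > 0
            last = j[nz] - 1
            over = np.clip(ends[last] - np.maximum(x[nz], starts[last]), 0, None)
            out[np.nonzero(nz)[0], states[last]] -= over
            return out

        return upto(b) - upto(a)

    def state_proportions(self, intervals: pd.DataFrame) -> np.ndarray:
        """Per-interval state-proportion vectors (rows sum to 1 over covered bases).

        Intervals with no covered base get a NaN row.
        """
        out = np.zeros((len(intervals), self.n_states), dtype=float)
        idx = np.arange(len(intervals))
        iv = intervals.reset_index(drop=True)
        for chrom, grp in iv.groupby("chrom", sort=False):
            counts = self.state_base_counts(chrom, grp["start"].to_numpy(), grp["end"].to_numpy())
            out[grp.index.to_numpy()] = counts
        totals = out.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out / totals[:, None]
        out[totals == 0] = np.nan
        return out

    def majority_states(self, intervals: pd.DataFrame) -> np.ndarray:
        """Majority-base state per interval; ties broken by the lowest state id."""
        props = self.state_proportions(intervals)
        bad = np.isnan(props[:, 0])
        props = np.nan_to_num(props, nan=-1.0)
        maj = props.argmax(axis=1).astype(np.int64)
        maj[bad] = -1
        return maj


# ----------------------------------------------------------------------- I/O
def read_state_bed(path, cell_type: Optional[str] = None, n_states: Optional[int] = None) -> StateSegmentation:
    """Read a 4-column BED (chrom, start, end, integer state id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "state"],
                     dtype={"chrom": str})
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["state"] = df["state"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer BED fields") from exc
    if cell_type is None:
        cell_type = str(path)
    return StateSegmentation.from_dataframe(df, cell_type, n_states)


def write_state_bed(seg: StateSegmentation, path) -> None:
    seg.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------- statistics
def state_coverage_fractions(seg: StateSegmentation) -> np.ndarray:
    """fraction[s] = bases in state s / total segmented bases."""
    total = seg.total_bases
    if total == 0:
        raise ValueError("empty segmentation")
    counts = np.zeros(seg.n_states, dtype=np.int64)
    for chrom in seg.data:
        counts += seg._cum_states(chrom)[-1]
    return counts / total


def _check_shared_genome(segs: Sequence[StateSegmentation]) -> None:
    ref = segs[0].chrom_lengths
    for seg in segs[1:]:
        if seg.chrom_lengths != ref:
            raise GenomeMismatchError(
                f"segmentations for {segs[0].cell_type!r} and {seg.cell_type!r} cover different genomes")


def quiescent_everywhere_fraction(segs: Sequence[StateSegmentation], quiescent: int = 0) -> float:
    """Fraction of the genome in the quiescent state in every cell type."""
    if not segs:
        raise ValueError("no segmentations given")
    _check_shared_genome(segs)
    total = segs[0].total_bases
    if total == 0:
        raise ValueError("empty segmentation")
    common = 0
    for chrom in segs[0].data:
        cuts = np.unique(np.concatenate(
            [np.concatenate([s.data[chrom][0], s.data[chrom][1]]) for s in segs]))
        left, right = cuts[:-1], cuts[1:]
        all_q = np.ones(len(left), dtype=bool)
        for s in segs:
            starts, ends, states = s.data[chrom]
            j = np.searchsorted(starts, left, side="right") - 1
            ok = (j >= 0) & (ends[np.clip(j, 0, None)] > left)
            st = np.where(ok, states[np.clip(j, 0, None)], -1)
            all_q &= st == quiescent
        common += int((right[all_q] - left[all_q]).sum())
    return common / total


@dataclass
class TransitionMatrix:
    """State-transition counts between two cell types over shared units."""

    from_cell: str
    to_cell: str
    counts: np.ndarray  # (n_states, n_states) non-negative ints
    unit: str  # "bins" or "regions"

    @property
    def n_units(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.counts.shape[0]
        i, j = np.nonzero(self.counts)
        return pd.DataFrame({
            "from_cell": self.from_cell, "to_cell": self.to_cell,
            "from_state": i, "to_state": j, "count": self.counts[i, j],
        })


def _tile_bins(chrom_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_lengths):
        n = int(np.ceil(chrom_lengths[chrom] / bin_size))
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, chrom_lengths[chrom])
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def transition_matrix(seg_a: StateSegmentation, seg_b: StateSegmentation,
                      regions: Optional[pd.DataFrame] = None,
                      bin_size: int = 200) -> TransitionMatrix:
    """Joint state counts between two cell types.

    With ``regions``, each region is reduced to one state per cell type by the
    majority-base rule (ties to the lowest id); otherwise the genome is tiled
    into ``bin_size`` bins and each bin is a unit.
    """
    _check_shared_genome([seg_a, seg_b])
    if regions is not None:
        lengths = seg_a.chrom_lengths
        for _, row in regions.iterrows():
            if row["chrom"] not in lengths or row["start"] < 0 or row["end"] > lengths[row["chrom"]]:
                raise GenomeMismatchError(f"region {row['chrom']}:{row['start']}-{row['end']} outside the segmented genome")
        units = regions
        unit_name = "regions"
    else:
        units = _tile_bins(seg_a.chrom_lengths, bin_size)
        unit_name = "bins"
    n = max(seg_a.n_states, seg_b.n_states)
    ma = seg_a.majority_states(units)
    mb = seg_b.majority_states(units)
    ok = (ma >= 0) & (mb >= 0)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (ma[ok], mb[ok]), 1)
    return TransitionMatrix(seg_a.cell_type, seg_b.cell_type, counts, unit_name)


# -------------------------------------------------------------- meta-profiles
SignalTrack = Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]  # chrom -> (starts, ends, values)


def _track_integral(track_chrom: Tuple[np.ndarray, np.ndarray, np.ndarray]):
    starts, ends, values = track_chrom
    seg_area = values * (ends - starts)
    cum = np.concatenate([[0.0], np.cumsum(seg_area)])

    def integral(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0, None)
        j = np.searchsorted(starts, x, side="right")
        out = cum[j].copy()
        nz = j > 0
        last = j[nz] - 1
        over = np.clip(ends[last] - np.maximum(x[nz], starts[last]), 0, None)
        out[nz] -= values[last] * over
        return out

    return integral


@dataclass
class MetaProfile:
    """Signal averaged into position bins around interval midpoints."""

    feature: str
    classes: list
    labels: np.ndarray          # per-interval class label
    matrix: np.ndarray          # (n_intervals, n_position_bins)
    window: int
    n_position_bins: int
    aggregate: Dict[object, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.aggregate:
            for c in self.classes:
                rows = self.matrix[self.labels == c]
                self.aggregate[c] = rows.mean(axis=0) if len(rows) else np.zeros(self.n_position_bins)


def meta_profile(track: SignalTrack, intervals: pd.DataFrame, labels: Sequence,
                 window: int = 2000, n_position_bins: int = 20,
                 feature: str = "signal") -> MetaProfile:
    """Average a binned signal track into position bins around interval midpoints.

    Windows are centred on interval midpoints and span ``+- window`` bases.
    Bases not covered by the track (or beyond chromosome start) read as 0;
    a warning is logged when that happens.
    """
    if n_position_bins < 1:
        raise ValueError("n_position_bins must be >= 1")
    labels = np.asarray(labels)
    iv = intervals.reset_index(drop=True)
    if len(labels) != len(iv):
        raise ValueError("one class label per interval required")
    matrix = np.zeros((len(iv), n_position_bins), dtype=float)
    edges_rel = np.linspace(-window, window, n_position_bins + 1)
    missing = False
    for chrom, grp in iv.groupby("chrom", sort=False):
        mids = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(float)
        edges = mids[:, None] + edges_rel[None, :]
        if chrom not in track:
            missing = True
            continue
        if (edges < 0).any():
            missing = True
        integral = _track_integral(track[chrom])
        flat = integral(edges.reshape(-1)).reshape(edges.shape)
        widths = np.diff(edges, axis=1)
        matrix[grp.index.to_numpy()] = np.diff(flat, axis=1) / widths
    if missing:
        log.warning("meta_profile: some windows extend beyond the signal track; missing signal read as 0")
    classes = list(dict.fromkeys(labels.tolist()))
    return MetaProfile(feature=feature, classes=classes, labels=labels,
                       matrix=matrix, window=window, n_position_bins=n_position_bins)
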