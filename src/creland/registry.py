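"""Candidate cis-regulatory element (cCRE) registry construction.

A cCRE is a genomic interval with reproducible nuclease accessibility in at
least one cell type that is not majority-quiescent in every cell type.
Registry construction merges reproducible peaks across cell types into
maximal intervals, annotates each interval with its per-cell-type state
proportions and majority state, applies the all-quiescent removal rule, and
records which cell types contributed a reproducible peak (peak support).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GenomeMismatchError
from .intervals import as_intervals, intersect_all, merge_intervals, overlaps_any
from .landscape import StateSegmentation

log = logging.getLogger(__name__)


def reproducible_peaks(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Reproducible peak set for one cell type.

    With one replicate the peaks are taken as-is (merged); with several, the
    base-level intersection across all replicates is returned as maximal
    intervals.  An empty result is valid.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate of peak calls is required")
    if len(replicates) == 1:
        return merge_intervals(replicates[0])
    return intersect_all(list(replicates))


@dataclass
class CcreRegistry:
    """Merged cCRE intervals with per-cell-type annotation.

    ``proportions`` has shape (n_ccres, n_cell_types, n_states); each
    proportion vector sums to 1 over the element's covered bases.
    """

    ccres: pd.DataFrame                # id, chrom, start, end
    cell_types: List[str]
    n_states: int
    quiescent: int
    proportions: np.ndarray            # (n, T, S)
    majority_state: np.ndarray         # (n, T) int
    peak_support: np.ndarray           # (n, T) bool
    active: np.ndarray = field(init=False)  # (n, T) bool

    def __post_init__(self):
        self.active = self.majority_state != self.quiescent

    def __len__(self) -> int:
        return len(self.ccres)

    def cell_index(self, cell_type: str) -> int:
        return self.cell_types.index(cell_type)

    def intervals(self) -> pd.DataFrame:
        return self.ccres[["chrom", "start", "end"]]

    # -------------------------------------------------------------- summaries
    def active_ccre_counts(self) -> Tuple[pd.Series, pd.DataFrame]:
        """(total active per cell type, per-state counts per cell type).

        The per-state table counts every majority state including quiescent;
        the totals exclude the quiescent state.
        """
        per_state = np.zeros((len(self.cell_types), self.n_states), dtype=np.int64)
        for t in range(len(self.cell_types)):
            np.add.at(per_state[t], self.majority_state[:, t], 1)
        frame = pd.DataFrame(per_state, index=self.cell_types,
                             columns=[f"state_{s}" for s in range(self.n_states)])
        totals = pd.Series(self.active.sum(axis=0), index=self.cell_types, name="active_ccres")
        return totals, frame

    def dynamic_ccre_counts(self) -> pd.Series:
        """Number of cCREs with reproducible peak support per cell type."""
        return pd.Series(self.peak_support.sum(axis=0), index=self.cell_types, name="dynamic_ccres")

    # ------------------------------------------------------------------- I/O
    def to_bed(self) -> pd.DataFrame:
        return self.ccres[["chrom", "start", "end", "id"]]

    def annotation_frame(self) -> pd.DataFrame:
        rows = []
        for t, ct in enumerate(self.cell_types):
            rows.append(pd.DataFrame({
                "id": self.ccres["id"],
                "cell_type": ct,
                "majority_state": self.majority_state[:, t],
                "active": self.active[:, t],
                "peak_support": self.peak_support[:, t],
                "proportions": [",".join(f"{p:.6g}" for p in v) for v in self.proportions[:, t, :]],
            }))
        return pd.concat(rows, ignore_index=True)


def annotate_intervals(intervals: pd.DataFrame,
                       segmentations: Mapping[str, StateSegmentation]) -> Tuple[np.ndarray, np.ndarray]:
    """State proportions and majority states of intervals in every cell type."""
    cell_types = list(segmentations)
    n_states = max(s.n_states for s in segmentations.values())
    props = np.zeros((len(intervals), len(cell_types), n_states), dtype=float)
    maj = np.zeros((len(intervals), len(cell_types)), dtype=np.int64)
    for t, ct in enumerate(cell_types):
        seg = segmentations[ct]
        p = seg.state_proportions(intervals)
        if p.shape[1] < n_states:
            p = np.pad(p, ((0, 0), (0, n_states - p.shape[1])))
        props[:, t, :] = p
        maj[:, t] = seg.majority_states(intervals)
    return props, maj


def build_registry(peaks_by_cell_type: Mapping[str, pd.DataFrame],
                   segmentations: Mapping[str, StateSegmentation],
                   quiescent: int = 0,
                   reproducible: bool = False) -> CcreRegistry:
    """Build the cCRE registry from reproducible peaks and state maps.

    ``peaks_by_cell_type`` maps cell type -> reproducible peak intervals
    (pass ``reproducible=False`` when replicate filtering already happened;
    with ``reproducible=True`` the values are lists of replicate frames fed
    through :func:`reproducible_peaks` first).  Cell types present in
    ``segmentations`` but absent from the peak mapping contribute no peaks
    yet are still annotated.
    """
    cell_types = list(segmentations)
    if reproducible:
        peaks = {ct: reproducible_peaks(reps) for ct, reps in peaks_by_cell_type.items()}
    else:
        peaks = {ct: merge_intervals(df) for ct, df in peaks_by_cell_type.items()}
    unknown = set(peaks) - set(cell_types)
    if unknown:
        raise ValueError(f"peaks given for cell types without segmentations: {sorted(unknown)}")

    frames = [df for df in peaks.values() if len(df)]
    if frames:
        merged = merge_intervals(pd.concat(frames, ignore_index=True))
    else:
        merged = as_intervals(None)

    # peaks must lie inside the segmented genome
    lengths = segmentations[cell_types[0]].chrom_lengths
    for chrom, grp in merged.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise GenomeMismatchError(f"peak on unsegmented chromosome {chrom!r}")
        if int(grp["end"].max()) > lengths[chrom]:
            raise GenomeMismatchError(f"peak beyond the segmented end of {chrom!r}")

    props, maj = annotate_intervals(merged, segmentations)
    n_states = props.shape[2]

    keep = (maj != quiescent).any(axis=1) if len(merged) else np.zeros(0, dtype=bool)
    dropped = int(len(merged) - keep.sum())
    if dropped:
        log.info("build_registry: removed %d merged peaks quiescent in all cell types", dropped)
    merged = merged[keep].reset_index(drop=True)
    props, maj = props[keep], maj[keep]

    support = np.zeros((len(merged), len(cell_types)), dtype=bool)
    for t, ct in enumerate(cell_types):
        if ct in peaks and len(peaks[ct]):
            support[:, t] = overlaps_any(merged, peaks[ct])

    ccres = merged.copy()
    width = max(6, len(str(max(len(ccres), 1))))
    ccres.insert(0, "id", [f"cCRE_{i + 1:0{width}d}" for i in range(len(ccres))])
    return CcreRegistry(ccres=ccres, cell_types=cell_types, n_states=n_states,
                        quiescent=quiescent, proportions=props,
                        majority_state=maj, peak_support=support)


def read_registry(bed_path, annotation_path, quiescent: int = 0) -> CcreRegistry:
    """Reconstruct a registry from its exported BED + annotation TSV."""
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "id"], dtype={"chrom": str})
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"cell_type": str})
    cell_types = list(dict.fromkeys(annot["cell_type"]))
    id_order = {cid: i for i, cid in enumerate(bed["id"])}
    n = len(bed)
    first = annot[annot["cell_type"] == cell_types[0]]
    n_states = len(str(first["proportions"].iloc[0]).split(",")) if len(first) else 1
    props = np.zeros((n, len(cell_types), n_states), dtype=float)
    maj = np.zeros((n, len(cell_types)), dtype=np.int64)
    support = np.zeros((n, len(cell_types)), dtype=bool)
    for t, ct in enumerate(cell_types):
        grp = annot[annot["cell_type"] == ct]
        rows = grp["id"].map(id_order).to_numpy()
        props[rows, t, :] = np.array([np.fromstring(s, sep=",") for s in grp["proportions"]])
        maj[rows, t] = grp["majority_state"].to_numpy()
        support[rows, t] = grp["peak_support"].to_numpy(dtype=bool)
    ccres = bed[["id", "chrom", "start", "end"]]
    return CcreRegistry(ccres=ccres, cell_types=cell_types, n_states=n_states,
                        quiescent=quiescent, proportions=props,
                        majority_state=maj, peak_support=support)


# ------------------------------------------------------------ set comparisons
@dataclass
class OverlapPartition:
    """UpSet-style partition of merged elements by catalog membership."""

    set_names: List[str]
    counts: Dict[Tuple[str, ...], int]
    totals: Dict[str, int]

    @property
    def n_elements(self) -> int:
        return sum(self.counts.values())


def catalog_overlap(catalogs: Mapping[str, pd.DataFrame]) -> OverlapPartition:
    """Merge the union of all catalogs and partition elements by membership."""
    names = list(catalogs)
    if len(names) < 2:
        raise ValueError("catalog_overlap needs at least two catalogs")
    frames = [df for df in catalogs.values() if df is not None and len(df)]
    if not frames:
        return OverlapPartition(names, {}, {n: 0 for n in names})
    # base-level merge: book-ended intervals from different catalogs fuse
    merged = merge_intervals(pd.concat(frames, ignore_index=True), touching=True)
    member = {name: overlaps_any(merged, catalogs[name]) for name in names}
    counts: Dict[Tuple[str, ...], int] = {}
    patterns = np.stack([member[n] for n in names], axis=1)
    for row in patterns:
        key = tuple(n for n, hit in zip(names, row) if hit)
        counts[key] = counts.get(key, 0) + 1
    totals = {n: int(member[n].sum()) for n in names}
    return OverlapPartition(names, counts, totals)


def capture_curve(catalog: pd.DataFrame, known_elements: pd.DataFrame) -> Tuple[int, int]:
    """(number of catalog intervals, number of known elements captured).

    A known element is captured when it overlaps >= 1 catalog interval by
    >= 1 base.
    """
    known = as_intervals(known_elements)
    captured = int(overlaps_any(known, catalog).sum()) if len(known) else 0
    return len(catalog), captured
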