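"""Synthetic data with known ground truth for the full pipeline.

The generator emulates the inputs an integrative hematopoiesis analysis
consumes: lineage-correlated chromatin-state maps over a tree of cell types
with a dominant quiescent state, accessibility peaks arising in open states
with replicate dropout and endpoint jitter, per-feature signal tracks drawn
from state emission means, and gene expression produced by a linear model
over promoter and pooled-cCRE state proportions with known coefficients and
known cCRE-gene links.  Everything is deterministic given the seed.

Model of the state maps: the root cell type follows a first-order Markov
chain along each chromosome that repeats the previous bin's state with
probability ``markov_persistence`` and otherwise redraws from a stationary
distribution placing ``quiescent_target`` mass on state 0; every other cell
type copies its parent's state per bin with probability ``inherit_prob`` and
otherwise redraws from the same stationary distribution, so the marginal
state distribution is identical in every cell type while local and lineage
correlation are controlled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import states as default_states
from .errors import ConfigError
from .intervals import merge_intervals, midpoints
from .io import (config_hash, write_bed3, write_bedgraph, write_expression_tsv,
                 write_gene_tsv, write_manifest, write_tsv)
from .landscape import StateSegmentation
from .registry import annotate_intervals


# --------------------------------------------------------------------- config
def default_lineage_tree(n: int) -> List[Optional[int]]:
    """A balanced binary tree: cell type 0 is the root (stem-like) population."""
    return [None] + [(i - 1) // 2 for i in range(1, n)]


@dataclass
class SimConfig:
    """All knobs of the synthetic dataset; defaults mirror the study conditions.

    20 cell types on a hematopoiesis-like lineage tree, 27 epigenetic states
    with quiescent state 0 occupying 86% of the genome, 200-base bins, and an
    expression model over promoter and pooled-cCRE state proportions.
    """

    n_cell_types: int = 20
    lineage_tree: Optional[List[Optional[int]]] = None
    n_states: int = default_states.N_STATES
    bin_size: int = 200
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000, "chr3": 4_000_000})
    quiescent_target: float = 0.86
    inherit_prob: float = 0.8
    markov_persistence: float = 0.9
    accessible_states: FrozenSet[int] = default_states.ACCESSIBLE_STATES
    peak_dropout: float = 0.1
    peak_jitter: int = 1          # max endpoint jitter in bins (0 disables)
    n_replicates: int = 2
    feature_names: Tuple[str, ...] = default_states.FEATURES
    emission_means: np.ndarray = field(default_factory=lambda: default_states.EMISSION_MEANS.copy())
    signal_noise_sd: float = 0.5
    n_genes: int = 2000
    links_per_gene: int = 5
    max_link_distance: int = 1_000_000
    promoter_window: int = 1000
    beta_promoter_truth: np.ndarray = field(default_factory=lambda: default_states.BETA_PROMOTER.copy())
    beta_ccre_truth: np.ndarray = field(default_factory=lambda: default_states.BETA_CCRE.copy())
    expression_intercept: float = 2.0
    expression_noise_sd: float = 0.1
    signal_features: Tuple[str, ...] = ("atac",)
    seed: int = 0

    def __post_init__(self):
        if self.lineage_tree is None:
            self.lineage_tree = default_lineage_tree(self.n_cell_types)
        self.accessible_states = frozenset(self.accessible_states)
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.beta_promoter_truth = np.asarray(self.beta_promoter_truth, dtype=float)
        self.beta_ccre_truth = np.asarray(self.beta_ccre_truth, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_cell_types < 1:
            raise ConfigError("n_cell_types must be >= 1")
        if len(self.lineage_tree) != self.n_cell_types:
            raise ConfigError("lineage_tree must have one entry per cell type")
        roots = [i for i, p in enumerate(self.lineage_tree) if p is None]
        if len(roots) != 1:
            raise ConfigError("lineage_tree must have exactly one root")
        # acyclicity: walking to the root must terminate for every node
        for i in range(self.n_cell_types):
            seen, node = set(), i
            while node is not None:
                if node in seen:
                    raise ConfigError("lineage_tree contains a cycle")
                seen.add(node)
                parent = self.lineage_tree[node]
                if parent is not None and not (0 <= parent < self.n_cell_types):
                    raise ConfigError("lineage_tree parent index out of range")
                node = parent
        if not 0.0 <= self.quiescent_target <= 1.0:
            raise ConfigError("quiescent_target must be in [0, 1]")
        if not 0.0 <= self.inherit_prob <= 1.0 or not 0.0 <= self.markov_persistence <= 1.0:
            raise ConfigError("probabilities must be in [0, 1]")
        if self.n_states < 1:
            raise ConfigError("n_states must be >= 1")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        if 0 in self.accessible_states:
            raise ConfigError("the quiescent state 0 cannot be accessible")
        if any(not 0 < s < self.n_states for s in self.accessible_states):
            raise ConfigError("accessible_states must be non-quiescent state ids")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.signal_noise_sd < 0 or self.expression_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        for name, beta in (("beta_promoter_truth", self.beta_promoter_truth),
                           ("beta_ccre_truth", self.beta_ccre_truth)):
            if beta.shape != (self.n_states,):
                raise ConfigError(f"{name} must have length n_states")
            if beta[0] != 0.0:
                raise ConfigError(f"{name}[0] must be 0 (quiescent reference)")
        if self.emission_means.shape != (self.n_states, len(self.feature_names)):
            raise ConfigError("emission_means must be n_states x n_features")
        if not set(self.signal_features) <= set(self.feature_names):
            raise ConfigError("signal_features must be a subset of feature_names")

    @property
    def cell_types(self) -> List[str]:
        return [f"ct{i:02d}" for i in range(self.n_cell_types)]

    @property
    def stationary(self) -> np.ndarray:
        if self.n_states == 1:
            return np.array([1.0])
        pi = np.full(self.n_states, (1.0 - self.quiescent_target) / (self.n_states - 1))
        pi[0] = self.quiescent_target
        return pi

    def n_bins(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.bin_size

    def topological_order(self) -> List[int]:
        order, placed = [], set()
        pending = list(range(self.n_cell_types))
        while pending:
            for i in list(pending):
                p = self.lineage_tree[i]
                if p is None or p in placed:
                    order.append(i)
                    placed.add(i)
                    pending.remove(i)
        return order

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accessible_states"] = sorted(self.accessible_states)
        d["emission_means"] = self.emission_means.tolist()
        d["beta_promoter_truth"] = self.beta_promoter_truth.tolist()
        d["beta_ccre_truth"] = self.beta_ccre_truth.tolist()
        return d


# ---------------------------------------------------------------------- truth
@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset (known links and coefficients)."""

    config: SimConfig
    bin_states: Dict[str, Dict[str, np.ndarray]]            # ct -> chrom -> per-bin state
    state_maps: Dict[str, StateSegmentation]
    true_accessibility: Dict[str, pd.DataFrame] = field(default_factory=dict)
    peaks: Dict[str, List[pd.DataFrame]] = field(default_factory=dict)
    true_ccres: Optional[pd.DataFrame] = None               # merged across cell types
    ccre_proportions: Optional[np.ndarray] = None           # (n, T, S)
    ccre_majority: Optional[np.ndarray] = None              # (n, T)
    genes: Optional[pd.DataFrame] = None                    # gene, chrom, tss, strand, n_links
    true_links: Optional[pd.DataFrame] = None               # gene_idx, ccre_idx
    prom_proportions: Optional[np.ndarray] = None           # (G, T, S)
    noiseless_log2: Optional[pd.DataFrame] = None
    expression_log2: Optional[pd.DataFrame] = None
    tpm: Optional[pd.DataFrame] = None

    @property
    def cell_types(self) -> List[str]:
        return self.config.cell_types


# ------------------------------------------------------------------ state maps
def _markov_chain(rng: np.random.Generator, n: int, pi: np.ndarray, persistence: float) -> np.ndarray:
    """Vectorised chain: repeat the previous state w.p. ``persistence`` else redraw from pi."""
    if n == 0:
        return np.zeros(0, dtype=np.int16)
    draws = rng.choice(len(pi), size=n, p=pi).astype(np.int16)
    keep = rng.random(n) < persistence
    keep[0] = False
    idx = np.where(~keep, np.arange(n), -1)
    last_draw = np.maximum.accumulate(idx)
    return draws[last_draw]


def simulate_state_maps(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Generate per-cell-type state maps tiling the genome in ``bin_size`` bins."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pi = config.stationary
    order = config.topological_order()
    cts = config.cell_types
    bin_states: Dict[str, Dict[str, np.ndarray]] = {ct: {} for ct in cts}
    for chrom in sorted(config.chrom_lengths):
        n = config.n_bins(chrom)
        per_ct: Dict[int, np.ndarray] = {}
        for i in order:
            parent = config.lineage_tree[i]
            if parent is None:
                per_ct[i] = _markov_chain(rng, n, pi, config.markov_persistence)
            else:
                redraw = rng.choice(config.n_states, size=n, p=pi).astype(np.int16)
                copy = rng.random(n) < config.inherit_prob
                per_ct[i] = np.where(copy, per_ct[parent], redraw)
        for i in order:
            bin_states[cts[i]][chrom] = per_ct[i]

    state_maps = {ct: _bins_to_segmentation(ct, bin_states[ct], config) for ct in cts}
    return SimTruth(config=config, bin_states=bin_states, state_maps=state_maps)


def _bins_to_segmentation(cell_type: str, chrom_bins: Mapping[str, np.ndarray],
                          config: SimConfig) -> StateSegmentation:
    data = {}
    for chrom, states in chrom_bins.items():
        n = len(states)
        if n == 0:
            continue
        brk = np.ones(n, dtype=bool)
        brk[1:] = states[1:] != states[:-1]
        starts = np.where(brk)[0] * config.bin_size
        ends = np.append(starts[1:], n * config.bin_size)
        data[chrom] = (starts.astype(np.int64), ends.astype(np.int64),
                       states[brk].astype(np.int64))
    return StateSegmentation(cell_type, data, config.n_states)


def _accessible_runs(states: np.ndarray, accessible: FrozenSet[int], bin_size: int) -> Tuple[np.ndarray, np.ndarray]:
    mask = np.isin(states, list(accessible)) if accessible else np.zeros(len(states), dtype=bool)
    if not mask.any():
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.where(d == 1)[0] * bin_size
    ends = np.where(d == -1)[0] * bin_size
    return starts.astype(np.int64), ends.astype(np.int64)


def true_accessible_intervals(truth: SimTruth) -> Dict[str, pd.DataFrame]:
    """Maximal runs of accessible-state bins, per cell type."""
    config = truth.config
    out = {}
    for ct in truth.cell_types:
        rows = []
        for chrom in sorted(config.chrom_lengths):
            s, e = _accessible_runs(truth.bin_states[ct][chrom], config.accessible_states,
                                    config.bin_size)
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        out[ct] = (pd.concat(rows, ignore_index=True) if rows else
                   pd.DataFrame(columns=["chrom", "start", "end"]))
    truth.true_accessibility = out
    return out


# --------------------------------------------------------------------- peaks
def simulate_peaks(truth: SimTruth, config: Optional[SimConfig] = None,
                   rng: Optional[np.random.Generator] = None) -> Dict[str, List[pd.DataFrame]]:
    """Replicate peak calls: per-interval Bernoulli dropout + endpoint jitter."""
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if not truth.true_accessibility:
        true_accessible_intervals(truth)
    peaks: Dict[str, List[pd.DataFrame]] = {}
    for ct in truth.cell_types:
        intervals = truth.true_accessibility[ct]
        reps = []
        for _ in range(config.n_replicates):
            if len(intervals) == 0:
                reps.append(intervals.copy())
                continue
            kept = intervals[rng.random(len(intervals)) >= config.peak_dropout].copy()
            if config.peak_jitter > 0 and len(kept):
                j = config.peak_jitter
                ds = rng.integers(-j, j + 1, size=len(kept)) * config.bin_size
                de = rng.integers(-j, j + 1, size=len(kept)) * config.bin_size
                # clip to the segmented span (whole bins only)
                seg_end = {c: config.n_bins(c) * config.bin_size for c in config.chrom_lengths}
                lengths = kept["chrom"].map(seg_end).to_numpy()
                start = np.clip(kept["start"].to_numpy() + ds, 0, None)
                end = np.minimum(kept["end"].to_numpy() + de, lengths)
                bad = start >= end
                start[bad] = kept["start"].to_numpy()[bad]
                end[bad] = kept["end"].to_numpy()[bad]
                kept["start"], kept["end"] = start, end
            reps.append(kept.reset_index(drop=True))
        peaks[ct] = reps
    truth.peaks = peaks
    return peaks


# ----------------------------------------------------------------- expression
def _place_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if config.n_genes == 0 or lengths.sum() == 0:
        return pd.DataFrame(columns=["gene", "chrom", "tss", "strand"])
    share = lengths / lengths.sum() * config.n_genes
    counts = np.floor(share).astype(int)
    rem = config.n_genes - counts.sum()
    if rem > 0:
        frac_order = np.argsort(-(share - counts), kind="mergesort")
        counts[frac_order[:rem]] += 1
    rows = []
    for chrom, cnt in zip(chroms, counts):
        span = config.n_bins(chrom) * config.bin_size  # segmented span only
        tss = np.sort(rng.integers(0, max(span, 1), size=cnt))
        strand = np.where(rng.random(cnt) < 0.5, "+", "-")
        rows.append(pd.DataFrame({"chrom": chrom, "tss": tss, "strand": strand}))
    genes = pd.concat(rows, ignore_index=True)
    genes.insert(0, "gene", [f"g{i + 1:05d}" for i in range(len(genes))])
    return genes


def _draw_links(genes: pd.DataFrame, ccres: pd.DataFrame, config: SimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    mids = midpoints(ccres)
    rows = []
    by_chrom = {c: g.index.to_numpy() for c, g in ccres.groupby("chrom", sort=False)}
    for gi, row in genes.iterrows():
        idx = by_chrom.get(row["chrom"])
        if idx is None:
            continue
        dist = np.abs(mids[idx] - row["tss"])
        cands = idx[dist <= config.max_link_distance]
        if len(cands) == 0:
            continue
        take = min(config.links_per_gene, len(cands))
        chosen = rng.choice(cands, size=take, replace=False)
        rows.append(pd.DataFrame({"gene_idx": gi, "ccre_idx": np.sort(chosen)}))
    if not rows:
        return pd.DataFrame(columns=["gene_idx", "ccre_idx"], dtype=np.int64)
    return pd.concat(rows, ignore_index=True)


def promoter_proportions(genes: pd.DataFrame, state_maps: Mapping[str, StateSegmentation],
                         window: int) -> np.ndarray:
    """(n_genes, n_cell_types, n_states) state proportions of TSS +- window."""
    prom = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.clip(genes["tss"] - window, 0, None),
        "end": genes["tss"] + window,
    })
    props, _ = annotate_intervals(prom, state_maps)
    return props


def simulate_expression(truth: SimTruth, config: Optional[SimConfig] = None,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Expression from the linear model over promoter/pooled-cCRE proportions.

    Returns the observed log2(TPM + 1)-scale matrix and fills the truth
    object with genes, links, proportions, noiseless values and the TPM
    export (2**x - 1, floored at 0).
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if not truth.true_accessibility:
        true_accessible_intervals(truth)

    frames = [df for df in truth.true_accessibility.values() if len(df)]
    ccres = (merge_intervals(pd.concat(frames, ignore_index=True)) if frames
             else pd.DataFrame(columns=["chrom", "start", "end"]))
    props, maj = annotate_intervals(ccres, truth.state_maps)
    truth.true_ccres, truth.ccre_proportions, truth.ccre_majority = ccres, props, maj

    genes = _place_genes(config, rng)
    links = _draw_links(genes, ccres, config, rng)
    n_links = np.zeros(len(genes), dtype=np.int64)
    if len(links):
        np.add.at(n_links, links["gene_idx"].to_numpy(), 1)
    genes["n_links"] = n_links
    truth.genes, truth.true_links = genes, links

    T, S = config.n_cell_types, config.n_states
    prom = promoter_proportions(genes, truth.state_maps, config.promoter_window)
    prom = np.nan_to_num(prom, nan=0.0)
    truth.prom_proportions = prom

    pooled = np.zeros((len(genes), T, S), dtype=float)
    if len(links):
        np.add.at(pooled, links["gene_idx"].to_numpy(), props[links["ccre_idx"].to_numpy()])
        nz = n_links > 0
        pooled[nz] /= n_links[nz, None, None]

    noiseless = (config.expression_intercept
                 + prom @ config.beta_promoter_truth
                 + pooled @ config.beta_ccre_truth)
    observed = noiseless + rng.normal(0.0, config.expression_noise_sd, size=noiseless.shape) \
        if config.expression_noise_sd > 0 else noiseless.copy()

    cts = config.cell_types
    truth.noiseless_log2 = pd.DataFrame(noiseless, index=genes["gene"], columns=cts)
    truth.expression_log2 = pd.DataFrame(observed, index=genes["gene"], columns=cts)
    truth.tpm = pd.DataFrame(np.clip(2.0 ** observed - 1.0, 0.0, None),
                             index=genes["gene"], columns=cts)
    return truth.expression_log2


# -------------------------------------------------------------------- signals
def simulate_signal_tracks(truth: SimTruth, config: Optional[SimConfig] = None,
                           features: Optional[Sequence[str]] = None,
                           rng: Optional[np.random.Generator] = None):
    """Per-cell-type, per-feature binned tracks: emission mean + truncated noise."""
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    features = list(features if features is not None else config.signal_features)
    fidx = {f: i for i, f in enumerate(config.feature_names)}
    missing = [f for f in features if f not in fidx]
    if missing:
        raise ConfigError(f"no emission means for features: {missing}")
    tracks: Dict[str, Dict[str, dict]] = {}
    for ct in truth.cell_types:
        tracks[ct] = {}
        for f in features:
            track = {}
            for chrom in sorted(config.chrom_lengths):
                states = truth.bin_states[ct][chrom]
                n = len(states)
                means = config.emission_means[states, fidx[f]]
                if config.signal_noise_sd > 0:
                    values = means + rng.normal(0.0, config.signal_noise_sd, size=n)
                else:
                    values = means.astype(float).copy()
                np.clip(values, 0.0, None, out=values)
                starts = np.arange(n, dtype=np.int64) * config.bin_size
                track[chrom] = (starts, starts + config.bin_size, values)
            tracks[ct][f] = track
    return tracks


# ------------------------------------------------------------------ orchestra
def simulate_dataset(config: SimConfig, signals: bool = False) -> SimTruth:
    """Run every generator stage in order with one seed."""
    truth = simulate_state_maps(config)
    true_accessible_intervals(truth)
    simulate_peaks(truth)
    simulate_expression(truth)
    if signals:
        truth.signal_tracks = simulate_signal_tracks(truth)  # type: ignore[attr-defined]
    return truth


def write_fixture_bundle(truth: SimTruth, out_dir, signals: bool = True) -> Path:
    """Write every simulated artifact plus a checksum manifest.

    Rerunning with the same config (including seed) reproduces byte-identical
    files; the manifest records the seed and a hash of the configuration.
    """
    config = truth.config
    out = Path(out_dir)
    files: List[Path] = []

    def reg(path: Path) -> Path:
        files.append(path)
        return path

    (out / "states").mkdir(parents=True, exist_ok=True)
    for ct, seg in truth.state_maps.items():
        seg.to_dataframe().to_csv(reg(out / "states" / f"{ct}.state.bed"),
                                  sep="\t", header=False, index=False)
    (out / "peaks").mkdir(exist_ok=True)
    for ct, reps in truth.peaks.items():
        for k, rep in enumerate(reps, start=1):
            write_bed3(rep, reg(out / "peaks" / f"{ct}.rep{k}.bed"))
    if signals and truth.bin_states:
        (out / "signals").mkdir(exist_ok=True)
        tracks = simulate_signal_tracks(truth)
        for ct, by_feature in tracks.items():
            for f, track in by_feature.items():
                write_bedgraph(track, reg(out / "signals" / f"{ct}.{f}.bedgraph"))
    if truth.tpm is not None:
        write_expression_tsv(truth.tpm, reg(out / "expression_tpm.tsv"))
        write_expression_tsv(truth.expression_log2, reg(out / "expression_log2.tsv"))
        write_gene_tsv(truth.genes, reg(out / "genes.tsv"))
        (out / "truth").mkdir(exist_ok=True)
        write_bed3(truth.true_ccres, reg(out / "truth" / "true_ccres.bed"))
        write_tsv(truth.true_links, reg(out / "truth" / "links.tsv"))
        betas = pd.DataFrame({"state": np.arange(config.n_states),
                              "beta_promoter": config.beta_promoter_truth,
                              "beta_ccre": config.beta_ccre_truth})
        write_tsv(betas, reg(out / "truth" / "betas.tsv"))
        write_expression_tsv(truth.noiseless_log2, reg(out / "truth" / "noiseless_log2.tsv"))
    return write_manifest(out, files, extra={
        "seed": str(config.seed),
        "config": config_hash(config.to_dict()),
    })
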