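"""Epigenetic regulatory potential (eRP) regression.

Gene expression on the log2(TPM + 1) scale is modelled as a linear function
of chromatin-state proportions in two contexts: the promoter window around
the TSS and the unweighted mean over a gene's candidate distal cCREs
("pooled" proportions).  State proportions sum to 1 per context, so one
state (the quiescent state, by default) is the reference with coefficient 0
and its column is dropped for identifiability alongside the intercept.

The eRP score of a cCRE in a cell type is the cCRE-context coefficient
vector dotted with the element's state-proportion vector; because pooling is
an unweighted mean, predicting a gene from the mean of its paired cCREs'
eRP scores is algebraically identical to predicting from the pooled design
row.

Candidate cCRE-gene pairs within 1 Mb of the TSS are screened by
correlation with the gene's expression and then pruned by an iterative
subselection during model fitting; the surviving pairs define the final
model and the exportable cCRE-target-gene table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse

from .landscape import StateSegmentation
from .registry import CcreRegistry
from .simulate import SimTruth, promoter_proportions

log = logging.getLogger(__name__)

CATEGORIES = ("consistently_low", "differentially_low", "differentially_high", "consistently_high")
MODES = ("promoter", "ccre", "both")


# ---------------------------------------------------------------- gene labels
def categorize_genes(tpm: pd.DataFrame, low_threshold: float = 1.0,
                     variability_threshold: float = 1.0) -> pd.Series:
    """Assign each gene to one of four expression categories.

    A gene is expressed in a cell type when TPM strictly exceeds
    ``low_threshold``.  Genes expressed nowhere are consistently low; genes
    expressed everywhere are consistently or differentially high depending
    on whether their log2(TPM + 1) spread is below ``variability_threshold``;
    everything else (expressed somewhere but not everywhere) is
    differentially low.
    """
    if tpm.shape[0] == 0 or tpm.shape[1] == 0:
        raise ValueError("empty expression matrix")
    expressed = tpm > low_threshold
    n_expr = expressed.sum(axis=1)
    log2 = np.log2(tpm + 1.0)
    spread = log2.max(axis=1) - log2.min(axis=1)
    out = pd.Series("differentially_low", index=tpm.index, name="category")
    out[n_expr == 0] = "consistently_low"
    everywhere = n_expr == tpm.shape[1]
    out[everywhere & (spread < variability_threshold)] = "consistently_high"
    out[everywhere & (spread >= variability_threshold)] = "differentially_high"
    return out


# -------------------------------------------------------------------- dataset
@dataclass
class ErpDataset:
    """Everything the regression needs, aligned on integer indices.

    ``pairs`` carries one row per candidate (gene, cCRE) pair with columns
    ``gene_idx``, ``ccre_idx``, ``distance``, ``screen_r`` and ``selected``.
    """

    genes: pd.DataFrame                 # gene, chrom, tss, strand [, category]
    expr_log2: np.ndarray               # (G, T)
    cell_types: List[str]
    ccres: pd.DataFrame                 # chrom, start, end [, id]
    proportions: np.ndarray             # (n_ccre, T, S)
    majority: np.ndarray                # (n_ccre, T)
    prom_proportions: np.ndarray        # (G, T, S)
    pairs: pd.DataFrame
    n_states: int
    reference_state: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def restrict_cell_types(self, keep: Sequence[int]) -> "ErpDataset":
        keep = list(keep)
        return replace(self,
                       expr_log2=self.expr_log2[:, keep],
                       cell_types=[self.cell_types[i] for i in keep],
                       proportions=self.proportions[:, keep, :],
                       majority=self.majority[:, keep],
                       prom_proportions=self.prom_proportions[:, keep, :],
                       pairs=self.pairs.copy())

    def tpm(self) -> pd.DataFrame:
        return pd.DataFrame(np.clip(2.0 ** self.expr_log2 - 1.0, 0.0, None),
                            index=self.genes["gene"], columns=self.cell_types)


def assign_candidates(genes: pd.DataFrame, ccres: pd.DataFrame,
                      max_distance: int = 1_000_000,
                      promoter_window: int = 1000) -> pd.DataFrame:
    """All (gene, cCRE) pairs with midpoint within ``max_distance`` of the TSS.

    Pairs on different chromosomes are excluded, the distance bound is
    inclusive, and cCREs overlapping the promoter window are excluded from
    the distal candidate set.
    """
    mids = ((ccres["start"].to_numpy() + ccres["end"].to_numpy()) // 2).astype(np.int64)
    by_chrom = {c: g.index.to_numpy() for c, g in ccres.groupby("chrom", sort=False)}
    rows = []
    for gi, row in genes.iterrows():
        idx = by_chrom.get(row["chrom"])
        if idx is None:
            continue
        tss = int(row["tss"])
        dist = np.abs(mids[idx] - tss)
        near = dist <= max_distance
        s = ccres["start"].to_numpy()[idx]
        e = ccres["end"].to_numpy()[idx]
        in_promoter = (s < tss + promoter_window) & (e > tss - promoter_window)
        take = near & ~in_promoter
        if take.any():
            rows.append(pd.DataFrame({"gene_idx": gi, "ccre_idx": idx[take],
                                      "distance": dist[take]}))
    if not rows:
        pairs = pd.DataFrame(columns=["gene_idx", "ccre_idx", "distance"]).astype(np.int64)
    else:
        pairs = pd.concat(rows, ignore_index=True)
    pairs["screen_r"] = np.nan
    pairs["selected"] = True
    return pairs


def dataset_from_truth(truth: SimTruth) -> ErpDataset:
    """Build a modelling dataset directly from generator ground truth.

    The candidate pairs are exactly the true links (all selected), which
    makes the dataset the oracle route for recovery tests.
    """
    pairs = truth.true_links.copy()
    mids = ((truth.true_ccres["start"].to_numpy() + truth.true_ccres["end"].to_numpy()) // 2)
    tss = truth.genes["tss"].to_numpy()
    pairs["distance"] = np.abs(mids[pairs["ccre_idx"].to_numpy()] - tss[pairs["gene_idx"].to_numpy()])
    pairs["screen_r"] = np.nan
    pairs["selected"] = True
    return ErpDataset(
        genes=truth.genes.copy(),
        expr_log2=truth.expression_log2.to_numpy(),
        cell_types=list(truth.cell_types),
        ccres=truth.true_ccres.copy(),
        proportions=truth.ccre_proportions,
        majority=truth.ccre_majority,
        prom_proportions=truth.prom_proportions,
        pairs=pairs,
        n_states=truth.config.n_states,
    )


def dataset_from_registry(registry: CcreRegistry, genes: pd.DataFrame,
                          tpm: pd.DataFrame,
                          segmentations: Mapping[str, StateSegmentation],
                          max_distance: int = 1_000_000,
                          promoter_window: int = 1000) -> ErpDataset:
    """Build a modelling dataset from a cCRE registry and a TPM matrix."""
    cell_types = [ct for ct in registry.cell_types if ct in tpm.columns]
    keep_t = [registry.cell_types.index(ct) for ct in cell_types]
    genes = genes.reset_index(drop=True)
    expr = np.log2(tpm.loc[genes["gene"], cell_types].to_numpy(dtype=float) + 1.0)
    prom = promoter_proportions(genes, {ct: segmentations[ct] for ct in cell_types},
                                promoter_window)
    prom = np.nan_to_num(prom, nan=0.0)
    ccres = registry.intervals().reset_index(drop=True)
    pairs = assign_candidates(genes, ccres, max_distance, promoter_window)
    return ErpDataset(
        genes=genes, expr_log2=expr, cell_types=cell_types,
        ccres=ccres,
        proportions=registry.proportions[:, keep_t, :],
        majority=registry.majority_state[:, keep_t],
        prom_proportions=prom,
        pairs=pairs,
        n_states=registry.n_states,
        reference_state=registry.quiescent,
    )


# ---------------------------------------------------------------------- model
@dataclass
class ErpModel:
    """Fitted per-state coefficients for the promoter and cCRE contexts."""

    mode: str
    beta_promoter: np.ndarray       # (S,), reference entry 0
    beta_ccre: np.ndarray           # (S,), reference entry 0
    intercept: float
    reference_state: int
    n_states: int
    category: str = "all"
    n_obs: int = 0
    n_params: int = 0               # coefficients excluding the intercept
    mse: float = float("nan")
    rank: Optional[int] = None

    def erp_scores(self, proportions: np.ndarray) -> np.ndarray:
        """eRP = sum over states of beta_ccre[s] * proportion[..., s]."""
        return proportions @ self.beta_ccre


def _pooled_proportions(dataset: ErpDataset, selected: np.ndarray,
                        proportions: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Mean proportion vector over each gene's selected cCREs; zero when none.

    Accumulated through a sparse pair-membership matrix so that very large
    candidate pair lists never materialise a per-pair proportion array.
    """
    props = proportions if proportions is not None else dataset.proportions
    G, T, S = dataset.n_genes, dataset.n_cell_types, dataset.n_states
    gi = dataset.pairs["gene_idx"].to_numpy()[selected]
    ci = dataset.pairs["ccre_idx"].to_numpy()[selected]
    n_sel = np.zeros(G, dtype=np.int64)
    if len(gi) == 0:
        return np.zeros((G, T, S), dtype=float), n_sel
    member = scipy.sparse.csr_matrix(
        (np.ones(len(gi)), (gi, ci)), shape=(G, props.shape[0]))
    pooled = (member @ props.reshape(props.shape[0], T * S)).reshape(G, T, S)
    np.add.at(n_sel, gi, 1)
    nz = n_sel > 0
    pooled[nz] /= n_sel[nz, None, None]
    return pooled, n_sel


def _design(dataset: ErpDataset, pooled: np.ndarray, mode: str,
            gene_mask: Optional[np.ndarray] = None,
            ct_mask: Optional[np.ndarray] = None,
            reference_state: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Flattened (gene, cell type) design matrix and response vector."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ref = dataset.reference_state if reference_state is None else reference_state
    keep_states = [s for s in range(dataset.n_states) if s != ref]
    gm = np.ones(dataset.n_genes, dtype=bool) if gene_mask is None else gene_mask
    cm = np.ones(dataset.n_cell_types, dtype=bool) if ct_mask is None else ct_mask
    blocks = [np.ones((gm.sum() * cm.sum(), 1))]
    if mode in ("promoter", "both"):
        blocks.append(dataset.prom_proportions[np.ix_(gm, cm)][:, :, keep_states]
                      .reshape(-1, len(keep_states)))
    if mode in ("ccre", "both"):
        blocks.append(pooled[np.ix_(gm, cm)][:, :, keep_states]
                      .reshape(-1, len(keep_states)))
    X = np.concatenate(blocks, axis=1)
    y = dataset.expr_log2[np.ix_(gm, cm)].reshape(-1)
    return X, y


def _unpack(coef: np.ndarray, mode: str, n_states: int, ref: int) -> Tuple[float, np.ndarray, np.ndarray]:
    keep = [s for s in range(n_states) if s != ref]
    intercept = float(coef[0])
    bp = np.zeros(n_states)
    bc = np.zeros(n_states)
    k = 1
    if mode in ("promoter", "both"):
        bp[keep] = coef[k:k + len(keep)]
        k += len(keep)
    if mode in ("ccre", "both"):
        bc[keep] = coef[k:k + len(keep)]
    return intercept, bp, bc


def fit_erp(dataset: ErpDataset, selected: Optional[np.ndarray] = None,
            mode: str = "both", gene_mask: Optional[np.ndarray] = None,
            ct_mask: Optional[np.ndarray] = None,
            proportions: Optional[np.ndarray] = None,
            reference_state: Optional[int] = None,
            category: str = "all", warn_rank: bool = True) -> ErpModel:
    """Ordinary least squares fit of the state-proportion model.

    Rank-deficient designs fall back to the minimum-norm pseudoinverse
    solution with a logged warning (fitted values are unaffected).
    """
    if selected is None:
        selected = dataset.pairs["selected"].to_numpy()
    pooled, _ = _pooled_proportions(dataset, selected, proportions)
    X, y = _design(dataset, pooled, mode, gene_mask, ct_mask, reference_state)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if warn_rank and rank < X.shape[1]:
        log.warning("fit_erp: rank-deficient design (rank %d < %d columns); "
                    "pseudoinverse solution used", rank, X.shape[1])
    ref = dataset.reference_state if reference_state is None else reference_state
    intercept, bp, bc = _unpack(coef, mode, dataset.n_states, ref)
    resid = y - X @ coef
    return ErpModel(mode=mode, beta_promoter=bp, beta_ccre=bc, intercept=intercept,
                    reference_state=ref, n_states=dataset.n_states, category=category,
                    n_obs=len(y), n_params=X.shape[1] - 1,
                    mse=float(resid @ resid / len(y)) if len(y) else float("nan"),
                    rank=int(rank))


def predict_expression(dataset: ErpDataset, model: ErpModel,
                       selected: Optional[np.ndarray] = None,
                       proportions: Optional[np.ndarray] = None) -> np.ndarray:
    """(G, T) predictions from the pooled design under the fitted model."""
    if selected is None:
        selected = dataset.pairs["selected"].to_numpy()
    pooled, _ = _pooled_proportions(dataset, selected, proportions)
    pred = np.full((dataset.n_genes, dataset.n_cell_types), model.intercept)
    if model.mode in ("promoter", "both"):
        pred = pred + dataset.prom_proportions @ model.beta_promoter
    if model.mode in ("ccre", "both"):
        pred = pred + pooled @ model.beta_ccre
    return pred


def predict_mean_erp(dataset: ErpDataset, model: ErpModel,
                     selected: Optional[np.ndarray] = None) -> np.ndarray:
    """cCRE-mode prediction as intercept + mean of per-pair eRP scores.

    Genes with no selected pair fall back to the intercept alone.  Equals
    :func:`predict_expression` in ``ccre`` mode to machine precision because
    pooling is the unweighted mean of per-cCRE proportion vectors.
    """
    if selected is None:
        selected = dataset.pairs["selected"].to_numpy()
    gi = dataset.pairs["gene_idx"].to_numpy()[selected]
    ci = dataset.pairs["ccre_idx"].to_numpy()[selected]
    erp = model.erp_scores(dataset.proportions[ci])  # (n_pairs, T)
    total = np.zeros((dataset.n_genes, dataset.n_cell_types))
    n_sel = np.zeros(dataset.n_genes, dtype=np.int64)
    if len(gi):
        np.add.at(total, gi, erp)
        np.add.at(n_sel, gi, 1)
        nz = n_sel > 0
        total[nz] /= n_sel[nz, None]
    return model.intercept + total


# ----------------------------------------------------------------- row pearson
def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row of two equally-shaped matrices; 0 when degenerate."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, 0.0)


# ------------------------------------------------------------------ screening
def correlation_filter(dataset: ErpDataset, proxy: np.ndarray,
                       min_abs_r: float = 0.3,
                       max_per_gene: Optional[int] = None) -> pd.DataFrame:
    """Set ``screen_r`` and ``selected`` on the candidate pairs.

    ``proxy`` is a per-cCRE, per-cell-type activity proxy; the screen
    correlation is the Pearson r across cell types between the proxy and the
    gene's log2(TPM + 1).  Pairs with undefined r (constant proxy or
    constant expression) are deselected and logged.  With ``max_per_gene``
    only each gene's top-ranked surviving pairs (by |r|) stay selected,
    bounding the cost of the downstream subselection.
    """
    if dataset.n_cell_types < 3:
        raise ValueError("correlation screening needs at least 3 cell types")
    pairs = dataset.pairs
    gi = pairs["gene_idx"].to_numpy()
    ci = pairs["ccre_idx"].to_numpy()
    r = np.empty(len(pairs), dtype=float)
    defined = np.empty(len(pairs), dtype=bool)
    chunk = 500_000
    for lo in range(0, len(pairs), chunk):
        hi = min(lo + chunk, len(pairs))
        a = proxy[ci[lo:hi]]
        b = dataset.expr_log2[gi[lo:hi]]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[lo:hi] = (ac * bc).sum(axis=1) / den
        defined[lo:hi] = den > 0
    n_undef = int((~defined).sum())
    if n_undef:
        log.info("correlation_filter: %d pairs with undefined screen correlation deselected", n_undef)
    pairs = pairs.copy()
    pairs["screen_r"] = np.where(defined, r, np.nan)
    selected = defined & (np.abs(np.where(defined, r, 0.0)) >= min_abs_r)
    if max_per_gene is not None and selected.any():
        sel_idx = np.nonzero(selected)[0]
        order = np.lexsort((sel_idx, -np.abs(r[sel_idx]), gi[sel_idx]))
        g_sorted = gi[sel_idx][order]
        first = np.r_[True, g_sorted[1:] != g_sorted[:-1]]
        start = np.maximum.accumulate(np.where(first, np.arange(len(order)), 0))
        rank = np.arange(len(order)) - start
        selected[sel_idx[order[rank >= max_per_gene]]] = False
    pairs["selected"] = selected
    return pairs


def activity_proxy(dataset: ErpDataset, bootstrap_fit: bool = True) -> np.ndarray:
    """Per-cCRE activity proxy for the correlation screen.

    With ``bootstrap_fit`` the proxy is each cCRE's eRP under an initial
    cCRE-mode fit on all candidate pairs; otherwise it is the element's
    non-quiescent proportion.
    """
    if bootstrap_fit and len(dataset.pairs):
        all_sel = np.ones(len(dataset.pairs), dtype=bool)
        model = fit_erp(dataset, selected=all_sel, mode="ccre")
        return model.erp_scores(dataset.proportions)
    return 1.0 - dataset.proportions[:, :, dataset.reference_state]


def screen_pairs(dataset: ErpDataset, min_abs_r: float = 0.3,
                 bootstrap_fit: bool = True,
                 max_per_gene: Optional[int] = 50) -> pd.DataFrame:
    """Convenience: activity proxy + correlation filter."""
    return correlation_filter(dataset, activity_proxy(dataset, bootstrap_fit),
                              min_abs_r, max_per_gene)


# ---------------------------------------------------------------- subselection
@dataclass
class SubselectResult:
    pairs: pd.DataFrame
    model: ErpModel
    n_iterations: int
    changed_per_iteration: List[int]


def _select_subset(traj: np.ndarray, r: np.ndarray, max_links: int,
                   n_starts: int) -> np.ndarray:
    """Best-subset search for one gene under equal-weight pooling.

    Finds the subset C of candidate eRP trajectories minimising
    ``|| r - mean(traj[C]) ||^2``: for every candidate size k a
    unit-coefficient pursuit approximates ``k * r`` by a sum of k
    trajectories (run from ``n_starts`` different first picks), followed by
    pairwise swap refinement; the size with the lowest SSE wins.  The
    equal-weight mean is the identifying constraint: an unlinked element
    cannot "freeload" because adding it dilutes the pooled amplitude.
    Constant trajectories are never selected.  Deterministic; ties break on
    the lowest candidate index.
    """
    n_c, T = traj.shape
    usable = np.ptp(traj, axis=1) > 0
    best_sse = float(r @ r)
    best = np.zeros(n_c, dtype=bool)
    if not usable.any() or best_sse == 0.0:
        return best
    blocked = ~usable
    ip = np.abs(traj @ r)
    ip[blocked] = -np.inf
    starts = np.argsort(-ip, kind="mergesort")[:n_starts]
    starts = starts[np.isfinite(ip[starts])]
    max_k = min(max_links, int(usable.sum()))
    for k in range(1, max_k + 1):
        target = k * r
        for first in starts:
            chosen = np.zeros(n_c, dtype=bool)
            chosen[first] = True
            ssum = traj[first].copy()
            for _ in range(k - 1):
                d = (((target - ssum)[None, :] - traj) ** 2).sum(axis=1)
                d[chosen | blocked] = np.inf
                j = int(np.argmin(d))
                chosen[j] = True
                ssum += traj[j]
            # swap refinement on the equal-weight objective
            sse = float(((r - ssum / k) ** 2).sum())
            while True:
                mem = np.nonzero(chosen)[0]
                non = np.nonzero(~chosen & usable)[0]
                if len(non) == 0:
                    break
                delta_best, swap = 1e-12, None
                for m in mem:
                    trial = ssum - traj[m] + traj[non]
                    sses = ((r[None, :] - trial / k) ** 2).sum(axis=1)
                    jb = int(np.argmin(sses))
                    if sse - sses[jb] > delta_best:
                        delta_best, swap = sse - sses[jb], (m, non[jb], trial[jb], float(sses[jb]))
                if swap is None:
                    break
                m, j, ssum, sse = swap[0], swap[1], swap[2], swap[3]
                chosen[m] = False
                chosen[j] = True
            if sse < best_sse - 1e-12:
                best_sse = sse
                best = chosen.copy()
    return best


def subselect(dataset: ErpDataset, mode: str = "both", max_iter: int = 4,
              max_links_per_gene: int = 8, n_starts: int = 5,
              representation: str = "proportions") -> SubselectResult:
    """Prune candidate pairs to those contributing to expression.

    Iterates model fitting and per-gene subset selection: each outer
    iteration fits the state-proportion model on the currently selected
    pairs, scores every candidate cCRE's eRP trajectory under the fitted
    coefficients, and re-selects each gene's pairs by best-subset search
    under the model's equal-weight pooling (see :func:`_select_subset`).
    Iteration stops at a fixed point or after ``max_iter`` rounds; the
    final coefficients are refit on the full state-proportion vectors of
    the surviving pairs.

    ``representation`` chooses how a cCRE is represented during selection:
    ``"proportions"`` (full state-proportion vector, default) or
    ``"majority"`` (one-hot majority state only).
    """
    if representation not in ("proportions", "majority"):
        raise ValueError("representation must be 'proportions' or 'majority'")
    pairs = dataset.pairs.copy()
    gi_all = pairs["gene_idx"].to_numpy()
    ci_all = pairs["ccre_idx"].to_numpy()
    candidate = pairs["selected"].to_numpy().copy()
    props = (dataset.proportions if representation == "proportions"
             else np.eye(dataset.n_states)[dataset.majority])

    selected = candidate.copy()
    changed_hist: List[int] = []
    it = 0
    genes = np.unique(gi_all[candidate])
    for it in range(1, max_iter + 1):
        model = fit_erp(dataset, selected=selected, mode=mode, proportions=props,
                        warn_rank=False)
        traj = props @ model.beta_ccre                      # (n_ccre, T)
        base = np.full_like(dataset.expr_log2, model.intercept)
        if mode in ("promoter", "both"):
            base = base + dataset.prom_proportions @ model.beta_promoter
        new = np.zeros(len(pairs), dtype=bool)
        for g in genes:
            rows = np.nonzero(candidate & (gi_all == g))[0]
            chosen = _select_subset(traj[ci_all[rows]], dataset.expr_log2[g] - base[g],
                                    max_links_per_gene, n_starts)
            new[rows[chosen]] = True
        changed_hist.append(int((new != selected).sum()))
        converged = bool((new == selected).all())
        selected = new
        if converged:
            break

    final_model = fit_erp(dataset, selected=selected, mode=mode)
    pairs["selected"] = selected
    return SubselectResult(pairs=pairs, model=final_model, n_iterations=it,
                           changed_per_iteration=changed_hist)


def add_distractor_pairs(dataset: ErpDataset, n_per_gene: int = 20,
                         max_distance: int = 1_000_000, seed: int = 0) -> pd.DataFrame:
    """Augment a truth-linked pair list with unlinked candidates (benchmark aid).

    For every gene, ``n_per_gene`` cCREs within ``max_distance`` of the TSS
    that are not already paired are added as candidate pairs.  The returned
    frame carries an ``is_true`` column marking the original pairs, so link
    recovery (recall/precision of the subselection) can be scored against
    generator truth.
    """
    rng = np.random.default_rng(seed)
    mids = ((dataset.ccres["start"].to_numpy() + dataset.ccres["end"].to_numpy()) // 2)
    by_chrom = {c: g.index.to_numpy() for c, g in dataset.ccres.groupby("chrom", sort=False)}
    rows = [dataset.pairs.assign(is_true=True)]
    linked = dataset.pairs.groupby("gene_idx")["ccre_idx"].apply(set)
    for gi, g in dataset.genes.iterrows():
        idx = by_chrom.get(g["chrom"])
        if idx is None:
            continue
        dist = np.abs(mids[idx] - g["tss"])
        cands = idx[dist <= max_distance]
        taken = linked.get(gi, set())
        cands = np.array([c for c in cands if c not in taken], dtype=np.int64)
        if len(cands) == 0:
            continue
        pick = rng.choice(cands, size=min(n_per_gene, len(cands)), replace=False)
        rows.append(pd.DataFrame({
            "gene_idx": gi, "ccre_idx": np.sort(pick),
            "distance": np.abs(mids[np.sort(pick)] - g["tss"]),
            "screen_r": np.nan, "selected": True, "is_true": False}))
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------- evaluation
def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    ss_res = float(((observed - predicted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    if np.isnan(r2) or n <= p + 1:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def loo_evaluate(dataset: ErpDataset, mode: str = "both", by_category: bool = False,
                 selection: str = "given", min_abs_r: float = 0.3,
                 subselect_kwargs: Optional[dict] = None,
                 low_threshold: float = 1.0,
                 variability_threshold: float = 1.0) -> pd.DataFrame:
    """Leave-one-cell-type-out evaluation by adjusted r².

    For each held-out cell type the model is trained on the remaining cell
    types (optionally re-running the correlation screen and subselection on
    the training cell types only when ``selection='pipeline'``), expression
    is predicted in the held-out cell type, and adjusted r² is reported with
    n = genes evaluated and p = fitted coefficients excluding the intercept.
    """
    T = dataset.n_cell_types
    if T < 3:
        raise ValueError("leave-one-out evaluation needs at least 3 cell types")
    if selection not in ("given", "pipeline"):
        raise ValueError("selection must be 'given' or 'pipeline'")
    categories: Optional[pd.Series] = None
    if by_category:
        if "category" in dataset.genes.columns:
            categories = dataset.genes["category"]
        else:
            categories = categorize_genes(dataset.tpm(), low_threshold, variability_threshold)
            categories.index = dataset.genes.index

    rows = []
    for t in range(T):
        train = [i for i in range(T) if i != t]
        ct_mask = np.zeros(T, dtype=bool)
        ct_mask[train] = True
        if selection == "pipeline" and mode != "promoter":
            # screen and prune on the training cell types only
            d_train = dataset.restrict_cell_types(train)
            d_train.pairs = screen_pairs(d_train, min_abs_r=min_abs_r)
            sub = subselect(d_train, mode=mode, **(subselect_kwargs or {}))
            selected = sub.pairs["selected"].to_numpy()
        else:
            selected = dataset.pairs["selected"].to_numpy()

        groups = [("all", None)] if not by_category else \
            [(c, (categories == c).to_numpy()) for c in CATEGORIES]
        for cat, gmask in groups:
            gm = np.ones(dataset.n_genes, dtype=bool) if gmask is None else gmask
            if gm.sum() == 0:
                continue
            model = fit_erp(dataset, selected=selected, mode=mode,
                            gene_mask=gm, ct_mask=ct_mask, category=cat)
            pred = predict_expression(dataset, model, selected=selected)
            obs = dataset.expr_log2[gm, t]
            r2 = _r_squared(obs, pred[gm, t])
            n, p = int(gm.sum()), model.n_params
            rows.append({"left_out": dataset.cell_types[t], "mode": mode,
                         "category": cat, "n": n, "p": p, "r2": r2,
                         "adjusted_r2": adjusted_r_squared(r2, n, p)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- export
def _position_in_tad(tads: pd.DataFrame, chrom: np.ndarray, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    """True where some single TAD interval contains both positions."""
    out = np.zeros(len(chrom), dtype=bool)
    for c, grp in tads.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        run_max_end = np.maximum.accumulate(ends)
        sel = chrom == c
        if not sel.any():
            continue
        j = np.searchsorted(starts, lo[sel], side="right")
        ok = j > 0
        res = np.zeros(int(sel.sum()), dtype=bool)
        res[ok] = run_max_end[j[ok] - 1] > hi[sel][ok]
        out[sel] = res
    return out


def export_pairs(dataset: ErpDataset, model: ErpModel, erp_threshold: float = 0.0,
                 tads: Optional[pd.DataFrame] = None,
                 same_tad_only: bool = False) -> pd.DataFrame:
    """Thresholded cCRE-target-gene table with per-cell-type eRP scores.

    A selected pair is exported when |eRP| >= threshold in at least one cell
    type.  When TAD intervals are supplied, ``same_tad`` records whether the
    cCRE midpoint and the TSS fall inside one TAD interval, and
    ``same_tad_only`` filters to those pairs.
    """
    pairs = dataset.pairs[dataset.pairs["selected"]].reset_index(drop=True)
    gi = pairs["gene_idx"].to_numpy()
    ci = pairs["ccre_idx"].to_numpy()
    erp = model.erp_scores(dataset.proportions[ci])  # (n, T)
    keep = (np.abs(erp) >= erp_threshold).any(axis=1)
    out = pd.DataFrame({
        "gene": dataset.genes["gene"].to_numpy()[gi],
        "ccre_chrom": dataset.ccres["chrom"].to_numpy()[ci],
        "ccre_start": dataset.ccres["start"].to_numpy()[ci],
        "ccre_end": dataset.ccres["end"].to_numpy()[ci],
        "distance": pairs["distance"].to_numpy(),
        "screen_r": pairs["screen_r"].to_numpy(),
    })
    for t, ct in enumerate(dataset.cell_types):
        out[f"erp_{ct}"] = erp[:, t]
    if tads is not None:
        mids = ((out["ccre_start"].to_numpy() + out["ccre_end"].to_numpy()) // 2)
        tss = dataset.genes["tss"].to_numpy()[gi]
        lo = np.minimum(mids, tss)
        hi = np.maximum(mids, tss)
        out["same_tad"] = _position_in_tad(tads, out["ccre_chrom"].to_numpy(), lo, hi)
        if same_tad_only:
            keep &= out["same_tad"].to_numpy()
    return out[keep].reset_index(drop=True)
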