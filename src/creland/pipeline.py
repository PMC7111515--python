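"""End-to-end orchestration: simulate -> registry -> landscape -> compare -> erp.

A run is described by a single YAML-able configuration with per-stage
blocks.  Every stage writes its outputs under ``outdir/<stage>/`` together
with a hash of the configuration that produced them; rerunning with an
unchanged configuration resumes from existing stage outputs, and a stage
whose upstream outputs are missing raises a dependency error naming the
stage.  A run manifest lists every output file with its SHA-256 checksum,
so two runs with the same seed are byte-identical exactly when their
manifests match.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import erp as erp_mod
from .errors import DependencyError
from .io import (config_hash, read_bed3, read_expression_tsv, read_gene_tsv,
                 write_manifest, write_tsv)
from .landscape import (StateSegmentation, quiescent_everywhere_fraction, read_state_bed,
                        state_coverage_fractions, transition_matrix)
from .registry import build_registry, read_registry, reproducible_peaks
from .simulate import SimConfig, simulate_dataset, write_fixture_bundle

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "registry", "landscape", "compare", "erp")


@dataclasses.dataclass
class RunConfig:
    outdir: str = "creland_run"
    seed: int = 0
    stages: List[str] = dataclasses.field(default_factory=lambda: list(ALL_STAGES))
    log_level: str = "INFO"
    simulate: Dict = dataclasses.field(default_factory=dict)
    registry: Dict = dataclasses.field(default_factory=dict)
    landscape: Dict = dataclasses.field(default_factory=dict)
    compare: Dict = dataclasses.field(default_factory=dict)
    erp: Dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def stage_hash(self, stage: str) -> str:
        chain = {"seed": self.seed}
        for s in ALL_STAGES:
            chain[s] = getattr(self, s)
            if s == stage:
                break
        return config_hash(chain)


class PipelineRun:
    """Stateful executor for one output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.files: List[Path] = []
        self.truth = None
        self.registry = None
        self.state_maps: Optional[Dict[str, StateSegmentation]] = None

    # ------------------------------------------------------------- plumbing
    def _stage_dir(self, stage: str) -> Path:
        return self.out / stage

    def _stage_done(self, stage: str) -> bool:
        d = self._stage_dir(stage)
        marker = d / ".stage_hash"
        return marker.exists() and marker.read_text().strip() == self.config.stage_hash(stage)

    def _mark(self, stage: str) -> None:
        (self._stage_dir(stage) / ".stage_hash").write_text(self.config.stage_hash(stage) + "\n")

    def _collect(self, stage: str) -> None:
        d = self._stage_dir(stage)
        self.files.extend(p for p in sorted(d.rglob("*"))
                          if p.is_file() and p.name != ".stage_hash")

    def _require(self, stage: str, upstream: str) -> None:
        if not self._stage_dir(upstream).exists():
            raise DependencyError(
                f"stage {stage!r} needs outputs of stage {upstream!r}; run it first")

    # --------------------------------------------------------------- stages
    def run_simulate(self) -> None:
        cfg = self.config.sim_config()
        self.truth = simulate_dataset(cfg)
        self.state_maps = self.truth.state_maps
        write_fixture_bundle(self.truth, self._stage_dir("simulate"),
                             signals=bool(self.config.simulate.get("write_signals", False)))
        self._mark("simulate")

    def _load_simulate(self, stage: str = "registry") -> None:
        d = self._stage_dir("simulate")
        self._require(stage, "simulate")
        cfg = self.config.sim_config()
        self.state_maps = {}
        for bed in sorted((d / "states").glob("*.state.bed")):
            ct = bed.name.replace(".state.bed", "")
            self.state_maps[ct] = read_state_bed(bed, cell_type=ct, n_states=cfg.n_states)

    def run_registry(self) -> None:
        if self.state_maps is None:
            self._load_simulate()
        d = self._stage_dir("simulate")
        quiescent = int(self.config.registry.get("quiescent_state", 0))
        peaks: Dict[str, List[pd.DataFrame]] = {}
        for bed in sorted((d / "peaks").glob("*.bed")):
            ct = bed.name.split(".rep")[0]
            peaks.setdefault(ct, []).append(read_bed3(bed))
        reg = build_registry({ct: reproducible_peaks(reps) for ct, reps in peaks.items()},
                             self.state_maps, quiescent=quiescent)
        self.registry = reg
        rd = self._stage_dir("registry")
        rd.mkdir(parents=True, exist_ok=True)
        reg.to_bed().to_csv(rd / "registry.bed", sep="\t", header=False, index=False)
        write_tsv(reg.annotation_frame(), rd / "annotation.tsv")
        totals, per_state = reg.active_ccre_counts()
        write_tsv(totals.rename_axis("cell_type").reset_index(), rd / "active_counts.tsv")
        write_tsv(per_state.rename_axis("cell_type").reset_index(), rd / "active_counts_by_state.tsv")
        write_tsv(reg.dynamic_ccre_counts().rename_axis("cell_type").reset_index(),
                  rd / "dynamic_counts.tsv")
        self._mark("registry")

    def _load_registry(self) -> None:
        rd = self._stage_dir("registry")
        if self.registry is None:
            self._require("erp", "registry")
            quiescent = int(self.config.registry.get("quiescent_state", 0))
            self.registry = read_registry(rd / "registry.bed", rd / "annotation.tsv", quiescent)

    def run_landscape(self) -> None:
        if self.state_maps is None:
            self._load_simulate("landscape")
        self._load_registry()
        ld = self._stage_dir("landscape")
        ld.mkdir(parents=True, exist_ok=True)
        quiescent = int(self.config.registry.get("quiescent_state", 0))
        segs = self.state_maps
        cov = pd.DataFrame({ct: state_coverage_fractions(s) for ct, s in segs.items()}).T
        cov.columns = [f"state_{s}" for s in cov.columns]
        write_tsv(cov.rename_axis("cell_type").reset_index(), ld / "coverage.tsv")
        qef = quiescent_everywhere_fraction(list(segs.values()), quiescent)
        (ld / "quiescent_everywhere.txt").write_text(f"{qef:.6f}\n")
        regions = self.registry.intervals()
        rows = []
        cts = list(segs)
        max_pairs = int(self.config.landscape.get("max_transition_pairs", 20))
        pairs = [(a, b) for i, a in enumerate(cts) for b in cts[i + 1:]][:max_pairs]
        for a, b in pairs:
            tm = transition_matrix(segs[a], segs[b], regions=regions)
            rows.append(tm.to_frame())
        if rows:
            write_tsv(pd.concat(rows, ignore_index=True), ld / "transitions_ccres.tsv")
        self._mark("landscape")

    def run_compare(self) -> None:
        self._load_registry()
        d = self._stage_dir("simulate")
        self._require("compare", "simulate")
        tpm = read_expression_tsv(d / "expression_tpm.tsv")
        cd = self._stage_dir("compare")
        cd.mkdir(parents=True, exist_ok=True)
        thresholds = self.config.compare.get("thresholds", [1, 5, 10])
        counts = cmp.expressed_gene_counts(tpm, thresholds)
        write_tsv(counts.reset_index(), cd / "expressed_counts.tsv")
        dynamic = self.registry.dynamic_ccre_counts()
        exclude = self.config.compare.get("exclude", [])
        try:
            assoc = cmp.expression_ccre_association(counts.iloc[:, 0], dynamic, exclude)
            write_tsv(pd.DataFrame([dataclasses.asdict(assoc)]), cd / "association.tsv")
        except ValueError as exc:
            log.warning("compare: association skipped (%s)", exc)
        # accessibility proxy at cCREs: non-quiescent proportion per cell type
        access = pd.DataFrame(1.0 - self.registry.proportions[:, :, self.registry.quiescent],
                              columns=self.registry.cell_types)
        if access.shape[0] >= 2 and access.shape[1] >= 2:
            corr = cmp.correlation_matrix(access, method="spearman")
            write_tsv(corr.rename_axis("sample").reset_index(), cd / "accessibility_corr.tsv")
            clust = cmp.hierarchical_cluster(corr)
            (cd / "accessibility_cluster.newick").write_text(clust.to_newick() + "\n")
            pca = cmp.pca_variance(access)
            write_tsv(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.variance_fractions))],
                                    "variance_fraction": pca.variance_fractions}),
                      cd / "pca_variance.tsv")
        qn = cmp.quantile_normalize(np.log2(tpm + 1.0))
        if qn.shape[1] >= 2 and qn.shape[0] >= 2:
            ecorr = cmp.correlation_matrix(qn, method="spearman")
            eclust = cmp.hierarchical_cluster(ecorr)
            (cd / "expression_cluster.newick").write_text(eclust.to_newick() + "\n")
        self._mark("compare")

    def run_erp(self) -> None:
        if self.state_maps is None:
            self._load_simulate("erp")
        self._load_registry()
        d = self._stage_dir("simulate")
        self._require("erp", "simulate")
        tpm = read_expression_tsv(d / "expression_tpm.tsv")
        genes = read_gene_tsv(d / "genes.tsv")
        ecfg = self.config.erp
        ds = erp_mod.dataset_from_registry(
            self.registry, genes, tpm, self.state_maps,
            max_distance=int(ecfg.get("max_distance", 1_000_000)),
            promoter_window=int(ecfg.get("promoter_window", 1000)))
        min_abs_r = float(ecfg.get("min_abs_r", 0.3))
        sub_kwargs = dict(ecfg.get("subselect", {}))
        ds.pairs = erp_mod.screen_pairs(ds, min_abs_r=min_abs_r)
        sub = erp_mod.subselect(ds, **sub_kwargs)
        ds.pairs = sub.pairs
        ed = self._stage_dir("erp")
        ed.mkdir(parents=True, exist_ok=True)
        model_rows = []
        for mode in ecfg.get("modes", ["promoter", "ccre", "both"]):
            model = erp_mod.fit_erp(ds, mode=mode)
            for s in range(ds.n_states):
                model_rows.append({"mode": mode, "state": s,
                                   "beta_promoter": model.beta_promoter[s],
                                   "beta_ccre": model.beta_ccre[s],
                                   "intercept": model.intercept})
        write_tsv(pd.DataFrame(model_rows), ed / "model.tsv")
        evals = []
        selection = ecfg.get("loo_selection", "given")
        for mode in ecfg.get("modes", ["promoter", "ccre", "both"]):
            evals.append(erp_mod.loo_evaluate(ds, mode=mode, selection=selection,
                                              min_abs_r=min_abs_r,
                                              subselect_kwargs=sub_kwargs,
                                              by_category=bool(ecfg.get("by_category", False))))
        write_tsv(pd.concat(evals, ignore_index=True), ed / "evaluation.tsv")
        final = erp_mod.fit_erp(ds, mode="ccre")
        tads = None
        if ecfg.get("tads"):
            tads = read_bed3(ecfg["tads"])
        pairs_table = erp_mod.export_pairs(ds, final,
                                           erp_threshold=float(ecfg.get("erp_threshold", 0.0)),
                                           tads=tads,
                                           same_tad_only=bool(ecfg.get("same_tad_only", False)))
        write_tsv(pairs_table, ed / "pairs.tsv")
        self._mark("erp")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the toggled stages in dependency order and write the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    run = PipelineRun(config)
    run.out.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": run.run_simulate,
        "registry": run.run_registry,
        "landscape": run.run_landscape,
        "compare": run.run_compare,
        "erp": run.run_erp,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if run._stage_done(stage):
            log.info("stage=%s resumed from existing outputs", stage)
            continue
        t0 = time.perf_counter()
        runners[stage]()
        log.info("stage=%s wall_time=%.2fs", stage, time.perf_counter() - t0)
    for stage in ALL_STAGES:
        if run._stage_dir(stage).exists():
            run._collect(stage)
    return write_manifest(run.out, run.files, extra={
        "seed": str(config.seed),
        "config": config_hash(dataclasses.asdict(config)),
    })
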