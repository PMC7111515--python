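# creland

Candidate *cis*-regulatory element (cCRE) registries, chromatin-state
landscapes, and epigenetic regulatory potential (eRP) regression for
multi-cell-type epigenomic panels.

Integrative epigenomic studies of differentiation systems such as mouse
hematopoiesis segment the genome of every cell type into epigenetic states
(recurring combinations of accessibility, histone marks and CTCF) and
intersect those maps with reproducible nuclease-accessibility peaks to
define cCREs — discrete intervals with regulatory potential in at least one
cell type. `creland` is a reusable implementation of the downstream
analysis for anyone with state maps (BED), peak calls (BED) and an
expression matrix (TSV):

- **Registry construction** — replicate-reproducible peaks (base-level
  intersection), cross-cell-type merging, per-cell-type state proportions,
  majority states, activity flags, and the rule that removes elements
  quiescent in every cell type.
- **Landscape statistics** — per-state genome coverage, the fraction of
  the genome quiescent in all cell types, pairwise state-transition
  matrices (per bin or per element), and aggregated signal meta-profiles
  around interval classes.
- **Comparative analytics** — Pearson/Spearman correlation matrices,
  hierarchical clustering with 1 − r distance, PCA with variance-explained
  fractions, quantile normalization, expressed-gene counts, and the
  expressed-genes-versus-dynamic-cCREs association.
- **eRP regression** — gene expression log2(TPM+1) modelled as a linear
  function of state proportions at promoters and at the unweighted mean of
  a gene's distal cCREs:

      y(g,t) = β0 + Σ_s βp[s]·P_prom(g,t,s) + Σ_s βc[s]·P_pool(g,t,s),

  with the quiescent state as the zero-coefficient reference. The eRP
  score of element c in cell type t is Σ_s βc[s]·proportion(c,t,s), and a
  gene's cCRE-mode prediction is exactly the mean of its paired elements'
  eRP scores. Candidate pairs within 1 Mb of the TSS are screened by
  correlation and pruned by an iterative subselection during model
  fitting; models are evaluated by leave-one-cell-type-out adjusted r²,
  overall and within four gene-expression categories, and thresholded
  cCRE–target-gene pairs are exported with optional TAD restriction.
- **Synthetic data** — a generator producing lineage-correlated state
  maps, replicate peaks, signal tracks and expression with *known* truth
  (coefficients and cCRE–gene links), so the whole pipeline is testable
  without any external download. See `docs/methods.md` for the model.

## Worked example

Run the default synthetic study (20 cell types, 3 × 4 Mb chromosomes,
27 states, 2,000 genes) through every stage:

```python
import creland
from creland import erp

cfg = creland.SimConfig(seed=1)
truth = creland.simulate_dataset(cfg)

peaks = {ct: creland.reproducible_peaks(reps) for ct, reps in truth.peaks.items()}
registry = creland.build_registry(peaks, truth.state_maps)
print(len(registry))                              # 5823 cCREs

frac = creland.state_coverage_fractions(truth.state_maps["ct00"])
print(round(frac[0] * 100, 1))                    # 86.4 % of the genome quiescent
qe = creland.quiescent_everywhere_fraction(list(truth.state_maps.values()))
print(round(qe * 100, 1))                         # 50.5 % quiescent in all 20 cell types

ds = erp.dataset_from_registry(registry, truth.genes, truth.tpm, truth.state_maps)
ds.pairs = erp.screen_pairs(ds)
ds.pairs = erp.subselect(ds).pairs
for mode in ("promoter", "ccre", "both"):
    ev = erp.loo_evaluate(ds, mode=mode, selection="given")
    print(mode, round(ev["adjusted_r2"].mean(), 3))
# promoter 0.185   ccre 0.714   both 0.870
```

The quiescent state dominates every cell type's genome (~86%), about half
the genome is quiescent in all cell types at once, and the registry holds
the few thousand accessibility-supported, non-quiescent elements. The
leave-one-out numbers say how much of the held-out cell type's expression
variation the fitted state coefficients explain: promoters alone carry
little at this noise level, distal cCREs most, and the combined model the
most — the qualitative ordering the eRP framework is built on. On data
with known links, the subselection recovers the true cCRE–gene pairs from
5 true + 20 unlinked candidates per gene with ~93% recall and ~89%
precision (see the acceptance output below).

A YAML-driven end-to-end run (writes per-stage outputs and a checksum
manifest; identical seed ⇒ byte-identical outputs):

```bash
creland simulate --outdir demo_fixture --seed 1
creland run config.yaml --seed 1 --outdir demo_run
```

Subcommands `creland landscape|registry|compare|erp ...` expose each stage
on files; see `creland --help`.

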