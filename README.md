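# cytokinetics

Single-cell mass-cytometry (CyTOF) analysis of T-cell receptor (TCR)
signalling kinetics, for immunologists and computational biologists who
want to ask: *when stimulation strength changes, does the programme of
signalling events change — or only the rate at which cells enter it?*

Naive CD8+ T cells stimulated with peptide ligands of graded potency
(strong N4, intermediate T4, weak G4, null NP68) are profiled at snapshot
timepoints (0/1/2/4/6 h) across ~20 channels: phospho-signalling readouts
(pS6, pERK1/2, pSTAT5, pAKT, pSLP76, pZAP70, pPLCγ1, pLCK), the
degradation readout IκBα, surface markers (CD44, CD25, CD8α, TCRβ, CD45),
DNA content (191Ir), viability (cisplatin) and normalization-bead
channels. The package implements the full analysis path plus a synthetic
generator with exact ground truth, so every stage is testable without any
download.

## What it computes

1. **Preprocessing** — logicle transformation (width w = 0.1 by default),
   cross-batch range normalization on shared samples (quantile p = 0.001,
   zero fixed), per-event normalization to DNA/total-protein channels, and
   six nested gates (beads → event length → single cell-equivalent of DNA
   → live → TCRβ⁺ → CD8⁺; the retention gates keep cells within 5 scaled
   MADs below the median). Positivity is called against unstimulated cells
   (99.5th percentile; mirrored for loss markers), yielding
   positive-fraction and 2^k combinatorial-state summaries.
2. **Differential abundance** — the transformed marker space (14 markers)
   is tiled with hyperspheres of radius `tol·√M` (tol = 0.4) centred on
   every 200th cell; per-sample counts in each hypersphere are tested with
   a replicate-blocked negative-binomial analysis of deviance
   (`counts_hs ~ NB(μ_hs, α)`, `log μ = offset + replicate + condition`),
   with a common dispersion α solved from the pooled Pearson chi-square.
   Multiplicity is controlled by a density-weighted Benjamini–Hochberg
   procedure over the marker space (spatial FDR, α = 0.05), and
   significant hyperspheres are clustered by Pearson correlation into the
   signalling phenotypes A (pS6⁺pSTAT5⁺pERK⁺), A′ (pS6⁺pSTAT5⁻pERK⁺),
   B (pS6⁺pSTAT5⁺pERK⁻) and B′ (pS6⁺pSTAT5⁻pERK⁻).
3. **Trajectory / event order** — per ligand, equal numbers of cells per
   timepoint are pooled with unstimulated cells and ordered by pS6
   intensity (a sustained marker that rises with activation), giving a
   pseudotime rank in [0, 1]. A sliding window (5% of 5000 cells, 1%
   steps) marks each marker's initiation: the first window whose mean
   deviates from the starting window by more than one starting-window SD.
   Orders are compared across ligands by the mean-squared distance (MSD)
   between rank vectors against an exact permutation null; independent
   per-replicate probabilities multiply into one combined p-value.
4. **Synthetic data** — each cell draws an activation initiation time
   T ~ Exponential(λ_ligand); event m switches on in
   [T + δ_m, T + δ_m + τ_m) with the fixed programme
   pS6 → pERK1/2 → pSTAT5 → CD44 (δ = 0/0.5/1.5/3 h) and transient
   (pERK1/2, pAKT, IκBα-loss) versus sustained (pS6, pSTAT5, CD44)
   durations. Intensities are bimodal log-normal mixtures; doublets sum
   the channels of two cells (≈2× DNA), dead cells are cisplatin-high,
   beads occupy the bead channel; two batches with affine channel
   distortions share four samples for normalization. Ground truth is
   emitted per event.

## Worked example

```python
from cytokinetics import AnalysisConfig, run_pipeline

cfg = AnalysisConfig(seed=5)
cfg.simulation.n_events_per_sample = 2000   # keep the example quick
cfg.diff_abundance.downsample = 100
state = run_pipeline(cfg, out_dir="results")

print(state["gate_result"].summary().to_string(index=False))
for rep, r in state["trajectories"].items():
    print("replicate", rep,
          {l: o.markers for l, o in r["orders"].items()},
          ["%.4g" % p for p in r["comparison"].pvalues])
print("combined p: %.3g" % state["combined_p"])
```

prints (seed 5):

```
        gate  n_before  n_after  n_removed
       beads     66231    64876       1355
event_length     64876    63108       1768
dna_singlets     63108    63108          0
        live     63108    61056       2052
        tcrb     61056    61056          0
         cd8     61056    61056          0
replicate 1 {'N4': ['pS6', 'pERK12', 'pSTAT5', 'CD44'], 'T4': ['pS6', 'pERK12', 'pSTAT5', 'CD44'], 'G4': ['pS6', 'pERK12', 'pSTAT5', 'CD44']} ['0.04167', '0.04167', '0.04167']
replicate 2 {'N4': ['pS6', 'pERK12', 'pSTAT5', 'CD44'], 'T4': ['pS6', 'pERK12', 'pSTAT5', 'CD44'], 'G4': ['pS6', 'pERK12', 'pSTAT5', 'CD44']} ['0.04167', '0.04167', '0.04167']
combined p: 0.00174
```

Reading the output: the gating report shows per-step attrition (doublets
are largely caught by the event-length gate because a fused event sums
the lengths of its constituents; dead cells fall at the live gate). Both
synthetic replicates recover the same event order — pS6 first, then
pERK1/2, then pSTAT5, then CD44 — for every ligand potency. Each pairwise
order comparison has probability 1/24 ≈ 0.0417 of matching this well by
chance (exactly one of the 24 permutations of four events attains
MSD = 0), and the two independent replicate-level comparisons combine to
(1/24)² = 1/576 ≈ 0.00174: the order of signalling events is shared
across stimulation strengths, while the rate of entry into the programme
(λ = 1.0/0.3/0.1 per hour for N4/T4/G4 by default) is what potency
controls.

The same pipeline is scriptable from a shell:

```bash
cytokinetics run --stages simulate,preprocess,da,trajectory \
    --config cfg.yaml --out results --seed 5
```

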