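# Methods

This note documents the models, numerical choices and limitations of the
package; the README describes the user-facing workflow.

## The scientific model

The package is built around a rate-not-order model of TCR-induced
signalling. A cell stimulated by a peptide ligand initiates a fixed
downstream programme after a random waiting time; ligand potency sets the
*rate* of initiation, not the *content or order* of the programme. The
analysis machinery exists to test exactly that claim on snapshot
mass-cytometry data: differential abundance asks which multidimensional
signalling states appear under which stimulus, and the trajectory module
asks whether the order of activation events is shared across stimuli.

## Synthetic-data generator

The generator produces CyTOF-like events with exact ground truth.

**Initiation.** Each live cell draws T ~ Exponential(λ) per ligand
(T = ∞ if λ = 0). The exponential is the simplest memoryless law
consistent with a per-cell constant probability of crossing the
activation threshold; λ is configurable per ligand. Defaults are
λ = 1.0, 0.3, 0.1 /h for N4, T4, G4 (a 10:3:1 potency ratio) and 0 for
the null peptide NP68.

**Event programme.** Activation event m switches on during
[T + δ_m, T + δ_m + τ_m). Default offsets δ (h): pS6 0, pERK1/2 0.5,
pSTAT5 1.5, CD44 3.0 (the ordered programme), plus pAKT/IκBα 0.5,
pSLP76 0.25, CD25 3.5, pZAP70/pPLCγ1 0. Transient durations τ (h):
pERK1/2 1.5, pAKT 1.5, IκBα 2.0, pSLP76 1.0, pZAP70/pPLCγ1 0.25;
all other events are sustained (τ = ∞). These numbers are design
choices — no quantitative kinetic constants are available for this
system — selected once to reproduce the qualitative snapshot kinetics
the analysis assumes: transient markers rise and fall within 6 h under
strong stimulation, sustained markers converge across potencies by 6 h,
and the four ordered events start in distinct pseudotime windows. They
live in `KineticModel` / `SimulationConfig`, not in code.

**Intensities.** Marker intensities are bimodal log10-normal on/off
mixtures (ion counts are nonnegative and heavy-tailed). IκBα is a loss
readout: its "on" (signalling) state is dimmer than rest, so the same
state machinery renders degradation. pS6 and CD44 ramp: their on-state
log-mean rises from the off level with a saturating exponential in the
time since the event switched on (time constants 1.2 h and 1.5 h). The
ramp gives the pS6 anchor graded progression information, matching the
observed gradual intensity increase of these markers; purely binary
markers would make an intensity-ordered trajectory uninformative within
the on state.

**Nuisance events.** Doublets are formed by summing all channels of two
cells (ion counts add in a fused event), so DNA content and event length
are ≈2×; the doublet fraction is larger for stronger ligands by default
(0.10/0.06/0.04/0.02 of cells for N4/T4/G4/NP68), mimicking
conjugate-rich strong stimulations. Dead cells (3%) are cisplatin-high
and never signal. Beads (2%) are bright on the bead channel and dim
everywhere else. Batch 2 applies per-channel multiplicative gains
(default drawn once from U(0.85, 1.18), overridable); four samples are
acquired in both batches to anchor range normalization.

**What the generator does not emulate:** acquisition drift, barcode
chemistry, channel spillover, cell-cycle DNA variation, autocrine IL2
feedback and cell-cell interaction effects. Tests passing on this
generator therefore validate the machinery under idealized staining
behaviour, not performance on arbitrary real panels.

## Preprocessing

**Logicle.** The biexponential with parameters t = 262144, m = 4.5,
a = 0 and w = 0.1 (the linearization width appropriate for near-zero
CyTOF background; t, m, a are the de-facto standard display defaults).
The forward map inverts the closed-form biexponential with a 4097-point
monotone grid initial guess refined by Newton iterations; round-trip
error is ~1e-10 relative. Output is in decades (a value of t maps to m).

**Batch range normalization.** Per channel, each batch's [p, 1−p]
quantile range over the pooled shared samples is affinely mapped onto
the across-batch mean range (p = 0.001). With `fix_zero` the map is a
pure scaling from the upper quantile, so zero stays zero. The
`relative_scale(batch, ref_batch)` read-out is convention-free: a
planted 2× distortion yields 0.5 regardless of the target convention.

**Gating.** Six nested gates in order: bead removal, high event length,
single cell-equivalent of DNA, dead-cell removal, TCRβ retention, CD8
retention. Mixture-based gates (beads, DNA, viability) fit a
two-component Gaussian mixture on the transformed channel and split at
the posterior-0.5 boundary; if the components are not separated (gap
below 2 component SDs) the data are deemed unimodal and nothing is
removed — this makes clean data pass untouched instead of clipping a
fixed quantile. Event length removes events above median + 5·MAD;
the TCRβ/CD8 gates keep cells above median − 5·MAD. MAD uses the 1.4826
normal-consistency constant by default (flag `mad_scaled`); thresholds
are computed on the transformed scale among survivors of prior gates.
Both conventions (scaled MAD, transformed scale) are choices the
upstream protocol leaves open; they are exposed in `PreprocessConfig`.

**Positivity.** Signalling-positive status is defined against
unstimulated cells: above their 99.5th percentile for gain markers,
below the mirrored 0.5th percentile for loss markers. The quantile is a
design choice pinned by the ~0.5% false-positive property test.

## Differential abundance

Hypersphere centers are every 200th cell in the deterministic ordering
of the (downsampled, equal-size) pooled samples; radius tol·√M with
tol = 0.4 over the M = 14 tested markers; hyperspheres kept only if
they contain strictly more than 50 cells on average.

The count model is a negative-binomial GLM with log link:
log μ = log(total cells) + replicate + condition. One dispersion α is
shared by all hyperspheres, solved from the pooled Pearson chi-square
equation Σ (y−μ)²/(μ+αμ²) = H·(n−p) alternating with NB refits (a
moment/median estimator was measurably biased low and inflated the
type-I error; the pooled solve is unbiased in simulation and calibrates
the test to ~5% at nominal 5%). Differential abundance per hypersphere
is a likelihood-ratio analysis of deviance dropping the condition
terms, referred to chi-square. All hyperspheres share one design matrix,
so the IRLS normal equations are solved batched; the fitter agrees with
statsmodels GLM coefficient-by-coefficient in tests. This NB-LRT is a
portable stand-in for a quasi-likelihood F-test; its calibration is
covered by the type-I-error property test rather than assumed.

Spatial FDR: weighted Benjamini–Hochberg where each hypersphere's
weight is the reciprocal of the number of hypersphere centers within
one radius of it (itself included), so dense regions do not consume the
FDR budget; step-up monotonicity is enforced, α = 0.05.

Phenotype clustering: average-linkage hierarchical clustering of the
significant hyperspheres' median marker intensities under correlation
distance (1 − Pearson r), cut at distance 0.05 by default. Constant
profiles get a defined distance (0 to identical constants, else 1).
Clusters are labelled by thresholded cluster-median positivity of pS6,
pSTAT5 and pERK1/2 (A/A′/B/B′; anything pS6⁻ is "other"), with CD44
positivity reported separately. The cut height is a free parameter — the
upstream analysis identified clusters visually on a dendrogram — and on
synthetic data 0.05 separates the phenotype branches while 0.5 merges
everything; it is exposed in `DAConfig`.

## Trajectory and event order

Per ligand and replicate, equal numbers of cells per stimulated
timepoint are pooled with the same number of unstimulated cells and
sorted by pS6 (ties broken by a seeded jitter of ~1e-9 of the range, so
ranks are a strict order and all-tied inputs yield a reproducible
permutation). Curves are smoothed with local-linear tricube (lowess)
regression, span 0.2 over 2000 sampled cells — degree-1 local
regression rather than degree-2; the difference is immaterial at this
span and is covered by an independent-implementation oracle test.

Initiation detection downsamples to 5000 cells, slides a 5% window in
1% steps, and flags the first window whose mean deviates from the
starting window's mean by more than 1 starting-window SD. Degenerate
sd₀ = 0 is replaced by the smallest positive window SD (machine epsilon
scale as last resort). A marker that never crosses but whose final
window has shifted by more than `shift_fraction` (default 0.5) SDs is
"shift without threshold" and ranks last; two or more failed markers,
or a shared initiation window, make the order indeterminate — reported
as a result, not an error.

Order agreement between two trajectories: p = P(MSD(order₁, π(order₂))
≤ observed MSD) under uniformly random permutations π, enumerated
exactly for ≤8 events (so p ≥ 1/n! > 0), sampled with a seeded
generator otherwise. Per-replicate comparisons are combined by
multiplying one independent comparison per replicate — the comparison
between the strongest and weakest ligand — which for two replicates
with identical four-event orders gives (1/24)² = 1/576 ≈ 0.00174. How
the three within-replicate pairs reduce to one number per replicate is
an interpretation (the pairs share trajectories and are not mutually
independent); the package reports all pairwise p-values alongside the
combined value.

## Problem sizes and determinism

Test and example runs use 1.5–20k events per sample (the order-recovery
property runs 3 ligands × 4 stimulated timepoints × 20k cells over 20
seeds; calibration uses 200 runs of 100 hyperspheres × 8 samples),
sizes at which every stochastic assertion has comfortable Monte-Carlo
margin. One global seed is split into per-stage seeds via
`SeedSequence` and recorded in `run.json`; reruns with the same config
are bit-reproducible.

## Known limitations

- The NB-LRT is mildly liberal at very small sample counts; the spatial
  FDR inherits whatever miscalibration the per-hypersphere p-values
  carry.
- The FCS reader/writer covers float list-mode single-dataset files
  only — enough for this pipeline's round trips, not a general parser.
- Cluster labels depend on the correlation-distance cut; on real data
  the default 0.05 should be revisited against the dendrogram.
- Doublet discrimination by DNA content assumes ~2× separation; the
  event-length gate usually removes summed events first, so the DNA
  mixture may legitimately find nothing to remove.
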