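# Methods

This note documents the models, estimators, numerical choices and known
limitations behind midnet. It is the package's own account of its science;
no empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Pipeline model

The object of analysis is a *functional* network: nodes are segmented
neuronal somas, edge weights are Spearman rank correlations of their calcium
activity over one condition window. Nothing here is assumed to reflect
synaptic (structural) or effective (directed) connectivity — the 10 Hz
sampling is too slow for lag-based directionality, and no lag or partial
correlation analysis is attempted.

### ΔF/F normalization

F₀ is the per-neuron **mean** of raw fluorescence over the baseline window.
The alternative, a low percentile, is exposed (`method="percentile"`) for
drifting baselines, but the mean is the default because it yields an exactly
testable invariant: the ΔF/F mean over the baseline window is 0 per neuron,
to float precision. Both condition windows are normalized against the
*baseline* F₀, so a drug-suppressed treatment window shows smaller
integrated ΔF/F rather than being re-referenced to its own mean. Raw traces
must be strictly positive; F₀ ≤ 10⁻⁶ is a hard error naming the neuron.
Frames are 0-based and windows half-open `[start, end)`.

### Integrated activity

"Total intensity per neuron" is the trapezoidal integral of signed ΔF/F over
the condition window, in ΔF/F·s (time step 1/frame rate). Signed integration
is the default — negative excursions subtract — because it is linear, which
the tests exploit; a rectified option integrates |ΔF/F| for users who prefer
an energy-like summary. The below-unity fraction counts neurons whose
treatment integral is strictly smaller than baseline; ties count as
not-below.

### Connectivity and thresholding

Spearman ρ is computed as the Pearson correlation of average-ranked traces
(standard tie handling). The matrix is symmetrized exactly, clipped to
[−1, 1] against float drift, and its diagonal forced to 0. A constant trace
makes ρ undefined for its pairs; those entries are set to 0 with a warning
rather than propagating NaN, which would poison every downstream metric.

The proportional threshold ranks the E = n(n−1)/2 unique pairs by **signed**
ρ descending and keeps the top ⌊pE⌋ with their weights, so the resulting
density is ⌊pE⌋/E exactly; ties at the cutoff break by (i, j) lexicographic
order for determinism. Signed ranking (not |ρ|) is the default because
empirical matrices in this preparation are predominantly positive and
anticorrelation is better read as dropout than as strength; magnitude
ranking is available via `rank_by="abs"`. The absolute threshold keeps
ρ ≥ t, and the densiometric sweep evaluates t = 0.05 … 1.00 in 0.05 steps
(20 points, non-increasing by construction).

### Topology metrics (weighted, undirected)

- **Density**: realized unique pairs / E. Binary by definition.
- **Clustering**: the Onnela geometric-mean form — weights scaled by the
  global maximum, C_i = 2/(k_i(k_i−1)) Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3} with k_i the
  binary degree, C_i = 0 for k_i < 2. It reduces exactly to the binary
  triangle fraction on 0/1 weights (tested against an independent
  implementation and against networkx).
- **Modularity**: Newman's weighted Q with resolution γ (default 1),
  maximized by Louvain with `restarts` (default 10) seeded runs, best Q
  kept; deterministic given the seed. Q itself is evaluated by our own
  matrix formula, cross-checked in the tests against exhaustive partition
  enumeration on ≤ 8-node fixtures. An edgeless network has undefined Q:
  the low-level function raises; `topology_report` records a missing value
  with a flag so DIV sweeps don't abort.
- **Assortativity**: Pearson correlation of endpoint node **strengths** over
  the edge list, each undirected edge contributing both orientations. A
  binary-degree variant is exposed for sensitivity checks. Zero endpoint
  variance (regular graphs) gives NaN with a flag, not an exception.

Because the weighted clustering/modularity formulas require nonnegative
weights, `topology_report` clips negative edges surviving a large-p
threshold to 0 before those metrics (logged and flagged); at the default
p = 0.15 on predominantly positive matrices this rarely triggers. Density is
computed before clipping.

### Comparison statistics

The unity deviation of a pair is the signed perpendicular distance of
(ρ_base, ρ_treat) to the line y = x: d = (ρ_treat − ρ_base)/√2, positive
favoring treatment. The 1/√2 factor is a geometric convention; the raw
difference is exposed, and because g₁, g₂, KS and Wilcoxon are all invariant
to positive rescaling, the choice cannot change any reported statistic
(asserted by test). Pairs are pooled across recordings before computing
distribution statistics.

Moments use population (biased) estimators: g₁ = m₃/m₂^{3/2} and excess
kurtosis g₂ = m₄/m₂² − 3, so a normal distribution scores 0; at the pair
counts this analysis runs on (10⁴–10⁵), bias-corrected variants are
numerically indistinguishable. The KS test compares d to a normal with the
*sample's* mean and SD — parameters are estimated, so the p-value is
optimistic in the Lilliefors sense and is reported as approximate. The
Wilcoxon signed-rank test of median 0 uses the normal approximation.

DIV trends are ordinary least squares of a metric on culture age, reporting
slope per day, r², and the two-sided p for slope ≠ 0; at least 3 distinct
ages are required, and a constant metric returns a flat trend (slope 0,
r² 0) rather than NaN. Group ANOVAs are deliberately not reimplemented:
they describe the original recordings, which are unavailable, and belong to
general statistics software.

## Synthetic culture model

The generator exists so every stage has ground truth. It emulates the
study's *conditions*, not its numbers.

**Spiking.** Each of `n_modules` modules owns a Poisson mother process at
rate `base_rate/share`; each member copies each mother spike independently
with probability `share` (the multiple-interaction construction). This gives
Poisson marginals at exactly `base_rate` and a within-module spike-count
correlation equal to `share`, in closed form — the reason this construction
was chosen over, e.g., a Hawkes process. An optional independent background
Poisson (`background_rate`, default 0) decorrelates members without changing
marginal-rate bookkeeping. Child RNG streams are derived per module and per
neuron from the root seed, so results are reproducible and independent of
evaluation order; everything is bit-deterministic given the spec.

**Composition.** 12% of neurons are dopaminergic (the immunocytochemical
fraction in this preparation), the rest GABAergic. D2-receptor expression:
all dopaminergic neurons (autoreceptors) and a configurable fraction
(default 1.0) of the GABAergic majority.

**Pharmacology.** Methamphetamine-evoked dopamine acting on D2 receptors is
collapsed into a single rate multiplier on D2+ neurons in the treatment
window: `drug_factor` (default 0.5, suppression). The sulpiride preset uses
`sulpiride_factor` (default 1.3 > 1): blockade removes the suppression and
disinhibits the network above baseline. No receptor kinetics, dopamine
diffusion, or concentration–response mapping is modeled; the presets encode
the *direction* of the reported effects only.

**Ageing.** The within-module copy probability decays geometrically with
culture age: share_eff = share · div_decay^(DIV − 9), anchored at DIV 9 (the
youngest age studied). With div_decay < 1 this makes mean pairwise
correlation decline across DIV — the direction of the empirical
connectivity decay — without asserting its magnitude.

**Fluorescence.** F(t) = f₀·(1 + A·(k ∗ s)(t)) + ε(t), where k is a
difference of exponentials with τ_rise = 0.1 s and τ_decay = 0.6 s
(literature-typical GCaMP6f; the study reports none), normalized to unit
peak so A = `amp_per_spike` (default 0.4) is the ΔF/F increment of an
isolated spike; ε is i.i.d. Gaussian with SD `noise_sd` (default 1.0 raw
units = 2% of the default f₀ = 50). Sampling is at 10 Hz over 120 s windows
(1200 frames), matching the acquisition protocol.

**Rates.** The study reports no firing statistics for these cultures;
`base_rate` = 1 Hz is a deliberate placeholder at the low end of spontaneous
culture activity, chosen once and not calibrated to any measured value.

**Movies.** Optional rendering draws each neuron as a Gaussian soma
(σ = radius/2, truncated at the ROI disk) scaled by its fluorescence, with
one global linear 8-bit quantization per movie (8-bit matches the upstream
processing of the real recordings) and a paired integer label mask.
Overlapping ROIs are rejected because they make the extraction ground truth
ambiguous. The render→extract round trip preserves per-neuron dynamics to
r > 0.99.

**Planted topologies** for metric recovery: `modular(k)` plants k dense
uniform(0.5, 1) blocks with no between-block edges; `disassortative` is a
pure unit-weight star (assortativity −1 exactly); `assortative` joins a
dense strong core clique with weak disjoint peripheral pairs and no
core–periphery edges, so all edges connect endpoints of similar strength.

### What the generator does not emulate

No spatial geometry of axons/dendrites, no photobleaching, drift or motion
artifacts, no bursting dynamics or refractoriness, no GABAergic sign
(inhibition is not modeled as negative coupling), and no coverslip-level
hierarchy (all pairs pool as if from one homogeneous experiment batch).
Passing tests therefore demonstrate the *estimators and their contracts* —
exact thresholding arithmetic, metric correctness against oracles, sign
reproduction of drug and ageing effects under the stated mechanisms — not
that real midbrain cultures obey the generative model, and not the study's
printed magnitudes (its means, r², skewness and F statistics derive from
recordings that are not public).

## Problem sizes and determinism

Tests and the acceptance script run simulations at 16–100 neurons, 30–120 s
windows at 10 Hz, 3 seeds, and DIV grids of 3–5 points — sizes chosen so
the full verification cycle completes in seconds while keeping estimation
error well below the effect sizes being sign-tested. All randomness funnels
through explicit seeds (simulation spec, Louvain restarts, acceptance
`--seed`); pipeline CSV output uses 17-significant-digit floats and
round-trip parsing, so re-running a configuration reproduces outputs
byte-identically and staged CLI runs equal the one-shot `all` run exactly.
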