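# Methods

## The model in brief

`leica` quantifies the complexity of time-resolved ("dynamic") functional
connectivity and fits a generative oscillator network to it. The analysis
chain is:

1. **Band-limited phase.** Each regional BOLD-like signal is demeaned,
   detrended, band-passed to 0.01–0.08 Hz and Hilbert-transformed, giving an
   instantaneous phase θ(n, t) per region.
2. **Phase coherence.** At each timepoint the N×N coherence matrix is
   dFC(m, n, t) = cos(θ(m, t) − θ(n, t)). Writing c = cos θ(:, t),
   s = sin θ(:, t), this equals ccᵀ + ssᵀ: symmetric, positive semidefinite,
   unit diagonal, rank ≤ 2.
3. **Leading-eigenvector compression.** Each dFC(t) is compressed to its
   leading eigenvector v₁(t) (unit norm, oriented so most elements are
   non-positive). Because the rank is at most two, the variance fraction
   ρ = λ₁/Σλ is ≥ ½ for every timepoint — the analytic identity the
   acceptance script re-measures. Concatenating v₁ over time and subjects
   gives the space–time matrix E. Two comparison compressions are provided:
   the vectorized upper triangle of dFC(t) (N(N−1)/2 rows) and the spatial
   mean (N rows); all three feed the identical downstream code.
4. **Dimensionality.** Rows of E are standardized; eigenvalues of their
   correlation matrix are compared with the Marčenko–Pastur upper edge
   σ²(1+√(1/q))², q = n/m, σ² = 1 by construction. The number k of
   eigenvalues above the edge estimates how many connectivity patterns recur
   above chance.
5. **Temporal ICA.** fastICA (log-cosh contrast, PCA whitening to k
   dimensions, max 1,000 iterations, tol 1e-6, seeded) extracts k temporally
   independent component time courses; components are ordered by mean
   absolute activity, sources standardized to zero mean/unit variance.
   Component sign is unidentifiable and reported as relative orientation;
   core regions of a map are those with |z| > 1.3 across regions, split by
   sign into the two opposing communities.
6. **Entropy.** Per-component Shannon entropies are estimated per subject;
   since ICA minimizes temporal dependence, the subject's joint entropy is
   the exact sum of component entropies (asserted bitwise). Groups are
   compared dimension-wise and on the joint entropy with a two-sided
   difference-of-means permutation test (10,000 label permutations by
   default, p = (1+#{|perm| ≥ |obs|})/(n_perm+1)), Hedges' g effect sizes,
   and step-up FDR (Šidák and Bonferroni available).
7. **Effective connectivity.** Each subject's entropy profile is fitted by a
   network of supercritical Hopf normal-form oscillators,
   dx = [(α − x² − y²)x − ωy + GΣᵢCᵢⱼ(xᵢ − x)]dt + β dW (and symmetrically
   for y), integrated by Euler–Maruyama. Couplings present in a structural
   template are free parameters in [0, c_max], optimized by global-best
   particle-swarm (w = 0.729, c₁ = c₂ = 1.494, 20 particles × 50 iterations
   by default) against the Euclidean distance between simulated and
   empirical component-entropy vectors.
8. **Group network inference.** Fitted directed matrices are compared
   edge-wise with pooled-variance t statistics; the network-based statistic
   thresholds |t|, finds connected components separately for the
   positive and negative contrasts (components on the undirected union of a
   signed edge set; tests stay per directed edge), and assigns each
   component a family-wise p-value from the permutation null of the maximal
   component edge count. Node in-/out-strengths (column/row sums) get
   per-node permutation tests with FDR. The t threshold has no data-driven
   choice; the sweep {4, 4.5, 5, 5.5} is run and reported side by side.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band | 0.01–0.08 | Hz | standard resting-state window; also averages out physiological noise |
| TR | user input (2.0 s synthetic) | s | never hard-coded; needed for Hz-domain filtering and ω estimation |
| filter | Butterworth order 2, zero-phase | — | see "Numerical choices" |
| n_permutations | 10,000 | — | headline test resolution 1/10,001 |
| entropy estimator | histogram differential, nats | — | see below |
| α (bifurcation) | 0 | — | critical regime between damped and oscillatory dynamics |
| G (global coupling) | 0.2 | — | operating point of the fitted network model |
| β (noise) | 0.02 | — | conventional amplitude for Hopf whole-brain models; exposed |
| dt / burn-in | 0.1 s / 20 s | s | stable at 0.01–0.08 Hz timescales; halving dt moves statistics < 2% |
| PSO | 20 × 50, w=0.729, c₁=c₂=1.494 | — | constriction-coefficient standard |
| c_max | 0.2 | — | coupling bound of the fitted template entries |
| NBS thresholds | 4, 4.5, 5, 5.5 | t | reported side by side; no data-driven choice exists |

**Entropy estimator.** The default is plug-in histogram entropy over
equal-width bins plus log(bin width) — a differential-entropy estimate in
nats — with Freedman–Diaconis bin count (Sturges below 64 samples), both
configurable, plus a discrete mode without the width correction. Reported
per-component values for near-Gaussian unit-variance sources sit just below
the Gaussian bound ½ln(2πe) ≈ 1.4189 nats, which the test suite verifies at
10⁶ samples. Absolute entropy values depend on the binning rule and log
base; only within-pipeline comparisons are meaningful.

## Numerical choices

- **Filter.** Zero-phase (forward–backward) Butterworth of order 2. An FIR
  kernel reaching 20 dB one octave outside a 0.01 Hz band edge needs ≈165
  taps — longer than a 175-volume series tolerates in zero-phase use. The
  squared response of the order-2 Butterworth gives ≈24 dB/octave; edge
  transients of the forward–backward pass are excluded when attenuation is
  measured.
- **Sign convention.** v₁ is flipped so that strictly more than N/2 elements
  are ≤ 0; at an exact tie the element sum decides; at zero sum the first
  nonzero element is made negative. Deterministic and idempotent.
- **Eigenvalue ties.** λ₁ = λ₂ within 1e-12 logs a warning and takes the
  solver's ordering; ties occur only on measure-zero inputs.
- **Hilbert edges.** The first and last ⌈T/20⌉ samples are flagged as
  edge-affected but kept (no trimming by default).
- **ρ on a PSD matrix.** Eigenvalues are clipped at zero before summing;
  tiny negative values are rounding noise.
- **Permutation p-values** use the +1 convention, so p is never 0 and the
  smallest attainable value is 1/(n_perm+1).
- **Stochastic EC objective.** Every objective evaluation draws a fresh
  simulation stream derived from (seed, evaluation counter); cost can be
  averaged over repeats (`n_repeats`, default 1). Non-finite costs penalize
  the particle with +∞ and the run continues. The global-best history is
  monotone non-increasing by construction.
- **Integrator guard.** |x| > 10⁶ raises an instability error naming dt.

## Dimensionality count and temporal autocorrelation

The Marčenko–Pastur null assumes independent columns. An eigenvector series
derived from band-limited signals is strongly temporally autocorrelated
(coherence patterns persist over several TRs), which widens the null spectrum and
biases the count upward on structure-free but band-limited data; the iid
null behaves exactly as theory predicts (mean spurious count ≤ 0.1 at
90 × 14,000 over 200 draws). `count_significant_dimensions` therefore keeps
the plain bound as the default (matching the published method) and offers
`autocorr_correction=True`, which replaces the column count with an
effective sample size n/τ (τ the mean integrated autocorrelation time of
the rows). The correction shrinks but does not remove the bias, and it
costs power on strongly persistent planted structure, so it is off by
default and the caveat stands: on real, oversampled data the count is best
read as an upper bound.

## What the synthetic generators emulate — and what they do not

- `synth_phase_communities` plants phase-locked region communities with
  distinct in-band carrier frequencies, slow phase diffusion, a switching
  dominance envelope (blocks ≈ 20 s), a deterministic anti-phase split
  inside each community (mirroring the two opposed communities a leading
  eigenvector separates), and independent band-limited noise. Group
  differences are planted through the variability (`amp_sd`) of a
  community's per-block activation level: spreading dominance across the
  idle-to-dominant range enriches that component's activity distribution
  and raises its differential entropy without changing the mean dominance
  schedule. This is the mechanism the end-to-end test detects at 10+10
  subjects, 300 volumes.
- `synth_hopf_cohort` simulates two groups from Hopf networks whose
  couplings differ on a planted edge set (scaled by 1 + effect size), with
  5% per-subject frequency jitter.
- `synth_ec_benchmark` builds the effective-connectivity recovery task:
  three reciprocally coupled node pairs with 2 mHz in-pair detuning, run
  above the bifurcation (α = 0.6, β = 0.01). Near-degenerate frequencies put
  each pair's coupling on its phase-locking transition, so the component
  entropies respond over the whole fitted range [0, 0.2] with variation well
  above the evaluation noise. At the empirical operating point (α = 0,
  noise-driven) the entropy cost is nearly flat in the couplings and a
  many-parameter fit is not identifiable at this scale; the benchmark
  regime is the designed exception, not the rule, which is why link-level
  effective-connectivity estimates on real data should be read as
  hypotheses rather than conclusions.

None of the generators include hemodynamic convolution, head motion,
scanner drift or spatially correlated noise; passing tests demonstrate the
statistical machinery under its stated assumptions, not robustness to
those real-data effects.

## Problem sizes used by tests

Unit and acceptance tests run the pipeline at 10 regions × 120–300 volumes
× 10 subjects per group, the dimensionality null at 90 × 14,000 × 200
draws, NBS calibration at 8 nodes × 12 + 12 subjects × 200 datasets
(n_perm = 500), and the recovery benchmark at 6 nodes × 10 subjects with
the default swarm settings — sizes chosen so the full suite completes on a
single desktop core while keeping every statistical check at the stated
replicate counts.

## Known limitations

- Absolute entropies are estimator-dependent; cross-study comparison
  requires identical binning and log base.
- The MP count is biased upward by temporal autocorrelation (see above).
- The entropy-distance objective identifies coupling only where entropy is
  sensitive to it; at criticality with many free parameters the fit is
  underdetermined, and per-edge estimates should not be over-read.
- The Hopf model omits transmission delays, neuromodulation and
  hemodynamics.
- NBS conclusions depend on the arbitrary t threshold; the sweep is
  reported, not optimized.
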