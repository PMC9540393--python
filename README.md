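# leica

Leading-Eigenvector Independent Component Analysis of dynamic functional
connectivity, with Hopf-network effective-connectivity fitting.

## What it is for

Resting-state fMRI connectivity changes from moment to moment. A standard
way to track it is the instantaneous phase-coherence matrix
dFC(m, n, t) = cos(θ(m, t) − θ(n, t)), where θ is the Hilbert phase of each
region's band-limited (0.01–0.08 Hz) signal. Each dFC(t) is rank ≤ 2, so its
leading eigenvector v₁(t) — which splits regions into two opposing
communities and always carries ≥ 50% of the eigenvalue mass — is a faithful
N-dimensional compression of an N(N−1)/2-dimensional object.

`leica` takes cohorts of parcellated BOLD time series and:

1. compresses them into the leading-eigenvector series **E** (or two
   comparison representations: vectorized dFC, spatial-mean dFC);
2. estimates how many connectivity patterns recur above chance by counting
   eigenvalues of **E**'s row correlation matrix above the Marčenko–Pastur
   edge σ²(1+√(1/q))²;
3. extracts that many temporally independent component time courses with
   fastICA;
4. computes per-component Shannon entropies and their exact sum, the
   subject's joint entropy, and compares groups with permutation tests,
   Hedges' g and FDR/Šidák/Bonferroni correction;
5. fits each subject's entropy profile with a network of coupled
   supercritical Hopf oscillators (dx = [(α−x²−y²)x − ωy + GΣᵢCᵢⱼ(xᵢ−x)]dt
   + βdW), optimizing the template-constrained couplings by particle swarm
   against the Euclidean entropy distance — a subject-level effective
   connectivity estimate;
6. compares fitted networks between groups with the network-based statistic
   (suprathreshold-t connected components, permutation family-wise p) and
   node in-/out-strength tests.

It is aimed at researchers analysing parcellated resting-state cohorts
(e.g. AAL-90; the package ships the region list) and at methodologists who
want a fully seeded, synthetic-data-validated reference implementation of
this pipeline. It starts from extracted regional time series: image
preprocessing and parcellation happen upstream.

## Worked example

Two synthetic 10-subject groups share three planted phase-locked
communities; the "patient" group's first community switches with much more
variable activation levels, which raises the entropy of the matching
component without changing anything else:

```python
from leica import LEICA, RunConfig
from leica.synthetic import SynthSpec, synth_phase_communities

base = SynthSpec(n_regions=10, n_timepoints=300, tr=2.0,
                 n_subjects_per_group=10, n_communities=3,
                 coupling_strength=1.0, noise_sd=0.2,
                 amp_sd=(0.05, 0.05, 0.05), seed=1000)
controls = synth_phase_communities(base)
patients = synth_phase_communities(base.replace(amp_sd=(1.5, 0.05, 0.05),
                                                seed=2000))

res = LEICA(controls, patients, RunConfig(n_permutations=2000, seed=0)).fit()
print(res.summary())
```

```
Leading-eigenvector independent component analysis
==========================================================
representation:      eigenvector
subjects:            10 + 10
components (MP):     3
rho (min / mean):    0.5041 / 0.7182
joint entropy:       3.0139 (mean over subjects, nats)
----------------------------------------------------------
 dim  mean diff        p    p_adj        g
   1    -0.1920   0.0015   0.0045  -2.0726 *
   2    -0.0138   0.6357   0.9095  -0.2150
   3     0.0035   0.9095   0.9095   0.0521
joint              0.0055           -1.3103
(* significant after fdr_bh at alpha=0.05)
```

Reading the output: the Marčenko–Pastur bound recovers the three planted
communities (`components (MP): 3`); every leading eigenvector captured at
least half the variance (`rho min 0.5041`); dimension 1 — the planted one —
has higher entropy in the second group (mean difference −0.192 nats,
permutation p = 0.0015, surviving FDR, Hedges' g = −2.07), and the joint
entropy difference is significant too (p = 0.0055). The other dimensions
are clean.

The same analysis runs from the shell (`leica run --group1 ... --group2
... --tr 2.0 --out report/`), and `leica dfc / decompose / entropy /
compare / fit-ec / nbs / simulate / synth` expose the stages individually,
resumable from the CSV/JSON intermediates each one writes — effective
connectivity fitting is orders of magnitude slower than the statistics, so
it is opt-in. See `docs/methods.md` for the model, estimator and parameter
details.

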