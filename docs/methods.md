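# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the design decisions taken where several reasonable
choices existed, and the limits of what the synthetic-data tests can show.

## Dynamic mean-field model

Each brain region contains an excitatory (NMDA) and an inhibitory (GABA-A)
population described by mean synaptic gating variables S_E, S_I ∈ [0, 1].
Input currents (nA) are

    I_E = w_E I_0 + w+ w_NMDA S_E + G w_NMDA Σ_p C_np S_E,p − J_n S_I
    I_I = w_I I_0 + w_NMDA S_E − S_I

with C the structural connectome, G the global coupling and J_n the
region-specific feedback-inhibition weight.  Currents become firing rates
through the sigmoidal-linear response

    H(I) = g (I − I_thr) / (1 − exp(−d g (I − I_thr)))

whose removable singularity at I = I_thr is replaced by its limit 1/d.
Gating evolves as

    dS_E/dt = −S_E/τ_NMDA + (1 − S_E) γ r_E + σ ν(t)
    dS_I/dt = −S_I/τ_GABA + r_I + σ ν(t)

Note the first term of the inhibitory equation: we decay S_I (not S_E) with
τ_GABA, the standard form of this model lineage.

Population defaults (overridable): g_E = g_I = 310 nC⁻¹, d_E = 0.16,
d_I = 0.087, I_thr_E = 0.403 nA, I_thr_I = 0.288 nA, w_E = 1, w_I = 0.7,
w+ = 1.4, w_NMDA = 0.15, I_0 = 0.382 nA, τ_NMDA = 0.1 s, τ_GABA = 0.01 s,
γ = 0.641, σ = 0.01 nA.

**Integration.**  Euler–Maruyama with default dt = 0.1 ms (configurable up
to 1 ms).  The integrator works internally in milliseconds — the
conventional units of this model class — so the noise increment per step is
σ√(dt_ms), independently per pool and region.  Gating is clamped to [0, 1]
after each step.  Trajectories are bit-reproducible for a given seed (the
noise stream comes from the compiled kernel's seeded generator).  The state
is recorded at `record_dt` (default 1 ms) as instantaneous samples.
Statistics discard a 10-s transient by convention.

## Feedback Inhibition Control

FIC tunes J_n so every region's long-run mean excitatory rate sits at the
~3.06 Hz operating point of the asynchronous regime (the rate H_E yields at
a mean input of I_thr_E − 0.026 nA), keeping rates in the 3–10 Hz band.
Three stages:

1. *analytic initialisation* — the noise-free steady state is solved
   exactly: the target rate fixes S_E; the inhibitory fixed point
   S_I = τ_GABA H_I(·) is found by scalar root-finding; J_n then follows in
   closed form from the current balance (at σ = 0 this is already the
   answer, and for G = 0 it reduces to the common isolated-region value);
2. *stochastic-approximation refinement* — simulation windows (8 s, then
   16 s) with a Robbins–Monro decreasing gain move each J_n by the observed
   error divided by the region's mean inhibitory gating (dI_E/dJ = −S_I
   exactly).  Early iterations use the current error; later iterations use
   the rate error divided by the local slope H′, which removes the upward
   bias that noise rectification through the convex response function
   otherwise leaves in the mean rate.  The final J averages the last
   iterates (Polyak–Ruppert);
3. *validation* — a 32-s window checks max per-region |mean r_E − target|
   against `tolerance` (nA at the local slope; default 0.015 nA ≈ 1.4 Hz,
   sized above the estimator noise of a 32-s window so the flag marks real
   failures).  A failed check returns the best-effort J flagged
   `converged=False`, and grid-search fitting excludes such points.

## Hemodynamics and filtering

The Balloon–Windkessel model maps r_E to BOLD per region:

    ds/dt = 0.5 r_E + 3 − κ s − γ_h (f − 1),   df/dt = s,
    τ dv/dt = f − v^{1/α},
    τ dq/dt = f (1 − (1−ρ)^{1/f})/ρ − q v^{1/α}/v,
    B = V0 [k1 (1−q) + k2 (1 − q/v) + k3 (1 − v)].

Constants follow the standard Friston/Stephan set: κ = 0.65 s⁻¹,
γ_h = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.02, k1 = 7ρ, k2 = 2,
k3 = 2ρ − 0.2; all overridable, and every output records the set used.  The
v and q equations are advanced in log-space at the recorded neuronal step so
both stay positive; the readout is sampled at `out_dt` (default 0.72 s, a
typical fMRI repetition time).  BOLD is band-passed 0.01–0.1 Hz with a
zero-phase (forward–backward) order-2 Butterworth after demeaning; the same
filter serves simulated and empirical series.

## Fitting the global coupling

Three statistics summarise the dynamics of a band-passed BOLD series:

* **metastability** — the population SD over time (divide by N; pinned by
  SD({0.4, 0.6}) = 0.1) of the Kuramoto order parameter computed from
  detrended, Hilbert-transformed phases;
* **phase-consistency distribution** — Pearson correlations between the
  strictly-upper triangles of instantaneous phase-coherence matrices
  cos(φ_j − φ_k) over time pairs (all pairs up to 2,000 time points, a
  seeded 2×10⁶-pair subsample beyond);
* **FCD distribution** — correlations between windowed FC matrices (80-s
  windows stepping 40 s, trailing partial windows dropped), summarised by
  the strictly-upper triangle of the FCD matrix.

`fit_G` scans a grid (default 0–2.5 in steps of 0.025), recalibrating FIC
and simulating `n_repeats` runs per point, and compares simulation to target
by |Δmetastability| and the Kolmogorov–Smirnov distances of the two
distributions.  Selection rule (recorded in the result): by default the grid
is restricted to points whose metastability and phase agreement lie within
110% of their own minima and the argmin of the FCD KS distance is taken
there; when that gate is empty the fallback — also directly selectable — is
the argmin of the sum of min–max-normalised curves.  On a 30-region
synthetic connectome with targets generated by the model itself at G = 1.0
(grid 0.8–1.2, step 0.05, two repeats, 370-s runs), the search returns
G_opt = 1.0.

## Network extraction and occupancy entropy

A (binned) region × time series is z-scored per region and reduced to
events at upward crossings of +1 SD (`level` mode marks all supra-threshold
samples instead).  The binary event matrix is z-scored again per region
(constant rows are excluded and recorded).  The number of networks is the
count of eigenvalues of the region × region event correlation matrix above
the Marchenko–Pastur upper edge (1 + √(n/T))²; no Tracy–Widom refinement is
applied.  Networks are unmixed by FastICA (logcosh contrast,
symmetric/parallel updates, PCA whitening to the component count) run with
time points as samples, so the spatial maps are the unit-norm, sign-fixed
columns of the mixing matrix.  Activity is the quadratic projection
A[c, b] = (w_c · E_b)², applied to the *binarized* event matrix by default
(the z-scored variant is switchable); occupancy is p(c) = Σ_b A_cb / Σ A,
and the entropy H = −Σ p ln p (0 ln 0 := 0) is normalised by ln(count) for
cross-scale comparison.  Scale sweeps run this chain per (spatial scale,
temporal bin, replicate); cells with fewer than two networks are marked
invalid rather than dropped silently.  Spatial scales are compared pairwise
with two-sided Mann–Whitney rank-sum tests (signed-rank selectable for
seed-paired replicates) under Benjamini–Hochberg correction.

## Synthetic data

**Connectomes** come from a stochastic block model: contiguous modules,
within-module edges 4× more probable than between-module edges at a given
overall density, log-normal (fiber-count-like) weights, symmetrised, zero
diagonal; empty rows (possible at very low density) are repaired with one
within-module edge and a warning.  Weights are rescaled so the mean row sum
equals `weight_scale` (default 0.25).  The default was chosen once so that
the FIC-calibrated network keeps the asynchronous 3–10 Hz contract over the
explored coupling range: at mean row sum 1.0 the recurrent excitation loop
escapes to a high-rate attractor already below G ≈ 1.

**Ground-truth BOLD** plants k spatial maps with disjoint supports (~20% of
regions each, positive uniform loadings, unit-norm and hence orthonormal).
A hidden state sequence is drawn i.i.d. per sample from a given occupancy
vector; the active map is scaled by a per-sample log-normal amplitude
(keeping the planted component structure full-rank even though exactly one
network is on at a time), Gaussian noise of SD 1/snr is added, and the
result is band-passed 0.01–0.1 Hz.  Supports are positive and disjoint
because upward-crossing events cannot represent negative loadings — with
signed overlapping maps the matched recovery tops out near |r| ≈ 0.75,
whereas this construction reaches |r| ≥ 0.98 at snr 10.

**What the generator does not emulate.**  Hemodynamic convolution of the
state sequence, spatial autocorrelation of parcels, subject-level
variability, scanner noise spectra, and head-motion artifacts.  Passing the
recovery tests therefore demonstrates the correctness of the extraction
chain on band-limited signals with planted low-rank structure, not
performance on real fMRI.

**A structural limit of occupancy recovery.**  The point process z-scores
every region and thresholds at +1 SD, which selects a similar upper
quantile of every region's distribution regardless of how often its network
is on; for a two-level signal with duty cycle 0.5 the active level sits
*exactly* at +1 SD.  Occupancy estimated through events is therefore
compressed toward uniform: on ground truth planted at (0.5, 0.25, 0.25)
(H_norm = 0.946) the pipeline stably measures H_norm ≈ 0.999.  This is a
property of the event/projection definitions themselves, not of this
implementation; the corresponding recovery tolerance is asserted as
specified and currently fails, with the analysis recorded here.  Entropy
comparisons *across* scales remain meaningful because every cell carries
the same compression.

## Problem sizes

Desk-scale defaults used by the test-suite and reproduction script: 30–60
regions, 120–600 s of simulated activity at dt = 0.1 ms, 10-s transients,
two or three replicates per condition, and the coarse coupling grid
0.8–1.2 × 0.05 for the self-recovery check.  The full protocol of the study
this models (hundreds of regions, dozens of iterations, the 0–2.5 × 0.025
grid) is supported through configuration but is cluster-scale.

## Known limitations

* No conduction delays, regional parameter heterogeneity, AMPA-resolved
  kinetics, or stimulation protocols in the DMF model.
* No nonlinear neurovascular coupling variants or regional hemodynamic
  variability; no physiological fMRI noise model.
* The grid search is the only fitting method (no gradient or Bayesian
  estimation), matching the source methodology.
* Normalized occupancy entropy at 30–60 regions carries replicate noise of
  the same order as its variation across temporal bins, so curve-shape
  claims at desk scale are weak; the temporal-scale sweep is exposed and
  tested for mechanics, with its scientific claim treated as a soft,
  cluster-scale target.
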