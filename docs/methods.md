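# Methods

## Model

A liver-on-chip (or static spheroid well) is represented by well-mixed
compartments: one or two media chambers, an interstitial space and the
aggregate intracellular space of the seeded hepatocytes. Drug moves between
compartments by passive diffusion and partitions according to thermodynamic
equilibrium; metabolism acts only on intracellular drug, at rate
`CL_c · C_c` (CL_c in mL/min). The system is linear throughout — no
saturable metabolism — which matches the concentration range of depletion
assays (~1 µM doses).

With `CL_c = 0` the volume vector `(V_m, V_i, V_c)` is a left null-vector of
the rate matrix, so total drug mass is conserved; with `CL_c > 0` it decays
monotonically. The matrix is Metzler (non-negative off-diagonals), so
concentrations stay non-negative and all eigenvalues have non-positive real
part. These three properties are enforced as tests.

Two-chamber chips add a second media compartment coupled to the first by the
mixing flow `Q_mix` (`±Q_mix/V` exchange terms); cells sit on chamber 1 and
the reported media concentration is the volume-weighted chamber mean, which
is what a recirculating sampling port sees.

An asymmetry worth flagging: the efflux rate constant `k4` is the *product*
`K_water_cell · PA_cell_int`, so a lipophilic compound (large cell:water
partition coefficient) leaves the cell compartment quickly and its
steady-state intracellular level `C_c/C_i = k3/k4 = K_water_int/K_water_cell`
is *low*. This is the mechanism by which the model attributes slow apparent
depletion to limited intracellular exposure rather than to slow metabolism.

## Solvers and numerics

The closed-form solution `C(t) = X e^{Λt} X⁻¹ C₀` is used whenever the
eigenvector matrix is well conditioned; a condition number above 1e8
triggers a logged fallback to LSODA (rtol 1e-8, atol 1e-10 by default).
Batched eigendecomposition (numpy's stacked `eig`) powers the Sobol analysis
(~11k simulations per call in well under a second).

The intracellular volume is tiny (3.4e-9 mL/cell, so ~1e-3 mL for 3e5
cells) against its exchange rates, giving trajectories a sub-second boundary
layer at t = 0. Uniform time grids therefore make trapezoidal AUCs
first-order accurate (1.5% error at 61 points). The default simulation grid
(`model.simulation_grid`) is log-graded over the first minute (60 points
down to 1e-4 min) and uniform beyond (121 points to t_end), restoring
~1e-6 relative AUC accuracy at ~180 points. Observation times are merged
into the grid exactly, so fitted predictions are never interpolated.

Time is minutes everywhere internally; readers converting from hours do so
on ingest. Concentrations are µmol/mL.

## Compound parameters

Six downstream parameters are derived from logP, MW and fu_media. The
concrete relations used here are the package's own,
kept deliberately simple and monotone, with every constant in
`livertwin/constants.py`:

- **Partitioning** — composition-based tissue:water coefficients
  `K = P·(V_nl + 0.3·V_ph) + (V_w + 0.7·V_ph)` with `P = 10^logP_eff`,
  using a plasma-like composition for the interstitium and a liver-like one
  for the cell; media is protein-free water (its binding is carried by
  fu_media), so `K_int_med` numerically equals `K_water_int`.
- **Ionisation** — a fixed per-class offset on the effective logP
  (−1.0 for acids, −0.5 for bases): ionised species partition into neutral
  lipid less avidly than their logP suggests. The class also scales the
  candidate Kp_uu grid (0.5× acids, 3× bases — bases accumulate by
  lysosomal trapping).
- **Permeability** — `P = P0 · 10^(a·logP_eff) · (MW_ref/MW)^b`, with a
  shallower logP slope and square-root MW dependence for the endothelial
  barrier (a=0.2, b=0.5, P0=5e-3 cm/min) than for the cell membrane (a=0.4,
  b=1, P0=1e-3 cm/min). PA products multiply the transcellular permeability
  by the aggregate membrane area (cell number × 1.1e-5 cm²); the same
  membrane bounds both directions, so `PA_int_cell = PA_cell_int` and all
  directional asymmetry comes from the partition coefficients.
- **fu_cell** — a hepatocyte-binding form
  `fu = 1/(1 + 125·V_R·10^(0.072·L² + 0.067·L − 1.126))` with V_R = 0.005.
  The quadratic argument is clamped at its vertex (L ≈ −0.47) so the
  prediction is monotone non-increasing in logP; below the vertex binding
  is negligible anyway (fu > 0.95). A second QSAR slot exists in the
  interface but is deliberately not implemented.

P0 values were chosen so that a mid-range compound (logP 2, fu 0.5) on the
CnBio-style preset depletes by ~50–80% over six hours at plausible
clearances, matching the shape of published chip depletion curves. These
relations are stand-ins for a full physiologically based parameterisation;
absolute partition/permeability values should not be over-interpreted — the
estimation and IVIVE machinery only requires them to be positive, monotone
and consistent between simulation and fitting.

## Estimation

The objective is the sum of squared *relative* residuals over the observed
media series, `Σ((obs−pred)/pred)²`, appropriate for depletion data spanning
orders of magnitude, plus (weight 1, configurable) the squared relative
Kp_uu anchor residual when an observed Kp_uu is available. Predictions that
are non-positive or non-finite at observation times receive a large finite
penalty (1e12) rather than NaN, keeping the simplex well-defined.

Free parameters (default `CL_c` and the media/interstitium exchange area
`SA`; optionally `P_endothelial`) are optimised on the log scale — enforcing
positivity without constraints — by Nelder–Mead (adaptive simplex,
xatol 1e-8, max 2000 iterations) from 5 seeded starts: the first at the
nominal values, the rest log-uniform over [1e-4, 10] mL/min for `CL_c` and
lognormally dispersed around the nominals for the others. The best start
wins; the coefficient of variation of `CL_c` across starts is reported and
a CV above 20% sets an identifiability flag (with media-only observations
and low permeability, uptake and clearance trade off).

When no observed Kp_uu exists, a grid of candidates
({0.1, 0.3, 1, 3, 10} × ionisation factor) is scanned with a full
multi-start fit each; the lowest-cost grid point is kept and the whole grid
is reported. The ratio `SF = Kp_uu,obs / Kp_uu,pred` at the optimum is the
compound-specific scaling factor used in the human scale-up. The fit report
(JSON) carries every option and the seed, so runs are exactly reproducible.

## Sensitivity

Output functional: AUC of the intracellular concentration over the window
(the quantity the Kp_uu anchor consumes); a `C_c(t_end)` endpoint mode is
available and gives the same qualitative ranking. Local indices are
normalised forward differences at +10% (central differences available);
global indices are first/total-order Sobol indices over uniform
[0.1×, 10×] ranges, Sobol'-sequence sampled, with a seeded percentile
bootstrap (100 resamples) for CIs. `n_base` must be a power of two; values
below 64 are accepted but flagged.

At the package's reference baseline — an uptake-limited configuration
(logP 2 neutral, MW 300, fu_media 0.1 on the CnBio preset, CL_c
0.1 mL/min) — clearance dominates both locally and globally, and the local
ranking continues with the uptake chain (fu, P_endothelial, SA, each
S ≈ +0.53). Globally those three saturate over the 0.1–10× sweep (once
uptake stops being limiting, more permeability changes little), so
non-saturating partition coefficients overtake them in total-order rank.
This regime dependence is intrinsic to the model; rankings should always be
read against the stated baseline.

## IVIVE

`CL_int(u),H = (CL_c/N_cells)·HC·LW/fu_inc·SF` with HC = 120e6 cells/g
liver and LW = 25.7 g liver/kg body weight, then the well-stirred model
with Q_H = 20.7 mL/min/kg and `fu_b` = measured value or `fu_p/Rbp`. For
twin-derived clearances `fu_inc` defaults to 1 — media binding already acts
inside k1, and dividing again would double-count it; for conventional
one-compartment clearances `fu_inc` defaults to the measured media unbound
fraction, the standard correction for a lumped estimate. Both defaults are
overridable. Benchmark summaries report mean/SD/CV of predicted:observed
ratios, the average fold error `AFE = 10^mean(log10 ratio)`, the fractions
within 1.5- and 3-fold of unity, and a kernel-density curve of the ratios
(for plotting only).

## Synthetic data

The generator simulates the model at known parameters and applies
multiplicative lognormal noise, median-unbiased at the design CV — the
natural error model for relative-residual fitting. Defaults: 8 samples over
0–360 min, triplicate, CV 10% (fits consume the replicate-mean series, as
depletion assays are usually analysed). The benchmark panel draws compounds
with logP ∈ [−1, 5], MW ∈ [200, 500], fu_media ∈ [0.05, 1] and random
ionisation across the four quantitative chip presets; per-cell clearances
are log-spaced (with seeded jitter) over 2.5 decades, and the resulting
whole-chip CL_c span is stretched to at least 100-fold if chip cell-number
differences compress it. Each member carries paired "observed" Kp_uu and
human clearance values computed from its own ground truth, so the noiseless
end-to-end predicted:observed target is exactly 1.

What the generator does *not* emulate: assay-plate binding and evaporation,
metabolite interference in quantification, inter-donor variability in cell
activity, time-dependent enzyme loss, and model mismatch (data are generated
by the same three-compartment structure that is fitted). Passing recovery
tests therefore demonstrates estimator correctness and identifiability under
the stated noise, not robustness to structural error in real chips.

Under 10% lognormal noise the minimised relative-residual objective has a
statistical floor of roughly `(n_points − n_free) · CV²/n_replicates`
(~0.02 for the default design); per-fit objectives below 0.01 are only
reachable when measurement noise is a few percent, as it is in well-behaved
published depletion data sets.

## Limitations

- Partition/permeability/fu_cell relations are simple QSPRs, not a full
  PBPK parameterisation; only one partitioning method is implemented
  (interfaces for the alternatives raise `NotImplementedError`).
- No active (transporter-mediated) uptake and no saturable metabolism.
- The Dynamic42 preset is placeholder geometry and warns on load.
- Point estimation only: uncertainty is summarised by the multi-start
  spread, not by a posterior.
- Whole-body PBPK simulation is out of scope; the predicted human hepatic
  clearance is the hand-off value such models consume.
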