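# livertwin

Digital-twin simulation and clearance estimation for liver-on-chip and
hepatocyte-spheroid drug-depletion assays, with in vitro – in vivo
extrapolation (IVIVE) to human hepatic clearance.

## The problem

Drug developers measure how fast hepatocytes clear a compound by following
its depletion from culture media on a liver-on-chip or in a spheroid plate.
The conventional analysis treats the whole system as one well-mixed
compartment, so permeability, partitioning and metabolism are lumped into a
single "clearance" — and the resulting human predictions are systematically
biased. `livertwin` instead maps the hardware (media chambers, flows, cell
load) and the biology (interstitial and intracellular spaces) onto an
explicit compartmental model, so that the *intrinsic* metabolic clearance of
the cells can be separated from passive transport.

## The model

Concentrations in media (m), interstitium (i) and the intracellular space
(c) follow linear mass balances:

    dC_m/dt = -(k1/V_m) C_m + (k2/V_m) C_i
    dC_i/dt =  (k1/V_i) C_m - ((k2+k3)/V_i) C_i + (k4/V_i) C_c
    dC_c/dt =  (k3/V_c) C_i - ((k4+CL_c)/V_c) C_c

with rate constants assembled from compound- and chip-specific parameters:

    k1 = fu_media · P_endothelial · SA_med_int_liver      k2 = k1 / K_int_med
    k3 = K_water_int · PA_int_cell                        k4 = K_water_cell · PA_cell_int

The linear system `C' = A·C` is solved in closed form by eigendecomposition
(`C(t) = X e^{Λt} X⁻¹ C₀`), with an automatic fallback to a stiff
integrator. `CL_c` (mL/min, intrinsic on-chip clearance) and the exchange
area `SA` are estimated by Nelder–Mead multi-start minimisation of the
relative-residual objective `ssq = Σ((obs−pred)/pred)²`, optionally anchored
by an observed unbound partitioning coefficient
`Kp_uu = AUC(i+c)/AUC(m) · fu_cell/fu_media`. Human scale-up uses the
hepatocellularity route and the well-stirred liver model:

    CL_int(u),H = (CL_c / N_cells) · HC · LW / fu_inc · SF,   HC = 120e6 cells/g, LW = 25.7 g/kg
    CL_H = Q_H · fu_b · CL_int(u),H / (Q_H + fu_b · CL_int(u),H),   Q_H = 20.7 mL/min/kg

Chip presets (CnBio-style recirculating chip, two-chamber Javelin-style
chip, two static spheroid formats) ship as YAML files; a seeded synthetic
module generates depletion panels with known ground truth for testing and
benchmarking. Sensitivity of intracellular exposure to the nine inputs is
available locally (normalised one-at-a-time) and globally (Sobol indices,
Saltelli-style estimation with bootstrap CIs).

## Worked example

```sh
python examples/fit_clearance.py
```

```
true CL_c               : 0.05 mL/min
digital-twin estimate   : 0.0512 mL/min (ssq 0.0254, SA 3.06 cm², converged True)
Kp_uu predicted/observed: 1.621 / 1.621 -> SF 1.000
one-compartment estimate: 0.0058 mL/min
```

A triplicate depletion series is simulated on the CnBio-style chip at a true
clearance of 0.05 mL/min with 10% lognormal noise. The digital twin recovers
the intracellular clearance within ~2% and co-estimates the exchange area
(3.06 cm² vs 3.0 true); the predicted Kp_uu matches the observed one, so the
compound-specific scaling factor is 1. The conventional one-compartment fit
reports 0.006 mL/min — nearly ten-fold low — because depletion is
rate-limited by uptake across the endothelial barrier, which the lumped
model cannot distinguish from metabolism. The other scripts in `examples/`
cover simulation, compound-parameter derivation, sensitivity analysis and
the end-to-end IVIVE benchmark; a thin CLI (`livertwin simulate|fit|
sensitivity|ivive|generate|panel`) wraps the same functions for scripted
runs with config files and run manifests.

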