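"""Estimate intrinsic on-chip clearance from a noisy depletion series.

Generates a synthetic triplicate depletion experiment at known clearance
(0.05 mL/min, 10% lognormal noise), then fits the digital twin by
Nelder-Mead multi-start with the Kp_uu anchor and compares against the
conventional one-compartment log-linear fit.
"""

import livertwin as lt

chip = lt.load_chip_preset("cnbio")
compound = lt.CompoundRecord(name="probe", logp=2.0, mw=350.0, fu_media=0.5, ionisation=0, rbp=1.0)

exp = lt.generate_depletion(chip, compound, cl_c=0.05, seed=7)
# an observed Kp_uu (here: computed from the ground truth) anchors the fit
pp = lt.compound_parameters(compound, chip)
truth = lt.solve_analytic(exp.params, exp.c0, lt.simulation_grid(360.0))
kpuu_obs = lt.predict_kpuu(truth, pp.fu_cell, compound.fu_media)

fit = lt.fit_twin(
    exp.design.times_min, exp.observed_mean, chip, compound,
    kpuu_obs=kpuu_obs, c0=exp.c0, options=lt.FitOptions(seed=7),
)
conv = lt.fit_one_compartment(exp.design.times_min, exp.observed_mean, chip.media_volume_ml)

print(f"true CL_c               : 0.05 mL/min")
print(f"digital-twin estimate   : {fit.cl_c_hat:.4f} mL/min "
      f"(ssq {fit.ssq:.3g}, SA {fit.sa_hat:.2f} cm², converged {fit.converged})")
print(f"Kp_uu predicted/observed: {fit.kpuu_pred:.3f} / {fit.kpuu_obs:.3f} -> SF {fit.sf:.3f}")
print(f"one-compartment estimate: {conv.cl_c:.4f} mL/min")
print(
    "\nThe twin recovers the intracellular clearance; the one-compartment fit "
    "reports the slower,\nlumped media-loss clearance because uptake across the "
    "endothelial barrier rate-limits depletion."
)
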