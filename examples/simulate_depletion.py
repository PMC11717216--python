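"""Simulate on-chip drug depletion for a preset chip and a test compound.

Builds the three-compartment kinetic model for the CnBio-style chip, doses
1 µM into the media and prints the concentration in each compartment over
six hours. With clearance on, media concentration falls as drug crosses into
the (tiny) interstitial and intracellular spaces and is metabolised there.
"""

import numpy as np

import livertwin as lt

chip = lt.load_chip_preset("cnbio")
compound = lt.CompoundRecord(name="probe", logp=2.0, mw=350.0, fu_media=0.5, ionisation=0, rbp=1.0)

pp = lt.compound_parameters(compound, chip)
params = lt.build_rate_constants(pp, chip, compound.fu_media, cl_c=0.05)
print(f"rate constants [mL/min]: k1={params.k1:.4g} k2={params.k2:.4g} "
      f"k3={params.k3:.4g} k4={params.k4:.4g} CL_c={params.cl_c}")

times = np.linspace(0.0, 360.0, 7)
traj = lt.solve_analytic(params, 1e-3, times)

print(f"\n{'t [min]':>8} {'media':>12} {'interstitium':>14} {'intracellular':>14}   [µmol/mL]")
for t, cm, ci, cc in zip(traj.times, traj.c_m, traj.c_i, traj.c_c):
    print(f"{t:8.0f} {cm:12.3e} {ci:14.3e} {cc:14.3e}")

print(
    f"\n{100 * (1 - traj.c_m[-1] / traj.c_m[0]):.0f}% of the dose left the media in 6 h; "
    "the intracellular level stays far below the media level because the\n"
    "cell:water partition coefficient drives fast efflux (k4 > k3) — the "
    "uptake limitation the three-compartment model makes explicit."
)
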