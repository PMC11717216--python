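"""Local and Sobol sensitivity of intracellular exposure.

Evaluates, at an uptake-limited reference configuration, how the AUC of the
intracellular concentration responds to the nine model inputs: one-at-a-time
+10% perturbations (signed, normalised) and global variance-based Sobol
indices over 0.1-10x ranges.
"""

import livertwin as lt

chip = lt.load_chip_preset("cnbio")
compound = lt.CompoundRecord(name="sens_probe", logp=2.0, mw=300.0, fu_media=0.1, ionisation=0, rbp=1.0)

problem = lt.TwinSensitivityProblem(chip, compound, cl_c=0.1)
report = lt.sobol_sensitivity(problem, n_base=1024, seed=0, n_boot=50)
report.local = lt.local_sensitivity(problem.evaluate, problem.baseline)

print(f"{'parameter':>18} {'local S':>9} {'sobol 1st':>10} {'sobol total':>12}")
for name in sorted(report.parameters, key=lambda k: -abs(report.sobol_total[k])):
    print(
        f"{name:>18} {report.local[name]:9.3f} "
        f"{report.sobol_first[name]:10.3f} {report.sobol_total[name]:12.3f}"
    )

print(
    "\nClearance dominates (negative sign: more clearance, less intracellular "
    "exposure). Locally, the\nuptake chain fu x P_endothelial x SA comes next; "
    "globally the partition coefficients gain weight\nbecause their effect does "
    "not saturate over the 0.1-10x sweep."
)
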