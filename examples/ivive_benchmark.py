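"""End-to-end benchmark on a synthetic compound panel.

Generates a 12-compound panel across the chip presets (known ground truth,
10% lognormal noise), fits every depletion series with both the digital twin
and the conventional one-compartment model, scales each fitted clearance to
a human hepatic clearance (hepatocellularity scale-up + well-stirred model),
and summarises predicted:observed ratios per method.
"""

import livertwin as lt

panel = lt.generate_benchmark_panel(12, seed=0)
run = lt.run_panel(panel, options=lt.FitOptions(seed=0))

for tag, s in run.summaries.items():
    print(
        f"{tag:>13}: n={s.n} mean ratio={s.mean_ratio:.2f} CV={s.cv_percent:.0f}% "
        f"AFE={s.afe:.2f} within 1.5-fold: {100 * s.frac_within_1_5:.0f}%"
    )

print(
    "\nA mean ratio and AFE near 1 mean unbiased human-clearance prediction. "
    "The digital twin separates\nmetabolism from uptake and partitioning, so its "
    "ratios centre on 1; the conventional route lumps\nall processes into one "
    "clearance and inherits whatever bias that lumping introduces."
)
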