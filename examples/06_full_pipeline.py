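"""End-to-end run: generate a small synthetic experiment, fit every curve,
and print the survival and cohort-ratio reports with a reproducibility
manifest.
"""

import radpop as rp

cfg = rp.RunConfig(
    design=rp.ExperimentDesign(
        doses=(0.0, 5.0, 10.0),
        seeding_densities=rp.ExperimentDesign().seeding_densities[-3:],
        seed=3,
    ),
    n_starts=60,
    seed=1,
)
bundle = rp.run_analysis(cfg)

print(f"Fitted {len(bundle['fits'])} curves "
      f"({len(bundle['failures'])} failures isolated).")
print("\nSurviving fractions (percent, mean ± sd across seeding densities):")
print(bundle["survival"].to_string(index=False))
print("\nTerminal-compartment ratios at 144 h:")
print(bundle["ratios"].to_string(index=False))
print(f"\nManifest: config {bundle['manifest']['config_hash'][:12]}…, "
      f"results {bundle['manifest']['results_hash'][:12]}… "
      f"(rerunning with the same config and seed reproduces both hashes).")
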