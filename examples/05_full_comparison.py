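"""Run the end-to-end comparison experiment at desk scale.

Executes phantom -> DRR -> {neural variants, FDK} -> volumes -> metrics in
one call and prints the comparison table.  At this tiny scale (32^3, 20
views, short training) the numbers are far below publication scale but the
relative behaviour of the variants is already visible.  Expect several
minutes of runtime for the full variant set; the default here trains only
the hash variant next to FDK.
"""

from mufield.experiment import ExperimentConfig, run_experiment, tiny_profile

config = tiny_profile(
    ExperimentConfig(
        phantom_kind="soft_adjacent",
        variants=("ingp", "fdk"),  # add "vanilla", "mip", "pixel" for the full set
        seed=1,
        out_dir="scratch/example_run",
    )
)
table = run_experiment(config)
print(table[["variant", "psnr_3d", "ssim_3d", "gmsd", "baseline_zero_psnr_3d"]].to_string(index=False))
print("artifacts in scratch/example_run/: config.yaml, phantom/, projections/, "
      "checkpoints/, volumes/, metrics.csv, log.txt")
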