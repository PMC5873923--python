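"""Scenario presets and the configuration-driven pipeline.

The presets mirror four reference multi-environment trials: two maize-like
settings with positive environment correlations (one strongly unbalanced,
one with a sizable iid line intercept) and two wheat-like settings (one with
a negatively correlated environment, one balanced with dominant GxE). This
script scales the unbalanced maize-like preset down, runs the full pipeline
(variance components + CV2 accuracy) for two model-method combinations, and
lists the artifacts written — variance-component tables, an accuracy table,
chains, partitions, and a provenance log keyed by seed and config hash.
"""

from megp import RunConfig, preset, run

for name in ("HEL_like", "USP_like", "WHE1_like", "WHE5_like"):
    s = preset(name)
    shape = f"{s.n_lines} lines x {s.n_envs} envs"
    extra = f", per-env counts {s.env_counts}" if s.env_counts else " (balanced)"
    print(f"{name:10s} {s.model:5s} {shape}{extra}")

config = RunConfig(
    seed=11,
    out_dir="scratch_example_run",
    models=["MDs-GB", "MDs-GK"],
    synthetic_preset="HEL_like",
    preset_overrides={"n_lines": 80, "n_markers": 300,
                      "env_counts": [45, 60, 80, 65, 60]},
    n_iter=600, burn_in=200, thin=2,
    cv_scheme="CV2", n_partitions=3,
)
out = run(config)
print("\nartifacts:")
for f in sorted(out.iterdir()):
    print(" ", f.name)
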