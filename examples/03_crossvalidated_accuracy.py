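"""Compare model prediction accuracy under sparse-testing cross-validation.

Simulates a trial with strong GxE (sigma2_ge / sigma2_g = 3), then scores
the main-effect model (MM) against the single-variance GxE model (MDs)
under CV2 — individual line-environment cells held out, so a line's records
in other environments stay in training. The printed table gives the mean
(SD) Pearson correlation between observed and predicted test phenotypes per
environment over partitions; MDs should beat MM everywhere because only it
can borrow the within-environment GxE signal.
"""

from megp import (
    McmcConfig,
    ModelSpec,
    SimulationSpec,
    evaluate,
    make_partitions,
    simulate_trial,
)

spec = SimulationSpec(
    n_lines=250, n_markers=600, n_envs=3, model="MDs",
    sigma2_g=0.3, sigma2_ge=0.9, sigma2=0.6, seed=3,
)
T, truth = simulate_trial(spec)
parts = make_partitions(T, "CV2", n_partitions=5, fraction_train=0.8, seed=7)

table = evaluate(
    T,
    [ModelSpec("MM", "GB"), ModelSpec("MDs", "GB")],
    {"GB": truth.K},
    parts,
    cfg=McmcConfig(n_iter=800, burn_in=300, thin=2, seed=11),
)
print(f"CV2, {parts.n_partitions} partitions, 80/20 train/test")
print(table.formatted())
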