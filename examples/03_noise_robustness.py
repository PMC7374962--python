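"""Miniature noise-robustness comparison: Student-t vs normal error.

Runs a reduced sweep (three noise levels, a few seeds) of the simulation
benchmark under zero-centered gamma noise.  The full-scale study is run
by `tgplvm benchmark` or scripts/acceptance.py; with gamma noise the
heavy-tailed Student-t error model recovers the manifold uniformly better
than the normal error model.
"""

from tgplvm import SweepConfig, run_noise_sweep

config = SweepConfig(
    n=100,
    levels=(0.1, 0.5, 1.0),
    noise_models=("gamma",),
    n_seeds=3,
    epochs=300,
    seed=0,
)
results = run_noise_sweep(config)
means = results.groupby(["level", "error_model"]).w2.mean().unstack().round(4)
print("mean W2 (lower = better manifold recovery):")
print(means)
print("\npositive (normal - student_t) differences mean the robust model wins:")
print((means["normal"] - means["student_t"]).round(4))
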