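"""The repeated-random-initialization benchmark protocol, scaled down.

Runs both labeling strategies over several random seed-set draws on the
boundary scenario and reports mean +/- std F1 with tie-averaged ranks,
the same summary the command-line `putsc benchmark` writes as CSV.
"""

from putsc import ExperimentConfig, generate_boundary_scenario, run_experiment

ds = generate_boundary_scenario(seed=3)
config = ExperimentConfig(
    methods=("st-scc", "scc-center-dtw"),
    pl_size=3,
    dba_iterations=15,
    n_pl_draws=5,
    n_dba_reps=2,
    seed=42,
    boundary_seed=True,
)
summary = run_experiment(ds, config)
print(summary.to_frame().to_string(index=False))
print()
print("Each row aggregates F1 over the random seed-set draws (x DBA")
print("repetitions for the barycenter method); rank 1 is the best mean F1")
print("on this dataset.")
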