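"""Small Monte Carlo comparison of penalized network-inference methods.

Averages support-recovery metrics over a handful of simulated datasets
for the lasso, elastic net and random lasso.  (The full netRL rows take
minutes per dataset; see scripts/acceptance.py for the complete run.)
"""

from netrl import RunConfig
from netrl.simulate import ScenarioSpec, run_benchmark

table = run_benchmark(
    ["lasso", "elastic-net", "random-lasso"],
    [ScenarioSpec(scenario=1, situation=1, u=10, sigma=1.0)],
    n_datasets=5,
    seed=0,
    netrl_config=RunConfig(omega=30, pi_reps=10),
)
cols = ["method", "criterion", "tpr", "tnr", "fdr", "acc", "edges", "mse"]
print(table[cols].round(3).to_string(index=False))
print("\nEach row averages 5 simulated datasets (Scenario 1, 4 active TF")
print("blocks, 110 candidate regulators, 48 training samples).")
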