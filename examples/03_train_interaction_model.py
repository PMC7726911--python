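"""Train the interaction classifier and compare it with the spatial-free
control.

Runs gene-exclusive 3-fold cross-validation on a simulated dataset twice:
once with the autocrine+ graph operator and once with the identity
(diagonal) operator, and prints the pooled per-ligand AUROC of each.
Takes a couple of minutes on one CPU.
"""

from spatialgcn import (ExperimentConfig, SimConfig, TrainConfig,
                        run_experiment, simulate)

dataset = simulate(SimConfig(seed=1))

for variant in ("autocrine_plus", "diagonal"):
    cfg = ExperimentConfig(
        variant=variant,
        k_folds=3,
        train=TrainConfig(epochs=60),
        seed=101,
    )
    report = run_experiment(dataset, cfg)
    print(f"{variant:15s} mean AUROC {report.mean_auroc:.3f}  "
          f"mean AUPRC {report.mean_auprc:.3f}  "
          f"({report.n_curves} ligand curves)")

# The autocrine+ model sees each cell's neighborhood and recovers the
# planted couplings well above chance; the diagonal model sees only
# same-cell co-expression and does much worse — the gap measures how much
# of the signal is genuinely spatial.
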