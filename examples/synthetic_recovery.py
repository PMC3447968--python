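"""Stress the full estimation pipeline on a grid of synthetic worlds.

Each cell pairs an evolutionary scenario with an observation scenario; per
world the pipeline estimates coverage, conserved fraction and interactome
size, and the summary reports bias and RMSE against the known ground truth.
The biased cell (reporting bias beta > 1) shows the expected inflation.
"""

from interolog import (
    ObservationParams,
    WorldParams,
    recovery_experiment,
    recovery_summary,
)

cells = [
    (WorldParams(n_ancestral_proteins=1000),
     ObservationParams(coverage_s=1.0, coverage_t=0.3)),
    (WorldParams(n_ancestral_proteins=1000),
     ObservationParams(coverage_s=1.0, coverage_t=0.3, bias_beta=6.0)),
]
df = recovery_experiment(cells, n_worlds=4, seed=5)
summary = recovery_summary(df)

for idx, label in ((0, "unbiased observation"), (1, "reporting bias beta=6")):
    row = summary.loc[idx]
    print(f"{label}:")
    print(f"  coverage bias {row.c_bias:+.3f}  (RMSE {row.c_rmse:.3f})")
    print(f"  conserved-fraction bias {row.f_true_bias:+.3f}  "
          f"(RMSE {row.f_true_rmse:.3f})")
    print(f"  size bias {row.size_bias:+.3f}  (RMSE {row.size_rmse:.3f})")

print("\nUnder model-true observation the estimators are unbiased within "
      "Monte-Carlo error; preferential reporting of interactions with a "
      "reported counterpart inflates the conserved-fraction estimate, the "
      "failure mode expected for heavily literature-driven interactomes.")
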