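"""The adversarial simulation benchmark: *ESPI vs the classical index.

Generates one 10-group study (log-normal signal, heavy-tailed noise,
outliers, missingness, copula-correlated environments), then compares
both indices against the known ground truth over all 45 group pairs.
"""

from espi import generate_study
from espi.evaluate import benchmark_report, unit_sensitivity_experiment

study = generate_study(seed=1)
sizes = [g.n for g in study.groups]
print(f"groups: {len(study.groups)}, replicates per group "
      f"{min(sizes)}-{max(sizes)}, 45 pairs\n")

report = benchmark_report(study, axes=(1, 2, 3, 5, 10))
cols = ["method", "n_axes", "bias", "rmse", "cv_percent"]
print(report[cols].to_string(index=False, float_format=lambda x: f"{x:9.2f}"))
print()
print("bias/rmse: accuracy against the true standardized effect;")
print("cv_percent: spread of the 45 pairwise values (smaller = more stable).")
print("The classical index is wildly unstable because one near-tied")
print("environmental value can explode its denominator; multi-axis *ESPI")
print("trades a modest systematic underestimate for far lower dispersion.\n")

unit = unit_sensitivity_experiment(study)
print(unit.to_string(index=False, float_format=lambda x: f"{x:10.3f}"))
print()
print("Rescaling the raw trait values (x0.5/x2/x10) drags the classical")
print("index with it 1:4:20, while the standardized index is unchanged.")
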