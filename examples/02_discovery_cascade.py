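"""Discover differentially methylated CpGs in a simulated discovery cohort.

Simulates a 10 responder vs 14 non-responder cohort on a 60-gene synthetic
450K-style manifest with six planted differentially methylated genes, then
runs the five-filter cascade: rank-sum p < 0.05, |delta-beta| >= 0.20,
promoter island/shore context, intragroup SD <= 0.20, and consecutive-CpG
consistency.
"""

from methsig import apply_cascade, test_all_probes
from methsig.io import PipelineConfig
from methsig.pipeline import simulate_study

config = PipelineConfig(seed=11)
data = simulate_study(config)

records = test_all_probes(data["discovery"].beta, data["samples"],
                          cohort="discovery", params=config.cascade)
result = apply_cascade(records, data["manifest"], config.cascade)

print("probes surviving each filter:")
for step, count in result.step_counts.items():
    print(f"  {step:12s} {count}")
print("\ncandidate genes (direction = which group is hypermethylated):")
print(result.candidates[["gene", "direction", "n_probes",
                         "mean_delta_beta"]].to_string(index=False))
# The planted genes (FERD3L, TRIP10, CHL1 hypermethylated in responders;
# LEF1, HOXA5, CDKL2 in non-responders) emerge as candidates; the step
# counts shrink monotonically through the cascade.
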