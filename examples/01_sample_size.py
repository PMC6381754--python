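"""Plan a two-arm methylation biomarker study.

Anticipating 45% pathological complete response among signature-positive
patients versus 10% among signature-negative ones, compute the patients
needed per arm at two-sided alpha 0.05 and 80% power, then inflate for
15% drop-out.
"""

from methsig import two_proportion_sample_size

plan = two_proportion_sample_size(p1=0.45, p2=0.10, alpha=0.05, power=0.80,
                                  dropout=0.15)
print(f"patients per group : {plan.n_per_group}")
print(f"patients total     : {plan.n_total}")
print(f"with 15% drop-out  : {plan.n_with_dropout}")
# The unpooled normal approximation gives 22 per group (44 total); planning
# for drop-out raises the recruitment target to 51 patients.
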