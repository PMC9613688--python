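"""The nonparametric battery on a small synthetic cohort table.

We build a long-format table (subject, condition, parameter, value) for the
eight factorial conditions #4-11, inject a latency load on the memory and
orientation environments, and run the aligned-rank-transform ANOVA plus the
pairwise Wilcoxon comparisons with Holm adjustment.
"""

import numpy as np
import pandas as pd

from oculosway import rank_factorial_anova, wilcoxon_pairwise
from oculosway.stats import CONDITION, PARAMETER, SUBJECT, VALUE, FACTORIAL_CONDITIONS

rng = np.random.default_rng(0)
n_subjects = 12
env_load = {4: 0.0, 5: 0.0, 6: 0.01, 7: 0.01, 8: 0.12, 9: 0.12, 10: 0.10, 11: 0.10}
task_load = {c: (0.04 if c % 2 else 0.0) for c in FACTORIAL_CONDITIONS}

rows = []
for s in range(n_subjects):
    base = rng.normal(0.23, 0.02)
    for c in FACTORIAL_CONDITIONS:
        value = base + env_load[c] + task_load[c] + rng.normal(0, 0.02)
        rows.append((s, c, "latency_mean", value))
table = pd.DataFrame(rows, columns=[SUBJECT, CONDITION, PARAMETER, VALUE])

print(rank_factorial_anova(table).to_string(index=False))
print("\npairwise Wilcoxon (latency), Holm-adjusted:")
for r in wilcoxon_pairwise(table):
    if r.condition_b == r.condition_a + 4 or (r.condition_a, r.condition_b) in [(4, 5)]:
        print(f"  #{r.condition_a} vs #{r.condition_b}: "
              f"p_adj={r.p_adjusted:.4f}, ES r={r.effect_size:.2f} ({r.magnitude})")
print("Environments with a latency load separate from the 2D baseline with"
      " large effect sizes; pro vs anti shows the injected 40 ms task cost.")
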