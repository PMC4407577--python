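"""Connectivity-behavior association with Bonferroni control.

Builds a noise-free cohort in which the IOG->OFC coupling decreases
monotonically with memory performance, then shows that the association
table reports the corresponding negative rank correlations and flags
them at the corrected threshold.
"""

import numpy as np
import pandas as pd

import emodcm as e
from emodcm.association import BU_TESTED

n = 18
pr = np.linspace(0.15, 0.65, n)          # memory performance across subjects
rng = np.random.default_rng(0)

bma = pd.DataFrame(rng.normal(0, 0.05, (n, len(BU_TESTED))),
                   index=range(n), columns=BU_TESTED)
bma["A:IOG->OFC"] = 0.4 - 0.5 * pr       # coupling falls with performance

rows = []
for s in range(n):
    for val in ("total", "negative", "neutral", "positive"):
        rows.append((s, val, pr[s] + rng.normal(0, 0.02),
                     0.35 + rng.normal(0, 0.05)))
scores = pd.DataFrame(rows, columns=["subject", "valence", "Pr", "Br"])

table = e.correlate_parameters_behavior(bma, scores, winning_family="BU")
print(f"tested {table.attrs['m']} parameters x 8 measures; "
      f"Bonferroni threshold {table.attrs['threshold']:.4f}")

iog = table[table["parameter"] == "A:IOG->OFC"]
print("\nIOG->OFC rows:")
print(iog[["measure", "r_s", "p", "significant_bonferroni"]]
      .to_string(index=False))
print("\nthe negative r_s across Pr measures is the constructed "
      "coupling-performance anticorrelation; Br rows stay null.")
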