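"""Score recognition memory and test the emotion effect.

Generates 18 subjects' recognition tables from known per-valence
(Pr, Br) truth, scores them with the two-high-threshold model, and runs
the repeated-measures ANOVA on response bias - the measure the
generator endows with an emotion effect (negative faces get a higher
Br than neutral or positive).
"""

import numpy as np
import pandas as pd

import emodcm as e
from emodcm.behavior import VALENCES

rng = np.random.default_rng(42)
tables = [e.generate_recognition(int(rng.integers(2 ** 31)), subject=s)
          for s in range(18)]
scores = e.score_recognition(pd.concat(tables, ignore_index=True))

print("group means (generating truth: Pr = 0.35 everywhere; "
      "Br = 0.45 / 0.33 / 0.35):")
print(scores.groupby("valence")[["Pr", "Br"]].mean().round(3))

br = e.scores_wide(scores, "Br")[list(VALENCES)].to_numpy()
res = e.rm_anova(br)
print(f"\nemotion effect on bias: F({res.df_effect_corrected:.2f}, "
      f"{res.df_error_corrected:.2f}) = {res.F:.2f}, p = {res.p:.4f}, "
      f"GG epsilon = {res.epsilon:.3f}, partial eta^2 = "
      f"{res.partial_eta_sq:.3f}")

t, df, p, r = e.paired_t(br[:, 0], br[:, 1])  # negative vs neutral
print(f"negative vs neutral bias: t({df}) = {t:.2f}, p = {p:.4f}, "
      f"r = {r:.3f}")
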