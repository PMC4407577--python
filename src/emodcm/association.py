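"""Connectivity-behavior association under Bonferroni control.

Correlates subject-level BMA connectivity estimates with recognition
scores (Pr and Br, total and per valence — 8 behavioral measures) using
Spearman rank correlation.  Only the pathways relevant for emotion
processing in the winning family are tested: the five endogenous
connections into OFC plus their ten valence modulations in the
bottom-up family, or the connections into HPC and their OFC gatings in
the top-down family.  Bonferroni correction runs over the tested
parameters (m = 15 for the bottom-up set), with the behavioral columns
treated as descriptive.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

BEHAVIOR_MEASURES = [("Pr", v) for v in ("total", "negative", "neutral", "positive")] + \
                    [("Br", v) for v in ("total", "negative", "neutral", "positive")]

BU_TESTED = ([f"A:{src}->OFC" for src in ("IOG", "FUS", "SPL", "HPC", "AMG")]
             + [f"B:{val}:{src}->OFC" for val in ("negative", "positive")
                for src in ("IOG", "FUS", "SPL", "HPC", "AMG")])
TD_TESTED = ([f"A:{src}->HPC" for src in ("IOG", "FUS", "SPL", "AMG", "OFC")]
             + [f"D:OFC:{src}->HPC" for src in ("IOG", "FUS", "SPL", "AMG")])


def spearman(x: np.ndarray, y: np.ndarray, exact: bool = False
             ) -> tuple[float, float]:
    """Spearman correlation: average-tie ranks, Pearson on ranks, and a
    two-sided p from the t approximation (or exact permutation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        p = _exact_permutation_p(rx, ry, rs)
    elif abs(rs) >= 1.0:
        p = 0.0
    else:
        t = rs * np.sqrt((n - 2) / (1.0 - rs ** 2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return rs, p


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    n = len(rx)
    if n > 8:
        raise ValueError("exact permutation limited to n <= 8")
    count = 0
    total = 0
    for perm in permutations(range(n)):
        rs = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(rs) >= abs(rs_obs) - 1e-12
        total += 1
    return count / total


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test threshold alpha/m (reported to 4 decimals)."""
    if m < 1 or not (0 < alpha < 1):
        raise ValueError("need m >= 1 and alpha in (0, 1)")
    return alpha / m


def correlate_parameters_behavior(bma_means: pd.DataFrame,
                                  scores: pd.DataFrame,
                                  winning_family: str = "BU",
                                  alpha: float = 0.05,
                                  exact: bool = False) -> pd.DataFrame:
    """Full tested-parameters x 8-measures Spearman table.

    ``bma_means`` is subjects x parameter-labels; ``scores`` is a scored
    recognition table (long form with subject/valence/Pr/Br columns).
    """
    tested = BU_TESTED if winning_family == "BU" else TD_TESTED
    present = [t for t in tested if t in bma_means.columns]
    m = len(tested)
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    subs = list(bma_means.index)
    for measure, val in BEHAVIOR_MEASURES:
        beh = scores[scores["valence"] == val].set_index("subject")[measure]
        if sorted(beh.index) != sorted(subs):
            raise ValueError("subject sets of estimates and scores differ")
        beh = beh.loc[subs].to_numpy()
        for par in present:
            est = bma_means[par].to_numpy()
            if np.ptp(est) == 0 or np.ptp(beh) == 0:
                # untestable: no variation on one side (e.g. a pathway
                # carrying zero posterior mass in every subject)
                rows.append((par, f"{measure}_{val}", np.nan, np.nan, False))
                continue
            rs, p = spearman(est, beh, exact=exact)
            rows.append((par, f"{measure}_{val}", rs, p, p < threshold))
    out = pd.DataFrame(rows, columns=["parameter", "measure", "r_s", "p",
                                      "significant_bonferroni"])
    out.attrs["threshold"] = threshold
    out.attrs["m"] = m
    return out
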