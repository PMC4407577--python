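"""Recognition-memory scoring and emotion-effect statistics.

Scores follow the two-high-threshold model: discrimination
``Pr = hit rate - false-alarm rate`` and response bias
``Br = false-alarm rate / (1 - Pr)``, computed per valence and from
pooled counts for the total.  Responses on the six-point confidence
scale collapse to old (1-3) vs new (4-6); trials without a response are
excluded.  The emotion effect is tested with a one-way repeated-measures
ANOVA with Greenhouse-Geisser correction, and follow-up paired t-tests
report the effect size r = sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VALENCES = ("negative", "neutral", "positive")


def collapse_confidence(table: pd.DataFrame) -> pd.DataFrame:
    """Map 6-point confidence to binary old/new; drop no-response trials."""
    out = table.dropna(subset=["response"]).copy()
    resp = out["response"].astype(int)
    if not resp.between(1, 6).all():
        raise ValueError("responses must lie on the 1..6 scale")
    out["response_binary"] = np.where(resp <= 3, "old", "new")
    return out


def compute_pr_br(h: float, f: float) -> tuple[float, float]:
    """Two-high-threshold indices from hit and false-alarm rates."""
    if not (0 <= h <= 1 and 0 <= f <= 1):
        raise ValueError("rates must lie in [0, 1]")
    pr = h - f
    if pr >= 1.0:
        raise ValueError("Br undefined at perfect discrimination")
    return pr, f / (1.0 - pr)


def compute_rates(binary: pd.DataFrame) -> pd.DataFrame:
    """Per subject x valence hit/false-alarm rates, plus pooled totals."""
    rows = []
    for (sub, val), grp in binary.groupby(["subject", "valence"]):
        old = grp[grp["status"] == "old"]
        new = grp[grp["status"] == "new"]
        rows.append((sub, val,
                     (old["response_binary"] == "old").mean(),
                     (new["response_binary"] == "old").mean()))
    for sub, grp in binary.groupby("subject"):
        old = grp[grp["status"] == "old"]
        new = grp[grp["status"] == "new"]
        rows.append((sub, "total",
                     (old["response_binary"] == "old").mean(),
                     (new["response_binary"] == "old").mean()))
    return pd.DataFrame(rows, columns=["subject", "valence", "hit_rate",
                                       "fa_rate"])


def score_recognition(table: pd.DataFrame) -> pd.DataFrame:
    """Full scoring: collapse confidence, rates, then Pr/Br per valence
    and total (total from pooled counts, not the mean of valences)."""
    rates = compute_rates(collapse_confidence(table))
    pr, br = zip(*(compute_pr_br(h, f) for h, f in
                   zip(rates["hit_rate"], rates["fa_rate"])))
    rates = rates.assign(Pr=pr, Br=br)
    return rates


def scores_wide(scores: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Pivot a scored table to subjects x (total + valences) columns."""
    wide = scores.pivot(index="subject", columns="valence", values=measure)
    return wide[["total", *VALENCES]]


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with sphericity correction."""

    F: float
    df_effect: float
    df_error: float
    epsilon: float
    df_effect_corrected: float
    df_error_corrected: float
    p: float
    partial_eta_sq: float


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """Sphericity index from the sample covariance of condition scores."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    H = np.eye(k) - np.ones((k, k)) / k
    St = H @ S @ H
    denom = (k - 1) * np.sum(St * St)
    if denom == 0:  # no within-subject variation: sphericity trivially holds
        return 1.0
    return float(np.trace(St) ** 2 / denom)


def rm_anova(data: np.ndarray) -> AnovaResult:
    """Within-subject one-way ANOVA over a subjects x conditions array."""
    data = np.asarray(data, dtype=float)
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells are not allowed")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_effect = n * np.sum((cond_means - grand) ** 2)
    ss_subject = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    if ss_effect <= 1e-12 * max(ss_total, np.finfo(float).tiny):
        F = 0.0  # numerically null effect (guards 0/0 at ss_error = 0)
    else:
        F = (ss_effect / df_effect) / (ss_error / df_error)
    eps = greenhouse_geisser_epsilon(data)
    p = float(stats.f.sf(F, eps * df_effect, eps * df_error))
    eta = ss_effect / (ss_effect + ss_error)
    return AnovaResult(F=float(F), df_effect=df_effect, df_error=df_error,
                       epsilon=eps, df_effect_corrected=eps * df_effect,
                       df_error_corrected=eps * df_error, p=p,
                       partial_eta_sq=float(eta))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, float]:
    """Two-sided paired t-test with effect size r = sqrt(t^2/(t^2+df))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0) and not np.allclose(diff.mean(), 0):
        raise ValueError("zero variance of differences with nonzero mean")
    res = stats.ttest_rel(a, b)
    df = len(a) - 1
    t = float(res.statistic)
    r = np.sqrt(t ** 2 / (t ** 2 + df)) if t == t else 0.0
    if np.allclose(diff, 0):
        t, r = 0.0, 0.0
        return t, df, 1.0, r
    return t, df, float(res.pvalue), float(r)
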