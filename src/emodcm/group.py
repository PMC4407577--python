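"""Random-effects Bayesian model selection, family inference and BMA.

Treats model identity as a random effect across subjects: model
frequencies ``p`` carry a Dirichlet(alpha0) prior, and the variational
scheme alternates subject-level model assignments

    u_nm  ∝  exp(F_nm + psi(alpha_m) - psi(sum alpha))

with Dirichlet updates ``alpha = alpha0 + sum_n g_nm`` until the alphas
settle.  Exceedance probabilities — the posterior probability that a
model (or family) is the most frequent in the population — are computed
by seeded Dirichlet Monte-Carlo.  Family comparison adjusts alpha0 so
each family holds equal prior mass regardless of its size; Bayesian
model averaging samples, per subject, a model from the family-restricted
posterior and parameters from that model's Gaussian posterior, with
parameters absent from the sampled model contributing exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma

from .inversion import InversionResult, param_label
from .model_space import FamilyPartition


@dataclass
class EvidenceMatrix:
    """Free energies (nats) for subjects x models."""

    F: np.ndarray
    subjects: tuple
    model_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite model evidence")
        if self.F.shape != (len(self.subjects), len(self.model_ids)):
            raise ValueError("evidence shape mismatch")


@dataclass
class RFXResult:
    alpha: np.ndarray
    expected: np.ndarray
    exceedance: np.ndarray
    g: np.ndarray              # subject-level model posteriors
    iterations: int
    model_ids: tuple[int, ...]


@dataclass
class FamilyResult:
    labels: tuple[str, ...]
    alpha: np.ndarray
    expected: np.ndarray
    exceedance: np.ndarray
    winner: str
    rfx: RFXResult


def rfx_bms(evidence: EvidenceMatrix, alpha0: float | np.ndarray = 1.0,
            n_samples: int = 1_000_000, seed: int = 0,
            tol: float = 1e-4, max_iter: int = 10_000) -> RFXResult:
    """Variational Dirichlet scheme over model frequencies."""
    F = evidence.F
    n_sub, n_mod = F.shape
    if n_mod < 2:
        raise ValueError("need at least 2 models")
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (n_mod,)).copy()
    alpha = alpha0.copy()
    for it in range(1, max_iter + 1):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        logu = logu - logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    expected = alpha / alpha.sum()
    xp = exceedance_probabilities(alpha, n_samples=n_samples, seed=seed)
    return RFXResult(alpha=alpha, expected=expected, exceedance=xp, g=g,
                     iterations=it, model_ids=tuple(evidence.model_ids))


def exceedance_probabilities(alpha: np.ndarray, n_samples: int = 1_000_000,
                             seed: int = 0) -> np.ndarray:
    """Monte-Carlo P(p_m > p_m' for all m' != m) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet parameters must be positive")
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(alpha))
    chunk = 200_000
    left = int(n_samples)
    while left > 0:
        m = min(chunk, left)
        draws = rng.standard_gamma(alpha, size=(m, len(alpha)))
        counts += np.bincount(draws.argmax(axis=1), minlength=len(alpha))
        left -= m
    return counts / n_samples


def family_inference(evidence: EvidenceMatrix, partition: FamilyPartition,
                     n_samples: int = 1_000_000, seed: int = 0) -> FamilyResult:
    """RFX-BMS with a uniform-family prior, then family-level posteriors."""
    ids = list(evidence.model_ids)
    missing = [m for m in ids if m not in partition.model_family]
    if missing:
        raise ValueError(f"partition does not cover models {missing}")
    labels = tuple(partition.families)
    sizes = partition.family_sizes()
    n_fam = len(labels)
    total = float(len(ids))
    alpha0 = np.array([total / (n_fam * sizes[partition.model_family[m]])
                       for m in ids])
    rfx = rfx_bms(evidence, alpha0=alpha0, n_samples=n_samples, seed=seed)
    member = np.array([[mid in partition.families[f] for mid in ids]
                       for f in labels])
    fam_alpha = member @ rfx.alpha
    fam_expected = fam_alpha / fam_alpha.sum()
    # family exceedance: compare summed frequencies
    rng = np.random.default_rng(seed + 1)
    counts = np.zeros(n_fam)
    left = int(n_samples)
    while left > 0:
        m = min(200_000, left)
        draws = rng.standard_gamma(rfx.alpha, size=(m, len(ids)))
        fam_draws = draws @ member.T
        counts += np.bincount(fam_draws.argmax(axis=1), minlength=n_fam)
        left -= m
    fam_xp = counts / n_samples
    winner = labels[int(np.argmax(fam_xp))]
    return FamilyResult(labels=labels, alpha=fam_alpha, expected=fam_expected,
                        exceedance=fam_xp, winner=winner, rfx=rfx)


@dataclass
class BMAResult:
    """Family-marginal connectivity estimates.

    ``subject_means`` holds, per subject, the Monte-Carlo mean of each
    parameter (union over family members, keyed by label); the summary
    reports median and quartiles of those subject means.
    """

    parameters: tuple[str, ...]
    subject_means: np.ndarray           # (n_subjects, n_parameters)
    subjects: tuple
    n_samples: int
    draws: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.subject_means, index=list(self.subjects),
                            columns=list(self.parameters))


def bma(rfx: RFXResult, posteriors: dict[tuple, InversionResult],
        partition: FamilyPartition, winning_family: str,
        n_samples: int = 10_000, seed: int = 0,
        subjects: tuple | None = None) -> BMAResult:
    """Random-effects BMA over the winning family.

    ``posteriors`` maps (subject, model_id) to inversion results; every
    winning-family model must be present for every subject.
    """
    members = [m for m in rfx.model_ids
               if m in partition.families.get(winning_family, ())]
    if not members:
        raise ValueError("empty winning family")
    if subjects is None:
        subjects = tuple(sorted({s for s, _ in posteriors}))
    # union parameter space over family members
    labels: list[str] = []
    for mid in members:
        for name in posteriors[(subjects[0], mid)].names:
            lab = param_label(name)
            if lab not in labels:
                labels.append(lab)
    col = {lab: k for k, lab in enumerate(labels)}
    rng = np.random.default_rng(seed)
    n_sub = len(subjects)
    means = np.zeros((n_sub, len(labels)))
    midx = [list(rfx.model_ids).index(m) for m in members]
    for si, sub in enumerate(subjects):
        w = rfx.g[si, midx]
        w = w / w.sum()
        counts = rng.multinomial(n_samples, w)
        acc = np.zeros(len(labels))
        for mi, mid in enumerate(members):
            k = counts[mi]
            if k == 0:
                continue
            post = posteriors[(sub, mid)]
            cols = [col[param_label(n)] for n in post.names]
            cov = post.cov + 1e-12 * np.eye(len(post.mean))
            L = np.linalg.cholesky(cov)
            draws = post.mean + rng.standard_normal((k, len(post.mean))) @ L.T
            acc[cols] += draws.sum(axis=0)
        means[si] = acc / n_samples
    return BMAResult(parameters=tuple(labels), subject_means=means,
                     subjects=tuple(subjects), n_samples=n_samples)


def summarize_bma(result: BMAResult) -> pd.DataFrame:
    """Median and 25%/75% quartiles of subject-level BMA means
    (linear-interpolation quantiles)."""
    q = np.percentile(result.subject_means, [50, 25, 75], axis=0)
    return pd.DataFrame({"parameter": list(result.parameters),
                         "median": q[0], "q25": q[1], "q75": q[2]})
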