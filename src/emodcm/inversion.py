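"""Variational-Laplace inversion of one model for one subject.

The scheme ascends the free energy F = accuracy - complexity by
Gauss-Newton steps on the parameter posterior, with the observation
gradient obtained from forward sensitivity equations integrated
alongside the states.  Per-region noise precisions carry Gamma
hyperpriors and are updated by expectation-maximization; slow drifts
and run means are absorbed by an orthonormal discrete-cosine confound
basis whose coefficients are profiled out by least squares inside each
iteration.  Complexity is the KL divergence of the Gaussian parameter
posterior (and Gamma precision posteriors) from their priors, so F is
a proper lower bound on log model evidence and usable for comparison.

Parameter vector ordering (deterministic, see :func:`default_priors`):
free off-diagonal A entries (row-major), B entries per modulatory input
(negative then positive), C entries, D entries, six self-decay
log-scales (A_ii = -0.5 exp(a_i)), then per-region log-kappa and
log-tau when hemodynamics are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln

from ._engine import rk4_run
from .generative import (KAPPA0, SELF_DECAY, TAU0, BOLDTimeSeries,
                         DCMParameters, InputFunction, _kernel_args)
from .model_space import (INPUT_INDEX, N_INPUTS, N_REGIONS, REGIONS,
                          ModelSpec)

# prior variances
VAR_COUPLING = 1.0 / 16.0   # A off-diagonal, B, D
VAR_DRIVE = 1.0             # C
VAR_SELF = 1.0 / 256.0      # self-decay log-scale
VAR_HEMO = 0.015            # log-kappa, log-tau
NOISE_SHAPE = 2.0           # Gamma hyperprior on precision
NOISE_RATE = 0.2


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior over the free parameters of a model."""

    names: tuple[tuple, ...]       # structured names, see module docstring
    mean: np.ndarray
    var: np.ndarray
    noise_shape: float = NOISE_SHAPE
    noise_rate: float = NOISE_RATE

    @property
    def n_params(self) -> int:
        return len(self.names)


def param_label(name: tuple) -> str:
    """Human-readable label, e.g. ``A:IOG->OFC`` or ``B:negative:SPL->OFC``."""
    kind = name[0]
    if kind == "A":
        return f"A:{REGIONS[name[2]]}->{REGIONS[name[1]]}"
    if kind == "B":
        inp = [k for k, v in INPUT_INDEX.items() if v == name[3]][0]
        return f"B:{inp}:{REGIONS[name[2]]}->{REGIONS[name[1]]}"
    if kind == "C":
        inp = [k for k, v in INPUT_INDEX.items() if v == name[2]][0]
        return f"C:{inp}->{REGIONS[name[1]]}"
    if kind == "D":
        return f"D:{REGIONS[name[3]]}:{REGIONS[name[2]]}->{REGIONS[name[1]]}"
    return f"{kind}:{REGIONS[name[1]]}"


def default_priors(spec: ModelSpec, estimate_hemo: bool = True) -> PriorSpec:
    """Zero-mean priors over every parameter freed by ``spec``'s masks."""
    names: list[tuple] = []
    var: list[float] = []
    for i in range(N_REGIONS):
        for j in range(N_REGIONS):
            if spec.A_mask[i, j]:
                names.append(("A", i, j))
                var.append(VAR_COUPLING)
    for m in range(N_INPUTS):
        for i in range(N_REGIONS):
            for j in range(N_REGIONS):
                if spec.B_masks[m, i, j]:
                    names.append(("B", i, j, m))
                    var.append(VAR_COUPLING)
    for i in range(N_REGIONS):
        for m in range(N_INPUTS):
            if spec.C_mask[i, m]:
                names.append(("C", i, m))
                var.append(VAR_DRIVE)
    for k in range(N_REGIONS):
        for i in range(N_REGIONS):
            for j in range(N_REGIONS):
                if spec.D_masks[k, i, j]:
                    names.append(("D", i, j, k))
                    var.append(VAR_COUPLING)
    for i in range(N_REGIONS):
        names.append(("self", i))
        var.append(VAR_SELF)
    if estimate_hemo:
        for i in range(N_REGIONS):
            names.append(("lkappa", i))
            var.append(VAR_HEMO)
        for i in range(N_REGIONS):
            names.append(("ltau", i))
            var.append(VAR_HEMO)
    return PriorSpec(names=tuple(names), mean=np.zeros(len(names)),
                     var=np.array(var))


def theta_to_params(theta: np.ndarray, priors: PriorSpec) -> DCMParameters:
    """Materialize dense matrices from a parameter vector."""
    p = DCMParameters.zeros()
    for val, name in zip(theta, priors.names):
        kind = name[0]
        if kind == "A":
            p.A[name[1], name[2]] = val
        elif kind == "B":
            p.B[name[3], name[1], name[2]] = val
        elif kind == "C":
            p.C[name[1], name[2]] = val
        elif kind == "D":
            p.D[name[3], name[1], name[2]] = val
        elif kind == "self":
            p.A[name[1], name[1]] = SELF_DECAY * np.exp(val)
        elif kind == "lkappa":
            p.kappa[name[1]] = KAPPA0 * np.exp(val)
        elif kind == "ltau":
            p.tau[name[1]] = TAU0 * np.exp(val)
    return p


def _kernel_indices(priors: PriorSpec):
    kinds = {"A": 0, "B": 1, "C": 2, "D": 3, "self": 4, "lkappa": 5, "ltau": 6}
    kd = np.array([kinds[n[0]] for n in priors.names], dtype=np.int64)
    a = np.array([n[1] for n in priors.names], dtype=np.int64)
    b = np.array([n[2] if len(n) > 2 else 0 for n in priors.names], dtype=np.int64)
    c = np.array([n[3] if len(n) > 3 else 0 for n in priors.names], dtype=np.int64)
    return kd, a, b, c


@dataclass
class InversionResult:
    """Posterior and evidence for one subject x model."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    iterations: int
    converged: bool
    names: tuple[tuple, ...]
    f_history: list[float] = field(default_factory=list)
    accuracy: float = np.nan
    noise_precision: np.ndarray | None = None

    def named_mean(self) -> dict[str, float]:
        return {param_label(n): float(v) for n, v in zip(self.names, self.mean)}

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist(),
                "free_energy": self.free_energy, "iterations": self.iterations,
                "converged": self.converged,
                "names": [list(n) for n in self.names]}

    @classmethod
    def from_dict(cls, d: dict) -> "InversionResult":
        return cls(mean=np.array(d["mean"]), cov=np.array(d["cov"]),
                   free_energy=float(d["free_energy"]),
                   iterations=int(d["iterations"]),
                   converged=bool(d["converged"]),
                   names=tuple(tuple(n) for n in d["names"]))


# -- confounds -------------------------------------------------------------

def confound_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal DCT drift basis (constant included) for one run.

    Retains the ``floor(2*n*tr/cutoff) + 1`` lowest discrete cosines,
    i.e. every component of period >= cutoff.
    """
    if n_scans < 2:
        raise ValueError("need at least 2 scans")
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2*TR")
    order = int(np.floor(2.0 * n_scans * tr / cutoff)) + 1
    order = min(order, n_scans)
    n = np.arange(n_scans)
    X = np.empty((n_scans, order))
    X[:, 0] = 1.0 / np.sqrt(n_scans)
    for k in range(1, order):
        X[:, k] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * k * (n + 0.5) / n_scans)
    return X


def _block_confounds(run_starts: np.ndarray, n_scans: int, tr: float,
                     cutoff: float) -> np.ndarray:
    bounds = list(run_starts) + [n_scans]
    cols = []
    for r in range(len(run_starts)):
        m = bounds[r + 1] - bounds[r]
        Xr = confound_basis(m, tr, cutoff)
        full = np.zeros((n_scans, Xr.shape[1]))
        full[bounds[r]:bounds[r + 1]] = Xr
        cols.append(full)
    return np.hstack(cols)


# -- forward pass ----------------------------------------------------------

def _forward(theta: np.ndarray, priors: PriorSpec, inputs: InputFunction,
             with_sens: bool):
    params = theta_to_params(theta, priors)
    args = _kernel_args(params)
    kd, a, b, c = _kernel_indices(priors)
    keep = inputs.bins_per_scan
    n_scans = inputs.scans_per_run
    P = priors.n_params
    n_total = inputs.n_runs * n_scans
    y = np.empty((n_total, N_REGIONS))
    J = np.empty((n_total, N_REGIONS, P)) if with_sens else None
    for r, start in enumerate(inputs.run_starts):
        u_run = np.ascontiguousarray(
            inputs.u[start:start + (n_scans - 1) * keep].astype(float))
        yr, Jr, status = rk4_run(*args, u_run, float(inputs.dt), keep, n_scans,
                                 kd, a, b, c, with_sens)
        if status >= 0:
            return None, None
        y[r * n_scans:(r + 1) * n_scans] = yr
        if with_sens:
            J[r * n_scans:(r + 1) * n_scans] = Jr
    return y, J


def _gamma_kl(a: float, b: float, a0: float, b0: float) -> float:
    return float((a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
                 + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b)


#: internal signal rescaling: the precision hyperprior presumes
#: observations of order one, while resting blood-volume fractions put
#: raw percent-signal amplitudes near 0.01; data and prediction are both
#: scaled, so parameter estimates are unaffected
SIGNAL_SCALE = 100.0


def invert(data: BOLDTimeSeries, inputs: InputFunction, spec: ModelSpec,
           priors: PriorSpec | None = None, tol: float = 0.01,
           max_iter: int = 64, cutoff: float = 128.0,
           estimate_hemo: bool = True,
           signal_scale: float = SIGNAL_SCALE) -> InversionResult:
    """Fit one DCM to one subject's concatenated runs.

    Masked parameters are simply absent from the parameter vector (their
    posterior equals the zero-point prior with zero variance).  The
    logged free energies of accepted iterations are non-decreasing: a
    Gauss-Newton step whose free energy falls below the incumbent is
    rejected and the step halved.
    """
    if priors is None:
        priors = default_priors(spec, estimate_hemo=estimate_hemo)
    Y = data.data * signal_scale
    n_scans, nr = Y.shape
    P = priors.n_params
    X = _block_confounds(data.run_starts, n_scans, data.tr, cutoff)
    dof = n_scans - X.shape[1]  # per-region effective scans
    pi0 = 1.0 / priors.var
    mu0 = priors.mean
    a0, b0 = priors.noise_shape, priors.noise_rate

    def project(M):
        return M - X @ (X.T @ M)

    theta = mu0.copy()
    lam = np.full(nr, a0 / b0)
    a_post = a0 + 0.5 * dof
    f_hist: list[float] = []
    best = None  # (F, theta, cov, lam, accuracy, b_post)
    converged = False
    it = 0
    step_scale = 1.0
    while it < max_iter:
        it += 1
        y, J = _forward(theta, priors, inputs, with_sens=True)
        if y is not None:
            y = y * signal_scale
            J = J * signal_scale
        if y is None:
            if best is None:
                raise RuntimeError("forward integration failed at initialization")
            # candidate blew up: revert and halve the step
            step_scale *= 0.5
            theta, lam = best[1].copy(), best[3].copy()
            if step_scale < 1.0 / 64.0 or best[6] is None:
                converged = True
                break
            theta = theta + step_scale * cho_solve(cho_factor(best[7]), best[6])
            continue
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(J))):
            # numerically degenerate iterate: treat like a rejected step
            if best is None:
                raise RuntimeError("non-finite gradient")
            step_scale *= 0.5
            theta, lam = best[1].copy(), best[3].copy()
            if step_scale < 1.0 / 64.0 or best[6] is None:
                converged = True
                break
            theta = theta + step_scale * cho_solve(cho_factor(best[7]), best[6])
            continue
        resid = project(Y - y)
        Jp = project(J.reshape(n_scans, nr * P)).reshape(n_scans, nr, P)
        # per-region Gauss-Newton pieces
        JtJ = np.einsum("nrp,nrq->rpq", Jp, Jp)
        Jte = np.einsum("nrp,nr->rp", Jp, resid)
        sse = np.einsum("nr,nr->r", resid, resid)
        # EM update of noise precisions, then posterior at current theta
        prec = np.diag(pi0) + np.einsum("r,rpq->pq", lam, JtJ)
        cf = cho_factor(prec + 1e-10 * np.eye(P))
        cov = cho_solve(cf, np.eye(P))
        trS = np.einsum("pq,rqp->r", cov, JtJ)
        b_post = b0 + 0.5 * (sse + trS)
        lam = a_post / b_post
        # refresh posterior precision with updated lambdas
        prec = np.diag(pi0) + np.einsum("r,rpq->pq", lam, JtJ)
        cf = cho_factor(prec + 1e-10 * np.eye(P))
        cov = cho_solve(cf, np.eye(P))
        trS = np.einsum("pq,rqp->r", cov, JtJ)
        d = theta - mu0
        elnlam = digamma(a_post) - np.log(b_post)
        accuracy = float(np.sum(0.5 * dof * elnlam - 0.5 * dof * np.log(2 * np.pi)
                                - 0.5 * lam * (sse + trS)))
        sign, logdet_cov = np.linalg.slogdet(cov)
        kl_theta = 0.5 * (np.sum(pi0 * np.diag(cov)) + np.sum(pi0 * d * d)
                          - P - np.sum(np.log(priors.var)) - logdet_cov)
        kl_lam = sum(_gamma_kl(a_post, bb, a0, b0) for bb in b_post)
        F = accuracy - float(kl_theta) - kl_lam

        if best is not None and F < best[0]:
            # reject: fall back to incumbent and retry with a smaller step
            step_scale *= 0.5
            theta, lam = best[1].copy(), best[3].copy()
            if step_scale < 1.0 / 64.0 or best[6] is None:
                converged = True
                break
            theta = theta + step_scale * cho_solve(cho_factor(best[7]), best[6])
            continue
        if best is not None and abs(F - best[0]) < tol:
            best = (F, theta.copy(), cov, lam.copy(), accuracy, b_post.copy(),
                    None, prec)
            f_hist.append(F)
            converged = True
            break
        grad = np.einsum("r,rp->p", lam, Jte) - pi0 * d
        best = (F, theta.copy(), cov, lam.copy(), accuracy, b_post.copy(),
                grad, prec)
        f_hist.append(F)
        step_scale = 1.0
        theta = theta + cho_solve(cf, grad)
    if best is None:
        raise RuntimeError("inversion produced no valid iterate")
    F, theta_b, cov_b, lam_b, acc_b = best[0], best[1], best[2], best[3], best[4]
    return InversionResult(mean=theta_b, cov=cov_b, free_energy=float(F),
                           iterations=it, converged=converged,
                           names=priors.names, f_history=f_hist,
                           accuracy=float(acc_b), noise_precision=lam_b)
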