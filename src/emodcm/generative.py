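"""Deterministic DCM forward model.

Neural dynamics follow the one-state bilinear/nonlinear form

    dz/dt = (A + sum_j u_j B^(j) + sum_k z_k D^(k)) z + C u

with ``A`` endogenous coupling (1/s, diagonal = self-decay), ``B^(j)``
input-dependent modulation, ``C`` driving gains and ``D^(k)``
activity-dependent gating by region ``k``.  Each region's neuronal
activity drives a balloon-Windkessel hemodynamic cascade

    ds/dt = z - kappa*s - gamma*(f - 1)
    df/dt = s
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f*(1 - (1-rho)**(1/f))/rho - v**(1/alpha) * q / v

observed as percent BOLD signal change

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)),
    k1 = 7*rho, k2 = 2, k3 = 2*rho - 0.2.

Integration is fixed-step RK4 on a microtime grid (default TR/16),
sampling scan n at t = n*TR; runs start from rest and are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import rk4_run
from .model_space import INPUT_INDEX, N_INPUTS, N_REGIONS, ModelSpec

#: default hemodynamic constants (per-region kappa/tau may vary)
KAPPA0 = 0.64   # signal decay, 1/s
GAMMA0 = 0.32   # autoregulation, 1/s
TAU0 = 2.0      # mean transit time, s
ALPHA0 = 0.32   # vessel stiffness
RHO0 = 0.34     # resting oxygen extraction
V00 = 0.02      # resting blood volume fraction
SELF_DECAY = -0.5  # fixed diagonal of A, 1/s


@dataclass
class DCMParameters:
    """Full parameterization of one subject's generative network."""

    A: np.ndarray                      # (6, 6), 1/s
    B: np.ndarray                      # (n_inputs, 6, 6), 1/s
    C: np.ndarray                      # (6, n_inputs), 1/s
    D: np.ndarray                      # (6, 6, 6), per gating region
    kappa: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, KAPPA0))
    gamma: float = GAMMA0
    tau: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, TAU0))
    alpha: float = ALPHA0
    rho: float = RHO0
    v0: float = V00

    def __post_init__(self) -> None:
        self.A = np.array(self.A, dtype=float)
        self.B = np.array(self.B, dtype=float)
        self.C = np.array(self.C, dtype=float)
        self.D = np.array(self.D, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)

    @classmethod
    def zeros(cls) -> "DCMParameters":
        A = np.eye(N_REGIONS) * SELF_DECAY
        return cls(A=A, B=np.zeros((N_INPUTS, N_REGIONS, N_REGIONS)),
                   C=np.zeros((N_REGIONS, N_INPUTS)),
                   D=np.zeros((N_REGIONS, N_REGIONS, N_REGIONS)))

    def validate(self, spec: ModelSpec | None = None) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("A diagonal (self-decay) must be strictly negative")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if not (0 < self.v0 <= 0.1):
            raise ValueError("v0 must lie in (0, 0.1]")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if spec is not None:
            off = ~np.eye(N_REGIONS, dtype=bool)
            if np.any(self.A[off & ~spec.A_mask] != 0):
                raise ValueError("A nonzero outside its mask")
            if np.any(self.B[~spec.B_masks] != 0):
                raise ValueError("B nonzero outside its mask")
            if np.any(self.C[~spec.C_mask] != 0):
                raise ValueError("C nonzero outside its mask")
            if np.any(self.D[~spec.D_masks] != 0):
                raise ValueError("D nonzero outside its mask")

    def copy(self) -> "DCMParameters":
        return DCMParameters(A=self.A.copy(), B=self.B.copy(), C=self.C.copy(),
                             D=self.D.copy(), kappa=self.kappa.copy(),
                             gamma=self.gamma, tau=self.tau.copy(),
                             alpha=self.alpha, rho=self.rho, v0=self.v0)


@dataclass
class InputFunction:
    """Boxcar stimulus functions on the microtime grid.

    ``u`` has one row per microtime bin and one column per input
    (all_faces, negative, positive); runs are concatenated, with
    ``run_starts`` giving each run's first bin.
    """

    u: np.ndarray            # (n_bins, n_inputs), values in {0, 1}
    dt: float                # microtime step, s
    tr: float                # repetition time, s
    scans_per_run: int
    run_starts: np.ndarray   # bin index of each run start

    @property
    def n_runs(self) -> int:
        return len(self.run_starts)

    @property
    def bins_per_scan(self) -> int:
        k = self.tr / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError("microtime step must divide TR")
        return int(round(k))


@dataclass
class BOLDTimeSeries:
    """Sampled BOLD signal, runs concatenated along the scan axis."""

    data: np.ndarray         # (n_scans_total, 6), percent-signal
    tr: float
    run_starts: np.ndarray   # scan index of each run start

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]


# -- pure reference derivatives (dimension generic, used in tests) ---------

def neural_derivative(z: np.ndarray, u: np.ndarray, params: DCMParameters) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B^(j) + sum_k z_k D^(k)) z + C u."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite neural state or input")
    M = params.A + np.tensordot(u, params.B, axes=1)
    M = M + np.tensordot(z, params.D, axes=([0], [0]))
    return M @ z + params.C @ u


def hemodynamic_derivative(state: np.ndarray, z: np.ndarray,
                           params: DCMParameters) -> np.ndarray:
    """Balloon-Windkessel derivatives; ``state`` rows are (s, f, v, q)."""
    state = np.asarray(state, dtype=float)
    s, f, v, q = state[..., 0], state[..., 1], state[..., 2], state[..., 3]
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("hemodynamic state left admissible domain")
    z = np.asarray(z, dtype=float)
    if state.ndim > 1:
        kappa = params.kappa[:state.shape[0]]
        tau = params.tau[:state.shape[0]]
    else:
        kappa = params.kappa[0]
        tau = params.tau[0]
    ds = z - kappa * s - params.gamma * (f - 1.0)
    df = s
    fv = v ** (1.0 / params.alpha)
    dv = (f - fv) / tau
    E = 1.0 - (1.0 - params.rho) ** (1.0 / f)
    dq = (f * E / params.rho - fv * q / v) / tau
    return np.stack([ds, df, dv, dq], axis=-1)


def bold_observe(v: np.ndarray, q: np.ndarray, params: DCMParameters) -> np.ndarray:
    """Percent-signal change from volume and deoxyhemoglobin."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    k1 = 7.0 * params.rho
    k2 = 2.0
    k3 = 2.0 * params.rho - 0.2
    return params.v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


# -- integration -----------------------------------------------------------

_EMPTY_I = np.zeros(0, dtype=np.int64)


def _kernel_args(params: DCMParameters):
    gates = np.array([k for k in range(N_REGIONS) if np.any(params.D[k])],
                     dtype=np.int64)
    neg = INPUT_INDEX["negative"]
    pos = INPUT_INDEX["positive"]
    return (np.ascontiguousarray(params.A),
            np.ascontiguousarray(params.B[neg]),
            np.ascontiguousarray(params.B[pos]),
            np.ascontiguousarray(params.C),
            np.ascontiguousarray(params.D), gates,
            params.kappa.astype(float), float(params.gamma),
            params.tau.astype(float), float(params.alpha), float(params.rho),
            float(params.v0))


def simulate_bold(params: DCMParameters, inputs: InputFunction,
                  spec: ModelSpec | None = None) -> BOLDTimeSeries:
    """Integrate the network from rest over each run and sample at scans.

    Deterministic for fixed inputs; raises on integration blow-up
    (|z| > 10 or an inadmissible hemodynamic state), naming the time.
    """
    params.validate(spec)
    keep = inputs.bins_per_scan
    n_scans = inputs.scans_per_run
    args = _kernel_args(params)
    out = np.empty((inputs.n_runs * n_scans, N_REGIONS))
    run_starts = np.arange(inputs.n_runs) * n_scans
    for r, start in enumerate(inputs.run_starts):
        u_run = np.ascontiguousarray(
            inputs.u[start:start + (n_scans - 1) * keep].astype(float))
        y, _, status = rk4_run(*args, u_run, float(inputs.dt), keep, n_scans,
                               _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I, False)
        if status >= 0:
            t_bad = status * inputs.dt
            raise RuntimeError(
                f"integration blow-up in run {r} at t = {t_bad:.2f} s")
        out[r * n_scans:(r + 1) * n_scans] = y
    return BOLDTimeSeries(data=out, tr=inputs.tr, run_starts=run_starts)
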