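"""Synthetic study generator.

Emulates the study conditions the analysis assumes: 18 subjects, 3 runs
of 159 scans at TR 2.4 s with the first 4 discarded (155 usable), 112
studied faces of 3.5 s each with inter-stimulus intervals drawn from
U(2, 18) s, valences split 38/37/37 (negative/neutral/positive), and a
surprise recognition test mixing the 112 studied with 56 new faces rated
on a six-point confidence scale.

Because 112 faces at the nominal mean ISI do not fit the scan windows,
drawn ISIs are rescaled affinely toward the 2 s floor until each run
fits — the draw keeps its uniform shape over a compressed support, and
the design errors out with an occupancy report if even minimal spacing
overflows.

Recognition responses are generated from the two-high-threshold model:
with discrimination Pr and bias Br, old items are called "old" with
probability H = Pr + Br(1-Pr) and new items with probability
F = Br(1-Pr); confidence within the chosen side is uniform (the
analysis collapses it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generative import (BOLDTimeSeries, DCMParameters, InputFunction,
                         simulate_bold)
from .model_space import (INPUT_INDEX, N_INPUTS, N_REGIONS, REGION_INDEX,
                          ModelSpec)

TR_DEFAULT = 2.4            # s
SCANS_PER_RUN = 155         # 159 acquired minus 4 discarded
N_RUNS = 3
N_STUDIED = 112
N_NEW = 56
FACE_DURATION = 3.5         # s
ISI_RANGE = (2.0, 18.0)     # s
VALENCES = ("negative", "neutral", "positive")
#: as-equal-as-possible valence splits
STUDIED_SPLIT = (38, 37, 37)
NEW_SPLIT = (19, 19, 18)


# -- event designs ---------------------------------------------------------

def sample_design(seed: int, n_runs: int = N_RUNS,
                  scans_per_run: int = SCANS_PER_RUN,
                  n_faces: int = N_STUDIED,
                  valence_split: tuple[int, int, int] = STUDIED_SPLIT,
                  tr: float = TR_DEFAULT,
                  duration: float = FACE_DURATION,
                  isi_range: tuple[float, float] = ISI_RANGE) -> pd.DataFrame:
    """Draw an event table (onset, duration, trial_type, run, face_id).

    Onsets are within-run seconds; runs are filled as evenly as possible
    and valences randomly interleaved.  Deterministic given the seed.
    """
    if sum(valence_split) != n_faces:
        raise ValueError("valence split must sum to the number of faces")
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(VALENCES), valence_split)
    rng.shuffle(labels)
    base, extra = divmod(n_faces, n_runs) if n_runs else (0, 0)
    per_run = [base + (1 if r < extra else 0) for r in range(n_runs)]
    lo, hi = isi_range
    window = scans_per_run * tr
    rows = []
    face_id = 0
    pos = 0
    for run, m in enumerate(per_run):
        if m == 0:
            continue
        isi = rng.uniform(lo, hi, size=m)  # isi[0] is the lead-in delay
        budget = window - m * duration - 1e-6
        min_total = m * lo
        if budget < min_total:
            occ = m * (duration + lo)
            raise ValueError(
                "design does not fit: run {} needs >= {:.1f} s for {} events "
                "but the window is {:.1f} s".format(run, occ, m, window))
        total = isi.sum()
        if total > budget:
            isi = lo + (isi - lo) * (budget - min_total) / (total - min_total)
        t = 0.0
        for k in range(m):
            t += isi[k]
            rows.append((t, duration, labels[pos], run, face_id))
            t += duration
            pos += 1
            face_id += 1
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                       "run", "face_id"])


def events_to_inputs(events: pd.DataFrame, dt: float,
                     n_runs: int = N_RUNS,
                     scans_per_run: int = SCANS_PER_RUN,
                     tr: float = TR_DEFAULT) -> InputFunction:
    """Boxcar stimulus functions: all faces drive the first column,
    valenced faces additionally their own column (neutral only the first).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    keep = int(round(tr / dt))
    bins_per_run = scans_per_run * keep
    u = np.zeros((n_runs * bins_per_run, N_INPUTS))
    for _, ev in events.iterrows():
        run = int(ev["run"])
        start = run * bins_per_run
        # a bin is active if its start time falls inside the event
        b0 = int(np.ceil(ev["onset"] / dt - 1e-9))
        b1 = int(np.ceil((ev["onset"] + ev["duration"]) / dt - 1e-9))
        b1 = min(b1, bins_per_run)
        u[start + b0:start + b1, INPUT_INDEX["all_faces"]] = 1.0
        if ev["trial_type"] in ("negative", "positive"):
            u[start + b0:start + b1, INPUT_INDEX[ev["trial_type"]]] = 1.0
    return InputFunction(u=u, dt=dt, tr=tr, scans_per_run=scans_per_run,
                         run_starts=np.arange(n_runs) * bins_per_run)


# -- cohort ----------------------------------------------------------------

#: group-level endogenous couplings into OFC (posterior medians of the
#: averaged network; remaining couplings are weak generic values chosen
#: to propagate the visual drive through the network)
TO_OFC_DEFAULTS = {"IOG": 0.073, "FUS": 0.047, "SPL": 0.047,
                   "HPC": 0.247, "AMG": -0.085}
MODULATION_DEFAULTS = {
    "negative": {"IOG": -0.096, "FUS": -0.054, "SPL": 0.038,
                 "HPC": 0.011, "AMG": -0.442},
    "positive": {"IOG": -0.095, "FUS": -0.008, "SPL": -0.450,
                 "HPC": -0.027, "AMG": -0.101},
}
_FORWARD_BACKBONE = {("IOG", "FUS"): 0.30, ("IOG", "SPL"): 0.30,
                     ("FUS", "HPC"): 0.20, ("FUS", "AMG"): 0.20,
                     ("SPL", "HPC"): 0.15, ("AMG", "HPC"): 0.15}
DRIVE_GAIN = 0.25
TD_DRIVE_GAIN = 0.15
TD_GATE_DEFAULT = 0.4


def default_group_parameters(spec: ModelSpec,
                             b_values: dict | None = None,
                             d_value: float = TD_GATE_DEFAULT) -> DCMParameters:
    """Group-mean generative parameters consistent with ``spec``'s masks."""
    p = DCMParameters.zeros()
    off = ~np.eye(N_REGIONS, dtype=bool)
    p.A[off] = 0.05
    for (src, dst), w in _FORWARD_BACKBONE.items():
        p.A[REGION_INDEX[dst], REGION_INDEX[src]] = w
    for src, w in TO_OFC_DEFAULTS.items():
        p.A[REGION_INDEX["OFC"], REGION_INDEX[src]] = w
    p.A[off & ~spec.A_mask] = 0.0
    if spec.family == "BU":
        bvals = b_values if b_values is not None else MODULATION_DEFAULTS
        for name in ("negative", "positive"):
            for src in spec.modulated_sources:
                p.B[INPUT_INDEX[name], REGION_INDEX["OFC"],
                    REGION_INDEX[src]] = bvals[name][src]
    p.C[REGION_INDEX["IOG"], INPUT_INDEX["all_faces"]] = DRIVE_GAIN
    if spec.family == "TD":
        p.C[REGION_INDEX["OFC"], INPUT_INDEX["negative"]] = TD_DRIVE_GAIN
        p.C[REGION_INDEX["OFC"], INPUT_INDEX["positive"]] = TD_DRIVE_GAIN
        for src in spec.modulated_sources:
            p.D[REGION_INDEX["OFC"], REGION_INDEX["HPC"], REGION_INDEX[src]] = d_value
    # zero anything the spec does not free (C handled above explicitly)
    p.B[~spec.B_masks] = 0.0
    p.D[~spec.D_masks] = 0.0
    return p


@dataclass
class CohortTruth:
    """Ground truth behind one synthetic cohort."""

    spec: ModelSpec
    subject_params: list[DCMParameters]
    noise_sd: np.ndarray                 # per-region observation noise SD
    behavior: dict[str, tuple[float, float]] = field(default_factory=dict)


def sample_cohort(seed: int, n_subjects: int, group_params: DCMParameters,
                  spec: ModelSpec, between_subject_sd: float = 0.1,
                  noise_sd: float | None = None, snr: float = 5.0,
                  n_runs: int = N_RUNS, scans_per_run: int = SCANS_PER_RUN,
                  tr: float = TR_DEFAULT, dt: float | None = None,
                  n_faces: int = N_STUDIED,
                  drift: bool = False,
                  behavior_truth: dict | None = None
                  ) -> tuple[list[BOLDTimeSeries], list[pd.DataFrame], CohortTruth]:
    """Simulate a cohort: per-subject designs, parameters and noisy BOLD.

    All subjects share one event design (one fixed stimulus sequence per
    cohort); free connectivity entries vary across subjects as
    Normal(group value, between_subject_sd^2), masked entries stay zero.
    When ``noise_sd`` is None it is set per region from the group-mean
    signal as std(signal)/snr.  Unstable subject draws are redrawn up to
    10 times.  Returns (series, event tables, truth).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    dt = tr / 16 if dt is None else dt
    off = ~np.eye(N_REGIONS, dtype=bool)
    series: list[BOLDTimeSeries] = []
    events_all: list[pd.DataFrame] = []
    params_all: list[DCMParameters] = []
    split = _even_split(n_faces)
    noise_vec: np.ndarray | None = None
    if noise_sd is not None:
        noise_vec = np.full(N_REGIONS, float(noise_sd))
    events = sample_design(int(rng.integers(2 ** 31)), n_runs=n_runs,
                           scans_per_run=scans_per_run, n_faces=n_faces,
                           valence_split=split, tr=tr)
    inputs = events_to_inputs(events, dt=dt, n_runs=n_runs,
                              scans_per_run=scans_per_run, tr=tr)
    for s in range(n_subjects):
        for attempt in range(10):
            p = group_params.copy()
            if between_subject_sd > 0:
                p.A[spec.A_mask & off] += rng.normal(
                    0, between_subject_sd, int((spec.A_mask & off).sum()))
                p.B[spec.B_masks] += rng.normal(0, between_subject_sd,
                                                int(spec.B_masks.sum()))
                p.D[spec.D_masks] += rng.normal(0, between_subject_sd,
                                                int(spec.D_masks.sum()))
            try:
                ts = simulate_bold(p, inputs, spec)
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError(f"subject {s}: no stable draw in 10 attempts")
        if noise_vec is None:
            sd = ts.data.std(axis=0)
            noise_vec = np.where(sd > 0, sd, sd.max()) / snr
        ts.data = ts.data + rng.normal(0, 1, ts.data.shape) * noise_vec
        if drift:
            ts.data = ts.data + _cosine_drift(rng, ts, noise_vec)
        series.append(ts)
        events_all.append(events)
        params_all.append(p)
    truth = CohortTruth(spec=spec, subject_params=params_all,
                        noise_sd=noise_vec,
                        behavior=dict(behavior_truth or {}))
    return series, events_all, truth


def _even_split(n: int) -> tuple[int, int, int]:
    base, extra = divmod(n, 3)
    return tuple(base + (1 if k < extra else 0) for k in range(3))


def _cosine_drift(rng: np.random.Generator, ts: BOLDTimeSeries,
                  noise_vec: np.ndarray) -> np.ndarray:
    """Slow cosine drift (periods >= 128 s) per run and region."""
    out = np.zeros_like(ts.data)
    bounds = list(ts.run_starts) + [ts.n_scans]
    for r in range(len(ts.run_starts)):
        n = bounds[r + 1] - bounds[r]
        t = np.arange(n) * ts.tr
        total = n * ts.tr
        periods = [p for p in (total, total / 2) if p >= 128.0]
        for per in periods:
            amp = rng.normal(0, 1, N_REGIONS) * noise_vec
            out[bounds[r]:bounds[r + 1]] += np.cos(2 * np.pi * t[:, None] / per) * amp
    return out


# -- recognition behavior --------------------------------------------------

#: default per-valence (Pr, Br) ground truth: moderate discrimination with
#: an elevated bias for negative faces, the direction the behavioral
#: analysis is built to detect
BEHAVIOR_DEFAULTS = {"negative": (0.35, 0.45),
                     "neutral": (0.35, 0.33),
                     "positive": (0.35, 0.35)}


def two_high_threshold_rates(pr: float, br: float) -> tuple[float, float]:
    """Hit and false-alarm probabilities implied by (Pr, Br)."""
    h = pr + br * (1.0 - pr)
    f = br * (1.0 - pr)
    if not (0.0 <= h <= 1.0):
        raise ValueError("Pr + Br*(1-Pr) outside [0, 1]")
    return h, f


def generate_recognition(seed: int,
                         truth: dict[str, tuple[float, float]] | None = None,
                         n_old_per_valence: tuple[int, int, int] = STUDIED_SPLIT,
                         n_new_per_valence: tuple[int, int, int] = NEW_SPLIT,
                         no_response_rate: float = 0.02,
                         subject: int = 0) -> pd.DataFrame:
    """Simulate one subject's recognition table.

    Columns: subject, face_id, valence, status ('old'/'new'), response
    (1..6 from "sure old" to "sure new", NaN for no response).
    """
    truth = dict(BEHAVIOR_DEFAULTS if truth is None else truth)
    rng = np.random.default_rng(seed)
    rows = []
    face_id = 0
    for vi, val in enumerate(VALENCES):
        pr, br = truth[val]
        if not (0 < pr < 1 and 0 < br < 1):
            raise ValueError("Pr and Br must lie in (0, 1)")
        h, f = two_high_threshold_rates(pr, br)
        for status, n_items, p_old in (("old", n_old_per_valence[vi], h),
                                       ("new", n_new_per_valence[vi], f)):
            for _ in range(n_items):
                if rng.random() < no_response_rate:
                    resp = np.nan
                elif rng.random() < p_old:
                    resp = rng.integers(1, 4)    # old side
                else:
                    resp = rng.integers(4, 7)    # new side
                rows.append((subject, face_id, val, status, resp))
                face_id += 1
    return pd.DataFrame(rows, columns=["subject", "face_id", "valence",
                                       "status", "response"])
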