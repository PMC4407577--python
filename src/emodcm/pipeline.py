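"""End-to-end seeded pipeline: simulate -> invert -> select -> average ->
score -> associate, with all interchange files written as plain text.

Formats: BIDS-style events TSV (onset, duration, trial_type in seconds),
time-series TSV with a region-label header plus a sidecar JSON carrying
TR and run boundaries, model space JSON, evidence TSV, RFX/family JSON,
BMA summary CSV (median/quartiles layout), behavioral CSV, association
CSV and a JSON run log with config hash, derived seeds and per-stage
wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import behavior as beh
from . import group as grp
from . import inversion as inv
from . import synthetic as syn
from .generative import BOLDTimeSeries
from .model_space import (REGIONS, ModelSpec, build_family_partition,
                          enumerate_bottom_up, enumerate_top_down)


@dataclass
class PipelineConfig:
    """Seeded configuration of the full analysis; round-trips via JSON."""

    seed: int = 0
    n_subjects: int = 8
    n_runs: int = 1
    scans_per_run: int = 100
    tr: float = 2.4
    n_faces: int = 24
    # model space: lists of modulated-source subsets per family
    bu_subsets: list = field(default_factory=lambda: [["IOG"], ["SPL"],
                                                      ["IOG", "SPL"], ["AMG"]])
    td_subsets: list = field(default_factory=lambda: [["IOG"], ["FUS"],
                                                      ["SPL"], ["AMG"]])
    # generating model
    generating_family: str = "BU"
    generating_sources: list = field(default_factory=lambda: ["IOG", "SPL"])
    bu_effect: float = 0.5
    td_effect: float = 0.6
    between_subject_sd: float = 0.1
    snr: float = 5.0
    # inversion
    inv_tol: float = 0.05
    inv_max_iter: int = 24
    estimate_hemo: bool = False
    dt_fraction: int = 8          # microtime step = TR / dt_fraction
    # Monte-Carlo sizes
    mc_exceedance: int = 200_000
    mc_bma: int = 2000
    out_dir: str = "emodcm_out"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.generating_family not in ("BU", "TD"):
            raise ValueError("generating family must be BU or TD")
        if not self.bu_subsets or not self.td_subsets:
            raise ValueError("both families need at least one model")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(h[:7], 16)  # < 2**28


def _write_timeseries(path: Path, ts: BOLDTimeSeries) -> None:
    pd.DataFrame(ts.data, columns=list(REGIONS)).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"TR": ts.tr, "run_boundaries": [int(r) for r in ts.run_starts]}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_timeseries(path) -> BOLDTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    return BOLDTimeSeries(data=df.to_numpy(), tr=float(meta["TR"]),
                          run_starts=np.array(meta["run_boundaries"]))


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def build_space(config: PipelineConfig) -> list[ModelSpec]:
    bu = enumerate_bottom_up("explicit_list",
                             [tuple(s) for s in config.bu_subsets], start_id=1)
    td_all = enumerate_top_down(start_id=len(bu) + 1)
    wanted = {tuple(s) for s in config.td_subsets}
    td = [m for m in td_all if m.modulated_sources in wanted]
    for k, m in enumerate(td):
        m.model_id = len(bu) + 1 + k
    return bu + td


def generating_spec(config: PipelineConfig) -> ModelSpec:
    sources = tuple(config.generating_sources)
    if config.generating_family == "BU":
        return enumerate_bottom_up("explicit_list", [sources])[0]
    td = [m for m in enumerate_top_down() if m.modulated_sources == sources]
    if not td:
        raise ValueError(f"invalid TD sources {sources}")
    return td[0]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the results bundle and writes files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.config_hash(), "stages": {}}
    bundle: dict = {}
    t_all = time.perf_counter()

    def stage(name):
        log["stages"][name] = {"seed": config.stage_seed(name)}
        return time.perf_counter()

    try:
        # -- model space --------------------------------------------------
        t0 = stage("model_space")
        models = build_space(config)
        partition = build_family_partition(models)
        from .model_space import save_model_space
        save_model_space(models, out / "model_space.json")
        log["stages"]["model_space"]["wall_s"] = time.perf_counter() - t0
        bundle["models"] = models
        bundle["partition"] = partition

        # -- cohort -------------------------------------------------------
        t0 = stage("cohort")
        gen = generating_spec(config)
        if config.generating_family == "BU":
            bvals = {v: {s: config.bu_effect for s in config.generating_sources}
                     for v in ("negative", "positive")}
            group_params = syn.default_group_parameters(gen, b_values=bvals)
        else:
            group_params = syn.default_group_parameters(gen,
                                                        d_value=config.td_effect)
        dt = config.tr / config.dt_fraction
        series, events, truth = syn.sample_cohort(
            config.stage_seed("cohort"), config.n_subjects, group_params, gen,
            between_subject_sd=config.between_subject_sd, snr=config.snr,
            n_runs=config.n_runs, scans_per_run=config.scans_per_run,
            tr=config.tr, dt=config.tr / 16, n_faces=config.n_faces)
        for s, (ts, ev) in enumerate(zip(series, events)):
            ev.to_csv(out / f"sub-{s:02d}_events.tsv", sep="\t", index=False)
            _write_timeseries(out / f"sub-{s:02d}_timeseries.tsv", ts)
        log["stages"]["cohort"]["wall_s"] = time.perf_counter() - t0
        bundle["truth"] = truth

        # -- inversion ----------------------------------------------------
        t0 = stage("inversion")
        posteriors: dict[tuple, inv.InversionResult] = {}
        F = np.zeros((config.n_subjects, len(models)))
        for s, (ts, ev) in enumerate(zip(series, events)):
            inputs = syn.events_to_inputs(ev, dt=dt, n_runs=config.n_runs,
                                          scans_per_run=config.scans_per_run,
                                          tr=config.tr)
            for mi, m in enumerate(models):
                res = inv.invert(ts, inputs, m, tol=config.inv_tol,
                                 max_iter=config.inv_max_iter,
                                 estimate_hemo=config.estimate_hemo)
                posteriors[(s, m.model_id)] = res
                F[s, mi] = res.free_energy
        evidence = grp.EvidenceMatrix(F=F, subjects=tuple(range(config.n_subjects)),
                                      model_ids=tuple(m.model_id for m in models))
        pd.DataFrame(F, columns=[f"model_{m.model_id}" for m in models]).to_csv(
            out / "evidence.tsv", sep="\t", index=False)
        log["stages"]["inversion"]["wall_s"] = time.perf_counter() - t0
        bundle["evidence"] = evidence
        bundle["posteriors"] = posteriors

        # -- model selection ---------------------------------------------
        t0 = stage("selection")
        fam = grp.family_inference(evidence, partition,
                                   n_samples=config.mc_exceedance,
                                   seed=config.stage_seed("selection"))
        (out / "rfx.json").write_text(json.dumps({
            "alpha": fam.rfx.alpha.tolist(),
            "expected": fam.rfx.expected.tolist(),
            "exceedance": fam.rfx.exceedance.tolist(),
            "model_ids": list(fam.rfx.model_ids)}, indent=1))
        (out / "family.json").write_text(json.dumps({
            "labels": list(fam.labels), "alpha": fam.alpha.tolist(),
            "expected": fam.expected.tolist(),
            "exceedance": fam.exceedance.tolist(),
            "winner": fam.winner}, indent=1))
        log["stages"]["selection"]["wall_s"] = time.perf_counter() - t0
        bundle["family"] = fam

        # -- BMA ----------------------------------------------------------
        t0 = stage("bma")
        bma_res = grp.bma(fam.rfx, posteriors, partition, fam.winner,
                          n_samples=config.mc_bma,
                          seed=config.stage_seed("bma"),
                          subjects=tuple(range(config.n_subjects)))
        summary = grp.summarize_bma(bma_res)
        summary.to_csv(out / "bma_summary.csv", index=False)
        bma_res.to_frame().to_csv(out / "bma_subject_means.csv")
        log["stages"]["bma"]["wall_s"] = time.perf_counter() - t0
        bundle["bma"] = bma_res

        # -- behavior -----------------------------------------------------
        t0 = stage("behavior")
        rng = np.random.default_rng(config.stage_seed("behavior"))
        tables = [syn.generate_recognition(int(rng.integers(2 ** 31)),
                                           subject=s)
                  for s in range(config.n_subjects)]
        recog = pd.concat(tables, ignore_index=True)
        scores = beh.score_recognition(recog)
        scores.to_csv(out / "behavior.csv", index=False)
        pr_wide = beh.scores_wide(scores, "Pr")
        anova = beh.rm_anova(pr_wide[list(beh.VALENCES)].to_numpy())
        log["stages"]["behavior"]["wall_s"] = time.perf_counter() - t0
        bundle["scores"] = scores
        bundle["anova"] = anova

        # -- association --------------------------------------------------
        t0 = stage("association")
        table = assoc.correlate_parameters_behavior(
            bma_res.to_frame(), scores, winning_family=fam.winner)
        table.to_csv(out / "association.csv", index=False)
        log["stages"]["association"]["wall_s"] = time.perf_counter() - t0
        bundle["association"] = table
    except Exception as exc:
        log["error"] = f"{type(exc).__name__}: {exc}"
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
        raise
    log["total_wall_s"] = time.perf_counter() - t_all
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    bundle["log"] = log
    return bundle


# -- replication experiments ----------------------------------------------
# Desk-scale stand-ins for the study's two key simulation claims, with
# problem sizes fixed here once (see docs/methods.md for the rationale).

def family_recovery_run(seed: int, generating_family: str = "BU") -> float:
    """Generate one 18-subject cohort from the given family, invert the
    reduced 4 BU + 4 TD model space for every subject, and return the
    generating family's exceedance probability.

    The bottom-up cohort uses one 155-scan run with 37 faces and a
    two-pathway generator (IOG->OFC and SPL->OFC modulated at 0.5); the
    top-down cohort uses one 100-scan run with 20 faces and OFC gating
    of IOG->HPC at 0.6.  Observation noise is set at SNR 5.
    """
    if generating_family == "BU":
        cfg = PipelineConfig(seed=seed, n_subjects=18, n_runs=1,
                             scans_per_run=155, n_faces=37)
    elif generating_family == "TD":
        cfg = PipelineConfig(seed=seed, n_subjects=18, n_runs=1,
                             scans_per_run=100, n_faces=20,
                             generating_family="TD",
                             generating_sources=["IOG"])
    else:
        raise ValueError("generating family must be BU or TD")
    models = build_space(cfg)
    partition = build_family_partition(models)
    gen = generating_spec(cfg)
    if cfg.generating_family == "BU":
        bvals = {v: {s: cfg.bu_effect for s in cfg.generating_sources}
                 for v in ("negative", "positive")}
        group_params = syn.default_group_parameters(gen, b_values=bvals)
    else:
        group_params = syn.default_group_parameters(gen,
                                                    d_value=cfg.td_effect)
    series, events, _ = syn.sample_cohort(
        cfg.stage_seed("cohort"), cfg.n_subjects, group_params, gen,
        between_subject_sd=cfg.between_subject_sd, snr=cfg.snr,
        n_runs=cfg.n_runs, scans_per_run=cfg.scans_per_run, tr=cfg.tr,
        dt=cfg.tr / 16, n_faces=cfg.n_faces)
    dt = cfg.tr / cfg.dt_fraction
    F = np.zeros((cfg.n_subjects, len(models)))
    for s, (ts, ev) in enumerate(zip(series, events)):
        inputs = syn.events_to_inputs(ev, dt=dt, n_runs=cfg.n_runs,
                                      scans_per_run=cfg.scans_per_run,
                                      tr=cfg.tr)
        for mi, m in enumerate(models):
            F[s, mi] = inv.invert(ts, inputs, m, tol=cfg.inv_tol,
                                  max_iter=cfg.inv_max_iter,
                                  estimate_hemo=cfg.estimate_hemo).free_energy
    evidence = grp.EvidenceMatrix(F=F, subjects=tuple(range(cfg.n_subjects)),
                                  model_ids=tuple(m.model_id for m in models))
    fam = grp.family_inference(evidence, partition,
                               n_samples=cfg.mc_exceedance,
                               seed=cfg.stage_seed("selection"))
    return float(fam.exceedance[fam.labels.index(cfg.generating_family)])


def modulation_recovery_run(seed: int, b_true: float = 0.4,
                            snr: float = 5.0) -> tuple[float, float]:
    """Simulate one full-length subject (3 x 155 scans, 112 faces) from a
    bottom-up model with both valence modulations of IOG->OFC at
    ``b_true``, invert the generating model with full hemodynamic
    estimation, and return the two posterior modulation means.
    """
    spec = enumerate_bottom_up("explicit_list", [("IOG",)])[0]
    bvals = {v: {"IOG": b_true} for v in ("negative", "positive")}
    params = syn.default_group_parameters(spec, b_values=bvals)
    events = syn.sample_design(seed, n_runs=3, scans_per_run=155, n_faces=112)
    fine = syn.events_to_inputs(events, dt=2.4 / 16)
    ts = syn.simulate_bold(params, fine, spec)
    sd = ts.data.std(axis=0)
    noise = np.where(sd > 0, sd, sd.max()) / snr
    rng = np.random.default_rng(seed + 2 ** 20)
    ts.data = ts.data + rng.normal(0, 1, ts.data.shape) * noise
    coarse = syn.events_to_inputs(events, dt=2.4 / 8)
    res = inv.invert(ts, coarse, spec, tol=0.01, max_iter=48,
                     estimate_hemo=True)
    nm = res.named_mean()
    return nm["B:negative:IOG->OFC"], nm["B:positive:IOG->OFC"]
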