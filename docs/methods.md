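# Methods

`emodcm` reimplements, on synthetic data, a dynamic-causal-modeling (DCM)
analysis of how the emotional expression of faces modulates effective
connectivity in a six-region network — inferior occipital gyrus (IOG),
fusiform gyrus (FUS), superior parietal lobule (SPL), hippocampus (HPC),
amygdala (AMG) and orbitofrontal cortex (OFC) — during incidental memory
encoding, together with the recognition-memory behavioral analysis and
the connectivity–behavior association that follow it.

## Generative model

Neuronal dynamics follow the one-state bilinear/nonlinear DCM form

    dz/dt = (A + Σ_j u_j B^(j) + Σ_k z_k D^(k)) z + C u

with inputs `u = (all_faces, negative, positive)` as unit boxcars.
`A` (1/s) is the context-independent coupling; its diagonal is a fixed
self-decay of −0.5 1/s in simulation and is parameterized as
−0.5·exp(a_ii) with a tight prior during inversion. `B^(j)` carries
input-dependent modulation (bottom-up hypotheses), `D^(k)` carries
activity-dependent gating by region k (top-down hypotheses), and `C`
injects driving input.

Each region's activity drives a balloon–Windkessel cascade —
vasodilatory signal s, inflow f, volume v, deoxyhemoglobin q:

    ds/dt = z − κs − γ(f − 1),    df/dt = s,
    τ dv/dt = f − v^(1/α),        τ dq/dt = f·E(f,ρ)/ρ − v^(1/α)·q/v,

with E(f,ρ) = 1 − (1−ρ)^(1/f), observed as percent signal change

    y = V0·(k1(1−q) + k2(1−q/v) + k3(1−v)),
    k1 = 7ρ, k2 = 2, k3 = 2ρ − 0.2.

Defaults: κ = 0.64 1/s, γ = 0.32 1/s, τ = 2.0 s, α = 0.32, ρ = 0.34,
V0 = 0.02; κ and τ may vary per region and are the only hemodynamic
parameters estimated.

**Integration.** Fixed-step RK4 on a microtime grid (default TR/16 =
0.15 s), sampling scan n at t = n·TR; each run starts from rest and runs
are concatenated. The hemodynamic states f, v, q are integrated in log
coordinates. This changes nothing about the ODE but guarantees
positivity and substantially extends the stable step size: in natural
coordinates the stiff v^(1/α) term destabilizes RK4 near 0.6 s steps
whenever inflow is high, which matters because the inverter deliberately
runs on a coarser grid than the simulator (see below). The integrator
aborts with the offending time if |z| > 10 or any |ln f|, |ln v|, |ln q|
exceeds 3 (f ≈ 20 is far outside physiology).

## Model space

All models share the fully connected endogenous backbone (30 directed
inter-regional couplings; self-connections are not enumerated) and the
"all faces" drive into IOG. The bottom-up (BU) family lets both valences
jointly modulate any nonempty subset of {IOG, FUS, SPL, HPC, AMG}→OFC —
full enumeration gives 31 models; a restricted published list can be
supplied as JSON. The top-down (TD) family routes the valences directly
into OFC as driving inputs and lets OFC activity gate any nonempty subset
of {IOG, FUS, SPL, AMG}→HPC — 15 models. Model ordering is deterministic:
family (BU first), subset size, then lexicographic position in the
canonical region order.

Family comparison uses a uniform-family prior: each family receives
equal prior mass split evenly over its members, so the 31-model family
does not outweigh the 15-model family by size alone.

## Inversion (variational Laplace)

Each subject × model fit maximizes the free energy F = accuracy −
complexity, a lower bound on log evidence. The scheme:

- **Gradient.** Forward sensitivity equations dS/dt = J_x S + J_θ are
  integrated alongside the states (cross-checked against finite
  differences in the tests), giving the exact RK4-discretized Jacobian
  of the predicted BOLD with respect to every free parameter.
- **Step.** Gauss–Newton on the log-joint with the prior; a step whose
  recomputed free energy falls below the incumbent is rejected and
  halved (down to 1/64), so accepted free energies are non-decreasing.
- **Noise.** Per-region precisions carry Gamma(2, 0.2) hyperpriors and
  are updated by EM. The hyperprior presumes observations of order one,
  so data and prediction are both scaled by 100 internally; parameter
  estimates are unaffected.
- **Confounds.** An orthonormal discrete-cosine basis per run (periods ≥
  128 s, constant included; 6 columns for a 155-scan run at TR 2.4 s) is
  projected out of data and Jacobian each iteration, absorbing run means
  and slow drift.
- **Priors.** Couplings A (off-diagonal), B, D ~ N(0, 1/16); drives C ~
  N(0, 1); self-decay log-scales ~ N(0, 1/256); log-κ, log-τ ~
  N(0, 0.015). Masked parameters are simply absent from the parameter
  vector (point priors at zero). Initialization at the prior mean; no
  internal randomness, so inversion is deterministic.
- **Convergence.** |ΔF| < 0.01 nats (default) or 64 iterations.

The inverter integrates at a coarser microtime step than the simulator
(TR/8 vs TR/16 in the experiments below) — a deliberate mismatch that
avoids the inverse crime of fitting on the generator's own grid. At
TR/4 the discretization error becomes large enough to distort *model
comparison* (families absorb the error differentially), which is why
TR/8 is the default for evidence-bearing fits.

## Group inference

Random-effects Bayesian model selection treats model identity as a
random effect: Dirichlet(α0) over model frequencies, variational updates
u_nm ∝ exp(F_nm + ψ(α_m) − ψ(Σα)), α = α0 + Σ_n g_nm, iterated to
max|Δα| < 1e-4. Exceedance probabilities are computed by seeded
Dirichlet Monte-Carlo (default 10^6 draws, accurate to ~10^-3); family
exceedance compares summed member frequencies. The family prior enters
through α0_m = M/(n_families · family_size(m)).

Bayesian model averaging draws, per subject, a model from the converged
subject-level posterior g_n restricted to the winning family, then
parameters from that model's Gaussian posterior; parameters absent from
the sampled model are exact zeros. Group summaries report median and
25%/75% quartiles (linear-interpolation convention throughout) of the
per-subject means.

## Behavior

Recognition responses on the 6-point scale collapse to old (1–3) vs new
(4–6); no-response trials are excluded. Two-high-threshold scores:
Pr = H − F (discrimination), Br = F/(1 − Pr) (bias), per valence and
from pooled counts for the total. Perfect discrimination raises an
error rather than applying a correction (an optional ±0.5/n correction
exists but is off by default, since the source analysis reports none).
The emotion effect is tested with a one-way repeated-measures ANOVA
with Greenhouse–Geisser ε from the doubly-centered condition covariance
(no Huynh–Feldt option), partial η² = SS_effect/(SS_effect+SS_error),
and follow-up paired t-tests reporting r = sqrt(t²/(t²+df)).

Associations between BMA estimates and the 8 behavioral measures (Pr,
Br × total + 3 valences) use Spearman correlation (average-tie ranks,
Pearson on ranks, two-sided p via the t approximation; an exact
permutation mode exists for n ≤ 8). Only emotion-relevant pathways are
tested — the 5 endogenous →OFC couplings plus their 10 valence
modulations when BU wins (m = 15), or the →HPC couplings and OFC
gatings when TD wins — with Bonferroni correction across parameters,
the behavioral columns treated as descriptive.

## Synthetic cohorts

The generator emulates the study conditions: 18 subjects, 3 runs × 159
scans at TR 2.4 s with the first 4 discarded (155 usable), 112 studied
faces of 3.5 s with ISI ~ U(2, 18) s and valences split 38/37/37, and a
recognition test adding 56 new faces (19/19/18). One stimulus sequence
is shared by the cohort. Two generator-design points deserve note:

- **ISI compression.** 112 faces at the nominal mean ISI of 10 s need
  ~1512 s of stimulation but the three runs provide 1116 s, so the
  nominal design cannot fit. Drawn ISIs are affinely rescaled toward the
  2 s floor until each run fits its window (preserving the uniform shape
  over a compressed support, effectively U(2, ~10.6) at the default
  counts); a design that cannot fit even at minimal spacing raises an
  error with an occupancy report.
- **Drive amplitude.** The "all faces" gain defaults to 0.25 1/s
  (valence drive into OFC, 0.15), keeping neuronal excursions and
  inflow in the physiological regime (f ≲ 2). Early development used
  0.5, which pushed some between-subject draws into z ≈ 2 and inflow
  f ≈ 7 — outside physiology and outside the coarse-step stability
  region of the integrator.

Endogenous couplings into OFC default to the posterior medians of the
averaged network (IOG 0.073, FUS 0.047, SPL 0.047, HPC 0.247, AMG
−0.085), as do the per-valence modulation defaults; the remaining
backbone uses weak generic values (0.05, with a stronger feed-forward
chain from IOG) chosen to propagate the visual drive. Subjects vary as
Normal(group, 0.1²) on free couplings; observation noise is Gaussian
with SD = std(noise-free signal)/SNR, SNR 5 by default; optional cosine
drift (periods ≥ 128 s) exercises the confound model and is off by
default.

Recognition behavior inverts the scoring model: H = Pr + Br(1−Pr),
F = Br(1−Pr); confidence is uniform within the chosen side (the
analysis collapses it, and the source found no confidence × emotion
interaction); 2% of trials are no-responses. Default truth: Pr = 0.35
for all valences; Br = 0.45/0.33/0.35 for negative/neutral/positive —
an emotion effect on bias, not discrimination, which is the pattern the
behavioral test is built to detect.

## Replication experiments and problem sizes

Two simulation claims are checked end-to-end, with problem sizes chosen
once as desk-scale stand-ins:

- **Modulation recovery.** Full-length single subjects (3 × 155 scans,
  112 faces, SNR 5) generated from a BU model with both valence
  modulations of IOG→OFC at 0.4; the generating model is inverted with
  full hemodynamic estimation (dt = TR/8). Pilot runs recover both
  entries within ±0.04; the acceptance check requires ±0.2 in ≥ 80% of
  20 seeds.
- **Family recovery.** 18-subject cohorts under a reduced 4 BU + 4 TD
  space (BU: {IOG}, {SPL}, {IOG,SPL}, {AMG}; TD singletons). The BU
  cohort uses 1 × 155 scans, 37 faces, a two-pathway generator
  ({IOG,SPL}→OFC modulated at 0.5); the TD cohort uses 1 × 100 scans,
  20 faces, OFC gating of IOG→HPC at 0.6 with valence drive 0.15.
  Inversion: dt = TR/8, ΔF tolerance 0.05, ≤ 24 iterations,
  hemodynamics fixed. The check requires the generating family's
  exceedance to exceed 0.9 in ≥ 8/10 seeds per direction.

A single-pathway BU generator separates less sharply: the TD family's
free valence→OFC drive mimics one modulated pathway almost perfectly at
short scan counts (and has the *looser* prior, so it is cheaper), while
a two-pathway generator, and more scans, make the mimicry measurably
worse. Passing these checks therefore shows recoverability under the
modeled conditions — Gaussian noise, shared design, no motion or
physiological artifacts, a generator inside the fitted model class —
not performance on real fMRI.

## Numerical and degenerate-input conventions

- Quantiles: linear interpolation between order statistics, everywhere.
- rm-ANOVA with a numerically null effect returns F = 0; ε of a
  degenerate covariance returns 1.
- Spearman on a constant vector raises; the association table instead
  marks such cells untestable (NaN, not significant) so a pathway with
  zero posterior mass cannot crash the run.
- Paired t with zero-variance nonzero-mean differences raises rather
  than reporting ±∞.
- Dirichlet exceedance: seeded generator, argmax over gamma draws in
  chunks of 2·10^5.
- BMA covariances receive 1e-12 jitter before Cholesky.

## Known limitations

- The free-energy surface is multimodal; occasional fits stop in local
  optima. The family-recovery criterion absorbs this through the
  random-effects scheme and the ≥ 8/10-seed margin.
- The simulator and inverter share the RK4 family; integration at
  different step sizes avoids the worst inverse crime but not
  model-misspecification effects present with real data.
- Only κ and τ are estimated among hemodynamic parameters; γ, α, ρ, V0
  are fixed at their defaults (a standard identifiability compromise).
- The restricted published BU model list (27 of the 31 subsets) is not
  reconstructable from available material; full enumeration is the
  default and all downstream code is count-agnostic.
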