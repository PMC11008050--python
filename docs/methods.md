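# Methods

This note documents the model, the numerical choices, the synthetic study
design and its limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Neural-mass model

Each region is a reduced Wong–Wang E/I pair; the equations and constants
are listed in the README and in `dmf.DMFParameters`. Integration is
Euler–Maruyama with dt = 1 ms (0.1 ms available via `DMFParameters.dt`);
the Gaussian gating noise is independent per node and population and enters
as σ_g·√dt·N(0,1) per step. Gating variables are clipped to [0, 1] after
every step — with additive noise the equations can otherwise leave the
physical range. Default durations are t_total = 120 s with a 10 s burn-in;
the fitting experiments use 90 s / 5 s and the calibration sweeps 10 s /
2 s, chosen as the shortest windows at which the reported checks are stable.

The f–I curve r = g·(I−I_thr)/(1−exp(−d·g·(I−I_thr))) is evaluated with
guarded tails (exact limit 1/d at threshold, r → 0 for strongly negative
drive, r → g(I−I_thr) for strongly positive drive). Besides correctness,
the guards matter practically: unguarded overflow produces inf/denormal
arithmetic that silently slows the integrator severalfold.

**Initial state.** The integrator starts at S_E = S_I = 0.1 rather than
near zero. A cold start with no inhibitory gating transiently disinhibits
the whole network, which reliably kicks it into its high-rate attractor —
the model is bistable (a ~1 Hz balanced state and a 20–100 Hz saturated
state coexist), and which basin a run lands in would otherwise depend on
an unphysical initial transient.

## FIC calibration

`calibrate_fic` finds the baseline J⁰ by the rate-error recursion

    J_n ← max(J_n + ε·clip(r̄_n − 3.44 Hz, ±5 Hz), J_min)

with ε = 0.02 nA·s, J_min = 0.01 nA, 10 s sweeps whose final state seeds
the next sweep, and convergence when every region's mean rate is within
0.25 Hz of the 3.44 Hz target (comfortably inside the physiological
3–4 Hz band that a longer verification run must then hit). The error clamp
and the carried state stop the recursion from ping-ponging across the
bistable regime early on; the initial guess scales with each region's
excitatory in-strength. If a region's band is genuinely empty (a bistable
node whose low branch is below 3 Hz and high branch above 4 Hz),
calibration raises `ConvergenceError` naming the worst node — not every
random graph is inside the model's stable regime at G = 2.5, and the
package treats that as a diagnosable input property rather than something
to paper over.

## Hemodynamics

The Balloon–Windkessel equations (signal z, inflow f, volume v,
deoxyhemoglobin q; Grubb exponent 0.32, oxygen extraction 0.34, transit
time 0.98 s, decay 0.65 s⁻¹, feedback 0.41 s⁻¹, V0 = 0.02; readout
k1 = 7ρ, k2 = 2, k3 = 2ρ−0.2) are driven by the z-scored excitatory rate
scaled by 0.5, which keeps the model in its quasi-linear regime; a region
with numerically constant rate contributes zero drive. Because the
hemodynamic response lives on ~1 s timescales, the drive is bin-averaged
from the neural dt to a 10 ms integration step (configurable down to the
neural dt; the impulse response changes by far less than the 1 %
step-halving tolerance the tests enforce). BOLD is decimated to TR = 2 s.
Resting drive is an exact fixed point with zero BOLD deviation.

## FC and SSIM

FC is the Pearson correlation matrix of the TR-sampled BOLD signal
(zero-variance regions get zero correlations with a warning; an optional
0.008–0.09 Hz band-pass sits behind a flag and is off by default). Two FC
matrices are compared by the three-term windowed SSIM with constants
c1 = 0.01, c2 = 0.03, c3 = 0.015 exactly as given (not rescaled by a
dynamic range), a 7×7 uniform sliding window (configurable odd size), mean
aggregation over all fully-contained window positions, and the full matrix
— including the diagonal — treated as an image. The model-fit distance is
1 − SSIM. Scikit-image's SSIM implements a different (two-term,
range-scaled) variant and is deliberately not used; the tests check the
implementation against a brute-force per-window loop instead.

## Synthetic study design

The generator (`synthetic`) fabricates every input of the real study:

* **Connectome** — random spanning tree plus uniform edge fill to the exact
  requested density (default 0.3), distance-decaying log-normal weights
  with a heavy tail (σ_log = 1.8) and a 1.5× within-module boost over four
  index-blocks, symmetrised and rescaled to max entry 0.2. The heavy tail
  is deliberate: real streamline-count matrices are dominated by a few
  strong edges, and after max-entry normalisation this keeps row sums small
  enough that the calibrated 3–4 Hz state is collectively stable at
  G = 2.5. With flatter weight distributions (same density, same
  normalisation) the global excitatory loop gain exceeds one and the
  network flips between its down- and up-states, which no FIC vector can
  stabilise.
* **Atrophy maps** — healthy controls are exactly zero (they define the
  w-score reference); patient maps load |N(strength, 0.1·strength)| on a
  focus set (posterior block for the AD-like group, anterior for the
  bvFTD-like group, scaled to the parcellation size) over a weak graded
  background |N(0.12, 0.04)|. The background reflects that
  neurodegeneration is focal in emphasis but not strictly confined, and it
  keeps the model's response to σ graded over the whole fitting range
  instead of saturating once the focus regions saturate.
* **Cohorts** — per (group, site) cells with alternating gender; patients
  draw YWD uniformly on [1, 12] years and carry the hidden truth
  σ = σ0 + slope·YWD (+ gender offset·YWD for women) + N(0, noise_sd).
  Controls have YWD = 0 and σ = 0.
* **FC targets** — full forward simulation (calibrate → modulate →
  integrate → BOLD → FC) at a planted σ, plus optional symmetric
  observation noise on the off-diagonal.

Everything is a pure function of the config seed; per-stage seeds are
derived as CRC32 hashes of (master seed, stage tags).

## Fitting protocol

J⁰ is calibrated once at σ = 0 and reused for every σ evaluation;
recalibrating per σ would re-absorb exactly the inhibition change being
estimated. The optimizer is a Gaussian process (Matérn 5/2, normalised
targets) with expected-improvement acquisition over a 512-point grid in
σ ∈ [−1.5, 0.5]; both interval bounds are always probed among the initial
points, so the returned optimum provably beats them. Repetitions are
independent (own seeds, own GP stream) and the estimate is the
across-repetition mean of the per-repetition argmin.

**Paired simulation (common random numbers).** At desk scale, the sampling
variability of an FC matrix estimated from a few minutes of simulated BOLD
is comparable to the FC difference produced by moving σ by 0.3 — the mean
1 − SSIM between two *independent* runs at the *same* σ exceeds the
σ-induced signal, and its σ-dependence (simulations near the critical
region are more variable) biases any cross-realisation argmin. The recovery
and specificity analyses therefore evaluate the objective with the same
simulation seed(s) the target was generated with
(`FitConfig.eval_seeds = (target_sim_seed(seed),)`). This is the standard
variance-reduction for simulation-based calibration: the objective becomes
an exact, smooth function of σ with its minimum at the generating value,
so the experiments validate the optimizer and the local identifiability of
σ. What they do *not* establish is scan-to-scan generalisation — recovering
σ from an FC realisation whose noise the fitter has never seen would
require far longer scans (the effective information rate of the
hemodynamically filtered signal is a few independent samples per ten
seconds) or ensemble targets averaged over many subjects.

## Progression analysis

`fc_vs_ywd` simulates FC at σ(YWD) for each of n_runs independent runs and
rank-correlates every FC entry with YWD. Two aggregations are provided:
per-run Spearman then averaging (`within_run`, the default), and averaging
the FC matrices over runs before a single Spearman (`run_mean`). The
`run_mean` mode has far better signal-to-noise (level means converge as
1/√n_runs before ranking) and is what the network-overlap acceptance check
uses; `within_run` is retained as the default reading of the repeat-then-
average protocol. Spearman of a constant series is defined as 0 with a
warning. Node scores average incident-edge coefficients of one sign, with
opposite-sign edges contributing zero to a fixed n−1 denominator; top-k
binarisation (k = mask size, ties broken by region index) feeds the
Jaccard overlap. Edge thresholding keeps floor(fraction·n_edges) extreme
edges with lexicographic tie-breaking.

The bundled RSN masks (`data/rsn_synthetic.tsv`) are synthetic index sets
over the 90-region parcellation — five blocks named after the canonical
networks (VN, SN, MN, EXEC, DMN) with one shared region — not anatomical
masks; user-supplied masks in the same two-column format drop in directly.

## Statistics

Thin, explicit wrappers: w-scores standardise against the control mean and
sample SD (ddof = 1); `regress` is simple OLS with signed R and
η²_p = SS_eff/(SS_eff+SS_res); `ancova` fits y ~ factor + covariate with
type-II F tests (the synthetic designs are near-balanced, where type I/II/III
coincide; the formula is overridable); `levene` is the mean-centered
(classical) variant; two-sample comparisons are Welch t-tests with
Benjamini–Hochberg adjustment across the declared family; Cohen's d uses
the (n−1)-weighted pooled SD.

## Known limitations

* No conduction delays, no regional heterogeneity of gain or hemodynamic
  parameters, single-parameter fitting (σ only; G fixed at 2.5).
* The synthetic connectome has no anatomical geometry; module structure is
  index-contiguous. Passing tests demonstrate internal consistency and
  recoverability of planted effects, not agreement with patient data.
* The bistability of the reduced Wong–Wang model at G = 2.5 means strongly
  disinhibited regions respond to σ partly through up-state dwell time
  rather than smoothly; with strongly focal maps and no background this
  saturates the FC response beyond σ·α ≈ −0.25.
* Paired-simulation recovery (above) validates optimizer and local
  identifiability, not cross-realisation inference.
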