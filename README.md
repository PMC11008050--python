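# dmfit

Whole-brain dynamic mean field (DMF) modelling of the loss of local
inhibition in neurodegeneration, with atrophy-modulated feedback inhibition
control, SSIM-based functional-connectivity fitting, and downstream
statistical and disease-progression analyses — all runnable end to end on a
built-in synthetic-data generator with known ground truth.

## Who this is for

Computational neuroscientists who want to (a) infer a regional-inhibition
marker from resting-state fMRI through a biophysical network model, or (b)
stress-test that inference pipeline — calibration, optimization, statistics —
against data where the right answer is planted and known.

## The model

Each of 90 brain regions holds one excitatory (E) and one inhibitory (I)
neural-mass population (reduced Wong–Wang model). Population currents are

```
I_E = W_E·I0 + W₊·J_NMDA·S_E + G·J_NMDA·Σ_p C_np·S_E,p − J_n·S_I
I_I = W_I·I0 + J_NMDA·S_E − S_I
```

with firing rates `r = g(I − I_thr) / (1 − exp(−d·g(I − I_thr)))` and
synaptic gating dynamics

```
dS_E/dt = −S_E/τ_NMDA + (1 − S_E)·γ·r_E + σ_g·v(t)
dS_I/dt = −S_I/τ_GABA + r_I + σ_g·v(t)
```

(standard constants: I0 = 0.382 nA, W_E = 1, W_I = 0.7, W₊ = 1.4,
J_NMDA = 0.15 nA, G = 2.5, g = 310 nC⁻¹, I_thr = 0.403/0.288 nA,
d = 0.16/0.087, τ = 100/10 ms, γ = 0.641, σ_g = 0.01 nA).

The per-region feedback inhibition control (FIC) weight `J_n` is first
calibrated so that every excitatory population fires in the physiological
3–4 Hz band, then modulated by the regional atrophy map `α` (w-scores,
positive = more atrophy):

```
J_n = J_n⁰ · (1 + σ·α_n)
```

The scalar atrophy coupling **σ** is the inferred quantity: σ = 0 means
atrophy leaves inhibition untouched; negative σ means inhibition is lost
exactly where tissue is lost. σ is fitted by Bayesian optimization
(Gaussian-process surrogate, expected improvement) to minimise `1 − SSIM`
between the simulated functional connectivity (FC; Pearson correlations of
Balloon–Windkessel BOLD signals) and a target FC, where SSIM is the
three-term windowed structural similarity with constants 0.01 / 0.03 /
0.015.

Downstream, the package regresses fitted σ against years-with-disease
(YWD), runs ANCOVA / Levene / FDR-corrected Welch tests / Cohen's d on
cohorts, simulates FC change along the fitted σ(YWD) trajectory (edge-wise
Spearman maps) and scores its overlap with resting-state-network masks by
the Jaccard index.

## Worked example

```python
from dmfit import (DMFParameters, FitConfig, SyntheticConfig, calibrate_fic,
                   fit_sigma, gen_atrophy_map, gen_connectome, gen_empirical_fc,
                   integrate, target_sim_seed)

cfg = SyntheticConfig(seed=1, atrophy_strength=1.5)
connectome = gen_connectome(cfg)             # 90x90, max entry 0.2, connected
atrophy = gen_atrophy_map(cfg, "AD")         # focal posterior loading ~1.5

J0 = calibrate_fic(DMFParameters(t_total=10.0, t_burn=2.0), connectome, seed=11)
check = integrate(DMFParameters(t_total=110.0, t_burn=10.0), connectome, J0, seed=123)
print(f"calibrated firing band: [{check.mean_rate.min():.2f}, {check.mean_rate.max():.2f}] Hz")

params = DMFParameters(t_total=90.0, t_burn=5.0)
target = gen_empirical_fc(connectome, atrophy, -0.3, params, seed=77, J0=J0)
result = fit_sigma(target, connectome, atrophy, J0, params,
                   FitConfig(n_calls=12, n_initial=4, n_repetitions=5, seed=5,
                             eval_seeds=(target_sim_seed(77),)))
print(f"recovered sigma = {result.sigma_hat:.3f} (planted -0.3); "
      f"1-SSIM at optimum = {result.objective_mean:.4f}")
```

Output:

```
calibrated firing band: [3.27, 3.41] Hz
recovered sigma = -0.330 (planted -0.3); 1-SSIM at optimum = 0.0005
```

The first line verifies the FIC calibration: after tuning `J⁰`, every
region's 100-second mean excitatory rate sits inside the 3–4 Hz band. The
second line shows paired-simulation parameter recovery: a synthetic FC
target is generated at σ\* = −0.3 and the optimizer, re-using the target's
noise realisation (common random numbers, see `docs/methods.md`), recovers
the planted coupling; the near-zero `1 − SSIM` says the optimum reproduces
the target FC almost exactly.

There is also a CLI (`dmfit synth / calibrate / simulate / fit / stats /
progression / run`); `dmfit run --config pipeline.yaml` executes the whole
study — synthesis, calibration, per-YWD-stratum fits, cohort statistics,
progression maps, RSN overlap — and writes a manifest of every output and
seed. See `tests/test_pipeline.py` for a minimal config.

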