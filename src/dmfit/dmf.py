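"""Whole-brain dynamic mean field (DMF) model with feedback inhibition control.

Each brain region holds one excitatory and one inhibitory neural-mass
population (a reduced Wong-Wang model). Regions are coupled through a
structural connectome acting on the excitatory gating variables. The
per-region inhibitory-to-excitatory weight J_n (feedback inhibition control,
FIC) is calibrated so that every excitatory population fires in the
physiological 3-4 Hz band, and can subsequently be modulated by a regional
atrophy map:

    J_n = J_n0 * (1 + sigma * alpha_n)

where alpha_n is the (positive-is-atrophy) regional atrophy loading and
sigma the global atrophy-coupling parameter fitted elsewhere. sigma = 0
leaves the calibrated balance untouched; negative sigma weakens inhibition
in atrophied regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import dmf_step_loop
from ._seeds import derive_seed
from .errors import ConvergenceError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "DMFParameters",
    "StructuralConnectome",
    "AtrophyMap",
    "FICVector",
    "SimulationOutput",
    "transfer_rate",
    "currents",
    "integrate",
    "calibrate_fic",
    "modulate_fic",
]


@dataclass
class DMFParameters:
    """Scalar constants of the neural-mass equations plus integration settings.

    Currents are in nA, times in seconds, rates in Hz. The defaults are the
    standard parameterisation of the reduced Wong-Wang model with global
    coupling G = 2.5.
    """

    I0: float = 0.382          # external current, nA
    W_E: float = 1.0           # excitatory scaling of I0
    W_I: float = 0.7           # inhibitory scaling of I0
    W_plus: float = 1.4        # local excitatory recurrence
    J_NMDA: float = 0.15       # excitatory coupling current, nA
    G: float = 2.5             # global coupling
    g_E: float = 310.0         # excitatory gain, nC^-1
    g_I: float = 310.0         # inhibitory gain, nC^-1
    I_thr_E: float = 0.403     # excitatory threshold current, nA
    I_thr_I: float = 0.288     # inhibitory threshold current, nA
    d_E: float = 0.16          # excitatory sigmoid shape constant
    d_I: float = 0.087         # inhibitory sigmoid shape constant
    tau_NMDA: float = 0.1      # excitatory (NMDA) decay constant, s
    tau_GABA: float = 0.01     # inhibitory (GABA) decay constant, s
    gamma: float = 0.641       # excitatory kinetic constant
    sigma_g: float = 0.01      # gating-noise amplitude, nA
    dt: float = 1e-3           # Euler-Maruyama step, s
    t_total: float = 120.0     # simulated duration, s
    t_burn: float = 10.0       # discarded transient, s

    def validate(self) -> None:
        if self.tau_NMDA <= 0 or self.tau_GABA <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0 or self.dt > self.tau_GABA / 5:
            raise ValueError(
                f"dt = {self.dt} must be positive and well below tau_GABA = {self.tau_GABA}"
            )
        if not 0 <= self.t_burn < self.t_total:
            raise ValueError("need 0 <= t_burn < t_total")

    def with_(self, **kwargs) -> "DMFParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class StructuralConnectome:
    """Structural coupling matrix C_np (square, symmetric, nonnegative, zero diagonal)."""

    C: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.labels is None:
            self.labels = [f"R{i:02d}" for i in range(self.C.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        C = self.C
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.allclose(C, C.T, atol=atol):
            raise ValueError("connectome must be symmetric")
        if (C < 0).any():
            raise ValueError("connectome weights must be nonnegative")
        if np.abs(np.diag(C)).max(initial=0.0) > atol:
            raise ValueError("connectome diagonal must be zero")


@dataclass
class AtrophyMap:
    """Per-region atrophy loading alpha_n.

    Stored in the positive-is-atrophy convention: larger values mean more
    atrophy, so a negative coupling sigma reduces inhibition (J_n) exactly in
    the atrophied regions.
    """

    alpha: np.ndarray
    convention: str = "positive-is-atrophy"

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()


@dataclass
class FICVector:
    """Baseline (J0) and effective (J) per-region feedback inhibition weights, nA."""

    J0: np.ndarray
    J: np.ndarray | None = None

    def __post_init__(self):
        self.J0 = np.asarray(self.J0, dtype=float).ravel()
        if self.J is None:
            self.J = self.J0.copy()
        else:
            self.J = np.asarray(self.J, dtype=float).ravel()
        if (self.J0 <= 0).any():
            raise ValueError("baseline FIC weights must be positive")


@dataclass
class SimulationOutput:
    """Recorded excitatory activity of one simulation (post burn-in)."""

    r_E_series: np.ndarray      # (n_steps_recorded, n_regions) firing rates, Hz
    S_E_series: np.ndarray      # (n_steps_recorded, n_regions) gating fractions
    mean_rate: np.ndarray       # time-averaged excitatory rate per region, Hz
    seed: int
    dt: float
    params: DMFParameters = field(repr=False, default=None)
    final_state: tuple = field(repr=False, default=None)  # (S_E, S_I) at the last step


def _as_matrix(connectome) -> np.ndarray:
    C = connectome.C if isinstance(connectome, StructuralConnectome) else np.asarray(connectome, float)
    return np.ascontiguousarray(C, dtype=float)


def _as_alpha(atrophy) -> np.ndarray:
    return atrophy.alpha if isinstance(atrophy, AtrophyMap) else np.asarray(atrophy, float).ravel()


def _as_J(fic) -> np.ndarray:
    return fic.J if isinstance(fic, FICVector) else np.asarray(fic, float).ravel()


def transfer_rate(I, population: str, params: DMFParameters | None = None):
    """Population firing rate (Hz) for input current I (nA).

    Implements r = g*(I - I_thr) / (1 - exp(-d*g*(I - I_thr))) with the
    removable singularity at I = I_thr evaluated as its limit 1/d. Total
    function: strictly increasing in I and always > 0 (tending to 0+ for
    strongly hyperpolarising currents).
    """
    p = params or DMFParameters()
    if population == "E":
        g, thr, d = p.g_E, p.I_thr_E, p.d_E
    elif population == "I":
        g, thr, d = p.g_I, p.I_thr_I, p.d_I
    else:
        raise ValueError(f"unknown population {population!r}; expected 'E' or 'I'")
    I = np.asarray(I, dtype=float)
    x = g * (I - thr)
    u = d * x
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        r = np.where(
            u > 30.0,
            x,
            np.where(
                u < -30.0,
                0.0,
                np.where(np.abs(u) < 1e-9, 1.0 / d, x / (1.0 - np.exp(-np.clip(u, -30.0, 30.0)))),
            ),
        )
    return r if r.ndim else float(r)


def currents(S_E, S_I, params: DMFParameters, connectome, fic):
    """Excitatory and inhibitory input currents (nA) for a given gating state.

    I_E = W_E*I0 + W_plus*J_NMDA*S_E + G*J_NMDA*(C @ S_E) - J*S_I
    I_I = W_I*I0 + J_NMDA*S_E - S_I
    """
    C = _as_matrix(connectome)
    J = _as_J(fic)
    S_E = np.asarray(S_E, float).ravel()
    S_I = np.asarray(S_I, float).ravel()
    n = C.shape[0]
    if not (len(S_E) == len(S_I) == len(J) == n):
        raise ValueError(
            f"dimension mismatch: connectome {n}, S_E {len(S_E)}, S_I {len(S_I)}, J {len(J)}"
        )
    p = params
    I_E = p.W_E * p.I0 + p.W_plus * p.J_NMDA * S_E + p.G * p.J_NMDA * (C @ S_E) - J * S_I
    I_I = p.W_I * p.I0 + p.J_NMDA * S_E - S_I
    return I_E, I_I


def integrate(
    params: DMFParameters,
    connectome,
    fic,
    seed: int,
    initial_state: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimulationOutput:
    """Euler-Maruyama integration of the gating equations.

    dS_E/dt = -S_E/tau_NMDA + (1 - S_E)*gamma*r_E + sigma_g*v(t)
    dS_I/dt = -S_I/tau_GABA + r_I + sigma_g*v(t)

    with independent standard-normal noise v per node and population, scaled
    by sigma_g*sqrt(dt). Gatings are clipped to [0, 1] after every step; the
    first t_burn seconds are discarded.
    """
    params.validate()
    C = _as_matrix(connectome)
    J = np.ascontiguousarray(_as_J(fic))
    n = C.shape[0]
    if len(J) != n:
        raise ValueError(f"FIC length {len(J)} does not match connectome size {n}")
    n_steps = int(round(params.t_total / params.dt))
    rec_from = int(round(params.t_burn / params.dt))
    rng = np.random.default_rng(seed)
    if params.sigma_g != 0.0:
        noise = rng.standard_normal((n_steps, 2 * n))
    else:
        noise = np.zeros((n_steps, 2 * n))
    if initial_state is None:
        # start inside the basin of the low-activity state; a cold start with
        # no inhibition (S_I ~ 0) transiently disinhibits the network and can
        # kick it into its high-rate attractor
        S_E0 = np.full(n, 0.1)
        S_I0 = np.full(n, 0.1)
    else:
        S_E0 = np.asarray(initial_state[0], float).copy()
        S_I0 = np.asarray(initial_state[1], float).copy()
    n_rec = n_steps - rec_from
    rE_out = np.empty((n_rec, n), dtype=np.float32)
    SE_out = np.empty((n_rec, n), dtype=np.float32)
    S_E_fin, S_I_fin = dmf_step_loop(
        C, J,
        params.I0, params.W_E, params.W_I, params.W_plus, params.J_NMDA, params.G,
        params.g_E, params.g_I, params.I_thr_E, params.I_thr_I, params.d_E, params.d_I,
        params.tau_NMDA, params.tau_GABA, params.gamma, params.sigma_g,
        params.dt, n_steps, rec_from, noise, S_E0, S_I0, rE_out, SE_out,
    )
    mean_rate = rE_out.mean(axis=0, dtype=np.float64)
    if not np.all(np.isfinite(mean_rate)):
        raise NumericalError(
            f"NaN/inf in firing rates; integration diverged at dt = {params.dt}"
        )
    return SimulationOutput(
        r_E_series=rE_out, S_E_series=SE_out, mean_rate=mean_rate,
        seed=seed, dt=params.dt, params=params, final_state=(S_E_fin, S_I_fin),
    )


def modulate_fic(fic, sigma: float, atrophy, j_min: float = 0.01) -> FICVector:
    """Atrophy modulation of the baseline FIC: J = J0 * (1 + sigma * alpha).

    Values are floored at j_min: strongly negative sigma*alpha would
    otherwise turn inhibition negative (runaway excitation, numerically
    unstable).
    """
    J0 = fic.J0 if isinstance(fic, FICVector) else np.asarray(fic, float).ravel()
    alpha = _as_alpha(atrophy)
    if len(alpha) != len(J0):
        raise ValueError(f"atrophy length {len(alpha)} does not match FIC length {len(J0)}")
    J = J0 * (1.0 + sigma * alpha)
    n_floored = int((J < j_min).sum())
    if n_floored:
        logger.warning(
            "modulate_fic: %d region(s) floored at J_min = %g (sigma = %g)",
            n_floored, j_min, sigma,
        )
        J = np.maximum(J, j_min)
    return FICVector(J0=J0, J=J)


def calibrate_fic(
    params: DMFParameters,
    connectome,
    target_rate: float = 3.44,
    eps: float = 0.02,
    j_min: float = 0.01,
    max_iter: int = 200,
    rate_tol: float = 0.25,
    sweep_duration: float = 10.0,
    sweep_burn: float = 2.0,
    seed: int = 0,
) -> FICVector:
    """Baseline FIC calibration by recursive rate-error adjustment.

    Repeatedly simulates `sweep_duration` seconds and nudges each region's
    inhibitory weight toward the target excitatory rate:

        J_n <- max(J_n + eps * (rbar_n - target_rate), j_min)

    until every node's mean rate is within rate_tol of target_rate (which
    places it comfortably inside the physiological [3, 4] Hz band) or
    max_iter sweeps have run. The initial guess scales with each region's
    total excitatory in-strength. Raises ConvergenceError naming the worst
    node if the band is not reached.
    """
    C = _as_matrix(connectome)
    n = C.shape[0]
    sweep_params = params.with_(t_total=sweep_duration, t_burn=sweep_burn)
    J = 0.75 * params.G * params.J_NMDA * C.sum(axis=1) + 1.0
    J = np.maximum(J, j_min)
    rates = None
    state = None
    for it in range(max_iter):
        out = integrate(
            sweep_params, C, J, seed=derive_seed(seed, "fic-sweep", it),
            initial_state=state,
        )
        state = out.final_state  # track the stable low-activity branch
        rates = out.mean_rate
        err = np.clip(rates - target_rate, -5.0, 5.0)
        if np.abs(err).max() < rate_tol:
            logger.info("calibrate_fic converged after %d sweeps", it + 1)
            return FICVector(J0=np.maximum(J, j_min))
        J = np.maximum(J + eps * err, j_min)
    worst = int(np.abs(rates - target_rate).argmax())
    raise ConvergenceError(
        f"FIC calibration did not converge in {max_iter} sweeps; "
        f"worst node {worst} at {rates[worst]:.2f} Hz (target {target_rate} Hz)"
    )
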