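"""Synthetic inputs with known ground truth for the whole pipeline.

Real studies of this kind consume a DTI structural connectome, per-region
gray-matter atrophy w-scores, subject-level empirical FC matrices and a
clinical cohort table. This module fabricates all of them with planted
parameters so that every downstream stage (FIC calibration, sigma fitting,
cohort statistics, progression mapping) can be tested against a known
truth:

* a connected, weighted, distance-decaying connectome with modular overlay,
  rescaled so its maximum entry is 0.2 (the normalisation under which the
  global coupling G = 2.5 keeps the model in its working regime);
* group atrophy maps with loading concentrated on a focus set of regions,
  stored positive-is-atrophy (healthy controls are all zeros by the w-score
  definition);
* cohorts in which each patient's true atrophy coupling follows a planted
  linear years-with-disease (YWD) relation with optional gender-specific
  slope offset;
* "empirical" FC targets produced by the forward model at a planted
  sigma_true, plus optional observation noise.

Every generator is a pure function of the config seed: the same seed gives
bit-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .dmf import AtrophyMap, DMFParameters, StructuralConnectome, calibrate_fic, modulate_fic
from .forward import simulate_fc
from .hemodynamics import BWParameters
from .similarity import FCMatrix

__all__ = [
    "SyntheticConfig",
    "DEFAULT_FOCI",
    "gen_connectome",
    "gen_atrophy_map",
    "gen_cohort",
    "gen_empirical_fc",
    "write_manifest",
]

GROUPS = ("HC", "AD", "bvFTD")
SITES = ("HIC", "Latam")
GENDERS = ("F", "M")

# Synthetic focus sets: a posterior (temporo-parietal-like) block for the
# AD-like condition and an anterior (fronto-insular-like) block for the
# bvFTD-like condition, on the 90-region synthetic parcellation.
DEFAULT_FOCI = {
    "AD": tuple(range(40, 52)),
    "bvFTD": tuple(range(0, 12)),
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study.

    noise_sd is used both as the FC observation-noise SD and as the SD of
    the subject-level jitter on the planted sigma values in the cohort.
    """

    n_regions: int = 90
    connectome_density: float = 0.3
    atrophy_focus: tuple[int, ...] | None = None   # None -> group-specific default
    atrophy_strength: float = 1.5                  # mean |w-score| on focus regions
    sigma_true: float = -0.3                       # planted atrophy coupling (baseline)
    ywd_slope: float = -0.02                       # planted change of sigma per year
    gender_effect: float = -0.01                   # additive slope offset for F
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0 < self.connectome_density <= 1:
            raise ValueError("connectome_density must lie in (0, 1]")
        if self.atrophy_focus is not None:
            focus = np.asarray(self.atrophy_focus, dtype=int)
            if focus.size and (focus.min() < 0 or focus.max() >= self.n_regions):
                raise ValueError("atrophy_focus indices out of range")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def gen_connectome(cfg: SyntheticConfig) -> StructuralConnectome:
    """Random connected weighted connectome with the requested edge density.

    Construction: a random spanning tree guarantees connectivity; the
    remaining edges are drawn uniformly to hit the requested density
    exactly. Weights decay with Euclidean distance between random 3-D node
    positions, carry log-normal heterogeneity, and are boosted within four
    index-contiguous modules. The matrix is symmetrised, zero-diagonal, and
    rescaled so its maximum entry is 0.2.
    """
    cfg.validate()
    n = cfg.n_regions
    rng = np.random.default_rng(derive_seed(cfg.seed, "connectome"))
    m_pairs = n * (n - 1) // 2
    target_edges = int(round(cfg.connectome_density * m_pairs))
    if target_edges < n - 1:
        raise ValueError(
            f"density {cfg.connectome_density} gives {target_edges} edges, "
            f"fewer than the {n - 1} needed to keep {n} regions connected"
        )
    pos = rng.uniform(size=(n, 3))
    # random recursive tree: node k attaches to a uniformly chosen earlier node
    order = rng.permutation(n)
    edges = set()
    for k in range(1, n):
        a = order[k]
        b = order[rng.integers(0, k)]
        edges.add((min(a, b), max(a, b)))
    # uniform fill to the target count
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    remaining = [e for e in all_pairs if e not in edges]
    extra = target_edges - len(edges)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        for k in idx:
            edges.add(remaining[k])
    module = np.floor_divide(np.arange(n), max(1, int(np.ceil(n / 4))))
    C = np.zeros((n, n))
    # heavy-tailed weights (as in streamline-count matrices): after
    # max-normalisation most edges are weak, keeping row sums small enough
    # that the balanced low-firing state stays collectively stable at G = 2.5
    for i, j in edges:
        d = np.linalg.norm(pos[i] - pos[j])
        w = np.exp(-d / 0.3) * rng.lognormal(mean=0.0, sigma=1.8)
        if module[i] == module[j]:
            w *= 1.5
        C[i, j] = C[j, i] = w
    C *= 0.2 / C.max()
    return StructuralConnectome(C=C)


def gen_atrophy_map(cfg: SyntheticConfig, group: str) -> AtrophyMap:
    """Group-level atrophy loading (positive-is-atrophy convention).

    Healthy controls are exactly zero (they define the w-score reference).
    Patient groups load ~ atrophy_strength on the focus regions, with mild
    heterogeneity, plus a weak graded background elsewhere (neurodegeneration
    is focal in emphasis but not strictly confined; the background also keeps
    the model's response to the atrophy coupling graded over the whole
    fitting range instead of saturating once the focus regions saturate).
    """
    cfg.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    n = cfg.n_regions
    if group == "HC":
        return AtrophyMap(alpha=np.zeros(n))
    focus = cfg.atrophy_focus
    if focus is None:
        # default foci are defined on the 90-region parcellation; rescale
        # proportionally for other sizes
        focus = tuple({min(n - 1, int(i * n / 90)) for i in DEFAULT_FOCI[group]})
    focus = np.asarray(sorted(set(int(i) for i in focus)), dtype=int)
    rng = np.random.default_rng(derive_seed(cfg.seed, "atrophy", group))
    alpha = np.abs(rng.normal(0.12, 0.04, size=n))  # weak graded background
    alpha[focus] = np.abs(rng.normal(cfg.atrophy_strength, 0.1 * abs(cfg.atrophy_strength), size=focus.size))
    return AtrophyMap(alpha=alpha)


def gen_cohort(cfg: SyntheticConfig, n_per_cell: int | dict = 10) -> pd.DataFrame:
    """Cohort table with a planted linear sigma-YWD relation.

    Each patient's hidden truth is
        sigma_true = sigma0 + ywd_slope * ywd + [gender_effect * ywd if F]
    plus N(0, noise_sd) jitter, with sigma0 = cfg.sigma_true. Healthy
    controls have ywd = 0 and sigma_true = 0 by construction. n_per_cell is
    either a single count per (group, site) cell or a {(group, site): n}
    mapping.
    """
    cfg.validate()
    if isinstance(n_per_cell, int):
        if n_per_cell <= 0:
            raise ValueError("n_per_cell must be positive")
        cells = {(g, s): n_per_cell for g in GROUPS for s in SITES}
    else:
        cells = {k: int(v) for k, v in n_per_cell.items()}
        if any(v <= 0 for v in cells.values()):
            raise ValueError("n_per_cell entries must be positive")
    rng = np.random.default_rng(derive_seed(cfg.seed, "cohort"))
    rows = []
    sid = 0
    for (group, site), count in sorted(cells.items()):
        for _ in range(count):
            gender = GENDERS[int(rng.integers(0, 2))]
            if group == "HC":
                ywd = 0.0
                sigma = 0.0
            else:
                ywd = float(rng.uniform(1.0, 12.0))
                slope = cfg.ywd_slope + (cfg.gender_effect if gender == "F" else 0.0)
                sigma = cfg.sigma_true + slope * ywd + float(rng.normal(0.0, cfg.noise_sd))
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "group": group,
                    "site": site,
                    "gender": gender,
                    "ywd": ywd,
                    "sigma_true": sigma,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def gen_empirical_fc(
    connectome,
    atrophy,
    sigma_true: float,
    dmf_params: DMFParameters | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    J0=None,
    bw: BWParameters | None = None,
) -> FCMatrix:
    """Forward-simulated FC target at a planted sigma, plus observation noise.

    Runs calibrate (unless a pre-calibrated J0 is supplied) -> modulate ->
    integrate -> BOLD -> FC, then adds N(0, noise_sd) to the off-diagonal
    entries, resymmetrises and resets the diagonal to 1.
    """
    params = dmf_params or DMFParameters()
    if J0 is None:
        J0 = calibrate_fic(params, connectome, seed=derive_seed(seed, "target-fic"))
    fic = modulate_fic(J0, sigma_true, atrophy)
    fc = simulate_fc(connectome, fic, params, seed=derive_seed(seed, "target-sim"), bw=bw)
    if noise_sd > 0:
        rng = np.random.default_rng(derive_seed(seed, "target-noise"))
        n = fc.n_regions
        eps = rng.normal(0.0, noise_sd, size=(n, n))
        eps = (eps + eps.T) / 2.0
        values = np.clip(fc.values + eps, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
        fc = FCMatrix(values=values)
    return fc


def target_sim_seed(seed: int) -> int:
    """Simulation seed used by gen_empirical_fc's forward run.

    Passing this as FitConfig.eval_seeds pairs the fit simulations with the
    target's noise realisation (common random numbers).
    """
    return derive_seed(seed, "target-sim")


def write_manifest(path: str | os.PathLike, entries: dict) -> None:
    """Write a flat key: value manifest (one entry per line, sorted keys)."""
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}: {entries[key]}\n")
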