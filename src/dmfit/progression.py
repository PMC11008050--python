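"""Model-based extrapolation of FC change with disease duration.

Given a mapping from years-with-disease (YWD) to the fitted atrophy
coupling sigma(t), the forward model is simulated repeatedly at each level
and every FC entry is rank-correlated (Spearman) with YWD within each run;
the per-edge coefficients are then averaged over runs. Node-level scores
(mean incident-edge coefficient, separately for positive and negative
edges) are thresholded to the size of each resting-state network (RSN) and
compared to the network masks with the Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .dmf import DMFParameters, modulate_fic
from .forward import simulate_fc
from .hemodynamics import BWParameters

__all__ = [
    "ProgressionMap",
    "fc_vs_ywd",
    "node_scores",
    "threshold_edges",
    "rsn_overlap",
    "jaccard",
    "read_rsn_masks",
    "default_rsn_masks",
]


@dataclass
class ProgressionMap:
    """Mean Spearman correlation of each FC entry with YWD."""

    rho: np.ndarray          # (n, n), symmetric, diagonal 0
    n_runs: int
    ywd_levels: np.ndarray


def _edgewise_spearman(fc_stack: np.ndarray, ywd: np.ndarray) -> np.ndarray:
    """Spearman rank correlation of each matrix entry across YWD levels.

    fc_stack has shape (L, n, n). Entries constant across levels get rho = 0
    (rank correlation is undefined there) with a warning.
    """
    from scipy.stats import rankdata

    L = fc_stack.shape[0]
    ranks = rankdata(fc_stack, axis=0)
    y_rank = rankdata(np.asarray(ywd, dtype=float))
    ry = (y_rank - y_rank.mean())[:, None, None]
    rx = ranks - ranks.mean(axis=0)
    num = (rx * ry).sum(axis=0)
    den = np.sqrt((rx**2).sum(axis=0) * float((ry**2).sum()))
    constant = den == 0
    if constant.any():
        off_diag_constant = int(constant.sum() - fc_stack.shape[1])
        if off_diag_constant > 0:
            warnings.warn(
                f"{off_diag_constant} FC entr(ies) constant across YWD levels; rho set to 0",
                stacklevel=2,
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(constant, 0.0, num / np.where(den == 0, 1.0, den))
    return rho


def fc_vs_ywd(
    sigma_by_ywd: dict,
    connectome,
    atrophy,
    J0,
    params: DMFParameters,
    n_runs: int = 100,
    seed: int = 0,
    bw: BWParameters | None = None,
    average: str = "within_run",
) -> ProgressionMap:
    """Edge-wise Spearman correlation between simulated FC and YWD.

    For each run and each YWD level t the model is simulated at sigma(t);
    with average="within_run" (default) the rank correlation across levels
    is computed per run and then averaged over runs, while
    average="run_mean" first averages the FC matrices over runs and
    computes a single rank correlation.
    """
    if len(sigma_by_ywd) < 3:
        raise ValueError("need at least 3 YWD levels")
    if average not in ("within_run", "run_mean"):
        raise ValueError("average must be 'within_run' or 'run_mean'")
    ywd = np.asarray(sorted(sigma_by_ywd), dtype=float)
    sigmas = np.asarray([sigma_by_ywd[t] for t in sorted(sigma_by_ywd)], dtype=float)
    if not np.all(np.isfinite(sigmas)):
        raise ValueError("sigma values must be finite")
    fics = [modulate_fic(J0, s, atrophy) for s in sigmas]
    n = fics[0].J.shape[0]
    L = len(ywd)
    if average == "within_run":
        acc = np.zeros((n, n))
        for r in range(n_runs):
            stack = np.empty((L, n, n))
            for k, fic in enumerate(fics):
                fc = simulate_fc(
                    connectome, fic, params, seed=derive_seed(seed, "prog", r, k), bw=bw
                )
                stack[k] = fc.values
            acc += _edgewise_spearman(stack, ywd)
        rho = acc / n_runs
    else:
        stack = np.zeros((L, n, n))
        for r in range(n_runs):
            for k, fic in enumerate(fics):
                fc = simulate_fc(
                    connectome, fic, params, seed=derive_seed(seed, "prog", r, k), bw=bw
                )
                stack[k] += fc.values
        stack /= n_runs
        rho = _edgewise_spearman(stack, ywd)
    np.fill_diagonal(rho, 0.0)
    rho = (rho + rho.T) / 2.0
    return ProgressionMap(rho=rho, n_runs=n_runs, ywd_levels=ywd)


def node_scores(pmap, sign: str) -> np.ndarray:
    """Mean incident-edge coefficient per region, restricted to one sign.

    Edges of the opposite sign contribute 0 to the mean (the denominator is
    always the full n-1 incident edges). Positive-sign scores are >= 0,
    negative-sign scores <= 0.
    """
    rho = pmap.rho if isinstance(pmap, ProgressionMap) else np.asarray(pmap, dtype=float)
    n = rho.shape[0]
    M = rho.copy()
    np.fill_diagonal(M, 0.0)
    if sign == "positive":
        M = np.where(M > 0, M, 0.0)
    elif sign == "negative":
        M = np.where(M < 0, M, 0.0)
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    return M.sum(axis=1) / (n - 1)


def threshold_edges(pmap, fraction: float, sign: str = "negative") -> np.ndarray:
    """The floor(fraction * n_edges) most extreme undirected edges of one sign.

    Returns an array of (i, j) index pairs with i < j. Ties at the cut are
    broken by the fixed lexicographic (i, j) edge ordering, so the result is
    deterministic.
    """
    rho = pmap.rho if isinstance(pmap, ProgressionMap) else np.asarray(pmap, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = rho.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = rho[iu, ju]
    k = int(np.floor(fraction * len(vals)))
    if sign == "negative":
        key = vals
    elif sign == "positive":
        key = -vals
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    order = np.lexsort((ju, iu, key))  # primary: extremity; ties: (i, j)
    sel = order[:k]
    return np.column_stack([iu[sel], ju[sel]])


def jaccard(a, b) -> float:
    """Jaccard index |a & b| / |a | b| of two index sets."""
    sa, sb = set(map(int, a)), set(map(int, b))
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def rsn_overlap(scores, masks: dict, select: str = "largest") -> dict:
    """Jaccard overlap between thresholded node scores and each RSN mask.

    For a network with k member regions the score vector is binarised by
    taking its top-k regions (select="largest"; use "smallest" for
    negative-sign scores, where more negative means stronger). Ties are
    broken by region index for determinism.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    out = {}
    for name, members in masks.items():
        members = sorted(set(int(i) for i in members))
        if not members:
            raise ValueError(f"mask {name!r} is empty")
        k = len(members)
        if k > n:
            raise ValueError(f"mask {name!r} has {k} members but only {n} regions exist")
        key = -scores if select == "largest" else scores
        order = np.lexsort((np.arange(n), key))
        top = order[:k]
        out[name] = jaccard(top, members)
    return out


def read_rsn_masks(path) -> dict:
    """Read RSN membership from a two-column text file (network, 0-based index)."""
    masks: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'network index', got {line!r}")
            name, idx = parts
            masks.setdefault(name, []).append(int(idx))
    return {k: sorted(set(v)) for k, v in masks.items()}


def default_rsn_masks() -> dict:
    """Bundled synthetic five-network masks over the 90-region parcellation."""
    from importlib.resources import files

    return read_rsn_masks(files("dmfit").joinpath("data/rsn_synthetic.tsv"))
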