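"""Functional connectivity and structural-similarity comparison of FC matrices.

FC is the region-by-region Pearson correlation of BOLD time series. Two FC
matrices are compared with a windowed structural similarity index (SSIM):
the whole matrix is treated as an image, a uniform square window slides over
it, and at every position the product of a luminance, a contrast and a
structure term is evaluated:

    [ (2*mu_x*mu_y + c1) / (mu_x^2 + mu_y^2 + c1) ]
  * [ (2*sd_x*sd_y + c2) / (sd_x^2 + sd_y^2 + c2) ]
  * [ (cov_xy + c3) / (sd_x*sd_y + c3) ]

with stabilisation constants c1 = 0.01, c2 = 0.03, c3 = 0.015 used exactly
as stated (not rescaled by any dynamic range). The SSIM score is the mean
over window positions, and the model-fit distance is 1 - SSIM, which jointly
penalises Euclidean (mean/variance) and correlation (structure)
discrepancies between the matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .hemodynamics import BOLDTimeseries

__all__ = ["SSIMConfig", "FCMatrix", "compute_fc", "ssim", "fc_distance", "bandpass"]


@dataclass
class SSIMConfig:
    c1: float = 0.01
    c2: float = 0.03
    c3: float = 0.015
    window: int = 7  # odd side length of the sliding window

    def validate(self, side: int | None = None) -> None:
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("stabilisation constants must be positive")
        if self.window % 2 != 1 or self.window < 1:
            raise ValueError("window must be a positive odd integer")
        if side is not None and self.window > side:
            raise ValueError(f"window {self.window} exceeds matrix side {side}")


@dataclass
class FCMatrix:
    """Region x region Pearson correlation matrix."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(V, V.T, atol=atol):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=atol):
            raise ValueError("FC diagonal must be 1")
        if V.min() < -1 - atol or V.max() > 1 + atol:
            raise ValueError("FC entries must lie in [-1, 1]")


def bandpass(signal: np.ndarray, tr: float, low: float = 0.008, high: float = 0.09, order: int = 2):
    """Zero-phase Butterworth band-pass of a (regions x time) signal."""
    from scipy.signal import butter, filtfilt

    nyq = 0.5 / tr
    b, a = butter(order, [low / nyq, high / nyq], btype="band")
    return filtfilt(b, a, signal, axis=-1)


def compute_fc(bold, apply_bandpass: bool = False, bandpass_range: tuple[float, float] = (0.008, 0.09)) -> FCMatrix:
    """Pearson correlation across time for every region pair.

    Regions with zero temporal variance get zero correlations (with a
    warning); the diagonal is always 1.
    """
    if isinstance(bold, BOLDTimeseries):
        sig = bold.signal
        tr = bold.TR
    else:
        sig = np.asarray(bold, dtype=float)
        tr = None
    if sig.ndim != 2:
        raise ValueError("BOLD signal must be 2-D (regions x time)")
    n, t = sig.shape
    if t < 2:
        raise ValueError(f"need at least 2 time points, got {t}")
    if apply_bandpass:
        if tr is None:
            raise ValueError("band-pass filtering needs a BOLDTimeseries with a TR")
        sig = bandpass(sig, tr, *bandpass_range)
    sd = sig.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} region(s) with zero variance; FC entries set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(sig)
    fc[np.isnan(fc)] = 0.0
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    return FCMatrix(values=fc)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, FCMatrix) else np.asarray(x, dtype=float)


def ssim(x, y, cfg: SSIMConfig | None = None) -> float:
    """Mean windowed structural similarity between two equal-shape matrices.

    ssim(x, x) = 1 for any finite matrix, and the score is symmetric in its
    arguments.
    """
    cfg = cfg or SSIMConfig()
    X = _as_values(x)
    Y = _as_values(y)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    cfg.validate(side=min(X.shape))
    w = cfg.window
    Xw = sliding_window_view(X, (w, w)).reshape(-1, w * w)
    Yw = sliding_window_view(Y, (w, w)).reshape(-1, w * w)
    mu_x = Xw.mean(axis=1)
    mu_y = Yw.mean(axis=1)
    dx = Xw - mu_x[:, None]
    dy = Yw - mu_y[:, None]
    var_x = (dx * dx).mean(axis=1)
    var_y = (dy * dy).mean(axis=1)
    sd_x = np.sqrt(var_x)
    sd_y = np.sqrt(var_y)
    cov = (dx * dy).mean(axis=1)
    lum = (2 * mu_x * mu_y + cfg.c1) / (mu_x**2 + mu_y**2 + cfg.c1)
    con = (2 * sd_x * sd_y + cfg.c2) / (var_x + var_y + cfg.c2)
    struct = (cov + cfg.c3) / (sd_x * sd_y + cfg.c3)
    return float(np.mean(lum * con * struct))


def fc_distance(x, y, cfg: SSIMConfig | None = None) -> float:
    """Model-fit distance 1 - SSIM between two FC matrices."""
    return 1.0 - ssim(x, y, cfg)
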