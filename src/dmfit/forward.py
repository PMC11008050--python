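"""Single forward pass of the generative model: neural sim -> BOLD -> FC."""

from __future__ import annotations

import numpy as np

from .dmf import DMFParameters, integrate
from .hemodynamics import BWParameters, bold_from_rate
from .similarity import FCMatrix, compute_fc

__all__ = ["simulate_fc"]


def simulate_fc(
    connectome,
    fic,
    params: DMFParameters,
    seed: int,
    bw: BWParameters | None = None,
) -> FCMatrix:
    """Simulate the DMF model and return the FC of the resulting BOLD signal."""
    bw = bw or BWParameters()
    out = integrate(params, connectome, fic, seed=seed)
    bold = bold_from_rate(out.r_E_series, bw, dt=params.dt)
    return compute_fc(bold)
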