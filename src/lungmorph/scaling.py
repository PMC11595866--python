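"""Ordinary least-squares power-law fits on log-log axes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScalingFit:
    """An OLS line fit through paired log-abscissae/ordinates."""

    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def n_points(self) -> int:
        return len(self.x)


def fit_loglog(x: np.ndarray, y: np.ndarray) -> ScalingFit:
    """OLS fit of y against x (already on log scales)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points for a line fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all abscissae equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ScalingFit(x=x, y=y, slope=float(slope), intercept=float(intercept),
                      r_squared=r2)
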