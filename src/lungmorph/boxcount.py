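"""Box-counting fractal dimension of a binary voxel mask.

The mask is covered by an axis-aligned grid of edge-length-epsilon cubes
anchored at the array origin (boundary cubes truncated); N(eps) is the
number of cubes containing at least one foreground voxel. The dimension
is the OLS slope of log N(eps) against log(1/eps):

    FD_box = slope of log N(eps) ~ log(1/eps)

Cube sizes are in voxel units; anisotropic spacing is deliberately
ignored so that the estimator is defined on the reconstructed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scaling import ScalingFit, fit_loglog
from .volume import VoxelMask


@dataclass
class BoxCountResult:
    epsilons: list[int]
    counts: list[int]
    fd_box: float
    fit: ScalingFit


def _block_any(fg: np.ndarray, eps: int) -> int:
    """Number of eps-cubes (origin-anchored, truncated) with >=1 foreground."""
    out = fg
    for ax in range(3):
        n = out.shape[ax]
        edges = np.arange(0, n, eps)
        out = np.maximum.reduceat(out, edges, axis=ax)
    return int(np.count_nonzero(out))


def box_counts(mask: VoxelMask, epsilons: list[int]) -> list[int]:
    """Covering counts N(eps) for each cube size eps (voxels)."""
    if mask.is_empty():
        raise ValueError("box counting is undefined on an empty mask")
    eps_arr = [int(e) for e in epsilons]
    if any(e < 1 for e in eps_arr):
        raise ValueError(f"cube sizes must be >= 1, got {epsilons}")
    fg = mask.foreground
    return [_block_any(fg, e) for e in eps_arr]


def default_epsilons(shape: tuple[int, int, int]) -> list[int]:
    """Powers of 2 from 1 up to floor(min(shape)/4)."""
    top = min(shape) // 4
    eps = []
    e = 1
    while e <= top:
        eps.append(e)
        e *= 2
    return eps


def estimate_box_dimension(
    mask: VoxelMask, epsilons: list[int] | None = None
) -> BoxCountResult:
    """Box-counting dimension from a log-log OLS fit over a size ladder.

    The default ladder is powers of 2 from 1 to floor(min(shape)/4) and
    must offer at least 4 rungs; an explicit ladder needs at least 2.
    """
    if epsilons is None:
        epsilons = default_epsilons(mask.shape)
        if len(epsilons) < 4:
            raise ValueError(
                f"mask of shape {mask.shape} too small for the default ladder; "
                "pass epsilons explicitly"
            )
    epsilons = sorted(int(e) for e in epsilons)
    if len(epsilons) < 2:
        raise ValueError("need at least 2 cube sizes")
    counts = box_counts(mask, epsilons)
    if len(set(counts)) < 2:
        raise ValueError("degenerate fit: all covering counts equal")
    x = np.log(1.0 / np.asarray(epsilons, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    fit = fit_loglog(x, y)
    return BoxCountResult(epsilons=epsilons, counts=counts, fd_box=fit.slope, fit=fit)
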