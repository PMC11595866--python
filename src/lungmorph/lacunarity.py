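"""Gliding-box lacunarity of a binary voxel mask.

A cubic box of edge epsilon glides over every position inside the grid
(all shape - eps + 1 offsets per axis, overlapping). The box mass is the
number of foreground voxels inside the box; lacunarity is the relative
variance of the mass distribution

    Lambda(eps) = sigma^2 / mu^2,

zero iff every box carries the same mass (perfect homogeneity), larger
for more clustered ("gappier") spatial arrangements. Boxes overlapping
empty regions are included (mass 0 is a valid observation). Only
axis-aligned cubic boxes are used, so the orientation index of the
rotational-invariance construction is degenerate here.

The per-subject aggregate is the unweighted mean of Lambda(eps) over the
size ladder; the full curve is always returned so any other reduction
can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VoxelMask


@dataclass
class LacunarityResult:
    epsilons: list[int]
    lambda_per_eps: list[float]
    aggregate: float


def _box_masses(fg: np.ndarray, eps: int) -> np.ndarray:
    """Masses of all gliding eps-boxes via an exact integral volume."""
    c = np.zeros(tuple(n + 1 for n in fg.shape), dtype=np.int64)
    c[1:, 1:, 1:] = fg.astype(np.int64)
    for ax in range(3):
        np.cumsum(c, axis=ax, out=c)
    e = eps
    # inclusion-exclusion over the 8 corners of each box
    m = (
        c[e:, e:, e:] - c[:-e, e:, e:] - c[e:, :-e, e:] - c[e:, e:, :-e]
        + c[:-e, :-e, e:] + c[:-e, e:, :-e] + c[e:, :-e, :-e] - c[:-e, :-e, :-e]
    )
    return m


def gliding_box_lacunarity(mask: VoxelMask, epsilon: int) -> float:
    """Lambda(eps) = sigma^2 / mu^2 of the gliding-box mass distribution."""
    epsilon = int(epsilon)
    if epsilon < 1 or epsilon > min(mask.shape):
        raise ValueError(
            f"box size {epsilon} invalid for mask of shape {mask.shape}"
        )
    if mask.is_empty():
        raise ValueError("lacunarity is undefined on an empty mask (mu = 0)")
    masses = _box_masses(mask.foreground, epsilon).ravel()
    mu = masses.mean()
    if mu == 0:
        raise ValueError("all gliding boxes empty (mu = 0)")
    var = masses.var()  # population variance
    return float(var / mu**2)


def default_epsilons(shape: tuple[int, int, int]) -> list[int]:
    """Powers of 2 from 2 up to floor(min(shape)/4)."""
    top = min(shape) // 4
    eps = []
    e = 2
    while e <= top:
        eps.append(e)
        e *= 2
    return eps


def lacunarity_curve(
    mask: VoxelMask, epsilons: list[int] | None = None
) -> LacunarityResult:
    """Lambda(eps) over a box-size ladder plus the mean aggregate."""
    if epsilons is None:
        epsilons = default_epsilons(mask.shape)
    epsilons = sorted(int(e) for e in epsilons)
    if not epsilons:
        raise ValueError("no valid box sizes for this mask shape")
    lambdas = [gliding_box_lacunarity(mask, e) for e in epsilons]
    return LacunarityResult(
        epsilons=epsilons,
        lambda_per_eps=lambdas,
        aggregate=float(np.mean(lambdas)),
    )
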