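"""Synthetic inputs with known ground truth for every pipeline stage.

Three families:

* binary fractal/reference voxel sets with analytically known dimension
  (Menger sponge: log 20 / log 3; solid cube / slab / line: 3 / 2 / 1;
  Mandelbrot percolation: expected dimension log(b^3 p) / log b),
* HU volumes whose NAA is a prescribed mask, exercising the exact
  boundary semantics of the attenuation interval, and
* survival cohorts with a stated multiplicative hazard structure, the
  exact proportional-hazards data-generating process the Cox stage
  assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import HU_HIGH_DEFAULT, HU_LOW_DEFAULT
from .volume import ImageVolume, VoxelMask

DEFAULT_SPACING = (1.0, 1.0, 2.5)


# ---------------------------------------------------------------------------
# geometric phantoms

def menger_sponge(level: int, spacing=DEFAULT_SPACING) -> VoxelMask:
    """Level-`level` Menger sponge on a (3^level)^3 grid; 20^level voxels.

    Each recursion keeps the 20 of 27 subcubes whose offset has at most
    one coordinate equal to 1 (removes face centers and the body center).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if level > 5:
        raise ValueError("level > 5 exceeds practical grid size")
    fg = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = fg.shape[0]
        out = np.zeros((3 * n,) * 3, dtype=bool)
        for dx in range(3):
            for dy in range(3):
                for dz in range(3):
                    if (dx == 1) + (dy == 1) + (dz == 1) >= 2:
                        continue
                    out[dx * n:(dx + 1) * n,
                        dy * n:(dy + 1) * n,
                        dz * n:(dz + 1) * n] = fg
        fg = out
    return VoxelMask(foreground=fg, spacing=spacing)


def reference_set(kind: str, extent: int, spacing=DEFAULT_SPACING) -> VoxelMask:
    """Solid cube (dim 3), one-voxel slab (dim 2), or digital line (dim 1)."""
    if extent < 8:
        raise ValueError("extent must be >= 8")
    if kind == "cube":
        fg = np.ones((extent, extent, extent), dtype=bool)
    elif kind == "slab":
        fg = np.ones((extent, extent, 1), dtype=bool)
    elif kind == "line":
        fg = np.ones((extent, 1, 1), dtype=bool)
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    return VoxelMask(foreground=fg, spacing=spacing)


def fractal_percolation(
    b: int, p: float, levels: int, seed: int, spacing=DEFAULT_SPACING
) -> VoxelMask:
    """Mandelbrot percolation: keep each of b^3 children with probability p.

    Expected fractal dimension log(b^3 p) / log b when supercritical.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = np.random.default_rng(seed)
    fg = np.ones((1, 1, 1), dtype=bool)
    for _ in range(levels):
        n = fg.shape[0]
        keep = rng.random((b * n,) * 3) < p
        fg = np.kron(fg, np.ones((b,) * 3, dtype=bool)) & keep
    return VoxelMask(foreground=fg, spacing=spacing)


def mask_to_hu(mask: VoxelMask, seed: int) -> ImageVolume:
    """HU volume whose NAA mask is exactly `mask`.

    Foreground voxels get HU uniform on (-950, -700], with one voxel
    pinned to exactly -700 (included by the right-closed interval) when
    the mask has >= 2 foreground voxels. Background voxels alternate
    between -1000 (air) and +40 (soft tissue), with one pinned to exactly
    -950 (excluded by the left-open interval) when >= 2 background voxels
    exist. Thresholding the result at the default interval recovers the
    input mask exactly, boundary values included.
    """
    rng = np.random.default_rng(seed)
    fg = mask.foreground
    values = np.empty(fg.shape, dtype=np.float64)

    n_fg = int(fg.sum())
    n_bg = fg.size - n_fg
    # uniform on (-950, -700]: r in [0, 1) maps to hu_high - width * r
    fg_vals = HU_HIGH_DEFAULT - (HU_HIGH_DEFAULT - HU_LOW_DEFAULT) * rng.random(n_fg)
    if n_fg >= 2:
        fg_vals[rng.integers(n_fg)] = HU_HIGH_DEFAULT
    values[fg] = fg_vals

    bg_vals = np.where(np.arange(n_bg) % 2 == 0, -1000.0, 40.0)
    if n_bg >= 2:
        bg_vals[rng.integers(n_bg)] = HU_LOW_DEFAULT
    values[~fg] = bg_vals
    return ImageVolume(values=values, spacing=mask.spacing, source_id="phantom")


# ---------------------------------------------------------------------------
# synthetic survival cohorts

#: covariate marginals loosely matched to the study population:
#: 76% male, 53.7% ever-smokers, 29.1% COPD, 8.6% IPF, 53.1% stage I-II,
#: 20.6% SABR (the rest IMRT).
DEFAULT_MARGINALS = {
    "male": 0.760,
    "smoker": 0.537,
    "copd": 0.291,
    "ipf": 0.086,
    "stage_i_ii": 0.531,
    "sabr": 0.206,
    "adenocarcinoma": 0.55,
}


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic time-to-event cohort.

    Event times are exponential with hazard
        baseline_hazard * hr_low_stratum^[index below median]
                        * exp(sum covariate effects),
    censored administratively at min(censor_horizon, U(0, censor_horizon)).
    """

    n_subjects: int = 175
    hr_low_stratum: float = 2.3
    baseline_hazard: float = 0.02  # events per month
    censor_horizon: float = 24.0  # months
    covariate_effects: dict = field(default_factory=dict)
    seed: int = 0
    index_name: str = "mst"  # which index carries the hazard contrast
    p_grade3_given_event: float = 0.3
    censor_mode: str = "uniform"  # "uniform": staggered entry, or "horizon"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if min(self.hr_low_stratum, self.baseline_hazard, self.censor_horizon) <= 0:
            raise ValueError("rates and horizon must be positive")
        if self.index_name not in ("boxdim", "lacunarity", "mst"):
            raise ValueError(f"unknown index {self.index_name!r}")
        if self.censor_mode not in ("uniform", "horizon"):
            raise ValueError(f"unknown censor_mode {self.censor_mode!r}")


# plausible per-index centers/spreads for the generated biomarkers
_INDEX_DIST = {
    "boxdim": (2.65, 0.06),
    "lacunarity": (0.46, 0.12),
    "mst": (2.716, 0.06),
}


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table with indices, covariates and RP outcomes.

    Returns one row per subject with columns: subject_id, index_boxdim,
    index_lacunarity, index_mst, age, sex, smoking, lung_disease,
    rt_technique, stage, histology, dlco_pct, time_months, event_grade2,
    event_grade3.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    latent = rng.standard_normal(n)
    indices = {}
    for name, (mu, sd) in _INDEX_DIST.items():
        if name == spec.index_name:
            z = latent
        else:
            # weakly correlated companion indices
            z = 0.4 * latent + np.sqrt(1 - 0.4**2) * rng.standard_normal(n)
        indices[name] = mu + sd * z

    m = DEFAULT_MARGINALS
    age = np.clip(rng.normal(74, 10, n), 38, 93).round(0)
    sex = np.where(rng.random(n) < m["male"], "male", "female")
    smoking = np.where(rng.random(n) < m["smoker"], "ever", "never")
    u = rng.random(n)
    lung_disease = np.where(
        u < m["ipf"], "IPF", np.where(u < m["ipf"] + m["copd"], "COPD", "none")
    )
    stage = np.where(rng.random(n) < m["stage_i_ii"], "I-II", "III")
    rt_technique = np.where(rng.random(n) < m["sabr"], "SABR", "IMRT")
    histology = np.where(
        rng.random(n) < m["adenocarcinoma"], "adenocarcinoma", "squamous"
    )
    dlco_pct = np.clip(rng.normal(85, 20, n), 25, 140).round(1)

    primary = indices[spec.index_name]
    low = primary < np.median(primary)

    log_hazard = np.log(spec.baseline_hazard) + low * np.log(spec.hr_low_stratum)
    cov_frame = {
        "age": age, "sex": sex, "smoking": smoking,
        "lung_disease": lung_disease, "rt_technique": rt_technique,
        "stage": stage, "histology": histology, "dlco_pct": dlco_pct,
    }
    _indicator = {
        "sex": lambda c: (c == "male").astype(float),
        "smoking": lambda c: (c == "ever").astype(float),
        "lung_disease": lambda c: (c != "none").astype(float),
        "rt_technique": lambda c: (c == "IMRT").astype(float),
        "stage": lambda c: (c == "III").astype(float),
        "histology": lambda c: (c == "squamous").astype(float),
    }
    for name, beta in spec.covariate_effects.items():
        col = np.asarray(cov_frame[name])
        x = _indicator[name](col) if name in _indicator else col.astype(float)
        log_hazard = log_hazard + beta * x

    event_time = rng.standard_exponential(n) / np.exp(log_hazard)
    if spec.censor_mode == "uniform":
        # staggered entry: administrative censoring uniform over follow-up
        censor_time = np.minimum(
            spec.censor_horizon, rng.uniform(0, spec.censor_horizon, n)
        )
    else:
        censor_time = np.full(n, spec.censor_horizon)
    observed = event_time <= censor_time
    time_months = np.where(observed, event_time, censor_time)
    grade3 = observed & (rng.random(n) < spec.p_grade3_given_event)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "index_boxdim": indices["boxdim"],
            "index_lacunarity": indices["lacunarity"],
            "index_mst": indices["mst"],
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "lung_disease": lung_disease,
            "rt_technique": rt_technique,
            "stage": stage,
            "histology": histology,
            "dlco_pct": dlco_pct,
            "time_months": time_months,
            "event_grade2": observed,
            "event_grade3": grade3,
        }
    )
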