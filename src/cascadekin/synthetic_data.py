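"""Synthetic measurement generation for the cascade pipeline.

Emulates the two read-outs the analysis consumes, at the statistical level
the downstream fitting assumes (integral/concentration values with additive
Gaussian noise; no spectral or chromatographic detail):

* decoupled 13C-NMR time courses — per-species relative integrals sampled
  every 6.5 min over 16 h, normalized per species to the maximal integral,
  pyruvate invisible (it is drained too fast to accumulate a signal);
* HPLC concentration series for mannose and lactate at 0, 1, 4, 8, 10 and
  18 h, in replicates;
* residual-activity decay assays for the half-life fits.

Noise is additive, Gaussian and homoscedastic per series — applied after
normalization for relative integrals, mirroring integration noise on
spectra of fixed receiver gain — and values are clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade_model import CascadeError, CascadeParams, default_params
from .simulator import (
    ReactionRecipe,
    SolverOptions,
    TimeCourse,
    _integrate,
)
from .fitting import normalize_timecourse

#: NMR acquisition cadence and span.
NMR_DT_MIN = 6.5
NMR_SPAN_H = 16.0

#: Species with an assignable chemical shift in the labelled run; pyruvate
#: and the cofactors never show an integral.
NMR_SPECIES: tuple[str, ...] = ("MAN", "ML", "MA", "KDG", "GA", "GLYA", "LA")

#: Default HPLC sampling times (h) and observed species.
HPLC_TIMEPOINTS: tuple[float, ...] = (0.0, 1.0, 4.0, 8.0, 10.0, 18.0)
HPLC_SPECIES: tuple[str, ...] = ("MAN", "LA")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: ``sd`` is a fraction of the per-species
    maximum for relative integrals, or mM for concentrations."""

    sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise CascadeError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def nmr_grid() -> np.ndarray:
    return np.arange(0.0, NMR_SPAN_H * 60.0 + 1e-9, NMR_DT_MIN) / 60.0


def generate_nmr_timecourse(
    recipe: ReactionRecipe,
    params: CascadeParams | None = None,
    noise: NoiseModel | None = None,
    solver_opts: SolverOptions | None = None,
) -> TimeCourse:
    """Simulate, sample on the NMR grid, normalize per species, add noise.

    Deterministic for a fixed ``noise.seed``; with ``sd = 0`` the output is
    exactly the normalized simulation.
    """
    params = params if params is not None else default_params()
    noise = noise if noise is not None else NoiseModel()
    opts = solver_opts if solver_opts is not None else SolverOptions()
    sim = _integrate(recipe, params, nmr_grid(), opts)
    rel = normalize_timecourse(sim.subset(NMR_SPECIES))
    if noise.sd > 0:
        rng = noise.rng()
        rel.values = np.clip(
            rel.values + rng.normal(0.0, noise.sd, rel.values.shape), 0.0, None
        )
    return rel


def generate_hplc_timecourse(
    recipe: ReactionRecipe,
    params: CascadeParams | None = None,
    noise: NoiseModel | None = None,
    timepoints_h: tuple[float, ...] = HPLC_TIMEPOINTS,
    replicates: int = 3,
    species: tuple[str, ...] = HPLC_SPECIES,
    solver_opts: SolverOptions | None = None,
) -> list[TimeCourse]:
    """Concentration series at discrete sampling times, one course per
    replicate, with independent additive noise (sd in mM) per replicate."""
    if replicates < 1:
        raise CascadeError("need at least one replicate")
    params = params if params is not None else default_params()
    noise = noise if noise is not None else NoiseModel(sd=0.1)
    opts = solver_opts if solver_opts is not None else SolverOptions()
    grid = np.asarray(timepoints_h, dtype=float)
    sim = _integrate(recipe, params, grid, opts).subset(species)
    rng = noise.rng()
    out = []
    for rep in range(replicates):
        values = sim.values.copy()
        if noise.sd > 0:
            values = np.clip(
                values + rng.normal(0.0, noise.sd, values.shape), 0.0, None
            )
        out.append(
            TimeCourse(
                times=grid.copy(),
                values=values,
                species=species,
                kind="concentration_mM",
                replicate=rep,
            )
        )
    return out


def generate_decay_assay(
    half_life_h: float,
    timepoints_h,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-activity fractions 2^(-t/t_half) with additive noise,
    clipped at zero.  ``seed`` overrides the noise model's own seed."""
    if half_life_h <= 0:
        raise CascadeError("half-life must be > 0")
    noise = noise if noise is not None else NoiseModel(sd=0.05)
    t = np.asarray(timepoints_h, dtype=float)
    if np.any(t < 0):
        raise CascadeError("timepoints must be >= 0")
    if np.isinf(half_life_h):
        a = np.ones_like(t)
    else:
        a = 2.0 ** (-t / half_life_h)
    if noise.sd > 0:
        rng = np.random.default_rng(seed if seed is not None else noise.seed)
        a = np.clip(a + rng.normal(0.0, noise.sd, t.shape), 0.0, None)
    return t, a
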