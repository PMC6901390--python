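"""Parameter estimation from cascade time courses.

Covers three jobs: (i) first-order half-life fits to residual-activity
assays, (ii) bounded multi-start least-squares fits of cascade parameters
to concentration or relative-integral time courses, and (iii) an AIC-style
comparison of two mechanisms for the aldol step (irreversible cleavage
vs. net reversible aldol) to explain biphasic KDG behaviour.

Relative-integral data (NMR peak areas normalized per species to their own
maximum) carry no absolute scale, so the model prediction is normalized the
same way, per species, before residuals are formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from .cascade_model import CascadeError, CascadeParams, default_params
from .simulator import (
    ReactionRecipe,
    SolverOptions,
    TimeCourse,
    _integrate,
)

#: Solver settings used inside fit objectives: slightly looser than the
#: reporting defaults, still well below the finite-difference step so the
#: numerical jacobian stays clean.
FIT_SOLVER = SolverOptions(rtol=1e-7, atol=1e-9)

_FREE_PARAM_NAMES = (
    "vcap_AldT",
    "vcap_ManD",
    "vcap_KDGA",
    "vcap_LDH",
    "km_AldT",
    "km_ManD",
    "km_KDGA",
    "km_LDH",
    "k_hyd",
    "k_gaox",
    "aldol_scale",
    "half_life_AldT",
    "half_life_ManD",
)

_KM_KEY = {"AldT": "MAN", "ManD": "MA", "KDGA": "PYR+GA", "LDH": "PYR"}


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters with (positive, finite) bounds, the
    species entering the loss, and the multi-start policy."""

    free: Mapping[str, tuple[float, float]]
    species: tuple[str, ...] | None = None
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.free) == 0:
            raise CascadeError("fit spec needs at least one free parameter")
        for name, (lo, hi) in self.free.items():
            if name not in _FREE_PARAM_NAMES:
                raise CascadeError(
                    f"unknown free parameter {name!r}; valid: "
                    f"{', '.join(_FREE_PARAM_NAMES)}"
                )
            if not (0 < lo < hi < math.inf):
                raise CascadeError(
                    f"{name}: bounds must be finite, positive and ordered, "
                    f"got ({lo}, {hi})"
                )
        if self.n_restarts < 1:
            raise CascadeError("n_restarts must be >= 1")


@dataclass
class FitResult:
    """Best estimates with approximate standard errors and diagnostics."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    n_restarts: int
    seed: int
    at_bound: dict[str, bool] = field(default_factory=dict)
    n_points: int = 0

    @property
    def ssr(self) -> float:
        return self.residual_norm**2


@dataclass
class HalfLifeFit:
    half_life_h: float
    a0: float
    residual_norm: float


@dataclass
class MechanismComparison:
    """Outcome of fitting the irreversible (A) and reversible (B) aldol
    mechanisms to the same data; lower AIC-style score wins, ties break
    toward the mechanism with fewer parameters."""

    fit_irreversible: FitResult | None
    fit_reversible: FitResult | None
    score_irreversible: float
    score_reversible: float
    selected: str  # "irreversible" | "reversible" | "undecided"
    n_points: int
    k_params: int


# --------------------------------------------------------------------------
# Half-life fitting
# --------------------------------------------------------------------------


def fit_half_life(times_h: Sequence[float], activities: Sequence[float]) -> HalfLifeFit:
    """Fit A(t) = A0 * 2^(-t/t_half) to a residual-activity assay.

    The long-time plateau is fixed at zero.  Non-decaying data yield
    ``t_half = inf`` with a warning rather than an error.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.size != a.size or t.size < 3:
        raise CascadeError("need >= 3 matching timepoints")
    if np.any(a < 0) or np.any(a > 1.2):
        raise CascadeError("activities must be fractions of initial, in [0, 1.2]")

    # log-linear probe for the decay direction and a starting value
    pos = a > 1e-9
    slope = 0.0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log2(a[pos]), 1)[0]
    if slope >= -1e-12:
        warnings.warn("activity does not decay; returning infinite half-life")
        return HalfLifeFit(half_life_h=math.inf, a0=float(a.mean()), residual_norm=float(np.linalg.norm(a - a.mean())))

    th0 = min(max(-1.0 / slope, 1e-3), 1e3)
    a00 = float(np.clip(a[0] if a[0] > 0 else 1.0, 1e-3, 1.2))

    def model(tt, a0, th):
        return a0 * 2.0 ** (-tt / th)

    popt, _ = curve_fit(
        model, t, a, p0=(a00, th0), bounds=((0.0, 1e-6), (1.5, np.inf)), maxfev=10000
    )
    resid = a - model(t, *popt)
    return HalfLifeFit(
        half_life_h=float(popt[1]),
        a0=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)),
    )


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------


def normalize_to_max(series: Sequence[float]) -> np.ndarray:
    """Scale a series by its maximum so the output peaks at exactly 1.

    An all-zero series is returned unchanged with a warning (there is no
    scale to normalize by).
    """
    s = np.asarray(series, dtype=float)
    m = s.max() if s.size else 0.0
    if m <= 0:
        warnings.warn("series has no positive maximum; returned unchanged")
        return s.copy()
    return s / m


def normalize_timecourse(tc: TimeCourse) -> TimeCourse:
    """Per-species max-normalization of a concentration course, yielding a
    relative-integral course (the form NMR peak areas are reported in)."""
    values = np.empty_like(tc.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(tc.species)):
            values[i] = normalize_to_max(tc.values[i])
    return TimeCourse(
        times=tc.times.copy(),
        values=values,
        species=tc.species,
        kind="relative_integral",
        replicate=tc.replicate,
    )


# --------------------------------------------------------------------------
# Cascade parameter fitting
# --------------------------------------------------------------------------


def apply_free_params(
    params: CascadeParams,
    recipe: ReactionRecipe,
    updates: Mapping[str, float],
) -> tuple[CascadeParams, ReactionRecipe]:
    """Return copies of (params, recipe) with named free parameters set.

    ``vcap_<Enz>`` rewrites the loading of that enzyme (U/ml); ``km_<Enz>``
    its Michaelis constant; ``half_life_<Enz>`` its deactivation half-life;
    ``k_hyd``/``k_gaox`` the auxiliary rates and ``aldol_scale`` the
    cleavage-capacity multiplier of the aldol step.
    """
    enzymes = dict(params.enzymes)
    aux = params.aux
    aldol_scale = params.aldol_scale
    loadings = list(recipe.loadings)

    for name, value in updates.items():
        if name.startswith("vcap_"):
            enz = name[5:]
            hits = [i for i, ld in enumerate(loadings) if ld.enzyme == enz]
            if not hits:
                raise CascadeError(f"recipe has no loading for {enz}")
            for i in hits:
                loadings[i] = replace(loadings[i], u_per_ml=float(value))
        elif name.startswith("km_"):
            enz = name[3:]
            e = enzymes[enz]
            km = dict(e.km)
            km[_KM_KEY[enz]] = float(value)
            enzymes[enz] = replace(e, km=km)
        elif name.startswith("half_life_"):
            enz = name[10:]
            enzymes[enz] = replace(enzymes[enz], half_life_h=float(value))
        elif name == "k_hyd":
            aux = replace(aux, k_hyd_per_min=float(value))
        elif name == "k_gaox":
            aux = replace(aux, k_gaox=float(value))
        elif name == "aldol_scale":
            aldol_scale = float(value)
        else:
            raise CascadeError(f"unknown free parameter {name!r}")

    new_params = params.updated(enzymes=enzymes, aux=aux, aldol_scale=aldol_scale)
    new_recipe = replace(recipe, loadings=tuple(loadings))
    return new_params, new_recipe


def current_values(
    params: CascadeParams, recipe: ReactionRecipe, names: Sequence[str]
) -> dict[str, float]:
    """Read the current value of each named free parameter."""
    out: dict[str, float] = {}
    for name in names:
        if name.startswith("vcap_"):
            enz = name[5:]
            hits = [ld.u_per_ml for ld in recipe.loadings if ld.enzyme == enz]
            if not hits:
                raise CascadeError(f"recipe has no loading for {enz}")
            out[name] = hits[0]
        elif name.startswith("km_"):
            enz = name[3:]
            out[name] = params.enzymes[enz].km[_KM_KEY[enz]]
        elif name.startswith("half_life_"):
            out[name] = params.enzymes[name[10:]].half_life_h
        elif name == "k_hyd":
            out[name] = params.aux.k_hyd_per_min
        elif name == "k_gaox":
            out[name] = params.aux.k_gaox
        elif name == "aldol_scale":
            out[name] = params.aldol_scale
        else:
            raise CascadeError(f"unknown free parameter {name!r}")
    return out


def _residual_vector(
    values: Mapping[str, float],
    tc: TimeCourse,
    recipe: ReactionRecipe,
    params: CascadeParams,
    species_sel: Sequence[str],
    solver_opts: SolverOptions,
) -> np.ndarray:
    p2, r2 = apply_free_params(params, recipe, values)
    sim = _integrate(r2, p2, tc.times, solver_opts)
    parts = []
    for sp in species_sel:
        model = sim.get(sp)
        if tc.kind == "relative_integral":
            m = model.max()
            if m > 0:
                model = model / m
        parts.append(model - tc.get(sp))
    return np.concatenate(parts)


def fit_cascade_params(
    tc: TimeCourse,
    spec: FitSpec,
    recipe: ReactionRecipe,
    params: CascadeParams | None = None,
    solver_opts: SolverOptions | None = None,
) -> FitResult:
    """Bounded least-squares fit of cascade parameters to one time course.

    Multi-start: the first start is the current parameter value (clipped to
    bounds), the rest are drawn log-uniformly within bounds from the seeded
    generator, which makes the whole fit reproducible bit-for-bit.
    """
    params = params if params is not None else default_params()
    solver_opts = solver_opts if solver_opts is not None else FIT_SOLVER
    species_sel = spec.species if spec.species is not None else tc.species
    for sp in species_sel:
        tc.get(sp)  # raises if absent

    names = list(spec.free)
    bounds = {n: spec.free[n] for n in names}
    rng = np.random.default_rng(spec.seed)

    defaults = current_values(params, recipe, names)
    starts: list[dict[str, float]] = [
        {n: float(np.clip(defaults[n], *bounds[n])) for n in names}
    ]
    for _ in range(spec.n_restarts - 1):
        starts.append(
            {
                n: float(
                    np.exp(
                        rng.uniform(np.log(bounds[n][0]), np.log(bounds[n][1]))
                    )
                )
                for n in names
            }
        )

    def objective(lmpars: lmfit.Parameters) -> np.ndarray:
        vals = {n: lmpars[n].value for n in names}
        return _residual_vector(vals, tc, recipe, params, species_sel, solver_opts)

    best: lmfit.minimizer.MinimizerResult | None = None
    for start in starts:
        lmpars = lmfit.Parameters()
        for n in names:
            lmpars.add(n, value=start[n], min=bounds[n][0], max=bounds[n][1])
        try:
            res = lmfit.minimize(
                objective, lmpars, method="least_squares", diff_step=1e-3
            )
        except Exception:  # a diverging start is not fatal for the multi-start
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return FitResult(
            estimates={n: math.nan for n in names},
            stderr={n: math.nan for n in names},
            residual_norm=math.nan,
            converged=False,
            n_restarts=spec.n_restarts,
            seed=spec.seed,
        )

    estimates = {n: float(best.params[n].value) for n in names}
    stderr = {
        n: float(best.params[n].stderr)
        if best.params[n].stderr is not None
        else math.nan
        for n in names
    }
    at_bound = {
        n: bool(
            min(estimates[n] - bounds[n][0], bounds[n][1] - estimates[n])
            < 1e-4 * (bounds[n][1] - bounds[n][0])
        )
        for n in names
    }
    return FitResult(
        estimates=estimates,
        stderr=stderr,
        residual_norm=float(np.sqrt(best.chisqr)),
        converged=bool(best.success),
        n_restarts=spec.n_restarts,
        seed=spec.seed,
        at_bound=at_bound,
        n_points=int(best.ndata),
    )


# --------------------------------------------------------------------------
# Mechanism comparison for the aldol step
# --------------------------------------------------------------------------


def aic_score(ssr: float, n: int, k: int) -> float:
    """AIC-style score n*ln(SSR/n) + 2k for least-squares fits."""
    if n <= 0:
        raise CascadeError("n must be positive")
    if ssr <= 0:
        return -math.inf + 2 * k if k == 0 else -1e300 + 2 * k
    return n * math.log(ssr / n) + 2 * k


def compare_kdg_mechanisms(
    tc: TimeCourse,
    recipe: ReactionRecipe,
    params: CascadeParams | None = None,
    free: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    solver_opts: SolverOptions | None = None,
) -> MechanismComparison:
    """Fit irreversible-cleavage (A) and net-reversible-aldol (B) variants
    of the cascade to data containing KDG, and pick the better mechanism.

    Both variants share the same free parameters (default: the cleavage
    capacity scale), so the AIC comparison reduces to the residual norms;
    exact ties break toward the mechanism with fewer parameters, i.e. the
    irreversible one.
    """
    if "KDG" not in tc.species:
        raise CascadeError("mechanism comparison needs KDG in the time course")
    params = params if params is not None else default_params()
    free = dict(free) if free is not None else {"aldol_scale": (0.05, 20.0)}

    fits: dict[str, FitResult | None] = {}
    for label, reverse in (("irreversible", False), ("reversible", True)):
        variant = params.updated(reverse_aldol=reverse)
        spec = FitSpec(free=free, species=tc.species, n_restarts=n_restarts, seed=seed)
        try:
            fits[label] = fit_cascade_params(
                tc, spec, recipe, variant, solver_opts=solver_opts
            )
        except Exception:
            fits[label] = None

    k = len(free)
    n = tc.values.size

    def score(fr: FitResult | None) -> float:
        if fr is None or not np.isfinite(fr.residual_norm):
            return math.inf
        return aic_score(fr.ssr, n, k)

    s_a, s_b = score(fits["irreversible"]), score(fits["reversible"])
    if math.isinf(s_a) and math.isinf(s_b):
        selected = "undecided"
    elif s_a <= s_b:  # ties (equal k) break toward the simpler mechanism
        selected = "irreversible"
    else:
        selected = "reversible"
    return MechanismComparison(
        fit_irreversible=fits["irreversible"],
        fit_reversible=fits["reversible"],
        score_irreversible=s_a,
        score_reversible=s_b,
        selected=selected,
        n_points=n,
        k_params=k,
    )
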