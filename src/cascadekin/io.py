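"""Configuration loading, tidy-CSV time-course I/O and run logging.

Recipes and fit specs are YAML; time courses travel as tidy long-format CSV
with columns ``time_h, species, value, kind, replicate`` — the long format
makes partial observation (HPLC sees two species, NMR seven) natural.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cascade_model import SPECIES, CascadeError, Loading, species_vector
from .fitting import FitSpec
from .simulator import ReactionRecipe, Spike, TimeCourse

log = logging.getLogger("cascadekin")

TIDY_COLUMNS = ("time_h", "species", "value", "kind", "replicate")

BUILTIN_RECIPES = (
    "onepot_standard",
    "nmr_onepot",
    "sequential_paper",
    "pure_mannose",
    "scg_hydrolysate",
)


class ValidationError(CascadeError):
    """Configuration or data-file validation failure (CLI exit code 2)."""


@dataclass(frozen=True)
class RunConfig:
    """Bookkeeping for one CLI run; the seed is recorded in all outputs."""

    recipe_path: str
    seed: int
    out_dir: str
    verbosity: int = 0
    fit_spec_path: str | None = None


# --------------------------------------------------------------------------
# Recipe configs
# --------------------------------------------------------------------------

_RECIPE_KEYS = {"label", "temperature_K", "buffer_mM", "initial", "loadings", "spikes"}
_LOADING_KEYS = {"enzyme", "u_per_ml", "addition_time_h"}
_SPIKE_KEYS = {"time_h", "species", "mM"}


def _parse_recipe(raw: dict, origin: str) -> ReactionRecipe:
    if not isinstance(raw, dict) or not raw:
        raise ValidationError(f"{origin}: empty or malformed recipe config")
    unknown = set(raw) - _RECIPE_KEYS
    if unknown:
        raise ValidationError(
            f"{origin}: unknown keys {sorted(unknown)}; allowed: "
            f"{sorted(_RECIPE_KEYS)}"
        )
    for key in ("initial", "loadings"):
        if key not in raw:
            raise ValidationError(f"{origin}: missing required key {key!r}")

    try:
        initial = species_vector(**{k: float(v) for k, v in raw["initial"].items()})
    except CascadeError as exc:
        raise ValidationError(f"{origin}: initial: {exc}") from exc

    loadings = []
    for i, ld in enumerate(raw["loadings"]):
        unknown = set(ld) - _LOADING_KEYS
        if unknown:
            raise ValidationError(
                f"{origin}: loadings[{i}]: unknown keys {sorted(unknown)}"
            )
        try:
            loadings.append(
                Loading(
                    enzyme=ld["enzyme"],
                    u_per_ml=float(ld["u_per_ml"]),
                    addition_time_h=float(ld.get("addition_time_h", 0.0)),
                )
            )
        except (KeyError, CascadeError) as exc:
            raise ValidationError(f"{origin}: loadings[{i}]: {exc}") from exc

    spikes = []
    for i, sp in enumerate(raw.get("spikes", []) or []):
        unknown = set(sp) - _SPIKE_KEYS
        if unknown:
            raise ValidationError(
                f"{origin}: spikes[{i}]: unknown keys {sorted(unknown)}"
            )
        try:
            spikes.append(
                Spike(
                    time_h=float(sp["time_h"]),
                    species=sp["species"],
                    mM=float(sp["mM"]),
                )
            )
        except (KeyError, CascadeError) as exc:
            raise ValidationError(f"{origin}: spikes[{i}]: {exc}") from exc

    try:
        return ReactionRecipe(
            initial=initial,
            loadings=tuple(loadings),
            spikes=tuple(spikes),
            temperature_K=float(raw.get("temperature_K", 323.0)),
            buffer_mM=float(raw.get("buffer_mM", 100.0)),
            label=str(raw.get("label", "")),
        )
    except CascadeError as exc:
        raise ValidationError(f"{origin}: {exc}") from exc


def load_recipe_config(path: str | Path) -> ReactionRecipe:
    """Load and fully validate a reaction recipe from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"recipe file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return _parse_recipe(raw, str(path))


def builtin_recipe(name: str) -> ReactionRecipe:
    """Load one of the packaged recipe fixtures (see BUILTIN_RECIPES)."""
    if name not in BUILTIN_RECIPES:
        raise ValidationError(
            f"unknown builtin recipe {name!r}; available: {', '.join(BUILTIN_RECIPES)}"
        )
    text = resources.files("cascadekin.data").joinpath(f"{name}.yaml").read_text()
    return _parse_recipe(yaml.safe_load(text), f"builtin:{name}")


# --------------------------------------------------------------------------
# Fit specs
# --------------------------------------------------------------------------

_FITSPEC_KEYS = {"free", "species", "n_restarts", "seed"}


def load_fit_spec(path: str | Path) -> FitSpec:
    """Load a fit specification (free parameters + bounds) from YAML."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"fit spec file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValidationError(f"{path}: empty or malformed fit spec")
    unknown = set(raw) - _FITSPEC_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    if "free" not in raw:
        raise ValidationError(f"{path}: missing required key 'free'")
    try:
        free = {
            name: (float(b[0]), float(b[1])) for name, b in raw["free"].items()
        }
        return FitSpec(
            free=free,
            species=tuple(raw["species"]) if raw.get("species") else None,
            n_restarts=int(raw.get("n_restarts", 5)),
            seed=int(raw.get("seed", 0)),
        )
    except (CascadeError, TypeError, IndexError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# Tidy CSV time courses
# --------------------------------------------------------------------------


def write_timecourse_csv(tcs: TimeCourse | list[TimeCourse], path: str | Path) -> None:
    """Serialize one or more time courses to tidy CSV (lossless floats)."""
    if isinstance(tcs, TimeCourse):
        tcs = [tcs]
    frame = pd.concat([tc.to_tidy() for tc in tcs], ignore_index=True)
    # %.17g guarantees binary-exact float round trips through text
    frame.to_csv(path, index=False, float_format="%.17g")


def read_timecourse_csv(path: str | Path) -> list[TimeCourse]:
    """Read tidy-CSV time courses, one per replicate.

    Species not present in the file are absent (unobserved), never imputed
    as zero.  Round-trips :func:`write_timecourse_csv` to full float
    precision.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"time-course file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TIDY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = sorted(set(frame["species"]) - set(SPECIES))
    if bad:
        raise ValidationError(
            f"{path}: unknown species {bad}; valid labels: {', '.join(SPECIES)}"
        )

    out = []
    for rep, grp in frame.groupby("replicate", sort=True):
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            raise ValidationError(f"{path}: replicate {rep} mixes kinds {kinds}")
        species = [s for s in SPECIES if s in set(grp["species"])]
        times = None
        rows = []
        for sp in species:
            sub = grp[grp["species"] == sp]
            t = sub["time_h"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"{path}: non-monotone time column for species {sp}, "
                    f"replicate {rep}"
                )
            if times is None:
                times = t
            elif t.shape != times.shape or not np.array_equal(t, times):
                raise ValidationError(
                    f"{path}: species {sp} has a different time grid "
                    f"(replicate {rep})"
                )
            rows.append(sub["value"].to_numpy(dtype=float))
        out.append(
            TimeCourse(
                times=times,
                values=np.vstack(rows),
                species=tuple(species),
                kind=str(kinds[0]),
                replicate=int(rep),
            )
        )
    return out


# --------------------------------------------------------------------------
# Logging helpers
# --------------------------------------------------------------------------


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    log.setLevel(level)
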