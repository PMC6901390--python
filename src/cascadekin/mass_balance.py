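"""Yield, titre, assay-quantification and biomass-hydrolysis arithmetic.

The cascade cleaves one C6 sugar into one C3 pyruvate (to lactate) and one
C3 glyceraldehyde (unused), so the theoretical maximum is 1 mol lactate per
mol mannose — 50 % of the carbon.  Yields are expressed as percent of that
maximum; titres in mM lactate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cascade_model import CascadeError


@dataclass(frozen=True)
class AssayConstants:
    """Extinction coefficients for the photometric assays (mM-1 cm-1)."""

    epsilon_340: float = 6.22   # NADH at 340 nm
    epsilon_549: float = 67.8   # thiobarbituric-acid KDG adduct at 549 nm
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon_340 <= 0 or self.epsilon_549 <= 0 or self.path_cm <= 0:
            raise CascadeError("extinction coefficients and path must be > 0")


@dataclass(frozen=True)
class HydrolysisBatch:
    """One dilute-acid hydrolysis batch of spent coffee grounds (SCG)."""

    scg_mass_mg: float
    measured_mg_per_100mg: float  # sugar found in the hydrolysate
    std_recovery: float           # recovery fraction of reducing-sugar standards

    def __post_init__(self) -> None:
        if not 0.0 < self.std_recovery <= 1.0:
            raise CascadeError("standard recovery must be in (0, 1]")
        if self.scg_mass_mg < 0 or self.measured_mg_per_100mg < 0:
            raise CascadeError("masses must be >= 0")


def theoretical_max_la(mannose_mM: float) -> float:
    """Stoichiometric lactate ceiling: 1 mol LA per mol mannose (mM)."""
    if mannose_mM < 0:
        raise CascadeError("mannose concentration must be >= 0")
    return mannose_mM


def percent_yield(la_mM: float, mannose_mM: float) -> float:
    """Lactate yield as percent of the theoretical maximum."""
    if mannose_mM <= 0:
        raise CascadeError("mannose concentration must be > 0 for a yield")
    if la_mM < 0:
        raise CascadeError("lactate concentration must be >= 0")
    return 100.0 * la_mM / theoretical_max_la(mannose_mM)


def titre_from_yield(yield_pct: float, mannose_mM: float) -> float:
    """Lactate titre (mM) implied by a percent yield and substrate load."""
    if yield_pct < 0:
        raise CascadeError("yield must be >= 0")
    return yield_pct / 100.0 * theoretical_max_la(mannose_mM)


def nadh_from_absorbance(
    A340: float, path_cm: float = 1.0, constants: AssayConstants | None = None
) -> float:
    """NADH concentration (mM) from absorbance at 340 nm, Beer-Lambert."""
    if A340 < 0:
        raise CascadeError("absorbance must be >= 0")
    if path_cm <= 0:
        raise CascadeError("path length must be > 0")
    eps = (constants or AssayConstants()).epsilon_340
    return A340 / (eps * path_cm)


def kdg_from_absorbance(
    A549: float, path_cm: float = 1.0, constants: AssayConstants | None = None
) -> float:
    """KDG concentration (mM) from the TBA-adduct absorbance at 549 nm."""
    if A549 < 0:
        raise CascadeError("absorbance must be >= 0")
    if path_cm <= 0:
        raise CascadeError("path length must be > 0")
    eps = (constants or AssayConstants()).epsilon_549
    return A549 / (eps * path_cm)


def corrected_scg_content(
    measured_mg_per_100mg: float, std_recovery: float
) -> float:
    """True sugar content of the biomass, correcting for hydrolysis losses.

    Reducing-sugar standards run through the same hydrolysis recover only a
    fraction ``std_recovery`` of their input; dividing the measured content
    by that fraction undoes the loss.
    """
    if not 0.0 < std_recovery <= 1.0:
        raise CascadeError("standard recovery must be in (0, 1]")
    if measured_mg_per_100mg < 0:
        raise CascadeError("measured content must be >= 0")
    return measured_mg_per_100mg / std_recovery


def round_report(x: float, ndigits: int = 1) -> float:
    """Round for tabular reporting (one decimal, mirroring the lab tables);
    full precision is kept internally everywhere else."""
    return round(x, ndigits)
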