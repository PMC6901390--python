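"""Rate laws and ODE assembly for a cell-free four-enzyme mannose-to-lactate cascade.

The cascade couples an aldohexose dehydrogenase (AldT; mannose -> mannono-1,4-
lactone, NAD+ -> NADH), spontaneous hydrolysis of the lactone to mannonate, a
mannonate dehydratase (ManD; mannonate -> 2-keto-3-deoxygluconate), a KDG
aldolase (KDGA; KDG <-> pyruvate + glyceraldehyde, reversible) and an
L-lactate dehydrogenase (LDH; pyruvate -> L-lactate, NADH -> NAD+).  The NADH
formed in the first oxidation is consumed in the final reduction, so the
cofactor pool cycles with no net consumption.  Because only the pyruvate half
of each cleaved KDG reaches lactate, at most one C3 lactate can form per C6
mannose: 50 % of the substrate carbon is the stoichiometric ceiling.

A small side reaction — oxidation of accumulated glyceraldehyde to glycerate,
attributed to the dehydrogenase — can be enabled; it consumes NAD+ and
produces one NADH per glycerate, so the total cofactor pool is still
conserved.

Units
-----
Concentrations are mM throughout.  Enzyme loadings are volumetric activities
in U/ml; one U converts 1 umol substrate per minute, so U/ml is numerically a
rate capacity in mM/min.  Time is handled in hours at the interface (assay
and process durations are quoted in hours) and converted to minutes where
rate constants apply.  Temperature is fixed at 323 K (50 C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import yaml

# --------------------------------------------------------------------------
# Canonical species set
# --------------------------------------------------------------------------

#: Canonical species ordering used by every state vector and time course.
SPECIES: tuple[str, ...] = (
    "MAN",   # D-mannose
    "ML",    # D-mannono-1,4-lactone
    "MA",    # D-mannonate
    "KDG",   # 2-keto-3-deoxygluconate
    "PYR",   # pyruvate
    "GA",    # D-glyceraldehyde
    "GLYA",  # glycerate (glyceraldehyde oxidation product)
    "LA",    # L-lactic acid
    "NADp",  # oxidized cofactor
    "NADH",  # reduced cofactor
)

IDX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

#: Carbon atoms per species (cofactor carbon is not tracked: the nicotinamide
#: skeleton never exchanges carbon with the sugar pool).
CARBON: np.ndarray = np.array([6, 6, 6, 6, 3, 3, 3, 3, 0, 0], dtype=float)

ENZYMES: tuple[str, ...] = ("AldT", "ManD", "KDGA", "LDH")

#: Gas constant in kJ mol-1 K-1.
R_KJ: float = 8.314462618e-3

MIN_PER_H = 60.0


class CascadeError(ValueError):
    """Domain error raised for invalid kinetic inputs."""


def species_vector(**conc: float) -> np.ndarray:
    """Build a state vector (mM) in canonical species order.

    Unlisted species default to 0.  Unknown labels or negative
    concentrations raise :class:`CascadeError`.
    """
    y = np.zeros(len(SPECIES))
    for name, value in conc.items():
        if name not in IDX:
            raise CascadeError(
                f"unknown species {name!r}; valid labels: {', '.join(SPECIES)}"
            )
        if value < 0:
            raise CascadeError(f"negative concentration for {name}: {value}")
        y[IDX[name]] = float(value)
    return y


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic constants and operational stability for one cascade enzyme.

    ``km`` maps substrate labels to Michaelis constants (mM); KDGA carries a
    single combined constant for pyruvate + glyceraldehyde under the key
    ``"PYR+GA"``.  ``half_life_h`` is the first-order thermal-deactivation
    half-life at process temperature (``math.inf`` for enzymes that stay
    fully active over the assay window).
    """

    name: str
    km: Mapping[str, float]
    vmax_u_per_mg: float
    kcat_per_s: float
    half_life_h: float
    substrates: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self) -> None:
        for sub, km in self.km.items():
            if km <= 0:
                raise CascadeError(f"{self.name}: Km for {sub} must be > 0, got {km}")
        if self.vmax_u_per_mg <= 0:
            raise CascadeError(f"{self.name}: Vmax must be > 0")
        if self.half_life_h <= 0:
            raise CascadeError(f"{self.name}: half-life must be > 0")

    @property
    def kcat_over_km(self) -> float:
        """Catalytic efficiency kcat/Km (mM-1 s-1) for the primary substrate."""
        km0 = next(iter(self.km.values()))
        return self.kcat_per_s / km0


@dataclass(frozen=True)
class Loading:
    """Volumetric enzyme loading with its addition time.

    ``u_per_ml`` is the activity loading (U/ml, numerically mM/min of rate
    capacity); ``addition_time_h`` supports sequential protocols where
    enzymes enter the pot at scheduled times.
    """

    enzyme: str
    u_per_ml: float
    addition_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise CascadeError(
                f"unknown enzyme {self.enzyme!r}; valid: {', '.join(ENZYMES)}"
            )
        if self.u_per_ml < 0:
            raise CascadeError(f"{self.enzyme}: loading must be >= 0")
        if self.addition_time_h < 0:
            raise CascadeError(f"{self.enzyme}: addition time must be >= 0")


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamics of the aldol step.

    ``dG_cleavage_kj`` is the standard transformed Gibbs energy of KDG
    cleavage into pyruvate + glyceraldehyde (kJ/mol, positive = slightly
    unfavourable at the 1 M standard state; dilution makes cleavage
    favourable at mM concentrations because one molecule becomes two).
    """

    dG_cleavage_kj: float = 6.2
    temperature_K: float = 323.0
    gas_constant_kj: float = R_KJ
    standard_state_M: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise CascadeError("temperature must be > 0 K")


@dataclass(frozen=True)
class AuxRates:
    """Rate scales of the two non-core steps.

    ``k_hyd_per_min``: first-order lactone -> mannonate hydrolysis (1/min);
    spontaneous at neutral pH.  ``k_gaox``: dimensionless scale of the
    glyceraldehyde-oxidation side reaction relative to the (decayed) AldT
    capacity.
    """

    k_hyd_per_min: float = 0.05
    k_gaox: float = 0.05

    def __post_init__(self) -> None:
        if self.k_hyd_per_min < 0 or self.k_gaox < 0:
            raise CascadeError("auxiliary rate constants must be >= 0")


@dataclass(frozen=True)
class CascadeParams:
    """Full parameter set for the cascade rate system."""

    enzymes: Mapping[str, EnzymeParams]
    thermo: ThermoParams = field(default_factory=ThermoParams)
    aux: AuxRates = field(default_factory=AuxRates)
    #: Saturation constant for the cofactor dependence of AldT (NAD+) and
    #: LDH (NADH).  Not measured for these enzymes; small by default so the
    #: factor is ~1 at the >= 1.25 mM cofactor used in practice, while still
    #: shutting turnover off at zero cofactor.  0 disables the dependence.
    km_cofactor_mM: float = 0.05
    #: Km of the glyceraldehyde-oxidation side reaction; None = reuse the
    #: dehydrogenase's mannose Km.
    km_ga_mM: float | None = None
    #: Km of the aldol cleavage branch; None = reuse the combined
    #: pyruvate+glyceraldehyde Km.
    km_cleave_mM: float | None = None
    #: Multiplier on the KDGA capacity in the net aldol rate (the one free
    #: thermodynamically-consistent scale of the reversible step).
    aldol_scale: float = 1.0
    reverse_aldol: bool = True
    ga_oxidation: bool = True

    def enzyme(self, name: str) -> EnzymeParams:
        return self.enzymes[name]

    def updated(self, **changes) -> "CascadeParams":
        return replace(self, **changes)


def default_params() -> CascadeParams:
    """Load the packaged parameter fixture (50 C, pH 7.0 constants)."""
    text = resources.files("cascadekin.data").joinpath("params_cascade.yaml").read_text()
    raw = yaml.safe_load(text)
    enzymes = {}
    for name, e in raw["enzymes"].items():
        enzymes[name] = EnzymeParams(
            name=name,
            km={k: float(v) for k, v in e["km_mM"].items()},
            vmax_u_per_mg=float(e["vmax_u_per_mg"]),
            kcat_per_s=float(e["kcat_per_s"]),
            half_life_h=float(e["half_life_h"]),
            substrates=tuple(e["substrates"]),
            products=tuple(e["products"]),
        )
    thermo = ThermoParams(
        dG_cleavage_kj=float(raw["thermo"]["dG_cleavage_kJ_per_mol"]),
        temperature_K=float(raw["thermo"]["temperature_K"]),
    )
    aux = AuxRates(
        k_hyd_per_min=float(raw["aux"]["k_hyd_per_min"]),
        k_gaox=float(raw["aux"]["k_gaox"]),
    )
    return CascadeParams(
        enzymes=enzymes,
        thermo=thermo,
        aux=aux,
        km_cofactor_mM=float(raw["cofactor_km_mM"]),
    )


# --------------------------------------------------------------------------
# Elementary rate laws
# --------------------------------------------------------------------------


def michaelis_menten_rate(S: float, Km: float, Vcap: float) -> float:
    """Single-substrate Michaelis-Menten rate Vcap*S/(Km+S) in mM/min.

    Monotone non-decreasing in S and bounded by the capacity ``Vcap``.
    """
    if Km <= 0:
        raise CascadeError(f"Km must be > 0, got {Km}")
    if S < 0:
        raise CascadeError(f"substrate concentration must be >= 0, got {S}")
    if Vcap < 0:
        raise CascadeError(f"capacity must be >= 0, got {Vcap}")
    return Vcap * S / (Km + S)


def aldol_addition_rate(pyr: float, ga: float, Km_comb: float, Vcap: float) -> float:
    """Rapid-equilibrium random-order aldol addition rate (mM/min).

    The aldolase was characterised with one combined Michaelis constant for
    pyruvate + glyceraldehyde, so the same ``Km_comb`` appears in both
    saturation factors: v = Vcap*pyr*ga/((Km+pyr)*(Km+ga)).  Symmetric in
    its two substrates and zero if either is absent.
    """
    if Km_comb <= 0:
        raise CascadeError(f"Km must be > 0, got {Km_comb}")
    if pyr < 0 or ga < 0:
        raise CascadeError("substrate concentrations must be >= 0")
    if Vcap < 0:
        raise CascadeError("capacity must be >= 0")
    return Vcap * pyr * ga / ((Km_comb + pyr) * (Km_comb + ga))


def equilibrium_constant_from_dG(dG_kj: float, T: float) -> float:
    """Equilibrium constant exp(-dG/RT) on a 1 M standard state.

    For the cleavage direction KDG <-> PYR + GA the returned value carries
    units of M ([PYR][GA]/[KDG] at equilibrium, concentrations in M).
    """
    if T <= 0:
        raise CascadeError(f"temperature must be > 0 K, got {T}")
    return math.exp(-dG_kj * 1000.0 / (R_KJ * 1000.0 * T))


def net_aldol_rate(
    kdg: float,
    pyr: float,
    ga: float,
    *,
    vcap: float,
    km_comb: float,
    thermo: ThermoParams,
    km_cleave: float | None = None,
    reverse: bool = True,
) -> float:
    """Net aldol rate in mM/min; positive = cleavage (KDG -> PYR + GA).

    Implemented as a reversible uni-bi rate law with a shared binding
    denominator,

        v = (Vcap/Kk) * (kdg - pyr*ga/Keq') /
            (1 + kdg/Kk + pyr/Kc + ga/Kc + pyr*ga/Kc^2)

    with Kk the cleavage Km (default: the combined addition Km Kc) and
    Keq' the cleavage equilibrium constant expressed in mM.  The forward
    limit (pyr = ga = 0) is exactly Michaelis-Menten in KDG; the reverse
    limit (kdg = 0) is the bi-substrate addition law scaled by the Haldane
    factor Kc^2/(Keq'*Kk), so the net rate vanishes exactly where the
    mass-action ratio pyr*ga/kdg equals Keq.  With ``reverse=False`` the
    addition branch is dropped and cleavage is plain MM in KDG.
    """
    if kdg < 0 or pyr < 0 or ga < 0:
        raise CascadeError("concentrations must be >= 0")
    if vcap < 0:
        raise CascadeError("capacity must be >= 0")
    if km_comb <= 0:
        raise CascadeError("Km must be > 0")
    kk = km_comb if km_cleave is None else km_cleave
    if kk <= 0:
        raise CascadeError("cleavage Km must be > 0")
    if not reverse:
        return michaelis_menten_rate(kdg, kk, vcap)
    keq_mM = equilibrium_constant_from_dG(thermo.dG_cleavage_kj, thermo.temperature_K)
    keq_mM *= 1000.0 * thermo.standard_state_M
    num = vcap * (kdg - pyr * ga / keq_mM) / kk
    den = 1.0 + kdg / kk + pyr / km_comb + ga / km_comb + pyr * ga / km_comb**2
    return num / den


def active_capacity(loading0: float, half_life_h: float, t_h: float) -> float:
    """Residual rate capacity (U/ml) after first-order thermal deactivation.

    A(t) = A0 * 2^(-t/t_half) with the long-time plateau fixed at zero;
    ``half_life_h = inf`` models enzymes that remain fully active.
    """
    if loading0 < 0:
        raise CascadeError("loading must be >= 0")
    if half_life_h <= 0:
        raise CascadeError("half-life must be > 0")
    if t_h < 0:
        raise CascadeError("time must be >= 0")
    if math.isinf(half_life_h):
        return loading0
    return loading0 * 2.0 ** (-t_h / half_life_h)


def lactone_hydrolysis_rate(ml: float, k_hyd: float) -> float:
    """First-order spontaneous lactone hydrolysis rate k_hyd*ml (mM/min)."""
    if ml < 0:
        raise CascadeError("concentration must be >= 0")
    if k_hyd < 0:
        raise CascadeError("rate constant must be >= 0")
    return k_hyd * ml


def _saturation(c: float, km: float) -> float:
    # km == 0 disables the dependence (factor 1 whenever any cofactor exists)
    if km == 0.0:
        return 1.0 if c > 0.0 else 0.0
    return c / (km + c)


# --------------------------------------------------------------------------
# Stoichiometry and derivative assembly
# --------------------------------------------------------------------------

#: Reactions in cascade order; columns of the stoichiometric matrix.
REACTIONS: tuple[str, ...] = (
    "AldT",      # MAN + NAD+ -> ML + NADH
    "hydrolysis",  # ML -> MA
    "ManD",      # MA -> KDG
    "aldol",     # KDG <-> PYR + GA (net, positive = cleavage)
    "LDH",       # PYR + NADH -> LA + NAD+
    "GA_ox",     # GA + NAD+ -> GLYA + NADH
)


def stoichiometric_matrix() -> np.ndarray:
    """Species x reaction stoichiometric matrix N (d state/dt = N v)."""
    N = np.zeros((len(SPECIES), len(REACTIONS)))

    def put(rxn: str, **coef: float) -> None:
        j = REACTIONS.index(rxn)
        for sp, c in coef.items():
            N[IDX[sp], j] = c

    put("AldT", MAN=-1, ML=+1, NADp=-1, NADH=+1)
    put("hydrolysis", ML=-1, MA=+1)
    put("ManD", MA=-1, KDG=+1)
    put("aldol", KDG=-1, PYR=+1, GA=+1)
    put("LDH", PYR=-1, LA=+1, NADH=-1, NADp=+1)
    put("GA_ox", GA=-1, GLYA=+1, NADp=-1, NADH=+1)
    return N


def build_rate_system(
    recipe,
    params: CascadeParams,
    *,
    clip: bool = True,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Assemble the derivative function t, state -> d(state)/dt (per hour).

    ``recipe`` must provide ``loadings`` (a sequence of :class:`Loading`);
    enzyme capacities decay from each enzyme's own addition time with its
    measured half-life.  States are clipped at zero inside the evaluation
    (stiff integrators can transiently undershoot) unless ``clip=False``.
    """
    loadings = list(recipe.loadings)
    for ld in loadings:
        if ld.enzyme not in params.enzymes:
            raise CascadeError(f"no kinetic parameters for enzyme {ld.enzyme!r}")

    by_enzyme: dict[str, list[tuple[float, float, float]]] = {e: [] for e in ENZYMES}
    for ld in loadings:
        hl = params.enzymes[ld.enzyme].half_life_h
        by_enzyme[ld.enzyme].append((ld.u_per_ml, ld.addition_time_h, hl))

    km_man = params.enzymes["AldT"].km["MAN"]
    km_ma = params.enzymes["ManD"].km["MA"]
    km_comb = params.enzymes["KDGA"].km["PYR+GA"]
    km_pyr = params.enzymes["LDH"].km["PYR"]
    km_cof = params.km_cofactor_mM
    km_ga = params.km_ga_mM if params.km_ga_mM is not None else km_man
    km_cleave = params.km_cleave_mM if params.km_cleave_mM is not None else km_comb
    k_hyd = params.aux.k_hyd_per_min
    k_gaox = params.aux.k_gaox if params.ga_oxidation else 0.0
    aldol_scale = params.aldol_scale
    reverse = params.reverse_aldol
    keq_mM = (
        equilibrium_constant_from_dG(
            params.thermo.dG_cleavage_kj, params.thermo.temperature_K
        )
        * 1000.0
        * params.thermo.standard_state_M
    )

    def cap(entries: list[tuple[float, float, float]], t: float) -> float:
        c = 0.0
        for u, t0, hl in entries:
            if t >= t0 and u > 0.0:
                c += u if math.isinf(hl) else u * 2.0 ** (-(t - t0) / hl)
        return c

    aldt_entries = by_enzyme["AldT"]
    mand_entries = by_enzyme["ManD"]
    kdga_entries = by_enzyme["KDGA"]
    ldh_entries = by_enzyme["LDH"]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if clip:
            y = np.maximum(y, 0.0)
        man, ml, ma, kdg, pyr, ga, _glya, _la, nadp, nadh = y

        cap_aldt = cap(aldt_entries, t)
        cap_mand = cap(mand_entries, t)
        cap_kdga = cap(kdga_entries, t)
        cap_ldh = cap(ldh_entries, t)

        f_nadp = _saturation(nadp, km_cof)
        f_nadh = _saturation(nadh, km_cof)

        v_aldt = cap_aldt * man / (km_man + man) * f_nadp
        v_hyd = k_hyd * ml
        v_mand = cap_mand * ma / (km_ma + ma)
        vcap_ald = aldol_scale * cap_kdga
        if reverse:
            num = vcap_ald * (kdg - pyr * ga / keq_mM) / km_cleave
            den = (
                1.0
                + kdg / km_cleave
                + pyr / km_comb
                + ga / km_comb
                + pyr * ga / km_comb**2
            )
            v_ald = num / den
        else:
            v_ald = vcap_ald * kdg / (km_cleave + kdg)
        v_ldh = cap_ldh * pyr / (km_pyr + pyr) * f_nadh
        v_gaox = k_gaox * cap_aldt * ga / (km_ga + ga) * f_nadp

        dy = np.empty(10)
        dy[0] = -v_aldt                      # MAN
        dy[1] = v_aldt - v_hyd               # ML
        dy[2] = v_hyd - v_mand               # MA
        dy[3] = v_mand - v_ald               # KDG
        dy[4] = v_ald - v_ldh                # PYR
        dy[5] = v_ald - v_gaox               # GA
        dy[6] = v_gaox                       # GLYA
        dy[7] = v_ldh                        # LA
        dy[8] = -v_aldt + v_ldh - v_gaox     # NAD+
        dy[9] = v_aldt - v_ldh + v_gaox      # NADH
        return dy * MIN_PER_H

    return rhs
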