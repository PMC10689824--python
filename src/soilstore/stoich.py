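"""Storage-explicit stoichiometric model of microbial C-P growth.

A homogeneous microbial community takes up organic C and inorganic P in
proportion to their availabilities (equal affinities, so the substrate C:P
ratio equals the uptake ratio u_c/u_p).  Carbon allocated to growth is fixed
into structural biomass with efficiency ``e`` (C:P ratio ``r_B``, mass basis);
the rest of the growth-allocated C is respired as growth-coupled respiration
(1-e)/e per unit growth.  Growth is the minimum of the C-allowed and
P-allowed rates, which switch at the threshold element ratio TER = r_B / e.

Three storage strategies:

* ``none`` — no storage; C in excess of P-allowed growth is lost as overflow
  respiration.
* ``reserve`` — a constitutive fraction ``f_res`` of C uptake goes to storage
  before growth allocation (a trade-off against short-term growth).
* ``surplus`` — under P limitation, excess C (up to ``phi_max`` of uptake)
  is diverted to storage instead of overflow respiration.

All fluxes are in C units relative to uptake; gradient sweeps normalise by
the C uptake rate at the baseline substrate C:P.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ModelConsistencyError, ValidationError

MODES = ("none", "reserve", "surplus")

#: C mass-balance tolerance (relative)
BALANCE_RTOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Community-level physiological parameters.

    e
        growth efficiency: fraction of growth-allocated C fixed in biomass.
    r_B
        structural biomass C:P ratio, mass basis.
    f_res
        constitutive reserve fraction of C uptake (reserve mode only).
    phi_max
        cap on surplus storage as a fraction of C uptake.
    baseline_cp
        substrate organic C : inorganic P mass ratio of the unamended soil.
    """

    e: float = 0.45
    r_B: float = 29.4
    f_res: float = 0.15
    phi_max: float = 1.0
    baseline_cp: float = 59.6

    def __post_init__(self) -> None:
        if not (0 < self.e < 1):
            raise ValidationError(f"e = {self.e} must be in (0, 1)")
        if self.r_B <= 0:
            raise ValidationError(f"r_B = {self.r_B} must be positive")
        if not (0 <= self.f_res < 1):
            raise ValidationError(f"f_res = {self.f_res} must be in [0, 1)")
        if not (0 < self.phi_max <= 1):
            raise ValidationError(f"phi_max = {self.phi_max} must be in (0, 1]")
        if self.baseline_cp <= 0:
            raise ValidationError("baseline_cp must be positive")


#: default parameterisations for the two incubation soils (biomass C:P and
#: substrate C:P from the site-mean fixture; e, f_res, phi_max are package
#: defaults chosen so the basalt baseline sits left of the TER and the
#: sandstone baseline right of it)
BASALT_PARAMS = ModelParams(e=0.45, r_B=29.4, f_res=0.15, phi_max=1.0, baseline_cp=59.6)
SANDSTONE_PARAMS = ModelParams(e=0.45, r_B=78.7, f_res=0.15, phi_max=1.0, baseline_cp=636.0)

SOIL_PARAMS = {"basalt": BASALT_PARAMS, "sandstone": SANDSTONE_PARAMS}


@dataclass(frozen=True)
class SubstrateState:
    """Relative organic C and inorganic P availabilities (both > 0)."""

    c_avail: float
    p_avail: float

    def __post_init__(self) -> None:
        if self.c_avail <= 0 or self.p_avail <= 0:
            raise ValidationError("substrate availabilities must be positive")

    @property
    def cp_ratio(self) -> float:
        return self.c_avail / self.p_avail


@dataclass(frozen=True)
class ModelFluxes:
    """C fluxes at one substrate state (all >= 0, C units)."""

    u_c: float
    u_p: float
    growth: float
    respiration: float
    storage_net: float
    overflow: float
    limitation: str  # "C_limited" | "P_limited"
    mode: str

    def normalised(self, scale: float) -> "ModelFluxes":
        if scale <= 0:
            raise ValidationError("normalisation scale must be positive")
        return replace(
            self,
            u_c=self.u_c / scale,
            u_p=self.u_p / scale,
            growth=self.growth / scale,
            respiration=self.respiration / scale,
            storage_net=self.storage_net / scale,
            overflow=self.overflow / scale,
        )


@dataclass
class GradientSweep:
    """Flux curves across a substrate C:P gradient, one mode per curve set."""

    cp_ratios: np.ndarray
    curves: dict[str, list[ModelFluxes]]
    ter: float
    baseline_cp: float


def threshold_element_ratio(params: ModelParams) -> float:
    """Substrate C:P at which growth switches from C to P limitation."""
    return params.r_B / params.e


def classify_limitation(cp_ratio: float, params: ModelParams) -> str:
    """P_limited iff cp_ratio > TER; the boundary itself is C_limited."""
    if cp_ratio <= 0:
        raise ValidationError("cp_ratio must be positive")
    return "P_limited" if cp_ratio > threshold_element_ratio(params) else "C_limited"


def simulate_point(
    mode: str, params: ModelParams, substrate: SubstrateState
) -> ModelFluxes:
    """Steady-state flux partitioning at one substrate state.

    Uptake is linear in availability with equal affinities (u_c = c_avail,
    u_p = p_avail in relative units).  Growth is min(C-allowed, P-allowed);
    the limitation flag records which constraint binds (tie -> C-limited).
    """
    if mode not in MODES:
        raise ValidationError(f"unknown storage mode {mode!r}")
    u_c = substrate.c_avail
    u_p = substrate.p_avail

    c_supply = (1.0 - params.f_res) * u_c if mode == "reserve" else u_c
    growth_c_allowed = params.e * c_supply
    growth_p_allowed = params.r_B * u_p
    if growth_p_allowed < growth_c_allowed:
        growth = growth_p_allowed
        limitation = "P_limited"
    else:
        growth = growth_c_allowed
        limitation = "C_limited"

    if mode == "reserve":
        storage = params.f_res * u_c
    elif mode == "surplus" and limitation == "P_limited":
        storage = min(u_c - growth / params.e, params.phi_max * u_c)
    else:
        storage = 0.0

    overflow = max(u_c - growth / params.e - storage, 0.0)
    respiration = (1.0 - params.e) / params.e * growth + overflow

    fluxes = ModelFluxes(
        u_c=u_c,
        u_p=u_p,
        growth=growth,
        respiration=respiration,
        storage_net=storage,
        overflow=overflow,
        limitation=limitation,
        mode=mode,
    )
    _check_balance(fluxes)
    return fluxes


def _check_balance(f: ModelFluxes) -> None:
    for name in ("growth", "respiration", "storage_net", "overflow"):
        if getattr(f, name) < 0:
            raise ModelConsistencyError(f"negative flux {name} = {getattr(f, name)}")
    resid = abs(f.u_c - (f.growth + f.respiration + f.storage_net))
    if resid > BALANCE_RTOL * max(f.u_c, 1.0):
        raise ModelConsistencyError(
            f"C mass balance violated: residual {resid} at u_c = {f.u_c}"
        )


def substrate_for_ratio(cp_ratio: float, baseline_cp: float) -> SubstrateState:
    """Substrate state for one point of a C:P gradient.

    Above the baseline, organic C is added at fixed P; below it, inorganic P
    is added at fixed C (matching how an amendment experiment moves C:P).
    C availability is expressed relative to the baseline (so the baseline C
    uptake is 1) and P availability on the same scale (1/baseline_cp at the
    baseline), keeping c_avail / p_avail equal to the actual substrate C:P.
    """
    if cp_ratio >= baseline_cp:
        return SubstrateState(c_avail=cp_ratio / baseline_cp, p_avail=1.0 / baseline_cp)
    return SubstrateState(c_avail=1.0, p_avail=1.0 / cp_ratio)


def sweep_gradient(
    mode: str,
    params: ModelParams,
    cp_min: float,
    cp_max: float,
    n_points: int = 201,
) -> GradientSweep:
    """Sweep one storage mode (or ``"all"``) across a log-spaced C:P grid.

    The baseline C:P is inserted into the grid; every flux is normalised by
    the C uptake rate at that baseline point, so the baseline u_c is 1.
    """
    if not (cp_min < params.baseline_cp < cp_max):
        raise ValueError(
            f"baseline_cp = {params.baseline_cp} must lie inside "
            f"({cp_min}, {cp_max})"
        )
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    grid = np.geomspace(cp_min, cp_max, n_points)
    grid = np.unique(np.append(grid, params.baseline_cp))

    modes: Sequence[str] = MODES if mode == "all" else (mode,)
    curves: dict[str, list[ModelFluxes]] = {}
    for m in modes:
        baseline = simulate_point(m, params, substrate_for_ratio(params.baseline_cp, params.baseline_cp))
        scale = baseline.u_c  # = 1 by construction, kept explicit
        curves[m] = [
            simulate_point(m, params, substrate_for_ratio(r, params.baseline_cp)).normalised(scale)
            for r in grid
        ]
    return GradientSweep(
        cp_ratios=grid,
        curves=curves,
        ter=threshold_element_ratio(params),
        baseline_cp=params.baseline_cp,
    )


def cue(fluxes: ModelFluxes, count_storage: bool = False) -> float:
    """Carbon use efficiency: (growth [+ net storage]) / C uptake."""
    if fluxes.u_c <= 0:
        raise ValidationError("u_c must be positive")
    num = fluxes.growth + (fluxes.storage_net if count_storage else 0.0)
    return num / fluxes.u_c


def sweep_to_frame(sweep: GradientSweep):
    """Long-format table of a sweep (one row per mode x C:P point)."""
    import pandas as pd

    rows = []
    for m, fl in sweep.curves.items():
        for r, f in zip(sweep.cp_ratios, fl):
            rows.append(
                {
                    "cp_ratio": r,
                    "mode": m,
                    "u_c": f.u_c,
                    "growth": f.growth,
                    "respiration": f.respiration,
                    "storage_net": f.storage_net,
                    "overflow": f.overflow,
                    "limitation": f.limitation,
                }
            )
    return pd.DataFrame(rows)
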