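"""Radius-halving inference: from sibling-pair rates back to a source radius.

The core statistic is the halving rate

    Rp = SP_r25 / SP_r50,

the factor by which the mean sibling-pair count per sample grows when the
source radius is halved (25 km vs 50 km scenarios).  Given the empirical
pair count SP_emp, the number of halvings needed to make SP_emp a typical
random outcome is

    n_halve = SP_emp / (Rp * SP_r25),        r_Rp = r25 / n_halve

— a *linear* division of the radius, mirroring the published arithmetic
(25 km / 5.8 = 4.31 km), not a geometric r25 / 2**n; the geometric variant
is available behind a flag.

Forward and inverse conversions between radius, habitat area, source-colony
count and TRC size deliberately follow two different conventions, both
explicit:

* forward (radius -> TRC) uses the unrounded colony density C_A = 102.3 /km^2
  and the daily factor 0.5, the chain that reproduces the published TRCs;
* inverse (TRC -> area/radius) uses the published rounded C_A = 102 /km^2
  and *no* daily factor, exactly as the published back-calculations do
  (A = TRC / (R_Cd * C_A * F_R), r = sqrt(A / pi)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RpEstimate",
    "RadiusSolution",
    "rp_rate",
    "solve_radius",
    "trc_from_disc_radius",
    "radius_from_colonies",
    "solve_full",
]


@dataclass(frozen=True)
class RpEstimate:
    """Halving rate of the mean sibling-pair count."""

    sp_r25: float
    sp_r50: float

    def __post_init__(self) -> None:
        if self.sp_r50 <= 0:
            raise ValueError("sp_r50 must be positive")
        if self.sp_r25 < 0:
            raise ValueError("sp_r25 must be nonnegative")

    @property
    def rp(self) -> float:
        return self.sp_r25 / self.sp_r50


def rp_rate(sp_r25: float, sp_r50: float) -> RpEstimate:
    """Rate ``Rp = SP_r25 / SP_r50`` at which pairs grow per radius halving."""
    return RpEstimate(sp_r25=sp_r25, sp_r50=sp_r50)


def solve_radius(
    sp_emp: float,
    rp: RpEstimate | float,
    r25: float = 25.0,
    geometric: bool = False,
) -> tuple[float, float]:
    """Halvings and radius at which ``sp_emp`` pairs become typical.

    Returns ``(n_halve, r_Rp)`` with ``n_halve = sp_emp / (Rp * SP_r25)``.
    By default the radius shrinks linearly, ``r_Rp = r25 / n_halve``; with
    ``geometric=True`` it shrinks as ``r25 / 2**n_halve``.
    """
    rate = rp.rp if isinstance(rp, RpEstimate) else float(rp)
    sp_r25 = rp.sp_r25 if isinstance(rp, RpEstimate) else None
    if sp_r25 is None:
        raise ValueError("solve_radius needs an RpEstimate carrying sp_r25")
    if sp_emp <= 0 or rate <= 0 or r25 <= 0:
        raise ValueError("sp_emp, Rp and r25 must all be positive")
    n_halve = sp_emp / (rate * sp_r25)
    r_rp = r25 / (2.0**n_halve) if geometric else r25 / n_halve
    return n_halve, r_rp


def trc_from_disc_radius(
    r: float | None,
    r_cd: float = 6.0,
    c_a: float = 102.3,
    f_r: float = 0.33,
    daily_factor: float = 0.5,
    area: float | None = None,
) -> int:
    """Forward conversion: disc radius (or explicit area) to TRC size.

    ``area`` overrides ``pi * r**2`` when a published (rounded) area is to
    be reproduced.  Truncates to an integer like every reported TRC.
    """
    if area is None:
        if r is None or r < 0:
            raise ValueError("need a nonnegative radius or an explicit area")
        area = math.pi * r**2
    return int(math.floor(r_cd * c_a * f_r * daily_factor * area))


def radius_from_colonies(
    trc: float,
    r_cd: float = 6.0,
    c_a: float = 102.0,
    f_r: float = 0.33,
) -> tuple[float, float]:
    """Inverse conversion: TRC size to habitat area (km^2) and disc radius (km).

    ``A = TRC / (R_Cd * C_A * F_R)``, ``r = sqrt(A / pi)``.  Defaults use the
    published rounded density 102 /km^2 and no daily factor — the inverse
    convention of the published back-calculations.
    """
    if trc < 0 or r_cd <= 0 or c_a <= 0 or f_r <= 0:
        raise ValueError("trc must be >= 0 and rates positive")
    area = trc / (r_cd * c_a * f_r)
    return area, math.sqrt(area / math.pi)


@dataclass(frozen=True)
class RadiusSolution:
    """Every derived quantity of the radius inference, with its conventions.

    Forward quantities (TRC_rRp) use C_A = ``c_a_forward`` with the daily
    factor; inverse quantities (A_Cmax, r_Cmax, r_iRCS) use the rounded
    ``c_a_inverse`` without it.
    """

    sp_emp: float
    rp: float
    n_halve: float
    r_rp: float
    a_rp: float
    trc_r_rp: int
    cmax: int
    trc_cmax: int
    a_cmax: float
    r_cmax: float
    trc_rircs: int | None
    a_rircs: float | None
    r_rircs: float | None
    c_a_forward: float
    c_a_inverse: float
    daily_factor: float


def solve_full(
    sp_emp: float,
    rp: RpEstimate,
    r25: float = 25.0,
    n_recruits: int = 168,
    n_pairs: int = 48,
    family_size: int = 6,
    r_cd: float = 6.0,
    c_a_forward: float = 102.3,
    c_a_inverse: float = 102.0,
    f_r: float = 0.33,
    daily_factor: float = 0.5,
    a_rp_override: float | None = None,
    trc_rircs: int | None = None,
) -> RadiusSolution:
    """Chain the whole radius inference into one report.

    ``a_rp_override`` lets the caller reproduce a published (rounded) area
    for the r_Rp disc; ``trc_rircs`` is the confidence-search cohort size if
    one has been computed (its radius is then back-calculated with the
    inverse convention).  ``Cmax = n_recruits - n_pairs`` and ``TRC_Cmax =
    family_size * Cmax``.
    """
    n_halve, r_rp = solve_radius(sp_emp, rp, r25)
    a_rp = math.pi * r_rp**2 if a_rp_override is None else a_rp_override
    trc_r_rp = trc_from_disc_radius(
        None, r_cd=r_cd, c_a=c_a_forward, f_r=f_r, daily_factor=daily_factor, area=a_rp
    )
    cmax = n_recruits - n_pairs
    trc_cmax = family_size * cmax
    a_cmax, r_cmax = radius_from_colonies(trc_cmax, r_cd=r_cd, c_a=c_a_inverse, f_r=f_r)
    if trc_rircs is not None:
        a_rircs, r_rircs = radius_from_colonies(
            trc_rircs, r_cd=r_cd, c_a=c_a_inverse, f_r=f_r
        )
    else:
        a_rircs = r_rircs = None
    return RadiusSolution(
        sp_emp=sp_emp,
        rp=rp.rp,
        n_halve=n_halve,
        r_rp=r_rp,
        a_rp=a_rp,
        trc_r_rp=trc_r_rp,
        cmax=cmax,
        trc_cmax=trc_cmax,
        a_cmax=a_cmax,
        r_cmax=r_cmax,
        trc_rircs=trc_rircs,
        a_rircs=a_rircs,
        r_rircs=r_rircs,
        c_a_forward=c_a_forward,
        c_a_inverse=c_a_inverse,
        daily_factor=daily_factor,
    )
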