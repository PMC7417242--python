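"""Demographic model of the theoretical total recruiting cohort (TRC).

The TRC is the complete pool of damselfish larvae arriving at the focal
reef on the sampling night.  Its size is a product of per-colony larval
output, colony density on suitable habitat, the fraction of simultaneously
reproducing females, and the habitat area within a putative source radius:

    TRC = R_Cd * C_A * F_R * daily_factor * A

where R_Cd = E * H * Hd * S is the daily number of larvae produced by an
average colony that survive the pelagic larval phase.  ``daily_factor``
(default 0.5) is an extra per-day scaling required to reconcile the
published parameter table with the published TRC sizes; it is exposed as an
explicit convention rather than folded silently into any other parameter.

The cohort itself is represented as ``K`` families of a fixed size ``s``
(six recruits per source colony by default): the family partition is the
null structure that the Monte-Carlo sampler draws from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColonyBiology",
    "HabitatModel",
    "RecruitCohort",
    "recruits_per_colony_day",
    "habitat_area",
    "trc_size",
    "build_cohort",
]


class ParameterError(ValueError):
    """A demographic parameter is missing or outside its valid range."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ColonyBiology:
    """Per-colony reproductive parameters.

    Parameters
    ----------
    eggs_per_colony
        Average clutch size ``E`` of a colony (eggs).
    hatch_rate
        Fraction ``H`` of eggs in a clutch that hatch.
    daily_hatch_fraction
        Fraction ``Hd`` of a colony's eggs hatching on any given day.
    pld_survival
        Fraction ``S`` of hatched larvae surviving the pelagic larval
        duration through to recruitment.
    recruits_per_colony_day
        ``R_Cd``; if None it is derived as ``E * H * Hd * S``.
    """

    eggs_per_colony: float
    hatch_rate: float
    daily_hatch_fraction: float
    pld_survival: float
    recruits_per_colony_day: float | None = None

    def __post_init__(self) -> None:
        if self.eggs_per_colony < 0:
            raise ParameterError("eggs_per_colony must be nonnegative")
        _check_fraction("hatch_rate", self.hatch_rate)
        _check_fraction("daily_hatch_fraction", self.daily_hatch_fraction)
        _check_fraction("pld_survival", self.pld_survival)
        if self.recruits_per_colony_day is not None and self.recruits_per_colony_day < 0:
            raise ParameterError("recruits_per_colony_day must be nonnegative")


def recruits_per_colony_day(bio: ColonyBiology) -> float:
    """Daily recruit output ``R_Cd`` of an average colony.

    Returns the supplied ``R_Cd`` if one was given, otherwise derives
    ``E * H * Hd * S``.
    """
    if bio.recruits_per_colony_day is not None:
        return float(bio.recruits_per_colony_day)
    return (
        bio.eggs_per_colony
        * bio.hatch_rate
        * bio.daily_hatch_fraction
        * bio.pld_survival
    )


@dataclass(frozen=True)
class HabitatModel:
    """Habitat geometry and colony-density parameters.

    ``colony_density`` (``C_A``, colonies per km^2) is always ``Da / At``:
    the transect colony count divided by the transect area.  Habitat area is
    either a coastal strip of length ``L`` and width ``W`` (``area_mode
    = "strip"``) or a disc of radius ``r`` (``area_mode = "disc"``).
    """

    colonies_per_transect: float = 10.23
    transect_area: float = 0.1
    reproductive_female_fraction: float = 0.33
    habitat_length: float | None = None
    habitat_width: float | None = None
    radius: float | None = None
    area_mode: str = "strip"
    daily_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.transect_area <= 0:
            raise ParameterError("transect_area must be positive")
        if self.colonies_per_transect < 0:
            raise ParameterError("colonies_per_transect must be nonnegative")
        _check_fraction(
            "reproductive_female_fraction", self.reproductive_female_fraction
        )
        _check_fraction("daily_factor", self.daily_factor)
        if self.area_mode not in ("strip", "disc"):
            raise ParameterError(f"unknown area_mode {self.area_mode!r}")

    @property
    def colony_density(self) -> float:
        """Colonies per km^2 of suitable habitat, ``C_A = Da / At``."""
        return self.colonies_per_transect / self.transect_area


def habitat_area(hab: HabitatModel) -> float:
    """Habitat area in km^2 under the model's geometry.

    Strip mode returns ``L * W``; disc mode returns ``pi * r**2``.
    """
    if hab.area_mode == "strip":
        if hab.habitat_length is None or hab.habitat_width is None:
            raise ParameterError("strip area requires habitat_length and habitat_width")
        return hab.habitat_length * hab.habitat_width
    if hab.radius is None:
        raise ParameterError("disc area requires radius")
    return math.pi * hab.radius**2


def trc_size(
    bio: ColonyBiology,
    hab: HabitatModel,
    area: float | None = None,
    *,
    colony_density: float | None = None,
) -> int:
    """Size of the theoretical total recruiting cohort for a habitat area.

    ``TRC = R_Cd * C_A * F_R * daily_factor * A``, truncated to an integer
    (truncation, not half-up rounding, reproduces all published cohort
    sizes).  ``area`` defaults to :func:`habitat_area`; ``colony_density``
    may override ``C_A`` when a rounded published density is wanted.
    """
    if area is None:
        area = habitat_area(hab)
    if area < 0:
        raise ParameterError("area must be nonnegative")
    c_a = hab.colony_density if colony_density is None else colony_density
    exact = (
        recruits_per_colony_day(bio)
        * c_a
        * hab.reproductive_female_fraction
        * hab.daily_factor
        * area
    )
    return int(math.floor(exact))


@dataclass(frozen=True)
class RecruitCohort:
    """A TRC of ``K`` families of exactly ``s`` recruits each.

    ``family_labels[i]`` is the family index of recruit ``i``; the realized
    cohort size is ``K * s`` (a non-divisible nominal size is floored).
    """

    n_families: int
    family_size: int
    family_labels: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.n_families * self.family_size

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 1:
            raise ParameterError("cohort needs at least one family of size >= 1")
        if len(self.family_labels) != self.size:
            raise ParameterError("family_labels length must equal K * s")


class CohortTooSmallError(ValueError):
    """Nominal cohort size is below one family."""


def build_cohort(n_total: int, family_size: int = 6) -> RecruitCohort:
    """Partition a nominal cohort of ``n_total`` recruits into families.

    ``K = floor(n_total / family_size)`` families of exactly ``family_size``
    members; remainder recruits (at most ``family_size - 1``) are dropped.
    """
    if family_size < 1:
        raise ParameterError("family_size must be >= 1")
    if n_total < family_size:
        raise CohortTooSmallError(
            f"cohort of {n_total} cannot hold a family of {family_size}"
        )
    k = n_total // family_size
    labels = np.repeat(np.arange(k, dtype=np.int64), family_size)
    return RecruitCohort(n_families=k, family_size=family_size, family_labels=labels)
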