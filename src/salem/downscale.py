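"""Downscaling stand summaries to individual-tree lists.

A stand summarised by (N, Dg, SI) is expanded into diameter classes under a
normal dbh distribution whose standard deviation is a Chapman-Richards
function of Dg, then each class centre receives a height from the
circumference-height model and a commercial volume from the two-entry volume
equation.  The expansion is deterministic: class counts are expected values,
never sampled.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import SpeciesParameterSet, load_default_parameters
from .species import Species
from .stand import StandState

#: diameter below which volume is extrapolated outside the commercial range
COMMERCIAL_DBH_CM = 7.5

#: half-width of the diameter-distribution window, in standard deviations
DIST_WINDOW_SD = 4.0


@dataclass(frozen=True)
class DiameterClass:
    dbh_c: float  # class-centre dbh, cm
    width: float  # class width, cm
    n_c: float  # stems/ha in the class (continuous)


@dataclass(frozen=True)
class TreeRecord:
    """One diameter class of the downscaled tree list."""

    species: Species
    dbh: float  # cm
    c130: float  # circumference at 1.30 m, cm
    height: float  # m
    volume: float  # dm3 per tree
    n_per_ha: float


def sigma_of_dg(
    species: Species | str,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Within-stand dbh standard deviation (cm) at mean quadratic diameter ``dg``."""
    if dg < 0:
        raise ValueError(f"dg must be >= 0 (got {dg})")
    sp = Species.from_code(species)
    dd = (params or load_default_parameters()).diameter_dist[sp]
    return dd.alpha * (1.0 - math.exp(-dd.gamma * dg)) ** dd.beta


def arithmetic_mean_dbh(dg: float, sigma: float) -> float:
    """Arithmetic mean diameter of a normal dbh distribution: sqrt(Dg^2 - sigma^2).

    Under normality the quadratic mean exceeds the arithmetic mean by exactly
    the variance, so sigma must be smaller than Dg.
    """
    if sigma >= dg:
        raise ValueError(
            f"sigma ({sigma}) must be smaller than dg ({dg}) for a normal "
            "diameter distribution"
        )
    return math.sqrt(dg * dg - sigma * sigma)


def diameter_distribution(
    species: Species | str,
    dg: float,
    n_tot: float,
    class_width: float = 1.0,
    params: SpeciesParameterSet | None = None,
) -> list[DiameterClass]:
    """Expected stems per diameter class for a stand of ``n_tot`` stems at ``dg``.

    Classes of width ``class_width`` cover the mean +/- 4 standard deviations,
    clipped to positive diameters; counts are the normal density at the class
    centre times n_tot times the class width (no renormalisation, so the sum
    is short of n_tot by the mass outside the window).
    """
    if n_tot <= 0 or dg <= 0:
        raise ValueError("n_tot and dg must be positive")
    sigma = sigma_of_dg(species, dg, params)
    if sigma == 0.0:
        return [DiameterClass(dbh_c=dg, width=class_width, n_c=n_tot)]
    dm = arithmetic_mean_dbh(dg, sigma)
    lo = max(dm - DIST_WINDOW_SD * sigma, 0.0)
    hi = dm + DIST_WINDOW_SD * sigma
    # class centres on a regular grid anchored at half a width above `lo`
    n_classes = max(int(math.ceil((hi - lo) / class_width)), 1)
    centres = lo + (np.arange(n_classes) + 0.5) * class_width
    centres = centres[centres > 0]
    dens = np.exp(-0.5 * ((centres - dm) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    counts = n_tot * class_width * dens
    return [
        DiameterClass(dbh_c=float(d), width=class_width, n_c=float(n))
        for d, n in zip(centres, counts)
    ]


def tree_height(
    species: Species | str,
    c130: float,
    dg: float,
    si: float | None = None,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Total tree height (m) from circumference at breast height (cm).

    Uses the species' fitted circumference-height form with the stand's Dg as
    development-stage proxy and, where the form includes it, the site index.
    Heights start at breast height (1.3 m) for a vanishing circumference.
    """
    if c130 <= 0:
        raise ValueError(f"c130 must be positive (got {c130})")
    sp = Species.from_code(species)
    hp = (params or load_default_parameters()).height[sp]
    if hp.uses_site_index and si is None:
        raise ValueError(f"height model for {sp.value!r} requires a site index")
    asymptote = hp.alpha + hp.g1(dg) + hp.g2(si)
    return 1.3 + asymptote * (1.0 - math.exp(-hp.beta * c130**hp.gamma))


def tree_volume(
    species: Species | str,
    dbh: float,
    h_tot: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Commercial volume (dm3) of one tree from dbh (cm) and total height (m).

    The equation integrates a cylinder form factor plus a diameter-dependent
    adjustment and a (negative) correction for the non-commercial top.  Below
    the 7.5 cm commercial limit the value is extrapolated with a warning.
    """
    if dbh <= 0 or h_tot <= 1.3:
        raise ValueError("dbh must be positive and h_tot above breast height")
    if dbh < COMMERCIAL_DBH_CM:
        warnings.warn(
            f"dbh {dbh:.1f} cm below the commercial limit "
            f"({COMMERCIAL_DBH_CM} cm); volume extrapolated",
            stacklevel=2,
        )
    sp = Species.from_code(species)
    vp = (params or load_default_parameters()).volume[sp]
    cylinder = math.pi * dbh * dbh * h_tot / 40.0
    return vp.beta1 * h_tot / dbh + (vp.beta2 + vp.beta3 * dbh) * cylinder


def stand_downscale(
    state: StandState,
    class_width: float = 1.0,
    params: SpeciesParameterSet | None = None,
) -> tuple[list[TreeRecord], float]:
    """Tree list and stand volume (m3/ha) for the current stand state.

    Each species is expanded independently (diameter classes -> heights ->
    volumes) and the stand volume is the count-weighted sum over classes.
    Classes whose volume prediction is non-positive (far below the
    calibration range) contribute zero volume.
    """
    params = params or load_default_parameters()
    records: list[TreeRecord] = []
    total_volume_dm3 = 0.0
    for c in state.cohorts:
        if c.n == 0:
            continue
        for dc in diameter_distribution(
            c.species, c.dg_ob, c.n, class_width, params
        ):
            c130 = math.pi * dc.dbh_c
            h = tree_height(c.species, c130, c.dg_ob, c.site_index, params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = max(tree_volume(c.species, dc.dbh_c, h, params), 0.0)
            records.append(
                TreeRecord(
                    species=c.species, dbh=dc.dbh_c, c130=c130,
                    height=h, volume=v, n_per_ha=dc.n_c,
                )
            )
            total_volume_dm3 += dc.n_c * v
    return records, total_volume_dm3 / 1000.0
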