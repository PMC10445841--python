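"""Site indices and basal-area increment, in pure stands and in mixture.

The increment model is multiplicative: a site-dependent potential (the site
index, SI) is reduced by a density response f2(DI) and a stage-of-development
response f3(Dg).  Its output is a five-year under-bark basal-area increment in
m2/ha; the annual simulator adds one fifth of it per step.  In a two-species
stand each species grows as a proportion-weighted pure stand modulated by a
pair-specific mixture multiplier (1 + u).
"""
from __future__ import annotations

import math
import warnings

from .params import (
    DERIVED_TERMS,
    SITE_VARIABLES,
    SpeciesParameterSet,
    load_default_parameters,
)
from .species import Species

#: the increment model predicts growth over this many years
INCREMENT_PERIOD_YEARS = 5


def compute_site_index(
    species: Species | str,
    site: dict[str, float],
    params: SpeciesParameterSet | None = None,
) -> float:
    """Site index from environmental variables: SI = a0 + sum(a_m * X_m).

    ``site`` maps variable names of the controlled vocabulary (see
    ``salem.params.SITE_VARIABLES``) to values.  Squared terms (ph_sq,
    cn_ratio_sq) are computed from the base variable; a value must be supplied
    for every variable carrying a coefficient for this species.  Unknown names
    are ignored with a warning.  A non-positive SI triggers a warning (the
    stand would not grow).
    """
    sp = Species.from_code(species)
    gp = (params or load_default_parameters()).growth[sp]

    required = {DERIVED_TERMS.get(v, (v,))[0] for v in gp.a_m}
    missing = sorted(required - set(site))
    if missing:
        raise ValueError(
            f"site description for {sp.value!r} is missing: {missing}"
        )
    unknown = sorted(set(site) - SITE_VARIABLES)
    if unknown:
        warnings.warn(f"unknown site variables ignored: {unknown}", stacklevel=2)

    si = gp.a0
    for var, coef in gp.a_m.items():
        if var in DERIVED_TERMS:
            base, power = DERIVED_TERMS[var]
            si += coef * site[base] ** power
        else:
            si += coef * site[var]
    if si <= 0:
        warnings.warn(
            f"non-positive site index ({si:.3f}) for {sp.value!r}", stacklevel=2
        )
    return si


def f2_density(
    species: Species | str,
    di: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Density response: DI^b, or (1+b)*DI/(b+DI) for the hyperbolic species.

    Both forms pass through 1 at DI = 1 and 0 at DI = 0, and are increasing.
    """
    if di < 0:
        raise ValueError(f"density index must be >= 0 (got {di})")
    sp = Species.from_code(species)
    gp = (params or load_default_parameters()).growth[sp]
    if gp.equation_form == "eq4":
        if di == 0:
            return 0.0
        return (1.0 + gp.b) * di / (gp.b + di)
    return di ** gp.b


def f3_stage(
    species: Species | str,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Stage-of-development response (exp(c1*Dg) + c2) / (1 + c2).

    Equals 1 for a nascent stand (Dg = 0) and declines towards the asymptote
    c2/(1+c2) as the stand matures.
    """
    if dg < 0:
        raise ValueError(f"dg must be >= 0 (got {dg})")
    sp = Species.from_code(species)
    gp = (params or load_default_parameters()).growth[sp]
    return (math.exp(gp.c1 * dg) + gp.c2) / (1.0 + gp.c2)


def pure_bai_5yr(
    species: Species | str,
    si: float,
    di: float,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Five-year under-bark basal-area increment of a pure stand (m2/ha).

    A non-positive site index yields zero growth (clamped, never negative).
    """
    if si <= 0:
        return 0.0
    return (
        si
        * f2_density(species, di, params)
        * f3_stage(species, dg, params)
    )


def mixture_effect_u(
    target: Species | str,
    companion: Species | str,
    x: float,
    si_target: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Relative mixture effect u on the target species' growth.

    ``x`` is the target's proportion of the total density index.  Pairs with no
    fitted relation are neutral (u = 0).  The effect vanishes as the stand
    tends to a pure stand of the target (x -> 1).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"mixture proportion must be in [0, 1] (got {x})")
    mp = (params or load_default_parameters()).mixture_params(target, companion)
    if mp is None:
        return 0.0
    if mp.s1 is None:
        return mp.s0 * (1.0 - x)
    return (mp.s0 + mp.s1 * si_target) * (1.0 - x)


def mixed_bai_5yr(
    target: Species | str,
    companion: Species | str,
    si_target: float,
    di_total: float,
    dg_target: float,
    x_target: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Five-year under-bark increment of the target species in mixture (m2/ha).

    The density response takes the TOTAL stand density index while the stage
    response takes the target's own Dg; the pure-stand prediction is weighted
    by the target's density proportion ``x_target`` and scaled by (1 + u).
    The result is clamped at zero (a strongly negative u cannot shrink BA).
    """
    base = pure_bai_5yr(target, si_target, di_total, dg_target, params)
    u = mixture_effect_u(target, companion, x_target, si_target, params)
    return max(0.0, base * x_target * (1.0 + u))
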