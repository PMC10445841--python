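"""Stand state, density index and bark conversions.

The simulator's whole state is a set of one or two species cohorts, each
summarised by its stem count N (continuous, stems/ha), its over-bark mean
quadratic diameter Dg (cm) and its site index.  Basal area (m2/ha) is always
derivable as N * pi * Dg^2 / 40000 and is never stored redundantly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .params import SpeciesParameterSet, load_default_parameters
from .species import Species

_BA_PER_STEM = math.pi / 40000.0  # m2 per stem per cm^2 of Dg^2


def ba_from_n_dg(n: float, dg: float) -> float:
    """Basal area (m2/ha) of ``n`` stems/ha with mean quadratic diameter ``dg`` cm."""
    return n * _BA_PER_STEM * dg * dg


def dg_from_ba_n(ba: float, n: float) -> float:
    """Mean quadratic diameter (cm) from basal area (m2/ha) and stem count.

    Exact inverse of :func:`ba_from_n_dg`; both inputs must be positive.
    """
    if ba <= 0 or n <= 0:
        raise ValueError(f"ba and n must be positive (got ba={ba}, n={n})")
    return 200.0 * math.sqrt(ba / (math.pi * n))


def n_max(
    species: Species | str,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Maximum stem count (stems/ha) on the self-thinning boundary at ``dg``."""
    if dg <= 0:
        raise ValueError(f"dg must be positive (got {dg})")
    sp = Species.from_code(species)
    st = (params or load_default_parameters()).self_thinning[sp]
    return math.exp(st.p + st.q * math.log(dg))


@dataclass
class SpeciesCohort:
    """One species' share of the stand."""

    species: Species
    n: float  # stems/ha, continuous
    dg_ob: float  # over-bark mean quadratic diameter, cm
    site_index: float

    def __post_init__(self) -> None:
        self.species = Species.from_code(self.species)
        if self.n < 0:
            raise ValueError("stem count must be >= 0")
        if self.n > 0 and self.dg_ob <= 0:
            raise ValueError("dg_ob must be positive for a non-empty cohort")

    @property
    def ba_ob(self) -> float:
        """Over-bark basal area, m2/ha."""
        return ba_from_n_dg(self.n, self.dg_ob)

    def density_index(self, params: SpeciesParameterSet | None = None) -> float:
        """This cohort's partial density index N / Nmax(Dg)."""
        if self.n == 0:
            return 0.0
        return self.n / n_max(self.species, self.dg_ob, params)


@dataclass
class StandState:
    """Evolving state of a mono- or bi-specific even-aged stand."""

    year: int
    cohorts: list[SpeciesCohort]

    def __post_init__(self) -> None:
        if not 1 <= len(self.cohorts) <= 2:
            raise ValueError("a stand holds one or two species cohorts")
        codes = [c.species for c in self.cohorts]
        if len(set(codes)) != len(codes):
            raise ValueError("species codes must be distinct")

    def copy(self) -> "StandState":
        return StandState(self.year, [replace(c) for c in self.cohorts])

    def cohort(self, species: Species | str) -> SpeciesCohort:
        sp = Species.from_code(species)
        for c in self.cohorts:
            if c.species is sp:
                return c
        raise KeyError(f"species {sp.value!r} not in stand")

    @property
    def total_ba_ob(self) -> float:
        return sum(c.ba_ob for c in self.cohorts)

    @property
    def total_n(self) -> float:
        return sum(c.n for c in self.cohorts)


@dataclass(frozen=True)
class DensityIndexValue:
    """Total density index and its per-species partials (additive)."""

    per_species: dict[Species, float]

    @property
    def total(self) -> float:
        return sum(self.per_species.values())

    def proportion(self, species: Species | str) -> float:
        """Share of the total density index held by ``species``."""
        sp = Species.from_code(species)
        tot = self.total
        if tot == 0:
            return 0.0
        return self.per_species.get(sp, 0.0) / tot


def density_index(
    state: StandState, params: SpeciesParameterSet | None = None
) -> DensityIndexValue:
    """Stand density index: the sum over species of N_i / Nmax_i(Dg_i)."""
    params = params or load_default_parameters()
    return DensityIndexValue(
        per_species={c.species: c.density_index(params) for c in state.cohorts}
    )


def bark_proportion(
    species: Species | str,
    dbh: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Bark share of basal area at ``dbh`` (cm), clamped to the calibration range.

    Diameters below 10 cm use the 10 cm prediction and diameters above the
    species' maximum calibrated dbh use the prediction at that maximum, so the
    function is defined (and continuous) for every positive diameter.
    """
    if dbh <= 0:
        raise ValueError(f"dbh must be positive (got {dbh})")
    sp = Species.from_code(species)
    bp = (params or load_default_parameters()).bark[sp]
    clamped = min(max(dbh, bp.min_dbh), bp.max_dbh)
    return bp.proportion(clamped)


def over_to_under_bark(
    ba_ob: float,
    species: Species | str,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Convert over-bark basal area to under-bark at the stand's Dg."""
    return ba_ob * (1.0 - bark_proportion(species, dg, params))


def under_to_over_bark(
    ba_ub: float,
    species: Species | str,
    dg: float,
    params: SpeciesParameterSet | None = None,
) -> float:
    """Exact inverse of :func:`over_to_under_bark` at the same Dg."""
    return ba_ub / (1.0 - bark_proportion(species, dg, params))
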