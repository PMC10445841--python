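"""Self-thinning mortality and rule-based thinning.

Both processes remove trees from below: removals have a mean quadratic
diameter smaller than the stand's, quantified by the ratio
Kg = Dg_removed^2 / Dg^2 < 1, so the surviving stand's Dg increases.
Mortality fires when the stand density index reaches the self-thinning
boundary (DI >= 1) and removes just enough stems to bring DI back to 1;
thinning follows a management prescription expressed as a density-index
trajectory with trigger bounds.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .params import SpeciesParameterSet, load_default_parameters
from .species import Species
from .stand import SpeciesCohort, StandState, density_index

#: Kg ratio applied by competition mortality (from French NFI mortality data)
KG_MORTALITY = 0.68

#: convergence tolerance on the density index for both dichotomy solvers
DI_TOLERANCE = 1e-6


@dataclass(frozen=True)
class SpeciesRemoval:
    """Per-species share of a removal event."""

    n_removed: float  # stems/ha
    ba_removed_ob: float  # over-bark basal area removed, m2/ha
    dg_removed: float  # mean quadratic diameter of the removed trees, cm


@dataclass(frozen=True)
class RemovalEvent:
    """Stems and basal area leaving the stand in one year, with its cause."""

    year: int
    cause: str  # "mortality" | "thinning"
    removals: dict[Species, SpeciesRemoval]

    @property
    def total_ba_ob(self) -> float:
        return sum(r.ba_removed_ob for r in self.removals.values())

    @property
    def total_n(self) -> float:
        return sum(r.n_removed for r in self.removals.values())


@dataclass(frozen=True)
class ThinningRule:
    """Management prescription: a density-index corridor plus removal style.

    The prescribed density rises linearly from ``di_initial`` at the start of
    the simulation to ``di_final`` at its end.  A thinning fires when the
    stand DI exceeds prescribed + ``bounds`` (and the minimum interval has
    elapsed) and brings it down to prescribed - ``bounds``.  ``kg_thin`` sets
    the size of removed trees relative to the stand; ``target_proportion_sp1``
    steers the species balance of a two-species stand; ``target_dg`` (cm), if
    set, ends the simulation once a species' Dg reaches it.
    """

    di_initial: float
    di_final: float
    bounds: float = 0.05
    min_interval_years: int = 5
    kg_thin: float = 0.95
    target_proportion_sp1: float = 1.0
    target_dg: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("di_initial", self.di_initial), ("di_final", self.di_final)):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1] (got {v})")
        if self.bounds <= 0:
            raise ValueError("bounds must be positive")
        if not 0.0 < self.kg_thin <= 1.0:
            raise ValueError("kg_thin must lie in (0, 1]")
        if not 0.0 <= self.target_proportion_sp1 <= 1.0:
            raise ValueError("target_proportion_sp1 must lie in [0, 1]")


def removal_update(
    n: float, dg: float, n_removed: float, kg: float
) -> tuple[float, float]:
    """Stem count and Dg after removing ``n_removed`` stems of relative size ``kg``.

    The removed trees carry a squared mean diameter of kg*dg^2, so the
    survivors' Dg follows from conservation of the summed squared diameters:
    dg_after = sqrt((n*dg^2 - n_removed*kg*dg^2) / (n - n_removed)).
    For kg < 1 (removal from below) Dg never decreases.
    """
    if n_removed == 0:
        return n, dg
    if not 0 <= n_removed < n:
        raise ValueError(
            f"n_removed must lie in [0, n) (got n_removed={n_removed}, n={n})"
        )
    n_after = n - n_removed
    dg_after = math.sqrt(dg * dg * (n - kg * n_removed) / n_after)
    return n_after, dg_after


def removed_ba_ob(dg: float, n_removed: float, kg: float) -> float:
    """Over-bark basal area (m2/ha) of the removed trees."""
    return n_removed * math.pi * (kg * dg * dg) / 40000.0


def _bisect_removal(g, n_available: float, target: float) -> float:
    """First root of g(r) = target for a function decreasing from g(0) > target.

    Brackets the root by geometric expansion from r = 0 and solves by
    dichotomy.  Removal fractions close to 1 are never explored (for steep
    self-thinning slopes the DI response turns back upward there), so the
    returned removal is the smallest one achieving the target.
    """
    f0 = g(0.0)
    if f0 <= target + DI_TOLERANCE:
        return 0.0
    lo = 0.0
    hi = 0.02 * n_available
    cap = 0.999 * n_available
    while g(hi) > target:
        lo = hi
        hi *= 1.6
        if hi >= cap:
            if g(cap) > target:
                raise RuntimeError(
                    "removal solver failed to bracket the density target"
                )
            hi = cap
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * n_available:
            break
    return hi


def apply_self_thinning_mortality(
    state: StandState, params: SpeciesParameterSet | None = None
) -> tuple[StandState, RemovalEvent | None]:
    """Reduce the stand to the self-thinning boundary (total DI = 1) if exceeded.

    The stems to kill are shared among species according to their stem-number
    proportion before mortality, and every species' Dg is updated with the
    mortality Kg of 0.68.  The post-mortality total DI equals 1 within the
    solver tolerance.  Returns the (possibly unchanged) state and the event.
    """
    params = params or load_default_parameters()
    di = density_index(state, params)
    if di.total < 1.0:
        return state, None
    shares = {c.species: c.n / state.total_n for c in state.cohorts}

    def post_di(r_total: float) -> float:
        total = 0.0
        for c in state.cohorts:
            n_a, dg_a = removal_update(
                c.n, c.dg_ob, r_total * shares[c.species], KG_MORTALITY
            )
            total += SpeciesCohort(c.species, n_a, dg_a, c.site_index).density_index(
                params
            )
        return total

    r_total = _bisect_removal(post_di, state.total_n, 1.0)
    if r_total == 0.0:  # DI within tolerance of the boundary already
        return state, None
    new_cohorts, removals = [], {}
    for c in state.cohorts:
        r = r_total * shares[c.species]
        n_a, dg_a = removal_update(c.n, c.dg_ob, r, KG_MORTALITY)
        new_cohorts.append(SpeciesCohort(c.species, n_a, dg_a, c.site_index))
        removals[c.species] = SpeciesRemoval(
            n_removed=r,
            ba_removed_ob=removed_ba_ob(c.dg_ob, r, KG_MORTALITY),
            dg_removed=math.sqrt(KG_MORTALITY) * c.dg_ob,
        )
    new_state = StandState(state.year, new_cohorts)
    return new_state, RemovalEvent(state.year, "mortality", removals)


def prescribed_di(
    year: int, rule: ThinningRule, start_year: int, end_year: int
) -> float:
    """Prescribed density index at ``year``: linear from di_initial to di_final."""
    if not start_year <= year <= end_year:
        raise ValueError(f"year {year} outside [{start_year}, {end_year}]")
    if end_year == start_year:
        return rule.di_initial
    frac = (year - start_year) / (end_year - start_year)
    return rule.di_initial + frac * (rule.di_final - rule.di_initial)


def _solve_cohort_removal(
    c: SpeciesCohort, di_target: float, kg: float, params: SpeciesParameterSet
) -> float:
    """Stems to remove from one cohort so its partial DI reaches ``di_target``."""

    def g(r: float) -> float:
        n_a, dg_a = removal_update(c.n, c.dg_ob, r, kg)
        return SpeciesCohort(c.species, n_a, dg_a, c.site_index).density_index(params)

    return _bisect_removal(g, c.n, di_target)


def maybe_thin(
    state: StandState,
    rule: ThinningRule,
    last_thin_year: int | None,
    start_year: int,
    end_year: int,
    params: SpeciesParameterSet | None = None,
) -> tuple[StandState, RemovalEvent | None]:
    """Apply the thinning prescription if its trigger conditions are met.

    Fires when total DI > prescribed + bounds and at least
    ``min_interval_years`` have elapsed since the previous thinning; the
    removal brings total DI to prescribed - bounds.  In a two-species stand
    the per-species removals steer the post-thinning DI share of the first
    species towards ``target_proportion_sp1``, subject to removals being
    non-negative; when the target share is unreachable all removal falls on
    the over-represented species.
    """
    params = params or load_default_parameters()
    target_now = prescribed_di(state.year, rule, start_year, end_year)
    di = density_index(state, params)
    if di.total <= target_now + rule.bounds:
        return state, None
    if last_thin_year is not None and state.year - last_thin_year < rule.min_interval_years:
        return state, None

    di_after_total = target_now - rule.bounds
    if len(state.cohorts) == 1:
        targets = {state.cohorts[0].species: di_after_total}
    else:
        sp1, sp2 = (c.species for c in state.cohorts)
        want = {
            sp1: rule.target_proportion_sp1 * di_after_total,
            sp2: (1.0 - rule.target_proportion_sp1) * di_after_total,
        }
        targets = dict(want)
        for sp in (sp1, sp2):
            other = sp2 if sp is sp1 else sp1
            if di.per_species[sp] < want[sp]:
                # cannot add trees: leave this species untouched and take the
                # whole removal from the other one
                warnings.warn(
                    f"thinning cannot raise the DI share of {sp.value!r}; "
                    "removing only from the other species",
                    stacklevel=2,
                )
                targets[sp] = di.per_species[sp]
                targets[other] = di_after_total - di.per_species[sp]

    new_cohorts, removals = [], {}
    for c in state.cohorts:
        r = _solve_cohort_removal(c, targets[c.species], rule.kg_thin, params)
        n_a, dg_a = removal_update(c.n, c.dg_ob, r, rule.kg_thin)
        new_cohorts.append(SpeciesCohort(c.species, n_a, dg_a, c.site_index))
        removals[c.species] = SpeciesRemoval(
            n_removed=r,
            ba_removed_ob=removed_ba_ob(c.dg_ob, r, rule.kg_thin),
            dg_removed=math.sqrt(rule.kg_thin) * c.dg_ob,
        )
    new_state = StandState(state.year, new_cohorts)
    return new_state, RemovalEvent(state.year, "thinning", removals)
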