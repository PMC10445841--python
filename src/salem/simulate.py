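"""The annual simulation loop, scenario configuration and trajectory record.

Each simulated year applies, in order: bark conversion of the over-bark basal
area, the under-bark basal-area increment (one fifth of the five-year model
prediction), back-conversion to over-bark, competition mortality at the
self-thinning boundary, and the thinning prescription.  Stem counts stay
constant under growth, so the added basal area translates into a larger mean
quadratic diameter.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .downscale import diameter_distribution, stand_downscale, tree_height, tree_volume
from .growth import INCREMENT_PERIOD_YEARS, mixed_bai_5yr, pure_bai_5yr
from .management import (
    KG_MORTALITY,
    RemovalEvent,
    ThinningRule,
    apply_self_thinning_mortality,
    maybe_thin,
)
from .params import SpeciesParameterSet, load_default_parameters
from .species import Species
from .stand import (
    SpeciesCohort,
    StandState,
    ba_from_n_dg,
    bark_proportion,
    density_index,
    dg_from_ba_n,
    n_max,
)


@dataclass(frozen=True)
class CohortConfig:
    """Initial description of one species: site index, Dg, optional explicit BA."""

    species: Species
    site_index: float
    dg: float  # over-bark mean quadratic diameter, cm
    ba: float | None = None  # over-bark basal area, m2/ha (overrides proportions)


@dataclass(frozen=True)
class SimulationConfig:
    """A complete scenario: initial stand, management rule and horizon.

    The initial split between the two species can be given as explicit
    per-species basal areas, or as a stand total plus the share of the first
    species; ``proportion_in`` selects whether total and share are read in
    basal-area ("ba") or density-index ("di") terms.
    """

    start_year: int
    end_year: int
    cohorts: tuple[CohortConfig, ...]
    total: float | None = None  # stand total BA (m2/ha) or DI
    proportion_sp1: float = 1.0
    proportion_in: str = "ba"
    thinning: ThinningRule | None = None
    class_width: float = 1.0
    increment_period_years: int = INCREMENT_PERIOD_YEARS
    compute_volume: bool = True

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if not 1 <= len(self.cohorts) <= 2:
            raise ValueError("one or two species must be configured")
        if not 0.0 <= self.proportion_sp1 <= 1.0:
            raise ValueError("proportion_sp1 must lie in [0, 1]")
        if self.proportion_in not in ("ba", "di"):
            raise ValueError("proportion_in must be 'ba' or 'di'")


@dataclass(frozen=True)
class AnnualRecord:
    """Stand summary at the end of one simulated year."""

    year: int
    species: dict[Species, dict[str, float]]  # n, dg_ob, ba_ob, di
    di_total: float
    volume_standing: float | None  # m3/ha
    events: tuple[RemovalEvent, ...] = ()


@dataclass
class Trajectory:
    """Per-year records plus the harvest ledger of a full simulation."""

    config: SimulationConfig
    records: list[AnnualRecord] = field(default_factory=list)
    harvest: list[dict] = field(default_factory=list)  # one row per event+species

    @property
    def final_state_record(self) -> AnnualRecord:
        return self.records[-1]

    def dg_of(self, species: Species | str, year: int) -> float:
        sp = Species.from_code(species)
        for rec in self.records:
            if rec.year == year:
                return rec.species[sp]["dg_ob"]
        raise KeyError(f"year {year} not in trajectory")

    def cumulative_harvested_ba(self, upto_year: int | None = None) -> float:
        return sum(
            r["ba_removed_ob"]
            for r in self.harvest
            if upto_year is None or r["year"] <= upto_year
        )

    def cumulative_harvested_volume(self, upto_year: int | None = None) -> float:
        return sum(
            r["volume_removed"]
            for r in self.harvest
            if upto_year is None or r["year"] <= upto_year
        )

    def total_volume_production(self, year: int | None = None) -> float:
        """Standing volume plus everything harvested or killed so far (m3/ha)."""
        rec = self.records[-1] if year is None else next(
            r for r in self.records if r.year == year
        )
        if rec.volume_standing is None:
            raise ValueError("volume tracking was disabled for this run")
        return rec.volume_standing + self.cumulative_harvested_volume(rec.year)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format per-year, per-species table (plus 'total' rows)."""
        rows = []
        for rec in self.records:
            for sp, vals in rec.species.items():
                rows.append({"year": rec.year, "species": sp.value, **vals})
            rows.append(
                {
                    "year": rec.year,
                    "species": "total",
                    "n": sum(v["n"] for v in rec.species.values()),
                    "dg_ob": float("nan"),
                    "ba_ob": sum(v["ba_ob"] for v in rec.species.values()),
                    "di": rec.di_total,
                    "volume_standing": rec.volume_standing,
                }
            )
        return pd.DataFrame(rows)

    def harvest_dataframe(self) -> pd.DataFrame:
        cols = ["year", "cause", "species", "n_removed", "ba_removed_ob",
                "volume_removed"]
        return pd.DataFrame(self.harvest, columns=cols)


def initialise_stand(
    config: SimulationConfig, params: SpeciesParameterSet | None = None
) -> StandState:
    """Build the initial stand state from the configured split.

    Cohorts configured with a zero share are dropped, so a two-species
    configuration with proportion 1.0 degenerates cleanly to a pure stand.
    """
    params = params or load_default_parameters()
    if len(config.cohorts) == 1:
        shares = [1.0]
    else:
        shares = [config.proportion_sp1, 1.0 - config.proportion_sp1]
    cohorts: list[SpeciesCohort] = []
    explicit = [cc.ba is not None for cc in config.cohorts]
    if any(explicit):
        if not all(explicit):
            raise ValueError("give an explicit basal area for every species or none")
        for cc in config.cohorts:
            cohorts.append(_cohort_from_ba(cc, cc.ba))
    else:
        if config.total is None:
            raise ValueError(
                "initial stand under-specified: give per-species basal areas "
                "or a stand total with proportion_sp1"
            )
        for cc, share in zip(config.cohorts, shares):
            if share == 0.0:
                continue
            if config.proportion_in == "ba":
                cohorts.append(_cohort_from_ba(cc, config.total * share))
            else:  # density-index split: DI_i -> N_i via the species boundary
                di_i = config.total * share
                n_i = di_i * n_max(cc.species, cc.dg, params)
                cohorts.append(
                    SpeciesCohort(cc.species, n_i, cc.dg, cc.site_index)
                )
    if not cohorts:
        raise ValueError("no species left with a positive share")
    return StandState(config.start_year, cohorts)


def _cohort_from_ba(cc: CohortConfig, ba: float) -> SpeciesCohort:
    n = ba / (math.pi * cc.dg**2 / 40000.0)
    return SpeciesCohort(cc.species, n, cc.dg, cc.site_index)


def step(
    state: StandState,
    config: SimulationConfig,
    last_thin_year: int | None,
    params: SpeciesParameterSet | None = None,
) -> tuple[StandState, list[RemovalEvent]]:
    """Advance the stand by one year; returns the new state and removal events."""
    params = params or load_default_parameters()
    di = density_index(state, params)
    grown: list[SpeciesCohort] = []
    for c in state.cohorts:
        if c.n == 0:
            grown.append(c)
            continue
        bp = bark_proportion(c.species, c.dg_ob, params)
        ba_ub = c.ba_ob * (1.0 - bp)
        others = [o for o in state.cohorts if o.species is not c.species and o.n > 0]
        if others:
            bai5 = mixed_bai_5yr(
                c.species, others[0].species, c.site_index,
                di.total, c.dg_ob, di.proportion(c.species), params,
            )
        else:
            bai5 = pure_bai_5yr(c.species, c.site_index, di.total, c.dg_ob, params)
        ba_ub += bai5 / config.increment_period_years
        # back-conversion reuses the pre-growth bark proportion: the Dg change
        # within one annual step is second-order for the bark share
        ba_ob = ba_ub / (1.0 - bp)
        grown.append(
            SpeciesCohort(c.species, c.n, dg_from_ba_n(ba_ob, c.n), c.site_index)
        )
    new_state = StandState(state.year + 1, grown)

    events: list[RemovalEvent] = []
    new_state, mort = apply_self_thinning_mortality(new_state, params)
    if mort is not None:
        events.append(mort)
    if config.thinning is not None:
        new_state, thin = maybe_thin(
            new_state, config.thinning, last_thin_year,
            config.start_year, config.end_year, params,
        )
        if thin is not None:
            events.append(thin)
    return new_state, events


def _removed_volume(
    event: RemovalEvent,
    kg: float,
    site_indices: dict[Species, float],
    class_width: float,
    params: SpeciesParameterSet,
) -> dict[Species, float]:
    """Volume (m3/ha) of the removed trees, by downscaling each removed batch.

    The removed batch of a species is treated as a pseudo-stand with the
    removal's own mean quadratic diameter; heights use the pre-removal stand
    Dg (recovered exactly from Dg_removed / sqrt(Kg)) as the stage proxy.
    """
    out: dict[Species, float] = {}
    for sp, rem in event.removals.items():
        if rem.n_removed <= 0 or rem.dg_removed <= 0:
            out[sp] = 0.0
            continue
        dg_stage = rem.dg_removed / math.sqrt(kg)
        vol_dm3 = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-commercial classes -> 0 volume
            for dc in diameter_distribution(
                sp, rem.dg_removed, rem.n_removed, class_width, params
            ):
                h = tree_height(
                    sp, math.pi * dc.dbh_c, dg_stage, site_indices[sp], params
                )
                v = max(tree_volume(sp, dc.dbh_c, h, params), 0.0)
                vol_dm3 += dc.n_c * v
        out[sp] = vol_dm3 / 1000.0
    return out


def _record(
    state: StandState,
    config: SimulationConfig,
    events: tuple[RemovalEvent, ...],
    params: SpeciesParameterSet,
) -> AnnualRecord:
    di = density_index(state, params)
    vol = None
    if config.compute_volume:
        _, vol = stand_downscale(state, config.class_width, params)
    return AnnualRecord(
        year=state.year,
        species={
            c.species: {
                "n": c.n, "dg_ob": c.dg_ob, "ba_ob": c.ba_ob,
                "di": di.per_species[c.species],
            }
            for c in state.cohorts
        },
        di_total=di.total,
        volume_standing=vol,
        events=events,
    )


def run(
    config: SimulationConfig, params: SpeciesParameterSet | None = None
) -> Trajectory:
    """Run a full scenario and return its trajectory.

    Purely deterministic: identical configurations give identical outputs.
    The run ends at ``end_year`` or as soon as a species' Dg reaches the
    thinning rule's ``target_dg``, whichever comes first.
    """
    params = params or load_default_parameters()
    state = initialise_stand(config, params)
    traj = Trajectory(config=config)
    traj.records.append(_record(state, config, (), params))
    last_thin_year: int | None = None
    site_indices = {cc.species: cc.site_index for cc in config.cohorts}

    while state.year < config.end_year:
        state, events = step(state, config, last_thin_year, params)
        for ev in events:
            kg = KG_MORTALITY if ev.cause == "mortality" else config.thinning.kg_thin
            vols = _removed_volume(ev, kg, site_indices, config.class_width, params)
            if ev.cause == "thinning":
                last_thin_year = ev.year
            for sp, rem in ev.removals.items():
                traj.harvest.append(
                    {
                        "year": ev.year, "cause": ev.cause, "species": sp.value,
                        "n_removed": rem.n_removed,
                        "ba_removed_ob": rem.ba_removed_ob,
                        "volume_removed": vols[sp],
                    }
                )
        traj.records.append(_record(state, config, tuple(events), params))
        rule = config.thinning
        if rule is not None and rule.target_dg is not None:
            if max(c.dg_ob for c in state.cohorts) >= rule.target_dg:
                break
    return traj


# ---------------------------------------------------------------------------
# scenario files


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed scenario document."""
    try:
        species_docs = doc["species"]
        start, end = int(doc["start_year"]), int(doc["end_year"])
    except KeyError as exc:
        raise ValueError(f"scenario file missing required key: {exc}") from exc
    cohorts = tuple(
        CohortConfig(
            species=Species.from_code(sd["code"]),
            site_index=float(sd["site_index"]),
            dg=float(sd["dg"]),
            ba=float(sd["ba"]) if "ba" in sd else None,
        )
        for sd in species_docs
    )
    init = doc.get("initial_density", {})
    thin_doc = doc.get("thinning")
    thinning = (
        ThinningRule(
            di_initial=float(thin_doc["di_initial"]),
            di_final=float(thin_doc["di_final"]),
            bounds=float(thin_doc.get("bounds", 0.05)),
            min_interval_years=int(thin_doc.get("min_interval_years", 5)),
            kg_thin=float(thin_doc.get("kg_thin", 0.95)),
            target_proportion_sp1=float(thin_doc.get("target_proportion_sp1", 1.0)),
            target_dg=(
                float(thin_doc["target_dg"]) if "target_dg" in thin_doc else None
            ),
        )
        if thin_doc is not None
        else None
    )
    return SimulationConfig(
        start_year=start,
        end_year=end,
        cohorts=cohorts,
        total=float(init["total"]) if "total" in init else None,
        proportion_sp1=float(init.get("proportion_sp1", 1.0)),
        proportion_in=str(init.get("proportion_in", "ba")),
        thinning=thinning,
        class_width=float(doc.get("class_width", 1.0)),
        increment_period_years=int(
            doc.get("increment_period_years", INCREMENT_PERIOD_YEARS)
        ),
    )


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    return config_from_dict(doc)


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialisable scenario document (inverse of :func:`config_from_dict`)."""
    doc: dict = {
        "start_year": config.start_year,
        "end_year": config.end_year,
        "class_width": config.class_width,
        "increment_period_years": config.increment_period_years,
        "species": [
            {
                "code": cc.species.value,
                "site_index": cc.site_index,
                "dg": cc.dg,
                **({"ba": cc.ba} if cc.ba is not None else {}),
            }
            for cc in config.cohorts
        ],
    }
    if config.total is not None:
        doc["initial_density"] = {
            "total": config.total,
            "proportion_sp1": config.proportion_sp1,
            "proportion_in": config.proportion_in,
        }
    if config.thinning is not None:
        t = config.thinning
        doc["thinning"] = {
            "di_initial": t.di_initial,
            "di_final": t.di_final,
            "bounds": t.bounds,
            "min_interval_years": t.min_interval_years,
            "kg_thin": t.kg_thin,
            "target_proportion_sp1": t.target_proportion_sp1,
            **({"target_dg": t.target_dg} if t.target_dg is not None else {}),
        }
    return doc
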