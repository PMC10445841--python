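"""Ready-made scenarios and randomised stand states.

The spruce-beech demonstration scenario (and its matched pure-stand variants)
exercises the full simulation chain with no external data; the random stand
generator supplies reproducible states for property testing.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .management import ThinningRule
from .simulate import CohortConfig, SimulationConfig, config_to_dict
from .species import ALL_SPECIES, Species
from .stand import SpeciesCohort, StandState, n_max

#: per-species Dg calibration envelope (cm) used by the random stand generator,
#: spanning the pure-stand inventory range the models were fitted on
DG_ENVELOPE: dict[Species, tuple[float, float]] = {
    Species.QUERCUS_ROBUR: (2.6, 106.5),
    Species.QUERCUS_PETRAEA: (1.2, 87.7),
    Species.QUERCUS_PUBESCENS: (2.4, 64.5),
    Species.FAGUS_SYLVATICA: (2.2, 117.0),
    Species.PINUS_PINASTER: (5.1, 66.8),
    Species.PINUS_SYLVESTRIS: (0.8, 59.0),
    Species.PINUS_LARICIO: (0.5, 78.8),
    Species.PINUS_NIGRA: (2.5, 48.3),
    Species.PINUS_HALEPENSIS: (2.8, 56.2),
    Species.ABIES_ALBA: (3.5, 87.0),
    Species.PICEA_ABIES: (1.5, 67.0),
    Species.PSEUDOTSUGA_MENZIESII: (1.3, 61.2),
}


@dataclass(frozen=True)
class ScenarioFixture:
    name: str
    config: SimulationConfig
    note: str


_SPRUCE = CohortConfig(Species.PICEA_ABIES, site_index=65.4, dg=17.5)
_BEECH = CohortConfig(Species.FAGUS_SYLVATICA, site_index=26.8, dg=12.2)

_THINNING = ThinningRule(
    di_initial=0.6,
    di_final=0.8,
    bounds=0.05,
    min_interval_years=5,
    kg_thin=0.95,
    target_proportion_sp1=0.6,
)


def use_case_spruce_beech() -> ScenarioFixture:
    """The 2000-2090 mixed spruce-beech demonstration scenario.

    Spruce SI 65.4 / beech SI 26.8, total over-bark basal area 32 m2/ha split
    60/40 (spruce first), Dg 17.5 / 12.2 cm, thinning corridor rising from
    0.6 to 0.8 with bounds 0.05, at least 5 years between thinnings,
    Kg 0.95, target spruce proportion 0.6.
    """
    config = SimulationConfig(
        start_year=2000,
        end_year=2090,
        cohorts=(_SPRUCE, _BEECH),
        total=32.0,
        proportion_sp1=0.6,
        proportion_in="ba",
        thinning=_THINNING,
    )
    return ScenarioFixture(
        name="spruce_beech_mixed",
        config=config,
        note="two-species demonstration stand, 2000-2090",
    )


def use_case_pure_spruce() -> ScenarioFixture:
    """Matched pure-spruce variant: same SI, Dg, total BA and thinning rule."""
    config = SimulationConfig(
        start_year=2000,
        end_year=2090,
        cohorts=(_SPRUCE,),
        total=32.0,
        thinning=replace(_THINNING, target_proportion_sp1=1.0),
    )
    return ScenarioFixture(
        name="spruce_pure",
        config=config,
        note="pure-stand comparison run for the mixed scenario",
    )


def use_case_pure_beech() -> ScenarioFixture:
    """Matched pure-beech variant: same SI, Dg, total BA and thinning rule."""
    config = SimulationConfig(
        start_year=2000,
        end_year=2090,
        cohorts=(_BEECH,),
        total=32.0,
        thinning=replace(_THINNING, target_proportion_sp1=1.0),
    )
    return ScenarioFixture(
        name="beech_pure",
        config=config,
        note="pure-stand comparison run for the mixed scenario",
    )


def all_use_cases() -> tuple[ScenarioFixture, ...]:
    return (use_case_spruce_beech(), use_case_pure_spruce(), use_case_pure_beech())


def write_fixtures(directory: str | Path) -> list[Path]:
    """Write every use-case scenario as a YAML file; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for fx in all_use_cases():
        path = directory / f"{fx.name}.yml"
        with open(path, "w") as fh:
            yaml.safe_dump(config_to_dict(fx.config), fh, sort_keys=False)
        paths.append(path)
    return paths


def random_stand(
    seed: int,
    species: tuple[Species | str, ...] | None = None,
    di_range: tuple[float, float] = (0.2, 1.0),
    dg_range: tuple[float, float] | None = None,
    si_range: tuple[float, float] = (5.0, 40.0),
    year: int = 2000,
) -> StandState:
    """Reproducible random stand inside the species' calibration envelopes.

    The stand's total density index is drawn uniformly from ``di_range`` and
    split randomly between the species; stem counts follow from each species'
    self-thinning boundary at its drawn Dg.
    """
    rng = np.random.default_rng(seed)
    if species is None:
        k = int(rng.integers(1, 3))
        idx = rng.choice(len(ALL_SPECIES), size=k, replace=False)
        chosen = [ALL_SPECIES[i] for i in idx]
    else:
        chosen = [Species.from_code(s) for s in species]
    di_total = rng.uniform(*di_range)
    splits = rng.dirichlet(np.ones(len(chosen)))
    cohorts = []
    for sp, di_share in zip(chosen, splits):
        lo, hi = dg_range if dg_range is not None else DG_ENVELOPE[sp]
        lo = max(lo, 5.0)  # keep clear of the near-zero boundary blow-up
        dg = float(rng.uniform(lo, min(hi, 80.0)))
        si = float(rng.uniform(*si_range))
        n = di_total * di_share * n_max(sp, dg)
        cohorts.append(SpeciesCohort(sp, n, dg, si))
    return StandState(year, cohorts)
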