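"""Typed registry of the published model parameters.

All numeric estimates live in the CSV files under :mod:`salem.data`, one file
per model family, so they can be diffed against their published source;
no fitted value is embedded in code.  :func:`load_default_parameters` reads
them once and returns an immutable :class:`SpeciesParameterSet`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .species import ALL_SPECIES, Species

#: controlled vocabulary of environmental variables of the site-index predictor
SITE_VARIABLES: frozenset[str] = frozenset(
    {
        "elevation_m",
        "aspect_north",
        "mask_gr",
        "feb_min_temp_c",
        "may_min_temp_c",
        "dec_min_temp_c",
        "feb_mean_temp_c",
        "jul_max_temp_c",
        "jun_pet_mm",
        "may_water_budget_mm",
        "may_water_deficit_mm",
        "jun_water_deficit_mm",
        "jul_water_deficit_mm",
        "may_available_water_mm",
        "swhc_mm",
        "swhc_first_horizon_mm",
        "ph",
        "cn_ratio",
        "limestone_bedrock",
        "hydromorphic_soils",
        "weakly_hydromorphic_soils",
        "carbonate_rock",
        "brown_soil",
        "rock_outcrop",
        "rock_content_40cm",
        "slope_pct",
        "greco_a",
        "greco_b",
        "greco_c",
        "greco_d",
        "greco_h",
        "greco_i",
        "greco_j",
    }
)

#: coefficient names that apply to a power of another variable
DERIVED_TERMS: Mapping[str, tuple[str, int]] = {
    "ph_sq": ("ph", 2),
    "cn_ratio_sq": ("cn_ratio", 2),
}

#: species whose bark model is borrowed from another fitted group
BARK_MODEL_OF: Mapping[Species, str] = {
    Species.QUERCUS_ROBUR: "Quercus spp.",
    Species.QUERCUS_PETRAEA: "Quercus spp.",
    Species.QUERCUS_PUBESCENS: "Quercus spp.",
    Species.PINUS_HALEPENSIS: "Pi. sy.",
}

#: species whose volume model is borrowed from an undistinguished group
VOLUME_MODEL_OF: Mapping[Species, str] = {
    Species.QUERCUS_PUBESCENS: "Qu. sp.",
}

#: minimum dbh (cm) at which bark models are evaluated (clamped below)
BARK_MIN_DBH = 10.0


@dataclass(frozen=True)
class GrowthParams:
    """Pure-stand increment model: SI intercept, site terms and shape terms."""

    equation_form: str  # "eq3" (power density response) or "eq4" (hyperbolic)
    a0: float
    a_m: Mapping[str, float]
    b: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.equation_form not in ("eq3", "eq4"):
            raise ValueError(f"unknown equation form {self.equation_form!r}")
        if not self.c1 < 0:
            raise ValueError("c1 must be negative (growth declines with Dg)")


@dataclass(frozen=True)
class SelfThinningParams:
    """log(Nmax) = p + q*log(Dg); q < 0."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not self.q < 0:
            raise ValueError("self-thinning slope q must be negative")


@dataclass(frozen=True)
class MixtureParams:
    """Directional effect of `companion` on the growth of `target`.

    ``s1 is None`` means the average-effect form u = s0*(1-x);
    otherwise u = (s0 + s1*SI)*(1-x).
    """

    target: Species
    companion: Species
    s0: float
    s1: float | None = None


@dataclass(frozen=True)
class BarkParams:
    """Bark proportion of basal area as a function of dbh, with clamping range."""

    form: str  # a_b_cinv | a_b | a_b_c2
    a: float
    b: float
    c: float | None
    max_dbh: float
    min_dbh: float = BARK_MIN_DBH

    def proportion(self, dbh: float) -> float:
        """Evaluate the raw (unclamped) bark proportion at ``dbh``."""
        if self.form == "a_b_cinv":
            return self.a + self.b * dbh + self.c / dbh
        if self.form == "a_b":
            return self.a + self.b * dbh
        if self.form == "a_b_c2":
            return self.a + self.b * dbh + self.c * dbh * dbh
        raise ValueError(f"unknown bark model form {self.form!r}")


@dataclass(frozen=True)
class DiameterDistParams:
    """sigma(Dg) = alpha*(1-exp(-gamma*Dg))^beta (Chapman-Richards)."""

    alpha: float
    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.gamma, self.beta) <= 0:
            raise ValueError("Chapman-Richards coefficients must be positive")


@dataclass(frozen=True)
class HeightParams:
    """h = 1.3 + (alpha + g1(Dg) + g2(SI)) * (1 - exp(-beta*c130^gamma))."""

    g1_form: str  # satexp | linear | quadratic | none
    g2_form: str  # linear | quadratic | log | satexp | none
    alpha: float
    a1: float | None
    a1_1: float | None
    a1_2: float | None
    a2: float | None
    a2_1: float | None
    a2_2: float | None
    beta: float
    gamma: float

    @property
    def uses_site_index(self) -> bool:
        return self.g2_form != "none"

    def g1(self, dg: float) -> float:
        if self.g1_form == "satexp":
            return self.a1_1 * (1.0 - math.exp(-self.a1_2 * dg))
        if self.g1_form == "linear":
            return self.a1 * dg
        if self.g1_form == "quadratic":
            return self.a1_1 * dg + self.a1_2 * dg * dg
        if self.g1_form == "none":
            return 0.0
        raise ValueError(f"unknown g1 form {self.g1_form!r}")

    def g2(self, si: float | None) -> float:
        if self.g2_form == "none":
            return 0.0
        if si is None:
            raise ValueError("this height model requires a site index")
        if self.g2_form == "linear":
            return self.a2 * si
        if self.g2_form == "quadratic":
            return self.a2_1 * si + self.a2_2 * si * si
        if self.g2_form == "log":
            return self.a2 * math.log(si)
        if self.g2_form == "satexp":
            return self.a2_1 * (1.0 - math.exp(-self.a2_2 * si))
        raise ValueError(f"unknown g2 form {self.g2_form!r}")


@dataclass(frozen=True)
class VolumeParams:
    """v = beta1*h/dbh + (beta2 + beta3*dbh)*pi*dbh^2*h/40 (dm3)."""

    beta1: float  # 0 where dropped
    beta2: float
    beta3: float  # 0 where dropped

    def __post_init__(self) -> None:
        if not 0.0 < self.beta2 < 1.0:
            raise ValueError("form factor beta2 must lie in (0, 1)")
        if self.beta1 > 0:
            raise ValueError("beta1 (non-commercial part) must be <= 0")


@dataclass(frozen=True)
class SpeciesParameterSet:
    """Immutable registry of every parameterised model for the 12 species."""

    growth: Mapping[Species, GrowthParams]
    self_thinning: Mapping[Species, SelfThinningParams]
    mixture: Mapping[tuple[Species, Species], MixtureParams]
    bark: Mapping[Species, BarkParams]
    diameter_dist: Mapping[Species, DiameterDistParams]
    height: Mapping[Species, HeightParams]
    volume: Mapping[Species, VolumeParams]

    def __post_init__(self) -> None:
        for name in ("growth", "self_thinning", "bark", "diameter_dist",
                     "height", "volume"):
            table: Mapping[Species, object] = getattr(self, name)
            missing = [sp.value for sp in ALL_SPECIES if sp not in table]
            if missing:
                raise ValueError(f"{name} parameters missing for: {missing}")

    def mixture_params(
        self, target: Species | str, companion: Species | str
    ) -> MixtureParams | None:
        """Directional mixture coefficients, or ``None`` for a neutral pair."""
        key = (Species.from_code(target), Species.from_code(companion))
        return self.mixture.get(key)


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("salem.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#", skip_blank_lines=True)


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _load_growth() -> dict[Species, GrowthParams]:
    core = _read_csv("growth_core.csv").set_index("species")
    terms = _read_csv("growth_site_terms.csv")
    known = SITE_VARIABLES | set(DERIVED_TERMS)
    bad = set(terms["variable"]) - known
    if bad:
        raise ValueError(f"growth_site_terms.csv: unknown variables {sorted(bad)}")
    out: dict[Species, GrowthParams] = {}
    for sp in ALL_SPECIES:
        if sp.value not in core.index:
            raise ValueError(f"growth parameters missing for {sp.value!r}")
        row = core.loc[sp.value]
        a_m = {
            r.variable: float(r.coefficient)
            for r in terms[terms["species"] == sp.value].itertuples()
        }
        out[sp] = GrowthParams(
            equation_form=str(row["equation_form"]),
            a0=float(row["a0"]),
            a_m=a_m,
            b=float(row["b"]),
            c1=float(row["c1"]),
            c2=float(row["c2"]),
        )
    return out


def _load_self_thinning() -> dict[Species, SelfThinningParams]:
    df = _read_csv("self_thinning.csv").set_index("species")
    return {
        sp: SelfThinningParams(p=float(df.loc[sp.value, "p"]),
                               q=float(df.loc[sp.value, "q"]))
        for sp in ALL_SPECIES
    }


def _load_mixture() -> dict[tuple[Species, Species], MixtureParams]:
    df = _read_csv("mixture.csv")
    out: dict[tuple[Species, Species], MixtureParams] = {}
    for r in df.itertuples():
        key = (Species.from_code(r.target), Species.from_code(r.companion))
        out[key] = MixtureParams(
            target=key[0], companion=key[1],
            s0=float(r.s0), s1=_opt(r.s1),
        )
    return out


def _load_bark() -> dict[Species, BarkParams]:
    df = _read_csv("bark.csv").set_index("model")
    out: dict[Species, BarkParams] = {}
    for sp in ALL_SPECIES:
        key = BARK_MODEL_OF.get(sp, sp.value)
        if key not in df.index:
            raise ValueError(f"bark model {key!r} (for {sp.value!r}) not found")
        row = df.loc[key]
        out[sp] = BarkParams(
            form=str(row["form"]), a=float(row["a"]), b=float(row["b"]),
            c=_opt(row["c"]), max_dbh=float(row["max_dbh"]),
        )
    return out


def _load_diameter_dist() -> dict[Species, DiameterDistParams]:
    df = _read_csv("diameter_distribution.csv").set_index("species")
    return {
        sp: DiameterDistParams(
            alpha=float(df.loc[sp.value, "alpha"]),
            gamma=float(df.loc[sp.value, "gamma"]),
            beta=float(df.loc[sp.value, "beta"]),
        )
        for sp in ALL_SPECIES
    }


def _load_height() -> dict[Species, HeightParams]:
    df = _read_csv("height.csv").set_index("species")
    out: dict[Species, HeightParams] = {}
    for sp in ALL_SPECIES:
        row = df.loc[sp.value]
        out[sp] = HeightParams(
            g1_form=str(row["g1_form"]), g2_form=str(row["g2_form"]),
            alpha=float(row["alpha"]),
            a1=_opt(row["a1"]), a1_1=_opt(row["a1_1"]), a1_2=_opt(row["a1_2"]),
            a2=_opt(row["a2"]), a2_1=_opt(row["a2_1"]), a2_2=_opt(row["a2_2"]),
            beta=float(row["beta"]), gamma=float(row["gamma"]),
        )
    return out


def _load_volume() -> dict[Species, VolumeParams]:
    df = _read_csv("volume.csv").set_index("model")
    out: dict[Species, VolumeParams] = {}
    for sp in ALL_SPECIES:
        key = VOLUME_MODEL_OF.get(sp, sp.value)
        if key not in df.index:
            raise ValueError(f"volume model {key!r} (for {sp.value!r}) not found")
        row = df.loc[key]
        out[sp] = VolumeParams(
            beta1=_opt(row["beta1"]) or 0.0,
            beta2=float(row["beta2"]),
            beta3=_opt(row["beta3"]) or 0.0,
        )
    return out


_DEFAULT: SpeciesParameterSet | None = None


def load_default_parameters(refresh: bool = False) -> SpeciesParameterSet:
    """Load (and cache) the full registry from the shipped data files."""
    global _DEFAULT
    if _DEFAULT is None or refresh:
        _DEFAULT = SpeciesParameterSet(
            growth=_load_growth(),
            self_thinning=_load_self_thinning(),
            mixture=_load_mixture(),
            bark=_load_bark(),
            diameter_dist=_load_diameter_dist(),
            height=_load_height(),
            volume=_load_volume(),
        )
    return _DEFAULT
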