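"""Registry loading, lookups and transcription fidelity of the parameter files.

The REF_* dictionaries below are a second, independently typed transcription
of the published parameter estimates; the fidelity tests require the shipped
CSV registry to agree with them value for value.
"""
import dataclasses

import pytest

from salem.params import (
    BARK_MODEL_OF,
    VOLUME_MODEL_OF,
    SpeciesParameterSet,
    load_default_parameters,
)
from salem.species import ALL_SPECIES, Species

S = Species

# --- second-pass transcriptions -------------------------------------------

REF_SELF_THINNING = {
    "Qu. ro.": (12.60, -1.86),
    "Qu. pe.": (13.10, -2.01),
    "Qu. pu.": (11.98, -1.66),
    "Fa. sy.": (13.99, -2.18),
    "Pi. pi.": (12.48, -1.80),
    "Pi. sy.": (13.44, -2.03),
    "Pi. la.": (10.66, -1.14),
    "Pi. ni.": (12.90, -1.81),
    "Pi. ha.": (12.83, -1.92),
    "Ab. al.": (13.08, -1.86),
    "Pi. ab.": (12.88, -1.76),
    "Ps. me.": (11.15, -1.30),
}

# equation form, a0, b, c1, c2
REF_GROWTH_CORE = {
    "Qu. ro.": ("eq3", 22.00, 0.588, -0.078, 0.098),
    "Qu. pe.": ("eq3", 55.87, 0.625, -0.111, 0.063),
    "Qu. pu.": ("eq3", 6.95, 0.631, -0.080, 0.345),
    "Fa. sy.": ("eq3", 39.71, 0.585, -0.083, 0.073),
    "Pi. pi.": ("eq3", 117.64, 0.699, -0.106, 0.051),
    "Pi. sy.": ("eq3", 291.25, 0.591, -0.146, 0.048),
    "Pi. la.": ("eq3", 73.41, 0.603, -0.165, 0.092),
    "Pi. ni.": ("eq3", 199.47, 0.693, -0.158, 0.058),
    "Pi. ha.": ("eq3", 19.30, 0.600, -0.118, 0.169),
    "Ab. al.": ("eq4", -7.43, 0.234, -0.077, 0.119),
    "Pi. ab.": ("eq3", 94.06, 0.637, -0.129, 0.104),
    "Ps. me.": ("eq4", 71.36, 0.450, -0.157, 0.180),
}

REF_SITE_TERMS = {
    "Qu. ro.": {"feb_mean_temp_c": 0.790, "may_water_deficit_mm": -0.171,
                "swhc_mm": 0.0282, "cn_ratio": -0.384,
                "limestone_bedrock": -3.358, "slope_pct": -0.079},
    "Qu. pe.": {"dec_min_temp_c": 4.372, "jul_water_deficit_mm": -0.354,
                "swhc_mm": 0.0372, "cn_ratio": -0.592,
                "limestone_bedrock": -11.097, "greco_d": -7.94},
    "Qu. pu.": {"swhc_mm": 0.0305, "cn_ratio": -0.167,
                "weakly_hydromorphic_soils": 2.426, "brown_soil": 0.840,
                "greco_b": 3.54},
    "Fa. sy.": {"elevation_m": -0.0083, "swhc_mm": 0.0531, "cn_ratio": -0.417,
                "carbonate_rock": 2.625, "slope_pct": -0.086, "greco_b": 4.64},
    "Pi. pi.": {"aspect_north": -4.369, "jun_water_deficit_mm": -0.374,
                "cn_ratio": -1.383, "limestone_bedrock": -32.884,
                "weakly_hydromorphic_soils": 6.394, "rock_outcrop": -1.403,
                "slope_pct": -0.197, "greco_j": -9.6825},
    "Pi. sy.": {"jul_max_temp_c": -3.302, "ph": -23.311, "ph_sq": 1.359,
                "cn_ratio": -4.455, "cn_ratio_sq": 0.066,
                "rock_content_40cm": -0.931, "slope_pct": -0.110,
                "greco_c": 15.37, "greco_h": -7.52},
    "Pi. la.": {"may_available_water_mm": 0.275, "cn_ratio": -1.020,
                "hydromorphic_soils": -8.713, "rock_content_40cm": -2.705},
    "Pi. ni.": {"mask_gr": -0.549, "jul_max_temp_c": -3.593,
                "cn_ratio": -1.621, "slope_pct": -0.350},
    "Pi. ha.": {"elevation_m": -0.0108},
    "Ab. al.": {"jun_pet_mm": 0.446, "swhc_first_horizon_mm": 0.5948,
                "cn_ratio": -0.891, "greco_a": 17.83, "greco_h": -11.56},
    "Pi. ab.": {"aspect_north": -3.705, "feb_min_temp_c": 5.566,
                "may_water_budget_mm": 0.179, "swhc_first_horizon_mm": 1.2870,
                "cn_ratio": -0.938, "limestone_bedrock": -8.100,
                "slope_pct": -0.255},
    "Ps. me.": {"mask_gr": -0.277, "may_min_temp_c": -4.301, "ph": 2.941,
                "greco_i": -26.72},
}

# (target, companion) -> (s0, s1 or None)
REF_MIXTURE = {
    ("Qu. ro.", "Pi. pi."): (0.692, None),
    ("Qu. ro.", "Pi. sy."): (0.374, None),
    ("Qu. pe.", "Qu. ro."): (0.215, None),
    ("Qu. pe.", "Fa. sy."): (0.618, -0.022),
    ("Qu. pe.", "Pi. sy."): (0.253, None),
    ("Qu. pu.", "Qu. ro."): (2.133, -0.323),
    ("Fa. sy.", "Qu. ro."): (2.299, -0.058),
    ("Fa. sy.", "Qu. pe."): (0.833, -0.019),
    ("Fa. sy.", "Pi. sy."): (0.714, None),
    ("Fa. sy.", "Ab. al."): (0.544, None),
    ("Fa. sy.", "Pi. ab."): (0.435, None),
    ("Pi. pi.", "Qu. ro."): (0.384, None),
    ("Pi. sy.", "Qu. pu."): (0.902, None),
    ("Pi. sy.", "Fa. sy."): (0.110, -0.012),
    ("Pi. sy.", "Pi. la."): (1.025, None),
    ("Pi. sy.", "Ab. al."): (-0.406, None),
    ("Pi. ni.", "Pi. sy."): (1.419, -0.017),
    ("Ab. al.", "Qu. pe."): (2.080, -0.060),
    ("Ab. al.", "Fa. sy."): (0.996, -0.032),
    ("Ab. al.", "Pi. sy."): (0.991, None),
    ("Ab. al.", "Pi. ab."): (0.910, -0.024),
    ("Ab. al.", "Ps. me."): (2.371, -0.060),
    ("Pi. ab.", "Pi. sy."): (0.417, None),
    ("Pi. ab.", "Ab. al."): (1.792, -0.024),
    ("Pi. ab.", "Ps. me."): (1.176, -0.016),
    ("Ps. me.", "Ab. al."): (0.259, None),
}

# model key -> (form, a, b, c, max_dbh)
REF_BARK = {
    "Quercus spp.": ("a_b_cinv", 0.1426, -0.000496, 1.028, 80),
    "Fa. sy.": ("a_b_cinv", 0.0502, -0.000042, 0.162, 80),
    "Pi. pi.": ("a_b_cinv", 0.4792, -0.003252, -0.765, 80),
    "Pi. sy.": ("a_b", 0.2711, -0.00128, None, 60),
    "Pi. la.": ("a_b_c2", 0.2948, -0.000679, -1.21e-5, 60),
    "Pi. ni.": ("a_b_cinv", 0.3311, -0.001611, -0.263, 60),
    "Ab. al.": ("a_b_cinv", 0.1084, -0.000139, 0.148, 80),
    "Pi. ab.": ("a_b_cinv", 0.0864, 0.000151, 0.522, 80),
    "Ps. me.": ("a_b_cinv", 0.1659, -0.001409, 3.0e-5, 60),
}

# alpha, gamma, beta
REF_DIAMETER_DIST = {
    "Qu. ro.": (11.43876, 0.09017, 3.33197),
    "Qu. pe.": (10.97643, 0.08640, 3.22690),
    "Qu. pu.": (7.72100, 0.18849, 8.74034),
    "Fa. sy.": (12.24093, 0.07743, 2.85483),
    "Pi. pi.": (6.65825, 0.08697, 2.14814),
    "Pi. sy.": (8.56996, 0.08513, 2.10282),
    "Pi. la.": (7.57343, 0.07817, 2.57583),
    "Pi. ni.": (6.35432, 0.16440, 5.72509),
    "Pi. ha.": (8.95631, 0.18881, 9.68719),
    "Ab. al.": (13.25233, 0.05094, 1.76612),
    "Pi. ab.": (30.18095, 0.00754, 0.94366),
    "Ps. me.": (7.38019, 0.12265, 4.59548),
}

# g1_form, g2_form, alpha, a1, a1_1, a1_2, a2, a2_1, a2_2, beta, gamma
REF_HEIGHT = {
    "Qu. ro.": ("satexp", "linear", -1.3624, None, 17.9437, 0.099, 0.4222,
                None, None, 0.0314, 0.8341),
    "Qu. pe.": ("linear", "quadratic", 2.1484, 0.1692, None, None, None,
                0.8495, -0.0114, 0.0067, 1.2896),
    "Qu. pu.": ("none", "quadratic", -3.7295, None, None, None, None,
                5.4023, -0.3118, 0.0102, 1.1533),
    "Fa. sy.": ("satexp", "quadratic", -5.8023, None, 15.8848, 0.0491, None,
                1.1844, -0.0145, 0.0137, 1.0219),
    "Pi. pi.": ("quadratic", "quadratic", -5.1515, None, 0.6972, -0.0058, None,
                0.3408, -0.0026, 0.0238, 0.9357),
    "Pi. sy.": ("satexp", "linear", -4.4002, None, 16.303, 0.0656, 0.1541,
                None, None, 0.0168, 1.0502),
    "Pi. la.": ("satexp", "quadratic", -20.9182, None, 45.475, 0.0645, None,
                0.3808, -0.0037, 0.0348, 0.7536),
    "Pi. ni.": ("satexp", "none", -6.342, None, 29.5273, 0.0725, None,
                None, None, 0.0224, 0.9475),
    "Pi. ha.": ("satexp", "log", -26.1684, None, 24.4999, 0.1001, 7.659,
                None, None, 0.0689, 0.6054),
    "Ab. al.": ("satexp", "log", 0.8475, None, 23.0394, 0.0411, 3.1832,
                None, None, 0.0075, 1.1343),
    "Pi. ab.": ("satexp", "satexp", -30.0783, None, 45.4929, 0.0897, None,
                17.3624, 0.0497, 0.016, 0.9984),
    "Ps. me.": ("satexp", "none", -5.5879, None, 50.3923, 0.0487, None,
                None, None, 0.0355, 0.7609),
}

# model key -> (beta1, beta2, beta3); 0 where the coefficient was dropped
REF_VOLUME = {
    "Qu. ro.": (0.0, 0.5057, 0.0),
    "Qu. pe.": (-4.438, 0.5455, -1.397e-3),
    "Qu. sp.": (-3.319, 0.5664, -1.778e-3),
    "Fa. sy.": (-4.498, 0.5107, -1.332e-3),
    "Pi. pi.": (-1.712, 0.5130, -1.124e-3),
    "Pi. sy.": (-2.247, 0.4985, -1.212e-3),
    "Pi. la.": (0.0, 0.5215, -1.271e-3),
    "Pi. ni.": (-8.427, 0.5857, -2.748e-3),
    "Pi. ha.": (0.0, 0.5258, -2.300e-3),
    "Ab. al.": (-4.523, 0.6011, -2.243e-3),
    "Pi. ab.": (-8.666, 0.5839, -2.679e-3),
    "Ps. me.": (-7.150, 0.5431, -2.951e-3),
}


# --- fidelity --------------------------------------------------------------


def test_self_thinning_fidelity(registry):
    for sp in ALL_SPECIES:
        p, q = REF_SELF_THINNING[sp.value]
        st = registry.self_thinning[sp]
        assert (st.p, st.q) == (p, q), sp.value


def test_growth_fidelity(registry):
    for sp in ALL_SPECIES:
        form, a0, b, c1, c2 = REF_GROWTH_CORE[sp.value]
        gp = registry.growth[sp]
        assert (gp.equation_form, gp.a0, gp.b, gp.c1, gp.c2) == (form, a0, b, c1, c2)
        assert dict(gp.a_m) == REF_SITE_TERMS[sp.value], sp.value


def test_mixture_fidelity(registry):
    got = {
        (t.value, c.value): (mp.s0, mp.s1)
        for (t, c), mp in registry.mixture.items()
    }
    assert got == REF_MIXTURE


def test_bark_fidelity(registry):
    for sp in ALL_SPECIES:
        key = BARK_MODEL_OF.get(sp, sp.value)
        form, a, b, c, max_dbh = REF_BARK[key]
        bp = registry.bark[sp]
        assert (bp.form, bp.a, bp.b, bp.c, bp.max_dbh) == (form, a, b, c, max_dbh)
        assert bp.min_dbh == 10.0


def test_diameter_dist_fidelity(registry):
    for sp in ALL_SPECIES:
        alpha, gamma, beta = REF_DIAMETER_DIST[sp.value]
        dd = registry.diameter_dist[sp]
        assert (dd.alpha, dd.gamma, dd.beta) == (alpha, gamma, beta), sp.value


def test_height_fidelity(registry):
    for sp in ALL_SPECIES:
        ref = REF_HEIGHT[sp.value]
        hp = registry.height[sp]
        got = (hp.g1_form, hp.g2_form, hp.alpha, hp.a1, hp.a1_1, hp.a1_2,
               hp.a2, hp.a2_1, hp.a2_2, hp.beta, hp.gamma)
        assert got == ref, sp.value


def test_volume_fidelity(registry):
    for sp in ALL_SPECIES:
        key = VOLUME_MODEL_OF.get(sp, sp.value)
        b1, b2, b3 = REF_VOLUME[key]
        vp = registry.volume[sp]
        assert (vp.beta1, vp.beta2, vp.beta3) == (b1, b2, b3), sp.value


# --- structure & lookups ---------------------------------------------------


def test_registry_complete_for_all_species(registry):
    for table in ("growth", "self_thinning", "bark", "diameter_dist",
                  "height", "volume"):
        assert set(getattr(registry, table)) == set(ALL_SPECIES)


def test_mixture_relation_count_and_pair_coverage(registry):
    """26 directed relations (7 pairs significant both ways) over 19 pairs."""
    assert len(registry.mixture) == 26
    unordered = {frozenset((t, c)) for t, c in registry.mixture}
    assert len(unordered) == 19
    both_ways = sum(
        1 for pair in unordered
        if len([k for k in registry.mixture if frozenset(k) == pair]) == 2
    )
    assert both_ways == 7


def test_mixture_lookup_directionality(registry):
    fwd = registry.mixture_params("Fa. sy.", "Qu. ro.")
    rev = registry.mixture_params("Qu. ro.", "Fa. sy.")
    assert fwd.s0 == 2.299 and fwd.s1 == -0.058
    assert rev is None  # non-significant in this direction


def test_mixture_lookup_absent_for_unstudied_species(registry):
    for other in ALL_SPECIES:
        if other is not S.PINUS_HALEPENSIS:
            assert registry.mixture_params(S.PINUS_HALEPENSIS, other) is None
            assert registry.mixture_params(other, S.PINUS_HALEPENSIS) is None


def test_significant_site_interactions_are_negative(registry):
    """Mixture benefits shrink on richer sites whenever the interaction is fitted."""
    for mp in registry.mixture.values():
        if mp.s1 is not None:
            assert mp.s1 < 0, (mp.target, mp.companion)


def test_invalid_species_code_raises():
    with pytest.raises(ValueError, match="unknown species code"):
        Species.from_code("Xx. yy.")
    with pytest.raises(ValueError, match="unknown species code"):
        load_default_parameters().mixture_params("Xx. yy.", "Fa. sy.")


def test_registry_reload_roundtrip(registry):
    """Re-reading the data files reproduces the registry losslessly."""
    fresh = load_default_parameters(refresh=True)
    assert fresh is not registry
    for name in ("growth", "self_thinning", "mixture", "bark",
                 "diameter_dist", "height", "volume"):
        assert getattr(fresh, name) == getattr(registry, name), name


def test_bark_prediction_stays_a_proportion(registry):
    """Every bark model stays inside (0, 1) over its calibration range."""
    import numpy as np
    for sp in ALL_SPECIES:
        bp = registry.bark[sp]
        for dbh in np.linspace(bp.min_dbh, bp.max_dbh, 200):
            assert 0.0 < bp.proportion(float(dbh)) < 1.0, (sp.value, dbh)
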