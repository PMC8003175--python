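"""Mediated system: effect decomposition identities, published arithmetic,
composition with the mixed-model engine, mediation classification."""

import math

import numpy as np
import pytest

from musclebone.data_model import default_model_spec
from musclebone.evaluation import standardized_cohort
from musclebone.lmm_engine import fit_random_intercept
from musclebone.mediation_model import (
    EffectEstimate,
    InsufficientDataError,
    classify_mediation,
    fit_mediated_system,
    indirect_effect,
    round3,
    total_effect,
)
from musclebone.synthetic_cohort import fixture_config


@pytest.fixture(scope="module")
def tiny_fit(tiny_standardized):
    return fit_mediated_system(tiny_standardized, default_model_spec("radial"))


def test_indirect_effect_published_arithmetic():
    """The mediated product reproduces published table cells at 3-decimal
    rounding: bone-age 0.480 x 0.288 -> 0.138; radial maturity
    0.135 x 0.257 -> 0.035."""
    assert round3(indirect_effect("bone_age", 0.480, 0.288, 0.038**2, 0.061**2).estimate) == 0.138
    assert round3(indirect_effect("maturity", 0.135, 0.257, 0.046**2, 0.072**2).estimate) == 0.035


def test_indirect_effect_null_path_closed_form():
    e = indirect_effect("x", 0.0, 0.7, 0.01, 0.5)
    assert e.estimate == 0.0
    assert e.se == pytest.approx(0.7 * 0.1, abs=1e-15)


def test_total_effect_published_arithmetic():
    """Totals are exactly direct + indirect: 0.241 + 0.061 -> 0.302 and
    0.264 + 0.177 -> 0.441."""
    ind = indirect_effect("m", 0.213, 0.288, 0.037**2, 0.061**2)
    assert round3(ind.estimate) == 0.061
    tot = total_effect("m", 0.241, ind, 0.052**2, 0.0, 0.213, 0.037**2, 0.288, 0.061**2)
    assert round3(tot.estimate) == 0.302
    ind_b = indirect_effect("m", 0.709, 0.250, 0.073**2, 0.093**2)
    tot_b = total_effect("m", 0.264, ind_b, 0.110**2, 0.0, 0.709, 0.073**2, 0.250, 0.093**2)
    assert round3(tot_b.estimate) == 0.441


def test_total_effect_degenerate_point_mass():
    ind = indirect_effect("m", 0.0, 0.0, 0.0, 0.0)
    tot = total_effect("m", 0.0, ind, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    assert tot.estimate == 0.0 and tot.se == 0.0 and tot.p == 1.0


def test_composition_with_engine(tiny_standardized, tiny_fit):
    """The system fit equals direct engine calls on the same complete
    cases, equation by equation."""
    spec = default_model_spec("radial")
    df = tiny_standardized.data
    m_cc = df.dropna(subset=("grip_strength",) + spec.muscle_equation.regressors)
    X = m_cc[list(spec.muscle_equation.regressors)].copy()
    X.insert(0, "const", 1.0)
    direct = fit_random_intercept(m_cc["grip_strength"], X, m_cc["participant_id"])
    assert np.allclose(
        direct.coefficients, tiny_fit.muscle_fit.coefficients[direct.coefficients.index], atol=1e-12
    )
    assert direct.loglik == pytest.approx(tiny_fit.muscle_fit.loglik, abs=1e-10)


def test_additivity_and_product_rule_exact(tiny_fit):
    """total = direct + indirect and indirect = a x b hold to 1e-12 for
    every modulator of a fitted system."""
    b = tiny_fit.bone_fit.coefficients["grip_strength"]
    for w in tiny_fit.spec.muscle_equation.covariates:
        a = tiny_fit.muscle_fit.coefficients[w]
        ind = tiny_fit.effect(w, "indirect_on_bone")
        tot = tiny_fit.effect(w, "total_on_bone")
        direct = (
            tiny_fit.effect(w, "direct_on_bone").estimate
            if w in tiny_fit.spec.bone_equation.covariates
            else 0.0
        )
        assert ind.estimate == pytest.approx(a * b, abs=1e-12)
        assert tot.estimate == pytest.approx(direct + ind.estimate, abs=1e-12)


def test_stars_consistent_with_p(tiny_fit):
    for e in tiny_fit.effects:
        if e.p < 0.001:
            assert e.stars == "***"
        elif e.p < 0.01:
            assert e.stars == "**"
        elif e.p < 0.05:
            assert e.stars == "*"
        else:
            assert e.stars == ""


def test_no_mediation_limit():
    """All muscle-equation coefficients zero: indirect effects average zero
    over seeds and totals equal directs for shared modulators."""
    cfg = fixture_config("null_effects")
    indirects = []
    for seed in range(15):
        table = standardized_cohort(cfg, seed=seed)
        result = fit_mediated_system(table, default_model_spec("tibial"))
        for w in result.spec.muscle_equation.covariates:
            indirects.append(result.effect(w, "indirect_on_bone").estimate)
            tot = result.effect(w, "total_on_bone").estimate
            if w in result.spec.bone_equation.covariates:
                d = result.effect(w, "direct_on_bone").estimate
                assert tot == pytest.approx(d + result.effect(w, "indirect_on_bone").estimate)
    assert abs(np.mean(indirects)) < 0.01


@pytest.mark.parametrize(
    "direct_p,indirect_p,expected",
    [(None, 0.0005, "full"), (0.0005, 0.0005, "partial"), (0.0005, 0.3, "none"), (0.6, 0.01, "full")],
)
def test_classify_mediation_patterns(direct_p, indirect_p, expected):
    effects = [EffectEstimate("x", "indirect_on_bone", 0.1, 0.05, 2.0, indirect_p)]
    if direct_p is not None:
        effects.append(EffectEstimate("x", "direct_on_bone", 0.2, 0.05, 4.0, direct_p))
    assert classify_mediation(effects) == expected


def test_requires_standardized_table(tiny_table):
    with pytest.raises(ValueError, match="standardized"):
        fit_mediated_system(tiny_table, default_model_spec("radial"))


def test_insufficient_data_error(tiny_standardized):
    broken = tiny_standardized.copy()
    broken.data.loc[:, "grip_strength"] = np.nan
    with pytest.raises(InsufficientDataError, match="muscle"):
        fit_mediated_system(broken, default_model_spec("radial"))


def test_pooled_stack_consistency(study_standardized):
    """With both sites generated from identical coefficients, the pooled
    stacked fit brackets between the site-specific fits and lands within
    2 SEs of the truth. The stacked GLS is not a coordinate-wise convex
    combination of the site fits, so the bracket allows a
    fraction-of-an-SE weighting excursion (typical observed scale is
    ~0.3 SE)."""
    fits = {
        site: fit_mediated_system(study_standardized, default_model_spec(site), site=site)
        for site in ("radial", "tibial", "pooled")
    }
    truth = {
        "muscle_strength": 0.288,
        "ntx_corrected": -0.184,
        "paqc": 0.056,
        "maturity_offset": 0.241,
        "bmi": -0.178,
    }
    site_name = {"muscle_strength": ("grip_strength", "knee_extension")}
    for coef, true_value in truth.items():
        rad_name, tib_name = site_name.get(coef, (coef, coef))
        rad = fits["radial"].bone_fit.coefficients[rad_name]
        tib = fits["tibial"].bone_fit.coefficients[tib_name]
        pooled = fits["pooled"].bone_fit.coefficients[coef]
        se = fits["pooled"].bone_fit.se[coef]
        slack = 0.75 * se
        assert min(rad, tib) - slack <= pooled <= max(rad, tib) + slack, coef
        assert abs(pooled - true_value) < 2.0 * se, coef


def test_round3_half_away_from_zero():
    assert round3(0.0005) == 0.001
    assert round3(-0.0005) == -0.001
    assert round3(0.2875) == 0.288
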