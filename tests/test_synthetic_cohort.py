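"""Synthetic cohort generator: design, calibration, determinism."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from musclebone.preprocessing import apply_exclusions
from musclebone.synthetic_cohort import (
    DEFAULT_CALIBRATION,
    CohortConfig,
    ConfigError,
    Missingness,
    ResidualSDs,
    StructuralCoefficients,
    VariableMoments,
    fixture_config,
    generate_cohort,
    make_fixture,
)


def test_study_scale_design_counts(study_table):
    """180 participants with the 36/53/72/19 session mix -> 434 rows."""
    assert study_table.n_observations == 434
    assert study_table.n_participants == 180
    counts = study_table.data.groupby("participant_id").size().value_counts().sort_index()
    assert counts.to_dict() == {1: 36, 2: 53, 3: 72, 4: 19}
    sexes = study_table.data.drop_duplicates("participant_id")["sex"].value_counts()
    assert sexes["male"] == 92 and sexes["female"] == 88


def test_seed_determinism():
    a = make_fixture("study_scale", seed=5)
    b = make_fixture("study_scale", seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = make_fixture("study_scale", seed=6)
    assert not a.data["radial_sos"].equals(c.data["radial_sos"])


def test_tiny_fixture_shape(tiny_table):
    assert tiny_table.n_observations == 16
    assert tiny_table.n_participants == 8
    assert (tiny_table.data.groupby("participant_id").size() == 2).all()


def test_generated_table_satisfies_data_contract(study_table):
    assert study_table.validate() == []


def test_degenerate_zero_noise_freezes_repeats():
    """Zero within-SDs and zero residual SDs: every participant's repeated
    values are constant across sessions."""
    cal = {
        k: VariableMoments(v.mean, 0.0, v.sd_between) for k, v in DEFAULT_CALIBRATION.items()
    }
    cfg = CohortConfig(
        variable_calibration=cal,
        residual_sds=ResidualSDs(0.0, 0.0, 0.0, 0.0),
        missingness=Missingness(grip_wave=None, ntx_rate=0.0),
    )
    _, report = generate_cohort(cfg, seed=3)
    assert report.moments.table["sd_within"].max() < 1e-9


def test_null_structural_coefficients_decouple_muscle_and_bone():
    """With every path zero, standardized muscle strength and bone SOS are
    uncorrelated up to Monte-Carlo error."""
    cfg = fixture_config("null_effects")
    corrs = []
    for seed in range(30):
        table, _ = generate_cohort(cfg, seed=seed)
        df = table.data.dropna(subset=["grip_strength", "radial_sos"])
        corrs.append(np.corrcoef(df["grip_strength"], df["radial_sos"])[0, 1])
    assert abs(np.mean(corrs)) < 2.5 / math.sqrt(30 * 350)


def test_moment_calibration_within_monte_carlo_error():
    """Over 50 replicate seeds the mean realized per-variable means and
    within/between SDs agree with the configured calibration at the
    2-Monte-Carlo-SE level: with 36 simultaneous unbiased statistics ~5%
    sit beyond 2 SEs by chance, so each must stay within a
    multiplicity-corrected 3.5 SEs and at most 3 may exceed 2 SEs. The
    structural outcomes are calibrated exactly and get a floating-point
    floor."""
    R = 50
    cfg = CohortConfig()
    acc: dict[str, list[np.ndarray]] = {}
    for seed in range(R):
        _, report = generate_cohort(cfg, seed=7000 + seed)
        for name in report.moments.table.index:
            acc.setdefault(name, []).append(
                report.moments.table.loc[name, ["mean", "sd_within", "sd_between"]].to_numpy()
            )
    exceedances = 0
    for name, rows in acc.items():
        arr = np.asarray(rows)
        mom = DEFAULT_CALIBRATION[name]
        targets = np.array([mom.mean, mom.sd_within, mom.sd_between])
        mc_se = arr.std(axis=0, ddof=1) / math.sqrt(R)
        fp_floor = 1e-9 * np.maximum(np.abs(targets), 1.0)
        gap = np.abs(arr.mean(axis=0) - targets)
        assert (gap < 3.5 * mc_se + fp_floor).all(), name
        exceedances += int((gap > 2.0 * mc_se + fp_floor).sum())
        if name in ("radial_sos", "tibial_sos", "grip_strength", "knee_extension"):
            assert (gap < 1e-6 * np.maximum(np.abs(targets), 1.0)).all(), name
    assert exceedances <= 3


def test_exclusion_flags_and_missingness_counts(study_table):
    analysis, log = apply_exclusions(study_table)
    assert log.removed == {
        "diabetes_t1": 6,
        "fracture": 8,
        "sos_undetected": 11,
        "missed_visit": 3,
    }
    assert analysis.n_observations == 406
    # within the unflagged rows, grip is absent only in the designated
    # (fall) season-year; flagged rows may blank grip for other reasons
    unflagged = study_table.data[study_table.data["exclusion_flags"].map(len) == 0]
    fall_missing = unflagged.loc[unflagged["grip_strength"].isna(), "season"]
    assert len(fall_missing) > 0
    assert set(fall_missing) <= {"fall"}


def test_positive_quantities_stay_positive():
    for seed in (0, 1, 2):
        table, _ = generate_cohort(CohortConfig(), seed=seed)
        for col in ("grip_strength", "knee_extension", "ntx_corrected", "waeq",
                    "energy_intake", "creatinine", "radial_sos", "tibial_sos"):
            assert (table.data[col].dropna() > 0).all(), col


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        CohortConfig(session_count_distribution=(0.5, 0.5, 0.5, 0.0)).validate()
    with pytest.raises(ConfigError):
        CohortConfig(missingness=Missingness(ntx_rate=1.5)).validate()
    with pytest.raises(ConfigError):
        CohortConfig(
            structural_coefficients=StructuralCoefficients(bone={"mediator": float("inf")})
        ).validate()
    with pytest.raises(ConfigError):
        dataclasses.replace(CohortConfig(), n_participants=0).validate()


def test_unknown_fixture_rejected():
    with pytest.raises(ValueError):
        make_fixture("nope")
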