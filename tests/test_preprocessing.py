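"""Exclusion cascade, derived variables, z-scoring, variance decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from musclebone.data_model import CohortTable, FLAG_COLUMN
from musclebone.preprocessing import (
    DegenerateScaleError,
    apply_exclusions,
    back_transform,
    compute_waeq,
    correct_ntx,
    variance_decomposition,
    zstandardize,
)


def _toy_table(values, participants=None, flags=None):
    n = len(values)
    df = pd.DataFrame(
        {
            "participant_id": participants or [f"p{i}" for i in range(n)],
            "session_index": (
                pd.Series(participants or range(n)).groupby(participants or range(n)).cumcount() + 1
                if participants
                else 1
            ),
            "season": "spring",
            "sex": "male",
            "x": values,
        }
    )
    if participants:
        df["session_index"] = df.groupby("participant_id").cumcount() + 1
    df[FLAG_COLUMN] = flags or [frozenset()] * n
    return CohortTable(df)


# -- exclusions --------------------------------------------------------------


def test_exclusions_no_flags_is_identity(tiny_table):
    out, log = apply_exclusions(tiny_table)
    assert log.initial == log.final == tiny_table.n_observations
    assert all(v == 0 for v in log.removed.values())
    assert log.balanced


def test_exclusions_multi_flag_attributed_to_first_reason():
    """A doubly-flagged record is removed once, charged to the cascade-first
    reason, and the ledger still balances."""
    flags = [
        frozenset({"fracture", "diabetes_t1"}),
        frozenset({"missed_visit", "sos_undetected"}),
        frozenset(),
    ]
    table = _toy_table([1.0, 2.0, 3.0], flags=flags)
    out, log = apply_exclusions(table)
    assert log.removed == {
        "diabetes_t1": 1,
        "fracture": 0,
        "sos_undetected": 1,
        "missed_visit": 0,
    }
    assert log.final == out.n_observations == 1
    assert log.balanced


def test_exclusions_idempotent(study_table):
    once, log1 = apply_exclusions(study_table)
    twice, log2 = apply_exclusions(once)
    assert log1.final == twice.n_observations
    assert all(v == 0 for v in log2.removed.values())


# -- NTX correction ----------------------------------------------------------


def test_correct_ntx_examples():
    assert correct_ntx(100.0, 2.0) == 50.0
    assert correct_ntx(539.8, 1.0) == 539.8


def test_correct_ntx_null_propagation_and_domain():
    assert np.isnan(correct_ntx(np.nan, 2.0))
    assert np.isnan(correct_ntx(100.0, np.nan))
    with pytest.raises(ValueError):
        correct_ntx(100.0, 0.0)
    with pytest.raises(ValueError):
        correct_ntx(np.array([1.0, 2.0]), np.array([1.0, -0.5]))


@given(
    raw=st.floats(min_value=1e-3, max_value=1e4),
    cr=st.floats(min_value=1e-3, max_value=1e3),
)
@settings(max_examples=100, derandomize=True)
def test_correct_ntx_equals_ratio(raw, cr):
    assert correct_ntx(raw, cr) == pytest.approx(raw / cr, rel=1e-12)


# -- WAeq score --------------------------------------------------------------


def test_waeq_examples_and_symmetry():
    assert compute_waeq(0, 0, 0) == 0.0
    assert compute_waeq(2, 1, 1, met_weights=(3, 5, 9)) == 20.0
    # permuting weights together with frequencies leaves the score unchanged
    assert compute_waeq(1, 2, 3, met_weights=(3, 5, 9)) == compute_waeq(
        3, 2, 1, met_weights=(9, 5, 3)
    )
    with pytest.raises(ValueError):
        compute_waeq(-1, 0, 0)


# -- z-standardization -------------------------------------------------------


def test_zstandardize_fixed_point_and_moments():
    table = _toy_table([-1.0, 1.0])
    out = zstandardize(table, ["x"])
    assert np.allclose(out.data["x"], [-1.0, 1.0], atol=1e-12)
    rng = np.random.default_rng(0)
    table = _toy_table(list(rng.normal(10, 3, 40)))
    out = zstandardize(table, ["x"])
    assert abs(out.data["x"].mean()) < 1e-10
    assert abs(out.data["x"].std(ddof=0) - 1.0) < 1e-10


def test_zstandardize_round_trip_and_idempotence():
    rng = np.random.default_rng(1)
    values = list(rng.lognormal(2, 0.4, 30))
    table = _toy_table(values)
    once = zstandardize(table, ["x"])
    twice = zstandardize(once, ["x"])
    assert np.allclose(once.data["x"], twice.data["x"], atol=1e-10)
    restored = back_transform(once, ["x"])
    assert np.allclose(restored.data["x"], values, atol=1e-10)


def test_zstandardize_preserves_nulls_and_rejects_constants():
    table = _toy_table([1.0, np.nan, 3.0])
    out = zstandardize(table, ["x"])
    assert out.data["x"].isna().sum() == 1
    with pytest.raises(DegenerateScaleError):
        zstandardize(_toy_table([2.0, 2.0, 2.0]), ["x"])


def test_zstandardize_reuses_external_params():
    """Stratified fits reuse the pooled scaling: passing params must apply
    exactly those, not re-estimate."""
    table = _toy_table([5.0, 7.0, 9.0])
    out = zstandardize(table, ["x"], params={"x": {"mean": 5.0, "sd": 2.0}})
    assert np.allclose(out.data["x"], [0.0, 1.0, 2.0])
    assert out.metadata["standardization"]["x"] == {"mean": 5.0, "sd": 2.0}


# -- variance decomposition --------------------------------------------------


def test_decomposition_matches_brute_force():
    rng = np.random.default_rng(2)
    participants = [p for p in "abcde" for _ in range(rng.integers(1, 5))]
    values = list(rng.normal(0, 2, len(participants)))
    table = _toy_table(values, participants=participants)
    dec = variance_decomposition(table, ["x"])["x"]

    # explicit two-pass loops
    by = {}
    for p, v in zip(participants, values):
        by.setdefault(p, []).append(v)
    devs = [v - np.mean(vs) for vs in by.values() for v in vs]
    pmeans = [np.mean(vs) for vs in by.values()]
    assert dec["mean"] == pytest.approx(np.mean(values), abs=1e-12)
    assert dec["sd_total"] == pytest.approx(np.std(values), abs=1e-12)
    assert dec["sd_within"] == pytest.approx(np.sqrt(np.mean(np.square(devs))), abs=1e-12)
    assert dec["sd_between"] == pytest.approx(np.std(pmeans), abs=1e-12)


def test_decomposition_degenerate_designs():
    # one observation per participant: no within variation
    table = _toy_table([1.0, 2.0, 4.0])
    dec = variance_decomposition(table, ["x"])["x"]
    assert dec["sd_within"] == 0.0
    assert dec["sd_between"] == pytest.approx(dec["sd_total"])
    # identical participant means: between collapses
    table = _toy_table([1.0, 3.0, 0.0, 4.0], participants=["a", "a", "b", "b"])
    dec = variance_decomposition(table, ["x"])["x"]
    assert dec["sd_between"] == 0.0
    assert dec["sd_within"] > 0
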