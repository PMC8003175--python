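"""Coefficient-equality (Chow-type) tests between strata.

With boys and girls fitted independently on a shared (whole-cohort)
standardization scale, equality of their coefficients is tested with a Wald
statistic: d = beta_a - beta_b has covariance V = V_a + V_b (independent
strata), and d' V^-1 d is chi-square with one degree of freedom per tested
coefficient. This is the standard mixed-model generalization of the
classical pooled-F Chow test, which has no single residual sum of squares
to build on here. Per-coefficient z tests and a total-effect difference
test (normal, variance = sum of variances) accompany the joint statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm_engine import wald_z
from .mediation_model import EffectEstimate, SEMResult, _effect


@dataclass
class ChowResult:
    tested_coefficients: list[str]
    statistic: float
    df: int
    p: float
    per_coefficient: pd.DataFrame  # difference, se, z, p per coefficient

    def to_json(self, path=None) -> str:
        payload = {
            "tested_coefficients": self.tested_coefficients,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "per_coefficient": self.per_coefficient.round(12).to_dict(orient="index"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.per_coefficient.to_csv(path, index_label="coefficient")


def chow_test(
    fit_a: SEMResult,
    fit_b: SEMResult,
    equation: str = "bone",
    coefficients: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> ChowResult:
    """Joint Wald test that the named coefficients are equal across strata.

    ``equation`` selects "bone" or "muscle"; by default every non-intercept
    coefficient of that equation is tested, minus any in ``exclude`` (the
    published usage tests the bone coefficients excluding BMI).
    """
    if equation not in ("bone", "muscle"):
        raise ValueError("equation must be 'bone' or 'muscle'")
    fa = fit_a.bone_fit if equation == "bone" else fit_a.muscle_fit
    fb = fit_b.bone_fit if equation == "bone" else fit_b.muscle_fit
    if coefficients is None:
        coefficients = [c for c in fa.coefficients.index if c != "const"]
    coefficients = [c for c in coefficients if c not in set(exclude)]
    missing = [c for c in coefficients if c not in fa.coefficients.index or c not in fb.coefficients.index]
    if missing or not coefficients:
        raise ValueError(f"non-conformable coefficient sets; missing: {missing}")

    d = fa.coefficients[coefficients].to_numpy() - fb.coefficients[coefficients].to_numpy()
    V = (
        fa.coefficient_covariance.loc[coefficients, coefficients].to_numpy()
        + fb.coefficient_covariance.loc[coefficients, coefficients].to_numpy()
    )
    statistic = float(d @ np.linalg.solve(V, d))
    df = len(coefficients)
    p = float(stats.chi2.sf(statistic, df))

    rows = {}
    for i, name in enumerate(coefficients):
        se = float(np.sqrt(V[i, i]))
        z, pz = wald_z(float(d[i]), se)
        rows[name] = {"difference": float(d[i]), "se": se, "z": z, "p": pz}
    return ChowResult(
        tested_coefficients=list(coefficients),
        statistic=statistic,
        df=df,
        p=p,
        per_coefficient=pd.DataFrame.from_dict(rows, orient="index"),
    )


def total_effect_difference(effect_a: EffectEstimate, effect_b: EffectEstimate) -> EffectEstimate:
    """Difference of one modulator's effects across independent strata."""
    if effect_a.kind != effect_b.kind or effect_a.modulator != effect_b.modulator:
        raise ValueError("effects must share modulator and kind")
    diff = effect_a.estimate - effect_b.estimate
    se = float(np.sqrt(effect_a.se**2 + effect_b.se**2))
    return _effect(effect_a.modulator, effect_a.kind, diff, se)
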