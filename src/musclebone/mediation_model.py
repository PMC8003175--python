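"""The mediated two-equation system and its effect decomposition.

The system is recursive: muscle strength M is regressed on modulators W
(muscle equation), and bone SOS Y on M plus modulators Z (bone equation).
Because the bone equation conditions on M and the cross-equation errors are
taken as independent, the joint likelihood factorizes and the two equations
are fitted separately by :mod:`musclebone.lmm_engine`, each on its own
complete cases — reproducing the estimand of a generalized-SEM fit without
joint optimization.

Per modulator the path decomposition is

* direct effect on bone = its bone-equation coefficient theta,
* effect on muscle = its muscle-equation coefficient a,
* indirect effect on bone = a * b (b = mediator coefficient), with the
  first-order delta (Sobel) standard error sqrt(b^2 var_a + a^2 var_b),
* total effect = theta + a * b, with delta-method variance
  var_theta + b^2 var_a + a^2 var_b + 2 a cov(theta, b); cov(theta, b)
  comes from the bone-equation coefficient covariance and cross-equation
  covariances are zero (the equations are fitted on different
  complete-case sets, so no joint covariance exists).

Additivity (total = direct + indirect) and the product rule are exact
identities of this decomposition, not approximations.

For the pooled site the radial and tibial rows are stacked (two rows per
session, outcome-matched mediator values) with shared coefficients, a
participant random intercept, and a session-level random intercept that
induces exchangeable cross-outcome correlation within a session; the
realized level-1 cross-outcome residual correlation is reported
descriptively.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import STACKED_SOURCES, CohortTable, ModelSpec, SchemaError
from .lmm_engine import (
    MixedFitResult,
    fit_nested_intercepts,
    fit_random_intercept,
    p_stars,
    wald_z,
)

logger = logging.getLogger(__name__)

EFFECT_KINDS = ("direct_on_bone", "effect_on_muscle", "indirect_on_bone", "total_on_bone")


class InsufficientDataError(ValueError):
    pass


def round3(x: float) -> float:
    """Three decimals, half away from zero (report-table convention)."""
    return math.copysign(math.floor(abs(x) * 1000.0 + 0.5) / 1000.0, x)


@dataclass(frozen=True)
class EffectEstimate:
    modulator: str
    kind: str
    estimate: float
    se: float
    z: float
    p: float

    @property
    def stars(self) -> str:
        return p_stars(self.p)

    def cell(self) -> str:
        """Publication-style cell: "estimate (se)" at 3 decimals + stars."""
        star = f" {self.stars}" if self.stars else ""
        return f"{round3(self.estimate):.3f}{star} ({round3(self.se):.3f})"


def _effect(modulator: str, kind: str, estimate: float, se: float) -> EffectEstimate:
    if se > 0:
        z, p = wald_z(estimate, se)
    else:  # degenerate: a point mass
        z = 0.0 if estimate == 0 else math.copysign(math.inf, estimate)
        p = 1.0 if estimate == 0 else 0.0
    return EffectEstimate(modulator, kind, float(estimate), float(se), z, p)


def indirect_effect(modulator: str, a: float, b: float, var_a: float, var_b: float) -> EffectEstimate:
    """Mediated product a*b with the first-order delta (Sobel) SE."""
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be non-negative")
    se = math.sqrt(b * b * var_a + a * a * var_b)
    return _effect(modulator, "indirect_on_bone", a * b, se)


def total_effect(
    modulator: str,
    direct: float,
    indirect: EffectEstimate,
    var_direct: float,
    cov_direct_mediator: float,
    a: float,
    var_a: float,
    b: float,
    var_b: float,
) -> EffectEstimate:
    """Total = direct + indirect, delta-method SE on T = theta + a*b."""
    est = direct + indirect.estimate
    var = var_direct + b * b * var_a + a * a * var_b + 2.0 * a * cov_direct_mediator
    return _effect(modulator, "total_on_bone", est, math.sqrt(max(var, 0.0)))


@dataclass
class SEMResult:
    """Both fitted equations plus the full effect decomposition."""

    bone_fit: MixedFitResult
    muscle_fit: MixedFitResult
    effects: list[EffectEstimate]
    spec: ModelSpec
    n_bone: int
    n_muscle: int
    site: str | None = None
    stratum: str | None = None
    residual_cross_correlation: float | None = None  # pooled fits only

    def effect(self, modulator: str, kind: str) -> EffectEstimate:
        for e in self.effects:
            if e.modulator == modulator and e.kind == kind:
                return e
        raise KeyError(f"no {kind} effect for {modulator!r}")

    def effects_for(self, modulator: str) -> list[EffectEstimate]:
        return [e for e in self.effects if e.modulator == modulator]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": self.site,
                "stratum": self.stratum,
                "modulator": e.modulator,
                "kind": e.kind,
                "estimate": e.estimate,
                "se": e.se,
                "z": e.z,
                "p": e.p,
                "stars": e.stars,
            }
            for e in self.effects
        ]
        return pd.DataFrame(rows)


def _require_standardized(table: CohortTable, names: Sequence[str]) -> None:
    have = set(table.metadata.get("standardization", {}))
    # an entirely-null column needs no scaling; the complete-case counts
    # downstream report it as an insufficient-data problem instead
    missing = [
        n
        for n in names
        if n not in have and n in table.data.columns and table.data[n].notna().any()
    ]
    if missing:
        raise ValueError(
            f"fit_mediated_system expects a z-standardized table; not standardized: {missing}"
        )


def _complete_cases(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    return df.dropna(subset=list(columns))


def _check_n(n: int, n_regressors: int, equation: str) -> None:
    if n < n_regressors + 3:
        raise InsufficientDataError(
            f"{equation} equation: {n} complete cases for {n_regressors} regressors"
        )


def _design(df: pd.DataFrame, regressors: Sequence[str], intercept: bool) -> pd.DataFrame:
    X = df[list(regressors)].astype(float)
    if intercept:
        X = X.copy()
        X.insert(0, "const", 1.0)
    return X


def _stack_long(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Two rows per session: one per bone site, with outcome-matched mediator."""
    keep = ["participant_id", "session_index"] + [c for c in covariates]
    out = []
    for site, (y_col, m_col) in (
        ("radial", ("radial_sos", "grip_strength")),
        ("tibial", ("tibial_sos", "knee_extension")),
    ):
        part = df[keep + [y_col, m_col]].copy()
        part = part.rename(columns={y_col: "bone_sos", m_col: "muscle_strength"})
        part["bone_site"] = site
        out.append(part)
    long = pd.concat(out, ignore_index=True)
    long["session_key"] = (
        long["participant_id"].astype(str) + ":" + long["session_index"].astype(str)
    )
    return long


def fit_mediated_system(table: CohortTable, spec: ModelSpec, reml: bool = False,
                        site: str | None = None, stratum: str | None = None) -> SEMResult:
    """Fit both structural equations and derive all four effect kinds.

    The table must already be z-standardized (so coefficients are the
    standardized betas the effects operate on). Each equation is fitted on
    its own complete cases; the pooled site uses the stacked two-row-per-
    session layout with nested participant/session random intercepts.
    """
    spec.validate_against(table)
    df = table.data
    bone_eq, muscle_eq = spec.bone_equation, spec.muscle_equation
    model_vars = set()
    for eq in (bone_eq, muscle_eq):
        for name in (eq.outcome,) + eq.regressors:
            model_vars.update(STACKED_SOURCES.get(name, (name,)))
    _require_standardized(table, sorted(model_vars))

    mediator = bone_eq.mediator
    stacked = spec.is_stacked
    if not stacked and mediator not in df.columns:
        raise SchemaError(f"mediator {mediator!r} absent from table")

    if stacked:
        long = _stack_long(df, sorted(set(bone_eq.covariates) | set(muscle_eq.covariates)))
        m_cc = _complete_cases(long, ("muscle_strength",) + muscle_eq.regressors)
        _check_n(len(m_cc), len(muscle_eq.regressors) + 1, "muscle")
        muscle_fit = fit_nested_intercepts(
            m_cc["muscle_strength"],
            _design(m_cc, muscle_eq.regressors, muscle_eq.intercept),
            m_cc[spec.grouping],
            m_cc["session_key"],
            reml=reml,
        )
        b_cc = _complete_cases(long, ("bone_sos",) + bone_eq.regressors)
        _check_n(len(b_cc), len(bone_eq.regressors) + 1, "bone")
        bone_fit = fit_nested_intercepts(
            b_cc["bone_sos"],
            _design(b_cc, bone_eq.regressors, bone_eq.intercept),
            b_cc[spec.grouping],
            b_cc["session_key"],
            reml=reml,
        )
        cross_corr = _residual_cross_correlation(b_cc, bone_fit, bone_eq)
    else:
        m_cc = _complete_cases(df, (muscle_eq.outcome,) + muscle_eq.regressors)
        _check_n(len(m_cc), len(muscle_eq.regressors) + 1, "muscle")
        muscle_fit = fit_random_intercept(
            m_cc[muscle_eq.outcome],
            _design(m_cc, muscle_eq.regressors, muscle_eq.intercept),
            m_cc[spec.grouping],
            reml=reml,
        )
        b_cc = _complete_cases(df, (bone_eq.outcome,) + bone_eq.regressors)
        _check_n(len(b_cc), len(bone_eq.regressors) + 1, "bone")
        bone_fit = fit_random_intercept(
            b_cc[bone_eq.outcome],
            _design(b_cc, bone_eq.regressors, bone_eq.intercept),
            b_cc[spec.grouping],
            reml=reml,
        )
        cross_corr = None

    effects = _derive_effects(bone_fit, muscle_fit, spec)
    return SEMResult(
        bone_fit=bone_fit,
        muscle_fit=muscle_fit,
        effects=effects,
        spec=spec,
        n_bone=bone_fit.n_obs,
        n_muscle=muscle_fit.n_obs,
        site=site,
        stratum=stratum,
        residual_cross_correlation=cross_corr,
    )


def _residual_cross_correlation(b_cc: pd.DataFrame, fit: MixedFitResult, bone_eq) -> float | None:
    """Descriptive cross-outcome correlation of session-paired marginal
    residuals in the stacked bone fit (the role the residual covariance
    matrix plays in a joint bivariate parameterization)."""
    X = _design(b_cc, bone_eq.regressors, bone_eq.intercept)
    resid = b_cc["bone_sos"].to_numpy(dtype=float) - X.to_numpy() @ fit.coefficients.to_numpy()
    frame = pd.DataFrame(
        {"session_key": b_cc["session_key"].to_numpy(), "site": b_cc["bone_site"].to_numpy(), "resid": resid}
    )
    wide = frame.pivot_table(index="session_key", columns="site", values="resid")
    wide = wide.dropna()
    if len(wide) < 3 or wide.shape[1] < 2:
        return None
    return float(np.corrcoef(wide.iloc[:, 0], wide.iloc[:, 1])[0, 1])


def _derive_effects(bone_fit: MixedFitResult, muscle_fit: MixedFitResult, spec: ModelSpec) -> list[EffectEstimate]:
    bone_eq, muscle_eq = spec.bone_equation, spec.muscle_equation
    mediator = bone_eq.mediator
    bcoef, bcov = bone_fit.coefficients, bone_fit.coefficient_covariance
    mcoef, mcov = muscle_fit.coefficients, muscle_fit.coefficient_covariance
    b = float(bcoef[mediator])
    var_b = float(bcov.loc[mediator, mediator])

    effects: list[EffectEstimate] = []
    effects.append(_effect(mediator, "direct_on_bone", b, math.sqrt(var_b)))
    for z in bone_eq.covariates:
        effects.append(
            _effect(z, "direct_on_bone", float(bcoef[z]), math.sqrt(float(bcov.loc[z, z])))
        )
    for w in muscle_eq.covariates:
        a = float(mcoef[w])
        var_a = float(mcov.loc[w, w])
        effects.append(_effect(w, "effect_on_muscle", a, math.sqrt(var_a)))
        ind = indirect_effect(w, a, b, var_a, var_b)
        effects.append(ind)
        if w in bone_eq.covariates:
            direct = float(bcoef[w])
            var_direct = float(bcov.loc[w, w])
            cov_tb = float(bcov.loc[w, mediator])
        else:  # no direct path: the total is purely mediated
            direct, var_direct, cov_tb = 0.0, 0.0, 0.0
        effects.append(
            total_effect(w, direct, ind, var_direct, cov_tb, a, var_a, b, var_b)
        )
    return effects


def classify_mediation(effects: Sequence[EffectEstimate], alpha: float = 0.05) -> str:
    """full / partial / none for one modulator's complete effect set.

    full    — indirect significant and no (or non-significant) direct path;
    partial — direct and indirect both significant;
    none    — indirect non-significant.
    """
    by_kind = {e.kind: e for e in effects}
    if "indirect_on_bone" not in by_kind:
        raise ValueError("effect set lacks an indirect effect")
    indirect = by_kind["indirect_on_bone"]
    if not indirect.p < alpha:
        return "none"
    direct = by_kind.get("direct_on_bone")
    if direct is not None and direct.p < alpha:
        return "partial"
    return "full"


def effects_to_csv(results: Sequence[SEMResult], path) -> pd.DataFrame:
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    frame.to_csv(path, index=False)
    return frame
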