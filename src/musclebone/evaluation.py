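"""Simulation-based validation harnesses for the mediated pipeline.

These routines answer the calibration questions a methods reviewer would
ask of the estimator itself, by simulation from the synthetic-cohort
generator with known truth:

* :func:`recover_paths` — repeated generate-and-refit with the configured
  structural coefficients as truth, reporting per-path bias and 95%
  Wald-CI coverage. Data are standardized with the generator's *configured*
  affine parameters, so the truth is exact on the fitted scale and the
  experiment isolates the structural estimator (empirical re-scaling adds
  scale-estimation noise that belongs to the data, not the estimator; the
  full empirical-standardization path is exercised elsewhere).
* :func:`chow_type_one_error` — rejection rate of the between-strata Wald
  test when both strata share one generating process.
* :func:`sobel_bootstrap_sd` — parametric-bootstrap sampling SDs of the
  indirect effects on a fixed fitted system, the brute-force yardstick for
  the first-order delta (Sobel) standard errors.

All routines derive per-replicate seeds from one ``numpy.random.SeedSequence``
so results are reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortTable, default_model_spec
from .group_comparison import chow_test
from .lmm_engine import fit_random_intercept
from .mediation_model import SEMResult, fit_mediated_system
from .preprocessing import apply_exclusions, zstandardize
from .synthetic_cohort import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


def configured_standardization(config: CohortConfig) -> dict[str, dict[str, float]]:
    """The generator's affine calibration as zstandardize parameters."""
    return {
        name: {"mean": mom.mean, "sd": mom.sd_total}
        for name, mom in config.variable_calibration.items()
    }


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def standardized_cohort(config: CohortConfig, seed: int) -> CohortTable:
    """Generate, exclude and standardize one analysis-ready cohort on the
    configured scale."""
    table, _ = generate_cohort(config, seed=seed)
    analysis, _ = apply_exclusions(table)
    return zstandardize(
        analysis,
        list(config.variable_calibration),
        params=configured_standardization(config),
    )


def true_paths(config: CohortConfig, site: str = "radial") -> dict[tuple[str, str], float]:
    """Generating truth keyed by (equation, coefficient name)."""
    spec = default_model_spec(site)
    coef = config.structural_coefficients
    truth: dict[tuple[str, str], float] = {("bone", spec.bone_equation.mediator): coef.bone["mediator"]}
    for name, value in coef.bone.items():
        if name != "mediator":
            truth[("bone", name)] = value
    for name, value in coef.muscle.items():
        truth[("muscle", name)] = value
    return truth


@dataclass
class RecoveryResult:
    """Per-path recovery summary over replicates."""

    table: pd.DataFrame  # index (equation, coefficient); truth, mean_estimate, bias, coverage
    n_replicates: int

    def __str__(self) -> str:
        return self.table.to_string()


def recover_paths(
    config: CohortConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    site: str = "radial",
    level: float = 0.95,
) -> RecoveryResult:
    """Generate-and-refit experiment for every structural path."""
    from scipy import stats

    config = config or CohortConfig()
    spec = default_model_spec(site)
    truth = true_paths(config, site)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    est = {key: [] for key in truth}
    cover = {key: [] for key in truth}
    for rep_seed in _child_seeds(seed, n_replicates):
        table = standardized_cohort(config, rep_seed)
        result = fit_mediated_system(table, spec)
        for (equation, name), true_value in truth.items():
            fit = result.bone_fit if equation == "bone" else result.muscle_fit
            b = float(fit.coefficients[name])
            se = float(fit.se[name])
            est[(equation, name)].append(b)
            cover[(equation, name)].append(abs(b - true_value) <= zcrit * se)
    rows = {}
    for key, true_value in truth.items():
        values = np.asarray(est[key])
        rows[key] = {
            "truth": true_value,
            "mean_estimate": float(values.mean()),
            "bias": float(values.mean() - true_value),
            "coverage": float(np.mean(cover[key])),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["equation", "coefficient"])
    return RecoveryResult(table=table, n_replicates=n_replicates)


def chow_type_one_error(
    config: CohortConfig | None = None,
    n_replicates: int = 500,
    seed: int = 0,
    site: str = "radial",
    alpha: float = 0.05,
    reml: bool = True,
) -> float:
    """Rejection rate of the joint coefficient-equality test when boys and
    girls are generated by one shared process (the null holds by design).

    The full empirical pipeline is used here — pooled standardization reused
    by both strata — because a common scale factor cancels from the
    between-stratum difference.
    """
    config = config or CohortConfig()
    spec = default_model_spec(site)
    rejections = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        table, _ = generate_cohort(config, seed=rep_seed)
        analysis, _ = apply_exclusions(table)
        std = zstandardize(analysis, list(config.variable_calibration))
        fits = {}
        for sex in ("male", "female"):
            sub = CohortTable(
                std.data[std.data["sex"] == sex].reset_index(drop=True), dict(std.metadata)
            )
            fits[sex] = fit_mediated_system(sub, spec, stratum=sex, reml=reml)
        result = chow_test(fits["male"], fits["female"], equation="bone")
        rejections += result.p < alpha
    return rejections / n_replicates


def sobel_bootstrap_sd(
    fitted: SEMResult,
    table: CohortTable,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap SDs of the indirect effects of a fitted system.

    Holding the realized design fixed, both equations' responses are redrawn
    from the fitted model (fixed effects + participant intercepts + residual
    noise at the estimated variances), refitted, and the indirect products
    a*b recomputed. Returns per-modulator bootstrap SD next to the
    delta-method (Sobel) SE of the original fit.
    """
    rng = np.random.default_rng(seed)
    spec = fitted.spec
    bone_eq, muscle_eq = spec.bone_equation, spec.muscle_equation
    if spec.is_stacked:
        raise NotImplementedError("bootstrap check runs on site-specific fits")
    df = table.data

    def refit_equation(eq, fit):
        cc = df.dropna(subset=(eq.outcome,) + eq.regressors)
        X = cc[list(eq.regressors)].astype(float)
        if eq.intercept:
            X = X.copy()
            X.insert(0, "const", 1.0)
        groups = cc["participant_id"].to_numpy()
        mu = X.to_numpy() @ fit.coefficients.to_numpy()
        codes, uniq = pd.factorize(groups, sort=True)
        g_draw = rng.normal(0.0, np.sqrt(fit.var_level2), len(uniq))
        y = mu + g_draw[codes] + rng.normal(0.0, np.sqrt(fit.var_level1), len(cc))
        return fit_random_intercept(y, X, groups)

    draws: dict[str, list[float]] = {w: [] for w in muscle_eq.covariates}
    mediator = bone_eq.mediator
    for _ in range(n_boot):
        bone_fit = refit_equation(bone_eq, fitted.bone_fit)
        muscle_fit = refit_equation(muscle_eq, fitted.muscle_fit)
        b = float(bone_fit.coefficients[mediator])
        for w in muscle_eq.covariates:
            draws[w].append(float(muscle_fit.coefficients[w]) * b)
    rows = {}
    for w in muscle_eq.covariates:
        rows[w] = {
            "bootstrap_sd": float(np.std(draws[w], ddof=1)),
            "sobel_se": fitted.effect(w, "indirect_on_bone").se,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["ratio"] = out["sobel_se"] / out["bootstrap_sd"]
    return out
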