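"""Synthetic mixed-longitudinal cohort generator.

Emulates a three-year pediatric bone study: 180 children measured at 1-4
annual sessions (36/53/72/19 participants respectively, 434 observations),
with the published per-variable means and within/between-participant SDs as
calibration targets, muscle strength generated from the muscle structural
equation (modulators W x Omega + participant effect + session noise) and
bone SOS from the bone equation (mediator x beta1 + modulators Z x Theta +
participant effect + session noise). Structural coefficients are specified
on the standardized (z-score) scale, matching how the analysis reports them;
natural units are recovered by affine mapping.

Calibration is exact in expectation, conditional on the drawn session
counts: variance contributions of the deterministic annual growth trend, the
session jitter and the participant intercept are budgeted against the
configured within/between SDs using the realized design constants (see
``_design_constants``), and the structural residual variances are, by
default, solved per seed so the endogenous variables also hit their targets
(explicit residual SDs override this).

Distributional families: age-like variables are Gaussian with a +1
year/session trend; BMI and PAQ-C are Gaussian; NTX, WAeq, energy intake
and creatinine are lognormal with exactly moment-matched mean and
within/between SDs (these are strictly positive, skewed quantities);
grip/knee/SOS must remain linear-Gaussian for the structural truth to be
exact, so they receive a positivity floor with an analytic mean
compensation (material only for knee extension, whose Gaussian left tail
crosses zero with probability ~1.5%).

Missingness is applied last and is completely at random within its stratum:
grip strength is absent for every observation falling in one designated
season-year (emulating a season when the test was not run), NTX (with
creatinine) is Bernoulli-missing per session, energy intake optionally so.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocessing
from .data_model import (
    EXCLUSION_REASONS,
    FLAG_COLUMN,
    CohortTable,
    config_hash,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VariableMoments:
    """Calibration target for one variable: mean, within-SD, between-SD."""

    mean: float
    sd_within: float
    sd_between: float

    @property
    def sd_total(self) -> float:
        return math.hypot(self.sd_within, self.sd_between)


#: Published summary moments of the study cohort (means, within/between SDs).
DEFAULT_CALIBRATION: dict[str, VariableMoments] = {
    "age": VariableMoments(11.8, 1.0, 1.5),
    "maturity_offset": VariableMoments(-0.9, 0.9, 1.9),
    "radial_sos": VariableMoments(3816.1, 51.4, 86.0),
    "tibial_sos": VariableMoments(3687.4, 49.8, 96.7),
    "grip_strength": VariableMoments(23.4, 3.2, 7.0),
    "knee_extension": VariableMoments(131.5, 22.3, 56.6),
    "ntx_corrected": VariableMoments(539.8, 169.9, 213.7),
    "energy_intake": VariableMoments(1593.4, 297.6, 370.0),
    "waeq": VariableMoments(73.8, 24.8, 32.9),
    "paqc": VariableMoments(0.1, 0.2, 0.2),
    "bmi": VariableMoments(19.5, 1.2, 3.6),
    "bone_age": VariableMoments(12.0, 1.1, 2.2),
}

#: Urinary creatinine is not summarized in the published table; plausible
#: pediatric first-morning values (mmol/L).
CREATININE_MOMENTS = VariableMoments(9.0, 2.0, 3.0)

TREND_VARIABLES = ("age", "maturity_offset", "bone_age")  # advance ~1 yr/session
GAUSSIAN_EXOGENOUS = ("bmi", "paqc")
LOGNORMAL_EXOGENOUS = ("ntx_corrected", "waeq", "energy_intake")

ANALYSIS_VARIABLES = tuple(DEFAULT_CALIBRATION)


@dataclass(frozen=True)
class StructuralCoefficients:
    """True standardized path coefficients of the two-equation system.

    ``bone`` maps modulator name -> direct path on bone SOS, with the key
    ``"mediator"`` for the muscle-strength path; ``muscle`` maps modulator
    name -> path on muscle strength. Defaults are the published total-cohort
    point estimates, shared by both bone sites.
    """

    bone: Mapping[str, float] = field(
        default_factory=lambda: {
            "mediator": 0.288,
            "ntx_corrected": -0.184,
            "paqc": 0.056,
            "maturity_offset": 0.241,
            "bmi": -0.178,
        }
    )
    muscle: Mapping[str, float] = field(
        default_factory=lambda: {
            "maturity_offset": 0.213,
            "bmi": 0.188,
            "bone_age": 0.480,
            "waeq": 0.047,
            "energy_intake": 0.032,
        }
    )


@dataclass(frozen=True)
class ResidualSDs:
    """Explicit structural residual SDs (standardized scale); None = solve
    them so endogenous variables hit their calibrated within/between SDs."""

    muscle_level1: float
    muscle_level2: float
    bone_level1: float
    bone_level2: float


@dataclass(frozen=True)
class Missingness:
    """MCAR missingness: grip by designated calendar wave, NTX/energy by
    per-session Bernoulli rates."""

    grip_wave: int | None = 1  # calendar wave index with no grip testing
    ntx_rate: float = 29.0 / 434.0
    energy_rate: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 180
    #: probability of attending 1, 2, 3 or 4 annual sessions
    session_count_distribution: tuple[float, float, float, float] = (
        36 / 180,
        53 / 180,
        72 / 180,
        19 / 180,
    )
    sex_ratio: float = 92 / 180  # fraction male
    variable_calibration: Mapping[str, VariableMoments] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    structural_coefficients: StructuralCoefficients = field(default_factory=StructuralCoefficients)
    residual_sds: ResidualSDs | None = None
    missingness: Missingness = field(default_factory=Missingness)
    exclusion_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "diabetes_t1": 6,
            "fracture": 8,
            "sos_undetected": 11,
            "missed_visit": 3,
        }
    )
    #: correlation of each variable's participant-level (between) draw with
    #: the maturity-offset participant draw; everything else is independent
    maturity_loadings: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.90,
            "bone_age": 0.85,
            "bmi": 0.30,
            "energy_intake": 0.25,
            "ntx_corrected": -0.35,
            "creatinine": 0.40,
        }
    )
    cross_outcome_corr_level2: float = 0.5  # grip/knee and radial/tibial participant effects
    cross_outcome_corr_level1: float = 0.3  # session-level residuals across outcomes
    positivity_floor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        p = np.asarray(self.session_count_distribution, dtype=float)
        if p.shape != (4,) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("session_count_distribution must be 4 probabilities summing to 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must lie in [0, 1]")
        for name, mom in self.variable_calibration.items():
            if mom.sd_within < 0 or mom.sd_between < 0:
                raise ConfigError(f"{name}: SDs must be non-negative")
        miss = self.missingness
        for rate in (miss.ntx_rate, miss.energy_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("missingness rates must lie in [0, 1]")
        for key, value in self.exclusion_counts.items():
            if key not in EXCLUSION_REASONS:
                raise ConfigError(f"unknown exclusion reason {key!r}")
            if value < 0:
                raise ConfigError("exclusion counts must be non-negative")
        for coef in list(self.structural_coefficients.bone.values()) + list(
            self.structural_coefficients.muscle.values()
        ):
            if not np.isfinite(coef):
                raise ConfigError("structural coefficients must be finite")
        for rho in list(self.maturity_loadings.values()) + [
            self.cross_outcome_corr_level1,
            self.cross_outcome_corr_level2,
        ]:
            if not -1.0 <= rho <= 1.0:
                raise ConfigError("correlations must lie in [-1, 1]")


@dataclass
class GenerationReport:
    """Realized complete-data moments (via the same decomposition operation
    preprocessing exposes, before missingness and exclusions thin the
    design), missing counts, residual SDs actually used and the seed echo."""

    moments: preprocessing.VarianceDecomposition
    missing_counts: dict[str, int]
    n_observations: int
    n_analysis: int
    n_participants: int
    residual_sds_used: dict[str, float]
    clip_adjustments: dict[str, float]
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "moments": json.loads(self.moments.to_json()),
            "missing_counts": self.missing_counts,
            "n_observations": self.n_observations,
            "n_analysis": self.n_analysis,
            "n_participants": self.n_participants,
            "residual_sds_used": self.residual_sds_used,
            "clip_adjustments": self.clip_adjustments,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# -- design-dependent calibration constants ---------------------------------


def _design_constants(k: np.ndarray) -> dict[str, float]:
    """Constants of the realized unbalanced design used by the exact moment
    budgeting. ``k`` = sessions per participant.

    For a participant with k sessions the annual trend contributes
    k(k^2-1)/12 to the pooled within-SS and (k-1)/2 to the participant mean;
    a session draw with variance v contributes (k-1)v to the within-SS and
    v/k to the participant-mean variance.
    """
    P = len(k)
    N = float(k.sum())
    return {
        "P": float(P),
        "N": N,
        "sum_km1": float(np.sum(k - 1)),
        "mean_inv_k": float(np.mean(1.0 / k)),
        "trend_ss": float(np.sum(k * (k**2 - 1) / 12.0)),
        "trend_obs_mean": float(np.sum(k * (k - 1) / 2.0) / N),
        "trend_offsets": (k - 1) / 2.0,
    }


def _within_budget(target_w2: float, trend_tau: float, dc: dict[str, float]) -> tuple[float, float]:
    """Split a within-variance target between trend and session jitter.

    Returns (tau_eff, jitter_var): if the trend alone overshoots the target
    the trend slope is shrunk to fit exactly (a zero within budget therefore
    freezes repeated values), otherwise the jitter absorbs the remainder.
    """
    if dc["sum_km1"] == 0:
        return trend_tau, target_w2  # no repeats: within moments unidentified
    trend_w = trend_tau**2 * dc["trend_ss"] / dc["N"]
    if trend_tau > 0 and trend_w > target_w2 > 0:
        return trend_tau * math.sqrt(target_w2 / trend_w), 0.0
    if target_w2 <= 0:
        return 0.0, 0.0
    return trend_tau, (dc["N"] * target_w2 - trend_tau**2 * dc["trend_ss"]) / dc["sum_km1"]


def _between_budget(target_b2: float, trend_var_fixed: float, jitter_var: float, dc: dict[str, float]) -> float:
    """Participant-intercept variance hitting the between-SD target exactly.

    E[popvar of participant means] = popvar(fixed trend offsets)
    + (P-1)/P * (sigma_b^2 + jitter_var * mean(1/k)).
    """
    P = dc["P"]
    if P <= 1:
        return max(target_b2, 0.0)
    v = (target_b2 - trend_var_fixed) * P / (P - 1.0) - jitter_var * dc["mean_inv_k"]
    return max(v, 0.0)


def _clip_bias(mean: float, sd: float, floor: float) -> float:
    """E[(floor - X)+] for X ~ N(mean, sd): the mean shift a floor clip adds."""
    if sd <= 0:
        return 0.0
    z = (mean - floor) / sd
    return float(sd * (stats.norm.pdf(z) - z * stats.norm.sf(z)))


def _pooled_within_ss(x: np.ndarray, pidx: np.ndarray, P: int) -> float:
    sums = np.bincount(pidx, weights=x, minlength=P)
    counts = np.bincount(pidx, minlength=P)
    return float(np.sum((x - (sums / counts)[pidx]) ** 2))


def _participant_mean_popvar(x: np.ndarray, pidx: np.ndarray, P: int) -> float:
    sums = np.bincount(pidx, weights=x, minlength=P)
    counts = np.bincount(pidx, minlength=P)
    means = sums / counts
    return float(np.var(means))


# -- generation -------------------------------------------------------------


def generate_cohort(config: CohortConfig, seed: int | None = None) -> tuple[CohortTable, GenerationReport]:
    """Draw one cohort. Deterministic given (config, seed); ``seed=None``
    uses ``config.seed``."""
    config.validate()
    used_seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(used_seed)
    cal = dict(config.variable_calibration)
    P = config.n_participants

    # --- design: session counts, sex, calendar waves -----------------------
    probs = np.asarray(config.session_count_distribution, dtype=float)
    ideal = probs * P
    if np.allclose(ideal, np.round(ideal), atol=1e-9):
        counts = np.repeat(np.arange(1, 5), np.round(ideal).astype(int))
    else:
        counts = rng.choice(np.arange(1, 5), size=P, p=probs)
    k = rng.permutation(counts).astype(int)
    dc = _design_constants(k)
    N = int(dc["N"])

    n_male = int(round(config.sex_ratio * P))
    sex_p = rng.permutation(np.array(["male"] * n_male + ["female"] * (P - n_male)))

    # annual visits on a 7-wave calendar (4 spring, 3 fall); late starts are
    # capped so every participant finishes within the study window
    start_hi = np.minimum(3, 8 - 2 * k)
    start = rng.integers(0, start_hi + 1)

    pidx = np.repeat(np.arange(P), k)  # participant index per observation
    t = np.concatenate([np.arange(1, ki + 1) for ki in k])  # session index
    wave = start[pidx] + 2 * (t - 1)
    season = np.where(wave % 2 == 0, "spring", "fall")

    # --- exogenous variables (standardized scale), correlated through the
    # --- maturity participant draw -----------------------------------------
    z_mat = rng.standard_normal(P)

    def correlated_base(name: str) -> np.ndarray:
        rho = config.maturity_loadings.get(name, 0.0)
        if name == "maturity_offset":
            return z_mat
        return rho * z_mat + math.sqrt(1.0 - rho**2) * rng.standard_normal(P)

    std: dict[str, np.ndarray] = {}  # standardized values per variable
    nat: dict[str, np.ndarray] = {}  # natural-unit values

    for name in TREND_VARIABLES:
        mom = cal[name]
        tau = 1.0 / mom.sd_total if mom.sd_total > 0 else 0.0  # +1 year/session
        w_t = (mom.sd_within / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        b_t = (mom.sd_between / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        tau_eff, jit_var = _within_budget(w_t, tau, dc)
        offsets = tau_eff * dc["trend_offsets"]
        base_var = _between_budget(b_t, float(np.var(offsets)), jit_var, dc)
        base = -tau_eff * dc["trend_obs_mean"] + math.sqrt(base_var) * correlated_base(name)
        x = base[pidx] + tau_eff * (t - 1) + math.sqrt(max(jit_var, 0.0)) * rng.standard_normal(N)
        std[name] = x
        nat[name] = mom.mean + mom.sd_total * x

    for name in GAUSSIAN_EXOGENOUS:
        mom = cal[name]
        w_t = (mom.sd_within / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        b_t = (mom.sd_between / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        _, jit_var = _within_budget(w_t, 0.0, dc)
        base_var = _between_budget(b_t, 0.0, jit_var, dc)
        base = math.sqrt(base_var) * correlated_base(name)
        x = base[pidx] + math.sqrt(max(jit_var, 0.0)) * rng.standard_normal(N)
        std[name] = x
        nat[name] = mom.mean + mom.sd_total * x

    def lognormal_variable(name: str, mom: VariableMoments) -> np.ndarray:
        """Lognormal draw with exactly moment-matched mean and realized
        within/between SDs (log-scale variances solved in closed form)."""
        m = mom.mean
        if m <= 0:
            raise ConfigError(f"{name}: lognormal family needs a positive mean")
        w_eff = (dc["N"] * mom.sd_within**2 / dc["sum_km1"]) if dc["sum_km1"] > 0 else 0.0
        b_eff = _between_budget(mom.sd_between**2, 0.0, w_eff, dc)
        tau_b2 = math.log1p(b_eff / m**2)
        tau_w2 = math.log1p(w_eff / (m**2 + b_eff))
        mu_log = math.log(m) - 0.5 * (tau_b2 + tau_w2)
        B = math.sqrt(tau_b2) * correlated_base(name)
        W = math.sqrt(tau_w2) * rng.standard_normal(N)
        return np.exp(mu_log + B[pidx] + W)

    for name in LOGNORMAL_EXOGENOUS:
        mom = cal[name]
        nat[name] = lognormal_variable(name, mom)
        std[name] = (nat[name] - mom.mean) / mom.sd_total
    creatinine = lognormal_variable("creatinine", CREATININE_MOMENTS)

    # --- endogenous: muscle equation then bone equation --------------------
    coef = config.structural_coefficients
    lp_muscle = np.zeros(N)
    for name, omega in coef.muscle.items():
        lp_muscle += omega * std[name]

    chol2 = np.linalg.cholesky(
        np.array([[1.0, config.cross_outcome_corr_level2], [config.cross_outcome_corr_level2, 1.0]])
    )
    chol1 = np.linalg.cholesky(
        np.array([[1.0, config.cross_outcome_corr_level1], [config.cross_outcome_corr_level1, 1.0]])
    )

    residual_used: dict[str, float] = {}
    clip_adjust: dict[str, float] = {}

    def solve_residuals(lp: np.ndarray, mom: VariableMoments, explicit: tuple[float, float] | None):
        """(level-1 SD, level-2 SD) for one outcome; explicit overrides."""
        if explicit is not None:
            return explicit
        w_t = (mom.sd_within / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        b_t = (mom.sd_between / mom.sd_total) ** 2 if mom.sd_total > 0 else 0.0
        if dc["sum_km1"] > 0:
            e2 = max((dc["N"] * w_t - _pooled_within_ss(lp, pidx, P)) / dc["sum_km1"], 0.0)
        else:
            e2 = w_t
        g2 = _between_budget(b_t, _participant_mean_popvar(lp, pidx, P), e2, dc)
        return math.sqrt(e2), math.sqrt(g2)

    def endogenous_outcome(
        lp: np.ndarray,
        mom: VariableMoments,
        z2: np.ndarray,
        z1: np.ndarray,
        explicit: tuple[float, float] | None,
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """One structural outcome, mapped to natural units with the
        positivity floor applied.

        With explicit residual SDs the outcome is the plain affine map of
        lp + residuals (floored, with the analytic Gaussian mean
        compensation). In auto mode the two residual variances are solved
        by damped fixed point against the realized post-floor within and
        between moments, and the realized mean is recentered exactly, so
        the floor's tail compression (material for knee extension, whose
        Gaussian left tail crosses zero with ~1.5% mass) cannot bias the
        calibration.
        """
        sd1, sd2 = solve_residuals(lp, mom, explicit)
        c_std = (config.positivity_floor - mom.mean) / mom.sd_total if mom.sd_total > 0 else -np.inf

        def construct(mu: float, e_sd: float, g_sd: float) -> np.ndarray:
            return np.maximum(mu + lp + g_sd * z2[pidx] + e_sd * z1, c_std)

        if explicit is not None:
            bias = _clip_bias(mom.mean, mom.sd_total, config.positivity_floor)
            y = construct(0.0, sd1, sd2) - bias / mom.sd_total
        else:
            w_t = (mom.sd_within / mom.sd_total) ** 2
            b_t = (mom.sd_between / mom.sd_total) ** 2
            e2, g2, mu0 = sd1**2, sd2**2, 0.0
            for _ in range(100):
                y = construct(mu0, math.sqrt(e2), math.sqrt(g2))
                w_real = _pooled_within_ss(y, pidx, P) / dc["N"] if dc["sum_km1"] > 0 else w_t
                b_real = _participant_mean_popvar(y, pidx, P)
                dm, dw, db = -y.mean(), w_t - w_real, b_t - b_real
                if abs(dm) < 1e-13 and abs(dw) < 1e-13 and abs(db) < 1e-13:
                    break
                mu0 += dm
                if dc["sum_km1"] > 0:
                    e2 = max(e2 + dw * dc["N"] / dc["sum_km1"], 0.0)
                g2 = max(g2 + db, 0.0)
            y = construct(mu0, math.sqrt(e2), math.sqrt(g2))
            sd1, sd2 = math.sqrt(e2), math.sqrt(g2)
        natural = mom.mean + mom.sd_total * y
        if (natural <= 0).any():  # explicit residual SDs only: floor minus compensation
            natural = np.maximum(natural, 1e-6 * max(mom.mean, 1.0))
        standardized = (natural - mom.mean) / mom.sd_total
        return natural, standardized, sd1, sd2

    rs = config.residual_sds
    explicit_m = (rs.muscle_level1, rs.muscle_level2) if rs is not None else None
    explicit_b = (rs.bone_level1, rs.bone_level2) if rs is not None else None

    z2_m = chol2 @ rng.standard_normal((2, P))
    z1_m = chol1 @ rng.standard_normal((2, N))
    for j, name in enumerate(("grip_strength", "knee_extension")):
        mom = cal[name]
        nat[name], std[name], sd1, sd2 = endogenous_outcome(
            lp_muscle, mom, z2_m[j], z1_m[j], explicit_m
        )
        residual_used[f"{name}_level1"], residual_used[f"{name}_level2"] = sd1, sd2
        clip_adjust[name] = _clip_bias(mom.mean, mom.sd_total, config.positivity_floor)

    z2_b = chol2 @ rng.standard_normal((2, P))
    z1_b = chol1 @ rng.standard_normal((2, N))
    for j, (name, mediator) in enumerate(
        (("radial_sos", "grip_strength"), ("tibial_sos", "knee_extension"))
    ):
        mom = cal[name]
        lp_bone = coef.bone["mediator"] * std[mediator]
        for zname, theta in coef.bone.items():
            if zname != "mediator":
                lp_bone = lp_bone + theta * std[zname]
        nat[name], std[name], sd1, sd2 = endogenous_outcome(
            lp_bone, mom, z2_b[j], z1_b[j], explicit_b
        )
        residual_used[f"{name}_level1"], residual_used[f"{name}_level2"] = sd1, sd2
        clip_adjust[name] = _clip_bias(mom.mean, mom.sd_total, config.positivity_floor)

    # --- assemble table -----------------------------------------------------
    df = pd.DataFrame(
        {
            "participant_id": np.char.add("P", np.char.zfill((pidx + 1).astype(str), 4)),
            "session_index": t,
            "season": season,
            "sex": sex_p[pidx],
        }
    )
    for name in ANALYSIS_VARIABLES:
        df[name] = nat[name]
    df["creatinine"] = creatinine
    df["ntx_raw"] = df["ntx_corrected"] * df["creatinine"]

    # calibration echo: moments of the complete data, before missingness and
    # exclusions thin the design (the calibration targets describe the
    # generative distribution, not any particular observed subset)
    complete = CohortTable(df.copy())
    moments = preprocessing.variance_decomposition(complete, ANALYSIS_VARIABLES)

    # --- missingness (MCAR within stratum), applied last --------------------
    miss = config.missingness
    if miss.grip_wave is not None:
        df.loc[wave == miss.grip_wave, "grip_strength"] = np.nan
    if miss.ntx_rate > 0:
        drop = rng.random(N) < miss.ntx_rate
        df.loc[drop, ["ntx_corrected", "ntx_raw", "creatinine"]] = np.nan
    if miss.energy_rate > 0:
        drop = rng.random(N) < miss.energy_rate
        df.loc[drop, "energy_intake"] = np.nan

    # --- exclusion flags -----------------------------------------------------
    flags = [frozenset()] * N
    total_flags = int(sum(config.exclusion_counts.values()))
    if total_flags > N:
        raise ConfigError("exclusion counts exceed the number of observations")
    if total_flags:
        chosen = rng.choice(N, size=total_flags, replace=False)
        cursor = 0
        for reason in EXCLUSION_REASONS:
            count = int(config.exclusion_counts.get(reason, 0))
            for idx in chosen[cursor : cursor + count]:
                flags[idx] = frozenset({reason})
                if reason == "sos_undetected":
                    df.loc[idx, ["radial_sos", "tibial_sos"]] = np.nan
                elif reason == "missed_visit":
                    df.loc[
                        idx,
                        ["radial_sos", "tibial_sos", "grip_strength", "ntx_corrected", "ntx_raw", "creatinine"],
                    ] = np.nan
            cursor += count
    df[FLAG_COLUMN] = flags

    meta = {
        "source": "synthetic",
        "seed": used_seed,
        "config_hash": config_hash(dataclasses.asdict(config)),
    }
    table = CohortTable(df, meta)

    analysis, _ = preprocessing.apply_exclusions(table)
    missing_counts = {
        name: int(analysis.data[name].isna().sum())
        for name in ("grip_strength", "ntx_corrected", "energy_intake")
    }
    report = GenerationReport(
        moments=moments,
        missing_counts=missing_counts,
        n_observations=N,
        n_analysis=analysis.n_observations,
        n_participants=P,
        residual_sds_used=residual_used,
        clip_adjustments=clip_adjust,
        seed=used_seed,
    )
    return table, report


# -- fixtures ---------------------------------------------------------------

#: Strong, well-separated paths and no missingness: a well-conditioned
#: fixture for closed-form and bootstrap oracle tests at very small n.
TINY_COEFFICIENTS = StructuralCoefficients(
    bone={
        "mediator": 0.6,
        "ntx_corrected": -0.3,
        "paqc": 0.1,
        "maturity_offset": 0.3,
        "bmi": -0.2,
    },
    muscle={
        "maturity_offset": 0.4,
        "bmi": 0.2,
        "bone_age": 0.5,
        "waeq": 0.1,
        "energy_intake": 0.05,
    },
)

_NO_EXCLUSIONS = {"diabetes_t1": 0, "fracture": 0, "sos_undetected": 0, "missed_visit": 0}


def fixture_config(name: str) -> CohortConfig:
    """Configuration behind each named fixture (see :func:`make_fixture`)."""
    if name == "tiny":
        # a well-conditioned 16-observation design for closed-form and
        # bootstrap oracles: balanced within/between variance in every
        # covariate (no nearly-unidentified direction at 8 groups),
        # mutually independent covariates, explicit residuals with a
        # dominant participant effect so the two-level structure is
        # clearly present, and strong structural paths
        balanced = {
            name_: VariableMoments(
                mom.mean, mom.sd_total / math.sqrt(2.0), mom.sd_total / math.sqrt(2.0)
            )
            for name_, mom in DEFAULT_CALIBRATION.items()
        }
        return CohortConfig(
            n_participants=8,
            session_count_distribution=(0.0, 1.0, 0.0, 0.0),
            variable_calibration=balanced,
            structural_coefficients=TINY_COEFFICIENTS,
            residual_sds=ResidualSDs(
                muscle_level1=0.2, muscle_level2=0.6, bone_level1=0.2, bone_level2=0.6
            ),
            maturity_loadings={},
            missingness=Missingness(grip_wave=None, ntx_rate=0.0),
            exclusion_counts=_NO_EXCLUSIONS,
        )
    if name == "study_scale":
        return CohortConfig()
    if name == "null_effects":
        return CohortConfig(
            structural_coefficients=StructuralCoefficients(
                bone={key: 0.0 for key in StructuralCoefficients().bone},
                muscle={key: 0.0 for key in StructuralCoefficients().muscle},
            )
        )
    raise ValueError(f"unknown fixture {name!r}")


def make_fixture(name: str, seed: int = 0) -> CohortTable:
    """tiny = 8 participants x 2 sessions; study_scale = study defaults;
    null_effects = every structural path zero."""
    table, _ = generate_cohort(fixture_config(name), seed=seed)
    return table
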