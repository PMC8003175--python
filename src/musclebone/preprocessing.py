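"""Exclusion cascade, derived variables, z-scoring and variance decomposition.

Order of play mirrors the analysis pipeline: flagged participant-sessions are
removed first (diabetes, fracture, undetectable SOS, missed second visit, in
that fixed cascade order), bone resorption is expressed per mmol of urinary
creatinine, the Godin leisure-time frequencies collapse to a MET-weighted
weekly score, analysis variables are z-standardized over the pooled
post-exclusion observations, and the within/between-participant variance
decomposition summarizes the two-level structure of every variable.

Numerical conventions (fixed here, logged in output metadata): population
standard deviations (divisor ``n``) everywhere, so a {-1, +1} column is a
fixed point of standardization and the decomposition components are mutually
consistent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import EXCLUSION_REASONS, FLAG_COLUMN, CohortTable, _as_flagset

logger = logging.getLogger(__name__)

DEFAULT_MET_WEIGHTS = (3.0, 5.0, 9.0)  # mild / moderate / strenuous (Godin convention)


class DegenerateScaleError(ValueError):
    """A column with fewer than two distinct values cannot be z-scored."""


# -- exclusion cascade ------------------------------------------------------


@dataclass
class ExclusionLog:
    """Per-reason removal counts; always balances initial = final + removed."""

    initial: int
    final: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def balanced(self) -> bool:
        return self.initial - sum(self.removed.values()) == self.final

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"initial": self.initial, "removed": self.removed, "final": self.final}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def apply_exclusions(table: CohortTable) -> tuple[CohortTable, ExclusionLog]:
    """Drop every record carrying an exclusion flag.

    A record with several flags is removed once and attributed to the first
    reason in the cascade order. Idempotent: the output carries no flags.
    """
    df = table.data
    flags = df[FLAG_COLUMN].map(_as_flagset) if FLAG_COLUMN in df.columns else pd.Series(
        [frozenset()] * len(df), index=df.index
    )
    removed = {reason: 0 for reason in EXCLUSION_REASONS}
    keep = np.ones(len(df), dtype=bool)
    for pos, flagset in enumerate(flags):
        unknown = flagset - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown exclusion flags {sorted(unknown)}")
        for reason in EXCLUSION_REASONS:  # cascade order fixes the attribution
            if reason in flagset:
                removed[reason] += 1
                keep[pos] = False
                break
    out = df.loc[keep].copy()
    out[FLAG_COLUMN] = [frozenset()] * len(out)
    log = ExclusionLog(initial=len(df), final=len(out), removed=removed)
    assert log.balanced
    meta = dict(table.metadata)
    meta["exclusions"] = {"initial": log.initial, "removed": removed, "final": log.final}
    logger.info("apply_exclusions: %d -> %d rows (%s)", log.initial, log.final, removed)
    return CohortTable(out.reset_index(drop=True), meta), log


# -- derived variables ------------------------------------------------------


def correct_ntx(ntx_raw, creatinine):
    """Creatinine-corrected NTX: raw / creatinine, nmol BCE per mmol.

    Null-propagating; a non-null creatinine <= 0 is a domain error. Accepts
    scalars or aligned array-likes.
    """
    raw = np.asarray(ntx_raw, dtype=float)
    cr = np.asarray(creatinine, dtype=float)
    if np.any(~np.isnan(cr) & (cr <= 0)):
        raise ValueError("creatinine must be strictly positive")
    with np.errstate(invalid="ignore"):
        out = raw / cr
    if out.ndim == 0:
        return float(out)
    if isinstance(ntx_raw, pd.Series):
        return pd.Series(out, index=ntx_raw.index, name="ntx_corrected")
    return out


def compute_waeq(mild, moderate, strenuous, met_weights: Sequence[float] = DEFAULT_MET_WEIGHTS):
    """Weekly leisure-activity MET score: weighted sum of weekly frequencies.

    Default weights 3/5/9 (mild/moderate/strenuous) follow the Godin
    instrument convention; they are configurable because the instrument, not
    the analysis, fixes them.
    """
    freq = [np.asarray(f, dtype=float) for f in (mild, moderate, strenuous)]
    for f in freq:
        if np.any(~np.isnan(f) & (f < 0)):
            raise ValueError("activity frequencies must be non-negative")
    if len(met_weights) != 3:
        raise ValueError("met_weights must be a (mild, moderate, strenuous) triple")
    out = sum(w * f for w, f in zip(met_weights, freq))
    return float(out) if np.ndim(out) == 0 else out


# -- standardization --------------------------------------------------------


def zstandardize(
    table: CohortTable,
    variables: Sequence[str],
    params: Mapping[str, Mapping[str, float]] | None = None,
) -> CohortTable:
    """Z-score ``variables`` over the pooled non-null observations.

    Subtracts the pooled mean and divides by the pooled *population* SD
    (divisor n). Nulls stay null. The affine parameters are attached to the
    output metadata under ``"standardization"`` so :func:`back_transform`
    can invert the map, and so stratified fits can reuse a common scaling.
    Passing ``params`` applies a previously computed scaling instead of
    re-estimating (required for between-stratum coefficient comparability).
    """
    df = table.data.copy()
    meta = dict(table.metadata)
    fitted: dict[str, dict[str, float]] = dict(meta.get("standardization", {}))
    for name in variables:
        if name not in df.columns:
            raise KeyError(f"variable {name!r} not in table")
        col = df[name].astype(float)
        if params is not None and name in params:
            mean, sd = float(params[name]["mean"]), float(params[name]["sd"])
        else:
            values = col.dropna()
            if values.nunique() < 2:
                raise DegenerateScaleError(f"{name}: fewer than two distinct non-null values")
            mean = float(values.mean())
            sd = float(values.std(ddof=0))
        df[name] = (col - mean) / sd
        fitted[name] = {"mean": mean, "sd": sd}
    meta["standardization"] = fitted
    meta["standardization_convention"] = "population SD (divisor n), pooled post-exclusion observations"
    return CohortTable(df, meta)


def back_transform(table: CohortTable, variables: Sequence[str] | None = None) -> CohortTable:
    """Invert :func:`zstandardize` using the metadata affine parameters."""
    fitted = table.metadata.get("standardization")
    if not fitted:
        raise ValueError("table carries no standardization parameters")
    names = list(variables) if variables is not None else list(fitted)
    df = table.data.copy()
    meta = dict(table.metadata)
    remaining = dict(fitted)
    for name in names:
        p = remaining.pop(name)
        df[name] = df[name] * p["sd"] + p["mean"]
    meta["standardization"] = remaining
    return CohortTable(df, meta)


# -- within / between variance decomposition --------------------------------


@dataclass
class VarianceDecomposition:
    """Per-variable mean and total / within / between-participant SDs.

    ``sd_between`` is the population SD of participant means; ``sd_within``
    pools squared deviations from each participant's own mean over all
    observations (single-session participants contribute zero deviations).
    """

    table: pd.DataFrame  # index = variable; columns mean, sd_total, sd_within, sd_between

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variable")

    def to_json(self, path=None) -> str:
        text = json.dumps(self.table.round(10).to_dict(orient="index"), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


def variance_decomposition(table: CohortTable, variables: Sequence[str]) -> VarianceDecomposition:
    df = table.data
    rows = {}
    for name in variables:
        sub = df[["participant_id", name]].dropna()
        if sub.empty:
            raise ValueError(f"{name}: no non-null observations")
        x = sub[name].to_numpy(dtype=float)
        mean = x.mean()
        sd_total = x.std(ddof=0)
        pmeans = sub.groupby("participant_id", sort=False)[name].transform("mean").to_numpy()
        sd_within = float(np.sqrt(np.mean((x - pmeans) ** 2)))
        per_participant = sub.groupby("participant_id", sort=False)[name].mean().to_numpy()
        sd_between = float(per_participant.std(ddof=0)) if len(per_participant) > 1 else 0.0
        rows[name] = {
            "mean": float(mean),
            "sd_total": float(sd_total),
            "sd_within": sd_within,
            "sd_between": sd_between,
        }
    return VarianceDecomposition(pd.DataFrame.from_dict(rows, orient="index"))
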