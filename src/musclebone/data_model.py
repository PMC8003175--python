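"""Longitudinal cohort data contract and declarative model specification.

The cohort is a tidy table with one row per participant-session. Repeated
annual sessions nest within participants, giving the two-level hierarchy
(level 1 = session, level 2 = participant) that every downstream fit assumes.
This module fixes the canonical variable registry, the on-disk CSV dialect,
and the declarative description of the two structural equations:

* the *bone* equation — bone speed of sound (SOS, m/s) regressed on muscle
  strength (the mediator) plus modulators Z;
* the *muscle* equation — muscle strength regressed on modulators W.

External CSV headers are mapped onto the canonical snake-case names through a
schema (a plain ``{file column: canonical name}`` mapping), so I/O dialects
never leak into the model layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("spring", "fall")
SEXES = ("male", "female")

#: Cascade order of the exclusion reasons; the order is part of the contract
#: (a record carrying several flags is attributed to the first one).
EXCLUSION_REASONS = ("diabetes_t1", "fracture", "sos_undetected", "missed_visit")

ID_COLUMNS = ("participant_id", "session_index", "season", "sex")
FLAG_COLUMN = "exclusion_flags"


class SchemaError(ValueError):
    """A mandatory column is missing or the schema mapping is unusable."""


class IntegrityError(ValueError):
    """The table violates a structural invariant (e.g. duplicated sessions)."""


@dataclass(frozen=True)
class VariableDef:
    """Canonical measured variable: name, unit and nullability contract."""

    name: str
    unit: str
    nullable: bool = True
    positive: bool = False  # strictly positive whenever non-null (natural scale)


#: Registry of canonical measured variables. Questionnaire scores (PAQ-C,
#: WAeq) are treated as arbitrary-scale scores, not physical quantities, and
#: are therefore exempt from the positivity contract.
VARIABLES: dict[str, VariableDef] = {
    v.name: v
    for v in (
        VariableDef("age", "years", nullable=False, positive=True),
        VariableDef("radial_sos", "m/s", positive=True),
        VariableDef("tibial_sos", "m/s", positive=True),
        VariableDef("grip_strength", "kg", positive=True),
        VariableDef("knee_extension", "peak torque, as recorded", positive=True),
        VariableDef("ntx_raw", "nmol BCE", positive=True),
        VariableDef("creatinine", "mmol", positive=True),
        VariableDef("ntx_corrected", "nmol BCE/mmol creatinine", positive=True),
        VariableDef("maturity_offset", "years from age of PHV", nullable=False),
        VariableDef("bone_age", "years", nullable=False, positive=True),
        VariableDef("bmi", "kg/m^2", nullable=False, positive=True),
        VariableDef("paqc", "score", nullable=False),
        VariableDef("waeq", "MET-weighted times/week"),
        VariableDef("energy_intake", "kcal/day", positive=True),
    )
}

MEASURE_COLUMNS = tuple(VARIABLES)
ALL_COLUMNS = ID_COLUMNS + MEASURE_COLUMNS + (FLAG_COLUMN,)

#: Virtual outcome/mediator names used by the pooled (stacked two-site) model
#: and the concrete columns they stack.
STACKED_SOURCES: dict[str, tuple[str, str]] = {
    "bone_sos": ("radial_sos", "tibial_sos"),
    "muscle_strength": ("grip_strength", "knee_extension"),
}


@dataclass(frozen=True)
class ObservationRecord:
    """One participant-session row, typed field for field."""

    participant_id: str
    session_index: int
    season: str
    sex: str
    age: float
    maturity_offset: float
    bone_age: float
    bmi: float
    paqc: float
    radial_sos: float | None = None
    tibial_sos: float | None = None
    grip_strength: float | None = None
    knee_extension: float | None = None
    ntx_raw: float | None = None
    creatinine: float | None = None
    ntx_corrected: float | None = None
    waeq: float | None = None
    energy_intake: float | None = None
    exclusion_flags: frozenset[str] = frozenset()

    def to_row(self) -> dict:
        d = {c: getattr(self, c) for c in ID_COLUMNS + MEASURE_COLUMNS}
        d[FLAG_COLUMN] = frozenset(self.exclusion_flags)
        return d


def _as_flagset(value) -> frozenset[str]:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


@dataclass
class CohortTable:
    """A cohort of participant-session observations plus provenance metadata.

    ``data`` holds one row per observation with the canonical columns;
    ``metadata`` carries provenance (source, seed, config hash) and, after
    standardization, the affine back-transformation parameters.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), json.loads(json.dumps(self.metadata)))

    @property
    def n_observations(self) -> int:
        return len(self.data)

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    def to_records(self) -> list[ObservationRecord]:
        out = []
        for _, row in self.data.iterrows():
            kwargs = {c: row[c] for c in ID_COLUMNS}
            for c in MEASURE_COLUMNS:
                v = row.get(c)
                kwargs[c] = None if pd.isna(v) else float(v)
            kwargs["session_index"] = int(row["session_index"])
            kwargs["exclusion_flags"] = _as_flagset(row.get(FLAG_COLUMN))
            out.append(ObservationRecord(**kwargs))
        return out

    @classmethod
    def from_records(cls, records: Iterable[ObservationRecord], metadata: dict | None = None) -> "CohortTable":
        df = pd.DataFrame([r.to_row() for r in records])
        return cls(df.reset_index(drop=True), metadata or {})

    # -- validation ---------------------------------------------------------

    def validate(self, strict: bool = True) -> list[str]:
        """Check the structural invariants; return the list of problems.

        With ``strict=True`` any problem raises :class:`IntegrityError`.
        Columns recorded as standardized in the metadata are exempt from the
        positivity contract (z-scores are signed by construction).
        """
        problems: list[str] = []
        df = self.data
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory identifier columns: {missing}")
        dup = df.duplicated(subset=["participant_id", "session_index"])
        if dup.any():
            problems.append(
                f"duplicate (participant, session) pairs: {df.loc[dup, ['participant_id', 'session_index']].values.tolist()}"
            )
        bad_season = ~df["season"].isin(SEASONS)
        if bad_season.any():
            problems.append(f"unknown season values: {sorted(df.loc[bad_season, 'season'].unique())}")
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            problems.append(f"unknown sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
        if (df["session_index"] < 1).any():
            problems.append("session_index must be >= 1")

        standardized = set(self.metadata.get("standardization", {}))
        for name, var in VARIABLES.items():
            if name not in df.columns or name in standardized:
                continue
            col = df[name]
            if var.positive and (col.dropna() <= 0).any():
                problems.append(f"{name}: non-positive values present")
            if not var.nullable and col.isna().any():
                problems.append(f"{name}: nulls present in a non-nullable column")
        if {"ntx_raw", "creatinine", "ntx_corrected"} <= set(df.columns):
            both = df["ntx_raw"].notna() & df["creatinine"].notna() & df["ntx_corrected"].notna()
            if both.any():
                expect = df.loc[both, "ntx_raw"] / df.loc[both, "creatinine"]
                if not np.allclose(expect, df.loc[both, "ntx_corrected"], rtol=1e-6, atol=1e-9):
                    problems.append("ntx_corrected inconsistent with ntx_raw / creatinine")
        if strict and problems:
            raise IntegrityError("; ".join(problems))
        return problems


# -- CSV input / output -----------------------------------------------------


def _load_schema(schema) -> dict[str, str]:
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = json.load(fh)
    return dict(schema)


def read_cohort(path, schema: Mapping[str, str] | str | Path | None = None) -> CohortTable:
    """Read a cohort CSV, mapping file headers onto canonical names.

    ``schema`` maps file column names to canonical registry names; canonical
    headers pass through unchanged. Unparseable numeric cells become nulls
    (counted and logged); duplicated (participant, session) pairs and missing
    identifier columns are fatal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = _load_schema(schema)
    raw = raw.rename(columns=rename)
    missing = [c for c in ID_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory identifier columns: {missing}")

    df = pd.DataFrame()
    df["participant_id"] = raw["participant_id"].astype(str)
    session = pd.to_numeric(raw["session_index"], errors="coerce")
    if session.isna().any():
        raise SchemaError("session_index contains unparseable values")
    df["session_index"] = session.astype(int)
    df["season"] = raw["season"].str.strip().str.lower()
    df["sex"] = raw["sex"].str.strip().str.lower()

    def parse_cell(s: str) -> float:
        # python float() is correctly rounded, so repr-precision CSVs
        # round-trip bit for bit (pandas' fast parser is 1-ulp lossy)
        if not s:
            return math.nan
        try:
            return float(s)
        except ValueError:
            return math.nan

    n_coerced = 0
    for name in (c for c in raw.columns if c in VARIABLES):  # keep file order
        text = raw[name].str.strip()
        values = text.map(parse_cell)
        coerced = int(((text != "") & values.isna()).sum())
        n_coerced += coerced
        if coerced:
            logger.warning("read_cohort: %d unparseable cell(s) in %s set to null", coerced, name)
        df[name] = values
    if FLAG_COLUMN in raw.columns:
        df[FLAG_COLUMN] = raw[FLAG_COLUMN].map(_as_flagset)
    else:
        df[FLAG_COLUMN] = [frozenset()] * len(raw)

    dup = df.duplicated(subset=["participant_id", "session_index"])
    if dup.any():
        raise IntegrityError(
            f"duplicate (participant, session) pairs in {path}: "
            f"{df.loc[dup, ['participant_id', 'session_index']].values.tolist()}"
        )
    logger.info("read_cohort: %d rows, %d unparseable cells nulled", len(df), n_coerced)
    meta = {"source": "file", "path": str(path), "coerced_nulls": n_coerced}
    return CohortTable(df, meta)


def write_cohort(table: CohortTable, path) -> Path:
    """Write a cohort table as RFC-4180 CSV (UTF-8, header row).

    Floats are written at full ``repr`` precision so a read-back reproduces
    the table bit for bit; exclusion flags serialize as ``;``-joined tokens.
    """
    df = table.data.copy()
    if FLAG_COLUMN in df.columns:
        df[FLAG_COLUMN] = df[FLAG_COLUMN].map(lambda s: ";".join(sorted(_as_flagset(s))))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def config_hash(obj) -> str:
    """Stable sha256 of any JSON-serializable configuration object."""

    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    text = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(text.encode()).hexdigest()


# -- model specification ----------------------------------------------------


@dataclass(frozen=True)
class EquationSpec:
    """One structural equation: outcome, optional mediator, covariates.

    The mediator path is present only in bone equations; the muscle equation
    has ``mediator=None``. ``intercept`` houses the constant term.
    """

    outcome: str
    covariates: tuple[str, ...]
    mediator: str | None = None
    intercept: bool = True

    def __post_init__(self):
        if not self.covariates:
            raise ValueError("covariates must be non-empty")
        if self.mediator is not None and self.mediator in self.covariates:
            raise ValueError("mediator must not also be listed among covariates")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates")

    @property
    def regressors(self) -> tuple[str, ...]:
        med = (self.mediator,) if self.mediator else ()
        return med + self.covariates


@dataclass(frozen=True)
class ModelSpec:
    """The mediated two-equation system plus grouping/stratification roles."""

    bone_equation: EquationSpec
    muscle_equation: EquationSpec
    grouping: str = "participant_id"
    stratify_by: str | None = None

    def __post_init__(self):
        if self.bone_equation.mediator is None:
            raise ValueError("bone equation must carry a mediator path")
        if self.bone_equation.mediator != self.muscle_equation.outcome:
            raise ValueError("bone mediator must equal the muscle-equation outcome")

    @property
    def is_stacked(self) -> bool:
        return self.bone_equation.outcome in STACKED_SOURCES

    def required_columns(self) -> set[str]:
        cols = {self.grouping}
        if self.stratify_by:
            cols.add(self.stratify_by)
        for eq in (self.bone_equation, self.muscle_equation):
            for name in (eq.outcome,) + eq.regressors:
                cols.update(STACKED_SOURCES.get(name, (name,)))
        return cols

    def validate_against(self, table: CohortTable) -> None:
        missing = sorted(self.required_columns() - set(table.data.columns))
        if missing:
            raise SchemaError(f"model variables absent from table: {missing}")


BONE_COVARIATES = ("ntx_corrected", "paqc", "maturity_offset", "bmi")
MUSCLE_COVARIATES = ("maturity_offset", "bmi", "bone_age", "waeq", "energy_intake")

SITES = ("radial", "tibial", "pooled")
SITE_MEDIATORS = {
    "radial": "grip_strength",
    "tibial": "knee_extension",
    "pooled": "muscle_strength",
}
SITE_OUTCOMES = {"radial": "radial_sos", "tibial": "tibial_sos", "pooled": "bone_sos"}


def default_model_spec(site: str) -> ModelSpec:
    """The published model for a site: grip mediates radial SOS, knee
    extension mediates tibial SOS, and the pooled model stacks both sites
    with a site-matched mediator. PAQ-C enters the bone equation, WAeq the
    muscle equation; bone age appears only in the muscle equation.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    mediator = SITE_MEDIATORS[site]
    bone = EquationSpec(outcome=SITE_OUTCOMES[site], covariates=BONE_COVARIATES, mediator=mediator)
    muscle = EquationSpec(outcome=mediator, covariates=MUSCLE_COVARIATES)
    return ModelSpec(bone_equation=bone, muscle_equation=muscle)
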