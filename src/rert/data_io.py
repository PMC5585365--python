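"""Cohort data model and CSV/schema input-output.

A cohort is a patient-level table of mixed quantitative and categorical
preoperative covariates, a binary outcome (1 = advanced surgical stage),
and a non-missing stratum label per row (histotype).  Categorical values
are stored as level indices after load; missing values are a ``NaN`` in
the numeric covariate matrix.  The outcome and the stratum may never be
missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

QUANTITATIVE = "quantitative"
BINARY = "binary"
ORDERED = "ordered-categorical"
NOMINAL = "nominal-categorical"

_KINDS = (QUANTITATIVE, BINARY, ORDERED, NOMINAL)
_CATEGORICAL_KINDS = (BINARY, ORDERED, NOMINAL)

#: cell contents treated as missing on load (case-insensitive)
MISSING_SENTINELS = frozenset({"", "na", "nan"})


class SchemaError(ValueError):
    """A column or covariate declaration is absent or inconsistent."""


class InputDataError(ValueError):
    """The input file itself is unusable (empty, malformed header...)."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of a single covariate column.

    Parameters
    ----------
    name : str
        Column name; unique within a schema.
    kind : str
        One of ``quantitative``, ``binary``, ``ordered-categorical``,
        ``nominal-categorical``.
    levels : tuple of str, optional
        Ordered category labels; required for the categorical kinds and
        forbidden for quantitative covariates.
    units : str
        Free-text measurement units (display only).
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind in _CATEGORICAL_KINDS:
            if not self.levels:
                raise SchemaError(f"covariate {self.name!r} ({self.kind}) needs levels")
            if self.kind == BINARY and len(self.levels) != 2:
                raise SchemaError(f"binary covariate {self.name!r} needs exactly 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"covariate {self.name!r} has duplicate levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels:
            raise SchemaError(f"quantitative covariate {self.name!r} cannot have levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind in _CATEGORICAL_KINDS


@dataclass
class Cohort:
    """In-memory cohort: covariate matrix + outcome + stratum.

    ``X`` is an ``(n, p)`` float matrix in schema order; categorical
    covariates hold level indices, missing values are ``NaN``.
    """

    schema: list[CovariateSpec]
    X: np.ndarray
    y: np.ndarray
    stratum: np.ndarray
    outcome_name: str = "outcome"
    stratum_name: str = "stratum"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.stratum = np.asarray(self.stratum, dtype=object)
        n = len(self.y)
        if n < 1:
            raise InputDataError("cohort must contain at least one row")
        if self.X.shape != (n, len(self.schema)):
            raise SchemaError(
                f"covariate matrix shape {self.X.shape} does not match "
                f"{n} rows x {len(self.schema)} covariates"
            )
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate covariate names in schema")
        if not np.isin(self.y, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(self.y, (0, 1)))[0]
            raise ValueError(f"outcome value {self.y[bad]!r} at row {bad} is not 0/1")
        self.y = self.y.astype(np.int8)
        if any(s is None or (isinstance(s, float) and math.isnan(s)) for s in self.stratum):
            raise ValueError("stratum labels may not be missing")
        for j, spec in enumerate(self.schema):
            if spec.is_categorical:
                col = self.X[:, j]
                obs = col[~np.isnan(col)]
                if obs.size and (
                    (obs != np.round(obs)).any()
                    or obs.min() < 0
                    or obs.max() >= len(spec.levels)
                ):
                    raise ValueError(f"covariate {spec.name!r} has out-of-range level index")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return len(self.schema)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schema]

    def col(self, name: str) -> np.ndarray:
        return self.X[:, self.index_of(name)]

    def index_of(self, name: str) -> int:
        for j, s in enumerate(self.schema):
            if s.name == name:
                return j
        raise SchemaError(f"covariate {name!r} not in schema")

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            schema=self.schema,
            X=self.X[idx],
            y=self.y[idx],
            stratum=self.stratum[idx],
            outcome_name=self.outcome_name,
            stratum_name=self.stratum_name,
        )

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("both outcome classes must be present")

    def to_frame(self) -> pd.DataFrame:
        """Decode to a DataFrame with original level labels (missing -> NA)."""
        data: dict[str, object] = {}
        for j, spec in enumerate(self.schema):
            col = self.X[:, j]
            if spec.is_categorical:
                labels = np.array(spec.levels, dtype=object)
                out = np.full(self.n, None, dtype=object)
                obs = ~np.isnan(col)
                out[obs] = labels[col[obs].astype(int)]
                data[spec.name] = out
            else:
                data[spec.name] = col
        data[self.outcome_name] = self.y.astype(int)
        data[self.stratum_name] = self.stratum
        return pd.DataFrame(data)


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_SENTINELS


def load_cohort(
    path,
    schema: list[CovariateSpec],
    outcome_name: str,
    stratum_name: str,
    outcome_map: dict[str, int] | None = None,
) -> Cohort:
    """Read a CSV file into a :class:`Cohort`.

    Columns are matched by name, not position.  Unparseable cells and the
    sentinels empty/``NA``/``NaN`` (case-insensitive) become missing.  The
    outcome is mapped through ``outcome_map`` (default identity on "0"/"1");
    it is never inferred from the data.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputDataError(f"{path}: empty input file") from exc
    if raw.shape[0] == 0:
        raise InputDataError(f"{path}: no data rows")
    if outcome_name not in raw.columns:
        raise SchemaError(f"outcome column {outcome_name!r} not in {list(raw.columns)}")
    if stratum_name not in raw.columns:
        raise SchemaError(f"stratum column {stratum_name!r} not in {list(raw.columns)}")
    for spec in schema:
        if spec.name not in raw.columns:
            raise SchemaError(f"covariate column {spec.name!r} missing from file")

    n = raw.shape[0]
    X = np.full((n, len(schema)), np.nan)
    for j, spec in enumerate(schema):
        cells = raw[spec.name].tolist()
        if spec.is_categorical:
            lookup = {lv: float(k) for k, lv in enumerate(spec.levels)}
            for i, cell in enumerate(cells):
                if _is_missing(cell):
                    continue
                val = lookup.get(cell.strip())
                if val is None:
                    raise ValueError(
                        f"row {i}, column {spec.name!r}: {cell!r} is not one of "
                        f"{list(spec.levels)}"
                    )
                X[i, j] = val
        else:
            for i, cell in enumerate(cells):
                if _is_missing(cell):
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    continue  # unparseable -> missing
                if math.isfinite(v):
                    X[i, j] = v

    if outcome_map is None:
        outcome_map = {"0": 0, "1": 1}
    y = np.empty(n, dtype=np.int8)
    for i, cell in enumerate(raw[outcome_name].tolist()):
        key = cell.strip()
        if key not in outcome_map:
            raise ValueError(f"row {i}, column {outcome_name!r}: unmapped outcome {cell!r}")
        val = outcome_map[key]
        if val not in (0, 1):
            raise ValueError(
                f"row {i}, column {outcome_name!r}: outcome maps to {val!r}, not 0/1"
            )
        y[i] = val

    stratum = np.array([c.strip() for c in raw[stratum_name].tolist()], dtype=object)
    for i, s in enumerate(stratum):
        if _is_missing(s):
            raise ValueError(f"row {i}: missing stratum label")

    return Cohort(schema, X, y, stratum, outcome_name, stratum_name)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV; missing cells become empty strings."""
    frame = cohort.to_frame()
    for spec in cohort.schema:
        if not spec.is_categorical:
            # plain repr keeps the round trip value-exact
            frame[spec.name] = [
                "" if np.isnan(v) else repr(float(v)) for v in frame[spec.name]
            ]
    frame.fillna("").to_csv(path, index=False)


def summarize_missingness(cohort: Cohort) -> dict[str, int]:
    """Missing-value count per covariate (outcome and stratum are never missing)."""
    return {
        spec.name: int(np.isnan(cohort.X[:, j]).sum())
        for j, spec in enumerate(cohort.schema)
    }


@dataclass
class SchemaConfig:
    """Parsed schema file: covariate specs plus outcome/stratum declarations."""

    covariates: list[CovariateSpec]
    outcome_name: str
    outcome_map: dict[str, int]
    stratum_name: str


def load_schema(path) -> SchemaConfig:
    """Read a YAML schema config.

    Expected layout::

        covariates:
          he4: {kind: quantitative, units: "pmol/L"}
          grading: {kind: ordered-categorical, levels: [G1, G2, G3]}
        outcome: {name: stage, map: {"I": 0, ">I": 1}}
        stratum: histotype
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "covariates" not in doc:
        raise SchemaError(f"{path}: schema file needs a 'covariates' mapping")
    specs = []
    for name, entry in doc["covariates"].items():
        entry = entry or {}
        specs.append(
            CovariateSpec(
                name=name,
                kind=entry.get("kind", QUANTITATIVE),
                levels=tuple(str(l) for l in entry["levels"]) if "levels" in entry else None,
                units=str(entry.get("units", "")),
            )
        )
    outcome = doc.get("outcome", {})
    if not outcome.get("name"):
        raise SchemaError(f"{path}: schema file needs outcome.name")
    omap = {str(k): int(v) for k, v in (outcome.get("map") or {"0": 0, "1": 1}).items()}
    stratum = doc.get("stratum")
    if not stratum:
        raise SchemaError(f"{path}: schema file needs a stratum column name")
    return SchemaConfig(specs, str(outcome["name"]), omap, str(stratum))


def dump_schema(config: SchemaConfig, path) -> None:
    """Write a :class:`SchemaConfig` as YAML (inverse of :func:`load_schema`)."""
    doc: dict = {"covariates": {}}
    for spec in config.covariates:
        entry: dict = {"kind": spec.kind}
        if spec.levels:
            entry["levels"] = list(spec.levels)
        if spec.units:
            entry["units"] = spec.units
        doc["covariates"][spec.name] = entry
    doc["outcome"] = {"name": config.outcome_name, "map": config.outcome_map}
    doc["stratum"] = config.stratum_name
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
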