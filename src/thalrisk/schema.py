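"""Survey-cohort schema, validation, encoding, and CSV I/O.

The default schema mirrors the 16-item structured survey used for
thalassemia risk assessment in pregnant women: demographics (age, BMI,
parity), hereditary flags (family history, genetic marker, known carrier
status), socioeconomic context (status, education, residence) and the
complete-blood-count indices (Hb, Hct, MCV, MCH, MCHC, RDW, RBC count).

``Patient_ID`` and ``Diagnosis`` columns are treated as metadata (ids and
labels respectively), never as model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CohortParseError,
    LevelError,
    MissingnessError,
    SchemaError,
)

#: Cell contents interpreted as an explicit missing marker.
MISSING_TOKENS = {"", "NA"}

ID_COLUMN = "Patient_ID"
LABEL_COLUMN = "Diagnosis"

#: Alternative spellings accepted on read for categorical levels.  The
#: survey instrument declares Yes/No answers but printed records also use
#: 0/1 flags and Carrier/Non-Car. abbreviations.
_LEVEL_ALIASES = {
    "Family_History_Thalassemia": {"1": "Yes", "0": "No", "TRUE": "Yes", "FALSE": "No"},
    "Genetic_Marker_Presence": {"1": "Yes", "0": "No", "TRUE": "Yes", "FALSE": "No"},
    "Carrier_Status": {
        "1": "Carrier",
        "0": "Non-Carrier",
        "YES": "Carrier",
        "NO": "Non-Carrier",
        "NON-CAR.": "Non-Carrier",
        "NON-CAR": "Non-Carrier",
    },
}


@dataclass(frozen=True)
class FeatureSpec:
    """One survey feature: name, kind, physical units, categorical levels."""

    name: str
    kind: str  # numeric | binary | ordinal | nominal
    units: str = ""
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"numeric", "binary", "ordinal", "nominal"}:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary feature {self.name!r} needs exactly 2 levels")
        if self.kind in {"ordinal", "nominal"} and len(self.levels) < 2:
            raise SchemaError(f"{self.kind} feature {self.name!r} needs >=2 levels")

    @property
    def categorical(self) -> bool:
        return self.kind != "numeric"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` with unique names."""

    entries: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def feature(self, name: str) -> FeatureSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise SchemaError(f"feature {name!r} not in schema")

    @property
    def numeric_names(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "numeric"]

    @property
    def categorical_names(self) -> list[str]:
        return [e.name for e in self.entries if e.categorical]


def default_schema() -> FeatureSchema:
    """The 16-feature survey schema with printed units."""
    return FeatureSchema(
        entries=(
            FeatureSpec("Age", "numeric", "years"),
            FeatureSpec("BMI", "numeric", ""),
            FeatureSpec("Hemoglobin_Level", "numeric", "g/dL"),
            FeatureSpec("Family_History_Thalassemia", "binary", levels=("No", "Yes")),
            FeatureSpec("Genetic_Marker_Presence", "binary", levels=("No", "Yes")),
            FeatureSpec("Socioeconomic_Status", "ordinal", levels=("Low", "Middle", "High")),
            FeatureSpec(
                "Education_Level",
                "ordinal",
                levels=(
                    "No formal education",
                    "Primary",
                    "Secondary",
                    "Higher Secondary",
                    "Graduate",
                ),
            ),
            FeatureSpec("Residence", "nominal", levels=("Urban", "Rural")),
            FeatureSpec("Parity", "numeric", "births"),
            FeatureSpec("Carrier_Status", "binary", levels=("Non-Carrier", "Carrier")),
            FeatureSpec("Hct", "numeric", "%"),
            FeatureSpec("MCV", "numeric", "fL"),
            FeatureSpec("MCH", "numeric", "pg"),
            FeatureSpec("MCHC", "numeric", "g/dL"),
            FeatureSpec("RDW", "numeric", "%"),
            FeatureSpec("RBC_Count", "numeric", "million cells/uL"),
        )
    )


@dataclass
class Cohort:
    """A validated table of survey records.

    ``data`` holds one column per schema feature (canonical level spellings,
    float numerics, NaN for missing).  ``ids``/``labels`` are optional
    per-record metadata; ``extra`` keeps passthrough columns untouched.
    """

    schema: FeatureSchema
    data: pd.DataFrame
    ids: pd.Series | None = None
    labels: pd.Series | None = None
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort data lacks schema columns: {missing}")
        self.data = self.data[self.schema.names]
        for spec in self.schema:
            if spec.categorical:
                col = self.data[spec.name]
                bad = col.dropna()[~col.dropna().isin(spec.levels)]
                if len(bad):
                    raise LevelError(
                        f"{spec.name!r}: value {bad.iloc[0]!r} outside levels "
                        f"{spec.levels} (row {bad.index[0]})"
                    )
            else:
                vals = self.data[spec.name].to_numpy(dtype=float)
                if np.any(np.isinf(vals)):
                    raise CohortParseError(f"{spec.name!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> list[dict]:
        return self.data.to_dict(orient="records")


@dataclass(frozen=True)
class MissingnessReport:
    """Per-feature missing-value counts."""

    counts: dict[str, int]
    total_records: int

    @property
    def any_missing(self) -> bool:
        return any(v > 0 for v in self.counts.values())


@dataclass
class EncodedMatrix:
    """Fully numeric design matrix plus the categorical code maps used."""

    values: pd.DataFrame
    encoding: dict[str, dict[str, object]]  # feature -> {kind, mapping/columns}

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _canonicalize(spec: FeatureSpec, raw: str) -> str:
    aliases = _LEVEL_ALIASES.get(spec.name, {})
    token = raw.strip()
    if token in spec.levels:
        return token
    alias = aliases.get(token.upper())
    if alias is not None:
        return alias
    # case-insensitive match against declared levels
    for lvl in spec.levels:
        if token.lower() == lvl.lower():
            return lvl
    raise LevelError(f"{spec.name!r}: unrecognized level {raw!r}")


def read_cohort(path, schema: FeatureSchema | None = None) -> Cohort:
    """Read a cohort CSV, validating against ``schema`` (default 16-feature).

    Header matching is order-insensitive.  ``Patient_ID`` becomes ``ids``,
    ``Diagnosis`` becomes ``labels``; any other non-schema column is kept in
    ``extra``.  Empty cells and ``NA`` are missing markers.
    """
    schema = schema or default_schema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    data = {}
    for spec in schema:
        col = raw[spec.name]
        out = []
        for i, cell in enumerate(col):
            token = cell.strip()
            if token in MISSING_TOKENS:
                out.append(np.nan)
            elif spec.categorical:
                out.append(_canonicalize(spec, token))
            else:
                try:
                    out.append(float(token))
                except ValueError as exc:
                    raise CohortParseError(
                        f"cannot parse {spec.name!r} value {cell!r} at row {i}"
                    ) from exc
        data[spec.name] = out
    frame = pd.DataFrame(data, columns=schema.names)

    ids = raw[ID_COLUMN].copy() if ID_COLUMN in raw.columns else None
    labels = raw[LABEL_COLUMN].copy() if LABEL_COLUMN in raw.columns else None
    passthrough = [
        c for c in raw.columns if c not in schema.names and c not in (ID_COLUMN, LABEL_COLUMN)
    ]
    extra = raw[passthrough].copy() if passthrough else None
    return Cohort(schema=schema, data=frame, ids=ids, labels=labels, extra=extra)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV; inverse of :func:`read_cohort`."""
    out = pd.DataFrame(index=cohort.data.index)
    if cohort.ids is not None:
        out[ID_COLUMN] = cohort.ids.values
    for spec in cohort.schema:
        col = cohort.data[spec.name]
        if spec.categorical:
            out[spec.name] = col.fillna("NA")
        else:
            # trim trailing zeros so integers round-trip as integers
            out[spec.name] = col.map(
                lambda v: "NA" if pd.isna(v) else (f"{v:g}")
            )
    if cohort.labels is not None:
        out[LABEL_COLUMN] = cohort.labels.values
    if cohort.extra is not None:
        for c in cohort.extra.columns:
            out[c] = cohort.extra[c].values
    out.to_csv(path, index=False)


def missingness(cohort: Cohort) -> MissingnessReport:
    """Count explicit missing markers per feature."""
    counts = {n: int(cohort.data[n].isna().sum()) for n in cohort.schema.names}
    return MissingnessReport(counts=counts, total_records=len(cohort))


def encode(
    cohort: Cohort,
    *,
    max_missing_fraction: float = 0.0,
) -> EncodedMatrix:
    """Encode a cohort to a numeric matrix.

    Binary features map to 0/1 in level order, ordinal features to
    consecutive integer codes in level order, nominal features to one-hot
    columns ``name=level``, numerics pass through.  The mapping used is
    recorded so categorical values can be decoded exactly.

    No imputation is performed: missingness above ``max_missing_fraction``
    (default 0, i.e. any missing value) raises :class:`MissingnessError`.
    """
    report = missingness(cohort)
    if len(cohort) > 0:
        frac = max(report.counts.values()) / len(cohort)
        if frac > max_missing_fraction:
            worst = max(report.counts, key=report.counts.get)
            raise MissingnessError(
                f"feature {worst!r} has {report.counts[worst]} missing values "
                f"(fraction {frac:.3f} > allowed {max_missing_fraction})"
            )

    cols: dict[str, np.ndarray] = {}
    encoding: dict[str, dict[str, object]] = {}
    for spec in cohort.schema:
        col = cohort.data[spec.name]
        if spec.kind == "numeric":
            cols[spec.name] = col.to_numpy(dtype=float)
            encoding[spec.name] = {"kind": "numeric"}
        elif spec.kind in {"binary", "ordinal"}:
            mapping = {lvl: i for i, lvl in enumerate(spec.levels)}
            cols[spec.name] = col.map(mapping).to_numpy(dtype=float)
            encoding[spec.name] = {"kind": spec.kind, "mapping": mapping}
        else:  # nominal -> one-hot
            onehot_cols = []
            for lvl in spec.levels:
                cname = f"{spec.name}={lvl}"
                cols[cname] = (col == lvl).to_numpy(dtype=float)
                onehot_cols.append(cname)
            encoding[spec.name] = {
                "kind": "nominal",
                "columns": onehot_cols,
                "levels": list(spec.levels),
            }
    values = pd.DataFrame(cols)
    return EncodedMatrix(values=values, encoding=encoding)


def decode(matrix: EncodedMatrix, schema: FeatureSchema) -> pd.DataFrame:
    """Invert :func:`encode` for categorical columns via the recorded map."""
    out = {}
    for spec in schema:
        enc = matrix.encoding[spec.name]
        if enc["kind"] == "numeric":
            out[spec.name] = matrix.values[spec.name].to_numpy()
        elif enc["kind"] in {"binary", "ordinal"}:
            inverse = {v: k for k, v in enc["mapping"].items()}
            out[spec.name] = matrix.values[spec.name].map(inverse).to_numpy()
        else:
            sub = matrix.values[enc["columns"]].to_numpy()
            idx = sub.argmax(axis=1)
            levels = np.asarray(enc["levels"], dtype=object)
            out[spec.name] = levels[idx]
    return pd.DataFrame(out, columns=schema.names)
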