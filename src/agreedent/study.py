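"""Data model and I/O for multi-observer, multi-session, multi-tooth rating studies.

A rating study is stored in long format: one record per
(subject, observer, session, tooth, method) holding either an ordinal stage
label, a non-negative continuous measurement, or an NA ("not assessable")
marker.  Analyses run on :class:`RatingMatrix` objects pivoted from the long
table: rows are analysis units — (subject, tooth) pairs — and columns are
observers.

Four assessment systems are built in:

========  ==========================  ===================  ==============
method    categories                  type                 teeth (FDI)
========  ==========================  ===================  ==============
KUL       stages 1–7                  ordinal              38, 48
DEM       stages A–H                  ordinal              18, 28, 38, 48
GHK       stages 1–10                 ordinal              18, 28, 38, 48
I3M       open-apex / length ratio    continuous (>= 0)    38, 48
========  ==========================  ===================  ==============

KUL has no crown-development stages and is defined for mandibular third
molars only; the third molar maturity index I3M is likewise a mandibular
measurement.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    EmptySelectionError,
    IncompleteDesignError,
    SchemaError,
    ValidationError,
)

#: canonical internal missing marker (exposed for writers)
NA_MARKER = "NA"

#: tokens recognised (case-insensitively) as NA on input
_NA_TOKENS = frozenset({"na", "n/a", ""})

ALL_TEETH = frozenset({18, 28, 38, 48})
MAXILLARY = frozenset({18, 28})
MANDIBULAR = frozenset({38, 48})

REQUIRED_COLUMNS = ("subject_id", "observer_id", "session", "tooth", "method", "value")


@dataclass(frozen=True)
class StagingScheme:
    """Ordered category alphabet of one assessment method.

    ``categories`` is empty iff the method is continuous.
    """

    method_id: str
    categories: tuple[str, ...]
    is_continuous: bool
    applicable_teeth: frozenset[int]

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.method_id}: duplicate categories")
        if self.is_continuous != (len(self.categories) == 0):
            raise ValueError(f"{self.method_id}: is_continuous must match empty categories")
        if not self.applicable_teeth <= ALL_TEETH:
            raise ValueError(f"{self.method_id}: teeth must be within {sorted(ALL_TEETH)}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def index(self, label: str) -> int:
        """0-based ordinal position of a stage label."""
        return self.categories.index(label)


KUL = StagingScheme("KUL", tuple(str(i) for i in range(1, 8)), False, frozenset({38, 48}))
DEM = StagingScheme("DEM", tuple("ABCDEFGH"), False, ALL_TEETH)
GHK = StagingScheme("GHK", tuple(str(i) for i in range(1, 11)), False, ALL_TEETH)
I3M = StagingScheme("I3M", (), True, frozenset({38, 48}))

SCHEMES: dict[str, StagingScheme] = {s.method_id: s for s in (KUL, DEM, GHK, I3M)}


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata; age is derived, in decimal years."""

    subject_id: str
    sex: str
    dob: _dt.date
    exposure_date: _dt.date
    chronological_age: float

    def __post_init__(self):
        if self.exposure_date <= self.dob:
            raise ValidationError(
                f"subject {self.subject_id}: exposure date must follow date of birth"
            )
        if not (0 < self.chronological_age < 130):
            raise ValidationError(
                f"subject {self.subject_id}: implausible age {self.chronological_age}"
            )


def chronological_age(dob: _dt.date, exposure: _dt.date) -> float:
    """Decimal age in years at radiograph exposure, day count / 365.25."""
    if exposure <= dob:
        raise ValidationError("exposure date must be strictly after date of birth")
    return (exposure - dob).days / 365.25


class RatingTable:
    """Validated long-format collection of rating records.

    Thin wrapper over a pandas DataFrame with columns
    ``subject_id, observer_id, session, tooth, method, value``.
    Ordinal values are stage-label strings, continuous values floats,
    missing values ``None``.
    """

    def __init__(self, df: pd.DataFrame, schemes: dict[str, StagingScheme] | None = None):
        self.schemes = dict(schemes or SCHEMES)
        self.df = _validate_frame(df, self.schemes)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingTable):
            return NotImplemented
        a = self.df.sort_values(list(REQUIRED_COLUMNS[:5])).reset_index(drop=True)
        b = other.df.sort_values(list(REQUIRED_COLUMNS[:5])).reset_index(drop=True)
        return a.equals(b)

    @property
    def n_na(self) -> int:
        return int(self.df["value"].isna().sum())

    def subjects(self) -> list:
        return sorted(self.df["subject_id"].unique())

    def observers(self) -> list:
        return sorted(self.df["observer_id"].unique())

    def methods(self) -> list[str]:
        return sorted(self.df["method"].unique())


def _normalise_value(raw, scheme: StagingScheme, row_no) -> object:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.lower() in _NA_TOKENS:
        return None
    if scheme.is_continuous:
        try:
            v = float(s)
        except ValueError:
            raise ValidationError(f"row {row_no}: {scheme.method_id} value {raw!r} is not numeric")
        if v < 0:
            raise ValidationError(f"row {row_no}: {scheme.method_id} value {v} is negative")
        return v
    if s not in scheme.categories:
        raise ValidationError(
            f"row {row_no}: stage {s!r} not in {scheme.method_id} alphabet "
            f"{list(scheme.categories)}"
        )
    return s


def _validate_frame(df: pd.DataFrame, schemes: dict[str, StagingScheme]) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["observer_id"] = out["observer_id"].astype(str)
    out["session"] = out["session"].astype(int)
    out["tooth"] = out["tooth"].astype(int)
    out["method"] = out["method"].astype(str)

    bad_session = out.loc[~out["session"].isin((1, 2))]
    if len(bad_session):
        raise ValidationError(f"session must be 1 or 2; offending rows {list(bad_session.index)}")

    errors = []
    values = []
    for row_no, rec in out.iterrows():
        scheme = schemes.get(rec["method"])
        if scheme is None:
            errors.append(f"row {row_no}: unknown method {rec['method']!r}")
            continue
        if rec["tooth"] not in scheme.applicable_teeth:
            errors.append(
                f"row {row_no}: tooth {rec['tooth']} not applicable for {scheme.method_id}"
            )
            continue
        try:
            values.append(_normalise_value(rec["value"], scheme, row_no))
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError("; ".join(errors))
    out["value"] = pd.Series(values, index=out.index, dtype=object)

    key_cols = list(REQUIRED_COLUMNS[:5])
    dup = out.duplicated(subset=key_cols)
    if dup.any():
        raise DuplicateRecordError(
            f"duplicate (subject, observer, session, tooth, method) rows: "
            f"{list(out.index[dup])}"
        )
    return out.reset_index(drop=True)


def read_ratings(
    path,
    schema: dict[str, str] | None = None,
    schemes: dict[str, StagingScheme] | None = None,
) -> RatingTable:
    """Read and validate a long-format rating CSV.

    ``schema`` optionally maps the required column names to the names used
    in the file, e.g. ``{"subject_id": "ID"}``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    return RatingTable(df, schemes)


def write_ratings(table: RatingTable, path) -> None:
    """Serialize a RatingTable back to CSV (NA cells written as ``NA``)."""
    df = table.df.copy()
    df["value"] = [
        NA_MARKER if v is None else (format(v, "g") if isinstance(v, float) else v)
        for v in df["value"]
    ]
    df.to_csv(path, index=False)


def read_metadata(path) -> list[SubjectMeta]:
    """Read subject metadata CSV (subject_id, sex, dob, exposure_date)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("subject_id", "sex", "dob", "exposure_date") if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file missing columns: {missing}")
    metas = []
    for _, rec in df.iterrows():
        dob = _dt.date.fromisoformat(rec["dob"])
        exposure = _dt.date.fromisoformat(rec["exposure_date"])
        metas.append(
            SubjectMeta(
                subject_id=str(rec["subject_id"]),
                sex=str(rec["sex"]),
                dob=dob,
                exposure_date=exposure,
                chronological_age=chronological_age(dob, exposure),
            )
        )
    return metas


def write_metadata(metas: list[SubjectMeta], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metas],
            "sex": [m.sex for m in metas],
            "dob": [m.dob.isoformat() for m in metas],
            "exposure_date": [m.exposure_date.isoformat() for m in metas],
            "chronological_age": [round(m.chronological_age, 4) for m in metas],
        }
    ).to_csv(path, index=False)


@dataclass
class RatingMatrix:
    """Units × raters grid of ratings for one method.

    A unit is a (subject, tooth) pair; cells are stage labels (ordinal
    schemes) or floats (continuous), with ``None`` marking NA.  Units with
    fewer than two non-NA cells carry no pairwise-agreement information and
    are listed in :attr:`uninformative_units`.
    """

    unit_ids: list
    rater_ids: list
    cells: np.ndarray  # dtype=object, shape (n_units, n_raters)
    scheme: StagingScheme
    session: int | None = None
    _mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=object)
        if self.cells.shape != (len(self.unit_ids), len(self.rater_ids)):
            raise ValueError("cells shape does not match unit/rater ids")
        self._mask = np.vectorize(lambda v: v is not None)(self.cells) if self.cells.size else (
            np.zeros(self.cells.shape, dtype=bool)
        )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @property
    def notna_mask(self) -> np.ndarray:
        return self._mask

    @property
    def n_observations(self) -> int:
        """Number of non-NA cells."""
        return int(self._mask.sum())

    @property
    def n_na(self) -> int:
        return int(self.cells.size - self._mask.sum())

    @property
    def uninformative_units(self) -> list:
        counts = self._mask.sum(axis=1)
        return [u for u, c in zip(self.unit_ids, counts) if c < 2]

    def counts(self, categories: tuple[str, ...] | None = None) -> np.ndarray:
        """Per-unit category counts r_ik over a category list (default: scheme)."""
        if self.scheme.is_continuous:
            raise ValidationError("counts() is defined for ordinal matrices only")
        cats = tuple(categories) if categories is not None else self.scheme.categories
        pos = {c: j for j, c in enumerate(cats)}
        r = np.zeros((self.n_units, len(cats)), dtype=np.int64)
        for i in range(self.n_units):
            for v in self.cells[i]:
                if v is not None:
                    if v not in pos:
                        raise ValidationError(f"category {v!r} absent from weight alphabet")
                    r[i, pos[v]] += 1
        return r

    def float_values(self) -> np.ndarray:
        """Cells as floats with NaN for NA (continuous schemes)."""
        out = np.full(self.cells.shape, np.nan)
        for i in range(self.n_units):
            for j in range(self.n_raters):
                if self.cells[i, j] is not None:
                    out[i, j] = float(self.cells[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([str(u) for u in self.unit_ids], name="unit")
        return pd.DataFrame(self.cells, index=idx, columns=[str(r) for r in self.rater_ids])


def pivot_to_matrix(
    table: RatingTable,
    method: str,
    teeth=None,
    session: int = 1,
    pooling: str = "overall",
) -> RatingMatrix:
    """Pivot the long table into a units × observers matrix.

    Units are (subject, tooth) pairs stacked across the selected teeth:
    ``overall`` pools every applicable tooth, ``per_jaw`` pools {18, 28} or
    {38, 48} (pass ``teeth`` to pick the jaw), ``per_tooth`` requires a
    single tooth.
    """
    scheme = table.schemes.get(method)
    if scheme is None:
        raise ValidationError(f"unknown method {method!r}")
    if teeth is None:
        if pooling == "per_tooth":
            raise EmptySelectionError("per_tooth pooling requires an explicit tooth")
        teeth = scheme.applicable_teeth
    teeth = frozenset(int(t) for t in teeth)
    if not teeth <= scheme.applicable_teeth:
        raise ValidationError(
            f"teeth {sorted(teeth - scheme.applicable_teeth)} not applicable for {method}"
        )
    if pooling == "per_tooth" and len(teeth) != 1:
        raise ValidationError("per_tooth pooling requires exactly one tooth")
    if pooling == "per_jaw" and not (teeth <= MAXILLARY or teeth <= MANDIBULAR):
        raise ValidationError("per_jaw pooling must not mix jaws")

    sub = table.df[
        (table.df["method"] == method)
        & (table.df["session"] == session)
        & (table.df["tooth"].isin(teeth))
    ]
    if sub.empty:
        raise EmptySelectionError(
            f"no records for method={method}, session={session}, teeth={sorted(teeth)}"
        )
    raters = sorted(sub["observer_id"].unique())
    subjects = sorted(sub["subject_id"].unique())
    units = [(s, t) for t in sorted(teeth) for s in subjects]
    unit_pos = {u: i for i, u in enumerate(units)}
    rater_pos = {r: j for j, r in enumerate(raters)}
    cells = np.full((len(units), len(raters)), None, dtype=object)
    for _, rec in sub.iterrows():
        cells[unit_pos[(rec["subject_id"], rec["tooth"])], rater_pos[rec["observer_id"]]] = rec[
            "value"
        ]
    return RatingMatrix(units, raters, cells, scheme, session=session)


def session_pairs(
    table: RatingTable, observer, method: str, tooth: int
) -> list[tuple[object, object, bool]]:
    """Per-subject (session-1 value, session-2 value, complete) triples.

    ``complete`` is False when either value is NA; downstream agreement
    statistics exclude those pairs but report their count.
    """
    observer = str(observer)
    sub = table.df[
        (table.df["observer_id"] == observer)
        & (table.df["method"] == method)
        & (table.df["tooth"] == int(tooth))
    ]
    if sub.empty:
        raise EmptySelectionError(f"no records for observer {observer}, {method} {tooth}")
    present = set(sub["session"].unique())
    if present != {1, 2}:
        raise IncompleteDesignError(
            f"observer {observer} has sessions {sorted(present)} for {method} {tooth}; need both"
        )
    s1 = sub[sub["session"] == 1].set_index("subject_id")["value"]
    s2 = sub[sub["session"] == 2].set_index("subject_id")["value"]
    common = sorted(set(s1.index) & set(s2.index))
    return [
        (s1[sid], s2[sid], s1[sid] is not None and s2[sid] is not None) for sid in common
    ]
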