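"""Long-format clinical tables: reading, validation and time-windowing.

The universal input is the long ("tall") tabular dialect used for pooled
ALS clinical records: one row per measurement, with columns
``subject_id, feature_name, value, delta_days``.  ``delta_days`` is the
day of the measurement relative to the onset of clinical records (trial
onset or first clinic visit).  Values are kept verbatim as text and
coerced per a feature dictionary at use time, because continuous and
categorical features share the single value column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "TimeWindow",
    "EARLY_WINDOW",
    "OUTCOME_WINDOW",
    "FeatureDictionary",
    "ClinicalTable",
    "read_clinical_table",
    "write_clinical_table",
    "read_feature_dictionary",
    "write_feature_dictionary",
    "window",
]

COLUMNS = ["subject_id", "feature_name", "value", "delta_days"]


class ValidationError(ValueError):
    """A table violates an invariant (e.g. feature typed inconsistently)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class TimeWindow:
    """Inclusive day range ``[start_day, end_day]`` relative to record onset."""

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValidationError(
                f"invalid window: start_day {self.start_day} > end_day {self.end_day}"
            )

    def contains(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day

    @property
    def tag(self) -> str:
        if (self.start_day, self.end_day) == (0, 91):
            return "0-3m"
        if (self.start_day, self.end_day) == (92, 365):
            return "3-12m"
        return f"{self.start_day}-{self.end_day}d"


#: First three months of records — the prediction input period.
EARLY_WINDOW = TimeWindow(0, 91)
#: Months 3–12 — the outcome period over which progression is measured.
OUTCOME_WINDOW = TimeWindow(92, 365)


@dataclass
class FeatureDictionary:
    """Maps each feature name to its kind (``continuous`` | ``discrete``) and units."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def kind(self, feature_name: str) -> str:
        try:
            return self.entries[feature_name][0]
        except KeyError:
            raise ValidationError(f"feature {feature_name!r} not in dictionary") from None

    def is_continuous(self, feature_name: str) -> bool:
        return self.kind(feature_name) == "continuous"

    def add(self, feature_name: str, kind: str, units: str = "") -> None:
        if kind not in ("continuous", "discrete"):
            raise ValidationError(f"unknown feature kind {kind!r}")
        self.entries[feature_name] = (kind, units)

    def __contains__(self, feature_name: str) -> bool:
        return feature_name in self.entries


@dataclass
class ClinicalTable:
    """Long-format longitudinal records.

    ``df`` has the canonical columns ``subject_id`` (str), ``feature_name``
    (str), ``value`` (str, verbatim) and ``delta_days`` (int).  Records may
    repeat; row order is meaningful only for breaking day ties.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"table missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        self.df["subject_id"] = self.df["subject_id"].astype(str)
        self.df["feature_name"] = self.df["feature_name"].astype(str)
        self.df["value"] = self.df["value"].astype(str)
        self.df["delta_days"] = self.df["delta_days"].astype(int)
        if (self.df["subject_id"] == "").any() or (self.df["feature_name"] == "").any():
            raise ValidationError("empty subject_id or feature_name")

    def __len__(self) -> int:
        return len(self.df)

    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    def features(self) -> list[str]:
        return sorted(self.df["feature_name"].unique())

    def for_subject(self, subject_id: str) -> pd.DataFrame:
        return self.df[self.df["subject_id"] == subject_id]

    def validate_types(self, dictionary: FeatureDictionary) -> None:
        """Check every feature is present in the dictionary and consistently typed."""
        for name, sub in self.df.groupby("feature_name"):
            if name not in dictionary:
                raise ValidationError(f"feature {name!r} not in dictionary")
            if dictionary.is_continuous(str(name)):
                coerced = pd.to_numeric(sub["value"], errors="coerce")
                if coerced.isna().any():
                    bad = sub["value"][coerced.isna()].iloc[0]
                    raise ValidationError(
                        f"non-numeric value {bad!r} for continuous feature {name!r}"
                    )


def read_clinical_table(path: str | Path, dictionary: FeatureDictionary | None = None) -> ClinicalTable:
    """Read a long-format clinical CSV, optionally validating feature types.

    The file must be comma-separated UTF-8 with the header
    ``subject_id,feature_name,value,delta_days``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    delta = pd.to_numeric(df["delta_days"], errors="coerce")
    if delta.isna().any():
        # +2: header line plus 1-based indexing
        line = int(delta.index[delta.isna()][0]) + 2
        raise ParseError(f"{path}: line {line}: non-integer delta_days {df['delta_days'][line - 2]!r}")
    df["delta_days"] = delta.astype(int)
    table = ClinicalTable(df)
    if dictionary is not None:
        table.validate_types(dictionary)
    return table


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_feature_dictionary(path: str | Path) -> FeatureDictionary:
    """Read a ``feature_name,kind,units`` CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("feature_name", "kind"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    d = FeatureDictionary()
    for _, row in df.iterrows():
        d.add(row["feature_name"], row["kind"], row.get("units", ""))
    return d


def write_feature_dictionary(dictionary: FeatureDictionary, path: str | Path) -> None:
    rows = [
        {"feature_name": name, "kind": kind, "units": units}
        for name, (kind, units) in dictionary.entries.items()
    ]
    pd.DataFrame(rows, columns=["feature_name", "kind", "units"]).to_csv(path, index=False)


def window(
    table: ClinicalTable,
    w: TimeWindow,
    subject: str,
    feature: str,
) -> list[tuple[int, str]]:
    """Records of ``feature`` for ``subject`` with day in ``w``, sorted by day.

    Ties in ``delta_days`` preserve input order (stable sort).  Negative
    pre-baseline days are excluded by any window starting at day 0.
    """
    df = table.df
    mask = (
        (df["subject_id"] == subject)
        & (df["feature_name"] == feature)
        & (df["delta_days"] >= w.start_day)
        & (df["delta_days"] <= w.end_day)
    )
    sub = df[mask].sort_values("delta_days", kind="stable")
    return list(zip(sub["delta_days"].tolist(), sub["value"].tolist()))
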