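"""Data model and CSV readers/writers for longitudinal biomarker cohorts.

The pipeline works on long-format blood-test data: one row per
(participant, biomarker, draw date, value), plus a participant table
(sex, age, optional BMI) and an intervention-choice table.  All interchange
is plain CSV with ISO-8601 dates; clinical range rules are YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "MeasurementTable",
    "RangeRule",
    "RangeRuleSet",
    "read_measurements",
    "write_measurements",
    "read_interventions",
    "write_interventions",
    "extract_pairs",
    "load_range_rules",
    "default_range_rules",
]

MEASUREMENT_COLUMNS = ["participant_id", "biomarker", "value", "draw_date"]
PARTICIPANT_COLUMNS = ["participant_id", "sex", "age", "bmi_baseline", "bmi_followup"]
PAIR_COLUMNS = [
    "participant_id",
    "biomarker",
    "baseline_value",
    "followup_value",
    "baseline_date",
    "followup_date",
    "delta",
]

_DEFAULT_RULES_PATH = Path(__file__).parent / "data" / "range_rules.yaml"


class FormatError(ValueError):
    """A file does not match the documented schema (e.g. missing column)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a data-model invariant."""


class ConfigError(ValueError):
    """A configuration file entry is malformed; the message carries its key path."""


@dataclass
class MeasurementTable:
    """Long-format biomarker observations plus the participant roster.

    ``measurements`` has columns participant_id, biomarker, value (float),
    draw_date (datetime64); ``participants`` has participant_id, sex
    ('male'/'female', possibly NA), age, bmi_baseline, bmi_followup.
    Every measurement's participant must appear in the roster, values must be
    finite, and (participant_id, biomarker, draw_date) must be unique.
    """

    measurements: pd.DataFrame
    participants: pd.DataFrame

    def __post_init__(self) -> None:
        self.measurements = _coerce_measurements(self.measurements)
        self.participants = _coerce_participants(self.participants)
        missing = set(self.measurements["participant_id"]) - set(
            self.participants["participant_id"]
        )
        if missing:
            raise ValidationError(
                f"measurements reference unknown participants: {sorted(missing)[:5]}"
            )

    @property
    def biomarkers(self) -> list[str]:
        return sorted(self.measurements["biomarker"].unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.measurements.sort_values(MEASUREMENT_COLUMNS).reset_index(drop=True)
        b = other.measurements.sort_values(MEASUREMENT_COLUMNS).reset_index(drop=True)
        return a.equals(b)


def _coerce_measurements(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurements table missing required column(s): {missing}")
    out = df[MEASUREMENT_COLUMNS].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["biomarker"] = out["biomarker"].astype(str)
    out["value"] = pd.to_numeric(out["value"], errors="raise").astype(float)
    if not np.isfinite(out["value"]).all():
        bad = out.index[~np.isfinite(out["value"])].tolist()[:5]
        raise ValidationError(f"non-finite measurement values at rows {bad}")
    out["draw_date"] = pd.to_datetime(out["draw_date"], format="ISO8601").dt.normalize()
    dup = out.duplicated(subset=["participant_id", "biomarker", "draw_date"], keep=False)
    if dup.any():
        offenders = (
            out.loc[dup, ["participant_id", "biomarker", "draw_date"]]
            .drop_duplicates()
            .head(5)
            .to_dict("records")
        )
        raise ValidationError(
            f"duplicate (participant, biomarker, date) measurements: {offenders}"
        )
    return out.reset_index(drop=True)


def _coerce_participants(df: pd.DataFrame) -> pd.DataFrame:
    if "participant_id" not in df.columns:
        raise FormatError("participants table missing required column: participant_id")
    out = df.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    if out["participant_id"].duplicated().any():
        dups = out.loc[out["participant_id"].duplicated(), "participant_id"].tolist()[:5]
        raise ValidationError(f"duplicate participant_id: {dups}")
    for col in PARTICIPANT_COLUMNS[1:]:
        if col not in out.columns:
            out[col] = np.nan
    sex = out["sex"].astype("string").str.lower()
    ok = sex.isin(["male", "female"]) | sex.isna()
    if not ok.all():
        raise ValidationError(
            f"sex must be 'male'/'female' or empty; got {sorted(sex[~ok].unique())}"
        )
    out["sex"] = sex
    for col in ["age", "bmi_baseline", "bmi_followup"]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out[PARTICIPANT_COLUMNS].reset_index(drop=True)


def read_measurements(
    path: str | Path, participants_path: str | Path | None = None
) -> tuple[MeasurementTable, pd.DataFrame]:
    """Read a measurements CSV (and optional participants CSV).

    Rows whose ``value`` is not numeric or whose date does not parse are
    rejected, not silently dropped: the second return value is a rejection
    report with the 1-based CSV data row number and reason for each bad row.
    A missing required column raises :class:`FormatError`; duplicate
    (participant, biomarker, date) rows raise :class:`ValidationError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")

    values = pd.to_numeric(raw["value"], errors="coerce")
    dates = pd.to_datetime(raw["draw_date"], format="ISO8601", errors="coerce")
    bad_value, bad_date = values.isna().values, dates.isna().values
    reasons = pd.Series(
        np.select(
            [bad_value & bad_date, bad_value, bad_date],
            ["unparseable value; unparseable draw_date", "unparseable value",
             "unparseable draw_date"],
            default="",
        ),
        index=raw.index,
    )
    bad = reasons != ""
    report = pd.DataFrame(
        {
            "row": raw.index[bad] + 1,  # 1-based data-row numbers
            "participant_id": raw.loc[bad, "participant_id"].values,
            "biomarker": raw.loc[bad, "biomarker"].values,
            "reason": reasons[bad].values,
        }
    ).reset_index(drop=True)

    good = raw.loc[~bad].copy()
    good["value"] = values[~bad]
    good["draw_date"] = dates[~bad]

    if participants_path is not None:
        participants = pd.read_csv(participants_path)
    else:
        participants = pd.DataFrame({"participant_id": good["participant_id"].unique()})
    table = MeasurementTable(good, participants)
    return table, report


def write_measurements(table: MeasurementTable, path: str | Path,
                       participants_path: str | Path | None = None) -> None:
    out = table.measurements.copy()
    out["draw_date"] = out["draw_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    if participants_path is not None:
        table.participants.to_csv(participants_path, index=False)


def read_interventions(path: str | Path) -> pd.DataFrame:
    """Read a participant_id,intervention_id CSV; duplicate pairs are invalid."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("participant_id", "intervention_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    df = df[["participant_id", "intervention_id"]]
    if df.duplicated().any():
        raise ValidationError("duplicate (participant_id, intervention_id) pairs")
    return df.reset_index(drop=True)


def write_interventions(choices: pd.DataFrame, path: str | Path) -> None:
    choices[["participant_id", "intervention_id"]].to_csv(path, index=False)


def extract_pairs(
    table: MeasurementTable,
    min_gap_days: int = 30,
    strategy: Literal["earliest", "latest"] = "earliest",
) -> pd.DataFrame:
    """Form baseline/follow-up pairs per (participant, biomarker).

    The baseline is the earliest measurement; the follow-up is the earliest
    (or, with ``strategy='latest'``, the latest) measurement at least
    ``min_gap_days`` whole days after it.  Series with no qualifying
    follow-up are omitted.  Returns a data frame with PAIR_COLUMNS, where
    ``delta = followup_value - baseline_value``.
    """
    if min_gap_days < 0:
        raise ValueError("min_gap_days must be >= 0")
    if strategy not in ("earliest", "latest"):
        raise ValueError(f"unknown follow-up strategy: {strategy!r}")

    df = table.measurements.sort_values(
        ["participant_id", "biomarker", "draw_date"], kind="mergesort"
    ).reset_index(drop=True)
    key = ["participant_id", "biomarker"]
    grouped = df.groupby(key, sort=True)
    df["baseline_date"] = grouped["draw_date"].transform("first")
    df["baseline_value"] = grouped["value"].transform("first")
    df["_rank"] = grouped.cumcount()
    gap = (df["draw_date"] - df["baseline_date"]).dt.days
    candidates = df[(df["_rank"] > 0) & (gap >= min_gap_days)]
    picked = candidates.groupby(key, sort=True)
    follow = picked.head(1) if strategy == "earliest" else picked.tail(1)
    out = pd.DataFrame(
        {
            "participant_id": follow["participant_id"].to_numpy(),
            "biomarker": follow["biomarker"].to_numpy(),
            "baseline_value": follow["baseline_value"].to_numpy(),
            "followup_value": follow["value"].to_numpy(),
            "baseline_date": follow["baseline_date"].to_numpy(),
            "followup_date": follow["draw_date"].to_numpy(),
        }
    )
    out["delta"] = out["followup_value"] - out["baseline_value"]
    return out.reset_index(drop=True)[PAIR_COLUMNS]


@dataclass(frozen=True)
class RangeRule:
    """Clinical out-of-range rule for one biomarker.

    ``direction_of_risk`` is the side on which people are most commonly out
    of range: 'high' means values strictly above the threshold are
    out-of-range, 'low' means strictly below.  Thresholds may differ by sex;
    ``sex_stratified`` marks biomarkers whose change analysis is run per sex.
    """

    biomarker: str
    direction_of_risk: Literal["high", "low"]
    threshold_male: float
    threshold_female: float
    units: str = ""
    sex_stratified: bool = False

    def threshold_for(self, sex: str | None) -> float:
        if self.threshold_male == self.threshold_female:
            return self.threshold_male
        if sex == "male":
            return self.threshold_male
        if sex == "female":
            return self.threshold_female
        raise ValidationError(
            f"{self.biomarker}: sex-specific threshold requires known sex"
        )

    @property
    def sex_specific(self) -> bool:
        return self.threshold_male != self.threshold_female


class RangeRuleSet(Mapping[str, RangeRule]):
    """Per-biomarker range rules; exactly one rule per biomarker."""

    def __init__(self, rules: Iterable[RangeRule]):
        self._rules: dict[str, RangeRule] = {}
        for rule in rules:
            if rule.biomarker in self._rules:
                raise ValidationError(f"duplicate rule for biomarker {rule.biomarker}")
            self._rules[rule.biomarker] = rule

    def __getitem__(self, biomarker: str) -> RangeRule:
        return self._rules[biomarker]

    def __iter__(self):
        return iter(self._rules)

    def __len__(self) -> int:
        return len(self._rules)


def _parse_rule(biomarker: str, entry: Mapping) -> RangeRule:
    keypath = f"range_rules.{biomarker}"
    direction = entry.get("direction")
    if direction not in ("high", "low"):
        raise ConfigError(f"{keypath}.direction: expected 'high' or 'low', got {direction!r}")
    thr = entry.get("threshold")
    if isinstance(thr, Mapping):
        try:
            male, female = float(thr["male"]), float(thr["female"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{keypath}.threshold: need numeric male/female: {exc}") from exc
    else:
        try:
            male = female = float(thr)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{keypath}.threshold: not numeric: {thr!r}") from exc
    return RangeRule(
        biomarker=biomarker,
        direction_of_risk=direction,
        threshold_male=male,
        threshold_female=female,
        units=str(entry.get("units", "")),
        sex_stratified=bool(entry.get("sex_stratified", False)),
    )


def load_range_rules(path: str | Path) -> RangeRuleSet:
    """Load a YAML/JSON range-rule config.

    Schema: ``{biomarker: {direction: high|low, threshold: x | {male, female},
    units: str, sex_stratified: bool}}``.  Malformed entries raise
    :class:`ConfigError` naming the offending key path.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping of biomarker -> rule")
    return RangeRuleSet(_parse_rule(b, entry) for b, entry in data.items())


def default_range_rules() -> RangeRuleSet:
    """The bundled clinical range rules (17 biomarkers, Quest-style cutoffs)."""
    return load_range_rules(_DEFAULT_RULES_PATH)
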