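"""Plausibility filtering: percentile-based outer limits on biomarker values.

Occasional lab-upload anomalies (e.g. a fasting glucose below 20 mg/dL) are
removed by per-biomarker "plausibility cutoffs": the 0.5 and 99.5 percentiles
of a large population reference sample.  A baseline/follow-up pair is dropped
from the analysis of a biomarker iff either endpoint falls strictly outside
the limits; removal is always per-(participant, biomarker), never
whole-participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .io import ConfigError

__all__ = [
    "PlausibilityLimits",
    "DerivationError",
    "derive_limits",
    "apply_limits",
    "load_limits",
    "default_limits",
]

_DEFAULT_LIMITS_PATH = Path(__file__).parent / "data" / "plausibility_limits.yaml"

MIN_REFERENCE_N = 200


class DerivationError(ValueError):
    """Limit derivation refused (too few reference values, or degenerate)."""


@dataclass(frozen=True)
class PlausibilityLimits:
    biomarker: str
    lower: float
    upper: float
    source: Literal["reference_sample", "config"] = "config"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DerivationError(
                f"{self.biomarker}: lower ({self.lower}) must be < upper ({self.upper})"
            )


def derive_limits(
    reference_values: Mapping[str, Iterable[float]],
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    min_n: int = MIN_REFERENCE_N,
) -> tuple[dict[str, PlausibilityLimits], dict[str, str]]:
    """Derive per-biomarker limits as percentiles of a reference sample.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default definition).  Biomarkers with fewer than ``min_n``
    reference values, or whose percentile bounds collapse (lower == upper),
    are refused individually; the second return value maps refused
    biomarkers to the refusal reason while all others proceed.
    """
    limits: dict[str, PlausibilityLimits] = {}
    errors: dict[str, str] = {}
    for biomarker, values in reference_values.items():
        arr = np.asarray(list(values), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < min_n:
            errors[biomarker] = f"only {arr.size} reference values (minimum {min_n})"
            continue
        lo, hi = np.percentile(arr, [lower_pct, upper_pct], method="linear")
        if not lo < hi:
            errors[biomarker] = f"degenerate limits (lower == upper == {lo})"
            continue
        limits[biomarker] = PlausibilityLimits(
            biomarker, float(lo), float(hi), source="reference_sample"
        )
    return limits, errors


def apply_limits(
    pairs: pd.DataFrame, limits: Mapping[str, PlausibilityLimits]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pairs whose baseline OR follow-up is strictly outside the limits.

    Limits are inclusive: a value exactly at a bound is retained.  Biomarkers
    with no limits pass through unfiltered and appear in the report with a
    warning flag.  Returns ``(filtered_pairs, report)`` where the report has
    one row per biomarker: n_removed, n_removed_baseline, n_removed_followup,
    n_retained, unfiltered.
    """
    pairs = pairs.reset_index(drop=True)
    keep = np.ones(len(pairs), dtype=bool)
    records = []
    for biomarker, grp in pairs.groupby("biomarker", sort=True):
        lim = limits.get(biomarker)
        if lim is None:
            records.append((biomarker, 0, 0, 0, len(grp), True))
            continue
        base_bad = (grp["baseline_value"] < lim.lower) | (grp["baseline_value"] > lim.upper)
        foll_bad = (grp["followup_value"] < lim.lower) | (grp["followup_value"] > lim.upper)
        bad = base_bad | foll_bad
        keep[grp.index[bad]] = False
        records.append(
            (biomarker, int(bad.sum()), int(base_bad.sum()), int(foll_bad.sum()),
             int((~bad).sum()), False)
        )
    report = pd.DataFrame(
        records,
        columns=["biomarker", "n_removed", "n_removed_baseline",
                 "n_removed_followup", "n_retained", "unfiltered"],
    )
    return pairs.loc[keep].reset_index(drop=True), report


def load_limits(path: str | Path) -> dict[str, PlausibilityLimits]:
    """Load a ``{biomarker: {lower, upper}}`` YAML/JSON limits config."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must map biomarker -> {{lower, upper}}")
    out = {}
    for biomarker, entry in data.items():
        try:
            out[biomarker] = PlausibilityLimits(
                biomarker, float(entry["lower"]), float(entry["upper"]), source="config"
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"plausibility_limits.{biomarker}: {exc}") from exc
    return out


def default_limits() -> dict[str, PlausibilityLimits]:
    """The bundled wide physiological bounds used by the synthetic presets."""
    return load_limits(_DEFAULT_LIMITS_PATH)
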