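"""Baseline-to-follow-up change testing, overall and in out-of-range subgroups.

For each biomarker a single clinical "direction of risk" defines who is
out-of-range at baseline (strictly beyond the threshold on the risky side,
sex-specific where the rule says so).  Changes are tested with the
two-sided Wilcoxon signed-rank test for paired samples; a designated
seasonal biomarker (vitamin D by default) is first adjusted by subtracting
a regression-estimated summer offset from measurements drawn June-September.
P-values in the out-of-range change table are deliberately not corrected
for multiple tests; only biomarkers with at least ``min_group`` out-of-range
participants are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from .io import RangeRule, RangeRuleSet

__all__ = [
    "SeasonalModel",
    "fit_seasonal_model",
    "apply_seasonal_adjustment",
    "default_seasonal_config",
    "flag_out_of_range",
    "wilcoxon_signed_rank",
    "paired_t_test",
    "out_of_range_change_table",
    "CHANGE_TABLE_COLUMNS",
]

DEFAULT_SUMMER_MONTHS = frozenset({6, 7, 8, 9})

_SEASONAL_PATH = Path(__file__).parent / "data" / "seasonal.yaml"

CHANGE_TABLE_COLUMNS = [
    "biomarker",
    "stratum",
    "group",
    "n",
    "baseline_median",
    "baseline_iqr",
    "followup_median",
    "followup_iqr",
    "baseline_median_raw",
    "followup_median_raw",
    "p_value",
    "improvement_direction",
    "threshold",
]


def default_seasonal_config() -> dict[str, dict]:
    """Bundled seasonal designation: {biomarker: {summer_months, offset}}."""
    data = yaml.safe_load(_SEASONAL_PATH.read_text())
    return {
        b: {"summer_months": frozenset(e["summer_months"]), "offset": float(e["offset"])}
        for b, e in data.items()
    }


@dataclass(frozen=True)
class SeasonalModel:
    """Additive summer offset for one biomarker, estimated by OLS."""

    biomarker: str
    offset_estimate: float
    summer_months: frozenset[int] = DEFAULT_SUMMER_MONTHS
    n_summer: int = 0
    n_other: int = 0


def _is_summer(dates, summer_months: Iterable[int]) -> np.ndarray:
    months = pd.DatetimeIndex(np.asarray(pd.to_datetime(dates))).month
    return np.isin(months, list(summer_months))


def fit_seasonal_model(
    values: pd.Series,
    dates: pd.Series,
    biomarker: str,
    summer_months: Iterable[int] = DEFAULT_SUMMER_MONTHS,
    min_per_season: int = 10,
) -> SeasonalModel:
    """OLS of pooled (baseline + follow-up) values on a binary summer indicator.

    The offset estimate is the coefficient of the summer dummy in
    ``value ~ intercept + summer``.  Requires at least ``min_per_season``
    measurements in each season.
    """
    summer = _is_summer(dates, summer_months).astype(float)
    n_summer, n_other = int(summer.sum()), int((1 - summer).sum())
    if n_summer < min_per_season or n_other < min_per_season:
        raise ValueError(
            f"{biomarker}: need >= {min_per_season} measurements per season "
            f"(got {n_summer} summer, {n_other} non-summer)"
        )
    design = sm.add_constant(summer)
    fit = sm.OLS(np.asarray(values, dtype=float), design).fit()
    return SeasonalModel(
        biomarker=biomarker,
        offset_estimate=float(fit.params[1]),
        summer_months=frozenset(summer_months),
        n_summer=n_summer,
        n_other=n_other,
    )


def apply_seasonal_adjustment(pairs: pd.DataFrame, model: SeasonalModel) -> pd.DataFrame:
    """Subtract the summer offset from summer-dated values of the model's biomarker.

    Both endpoints are adjusted independently (a pair with both tests in
    summer keeps its delta); deltas are recomputed.  Non-summer values and
    other biomarkers are untouched.
    """
    out = pairs.copy()
    mask = out["biomarker"] == model.biomarker
    base_summer = mask & _is_summer(out["baseline_date"], model.summer_months)
    foll_summer = mask & _is_summer(out["followup_date"], model.summer_months)
    out.loc[base_summer, "baseline_value"] -= model.offset_estimate
    out.loc[foll_summer, "followup_value"] -= model.offset_estimate
    out["delta"] = out["followup_value"] - out["baseline_value"]
    return out


def flag_out_of_range(
    pairs: pd.DataFrame, rules: RangeRuleSet, participants: pd.DataFrame
) -> pd.DataFrame:
    """Baseline out-of-range flags per (participant, biomarker) pair.

    Strict inequality past the direction-of-risk threshold; the threshold is
    chosen by sex for sex-specific rules.  Pairs for biomarkers without a
    rule, or sex-specific flagging with unknown sex, get flag NA and an
    ``excluded_reason``.  Row order follows ``pairs``.
    """
    sex_by_pid = participants.set_index("participant_id")["sex"]
    sex = pairs["participant_id"].map(sex_by_pid)
    flags = pd.Series(pd.NA, index=pairs.index, dtype="boolean")
    reason = pd.Series("", index=pairs.index, dtype="string")
    for biomarker, idx in pairs.groupby("biomarker", sort=False).groups.items():
        rule = rules.get(biomarker)
        if rule is None:
            reason[idx] = "no range rule"
            continue
        grp_sex = sex[idx]
        if rule.sex_specific:
            unknown = grp_sex.isna()
            reason[idx[unknown]] = "sex-specific rule, unknown sex"
            idx = idx[~unknown]
            grp_sex = grp_sex[idx]
        thr = np.where(grp_sex == "female", rule.threshold_female, rule.threshold_male)
        baseline = pairs.loc[idx, "baseline_value"].to_numpy()
        if rule.direction_of_risk == "high":
            flags[idx] = baseline > thr
        else:
            flags[idx] = baseline < thr
    out = pairs.copy()
    out["out_of_range"] = flags
    out["excluded_reason"] = reason
    return out


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum under random signs.

    Convolves the distribution of W+ = sum of ranks with positive sign over
    all 2^n equiprobable sign patterns.  Ranks may be tied (half-integer
    average ranks); doubling makes every rank an integer so the distribution
    lives on an exact integer grid.  The null distribution is symmetric
    about sum(ranks)/2, so the two-sided p doubles the smaller tail.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(np.rint(2 * w_plus))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    baseline: np.ndarray,
    followup: np.ndarray,
    exact_threshold: int = 25,
    zero_method: str = "wilcox",
) -> tuple[float, int]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped before ranking (``zero_method='wilcox'``;
    'pratt' keeps them in the ranking).  With effective n <= exact_threshold
    the p-value is exact (signed-rank-sum convolution, valid under ties);
    larger samples use the normal approximation with continuity and tie
    correction.  All differences zero returns ``(1.0, 0)`` — "no change".
    Returns ``(p, n_effective)``.
    """
    diffs = np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)
    if diffs.size < 1:
        raise ValueError("need at least one pair")
    nonzero = diffs != 0
    if not nonzero.any():
        return 1.0, 0
    if zero_method == "wilcox":
        d = diffs[nonzero]
    elif zero_method == "pratt":
        d = diffs
    else:
        raise ValueError(f"unknown zero_method: {zero_method!r}")
    n_eff = int(np.count_nonzero(d))
    if zero_method == "wilcox" and n_eff <= exact_threshold:
        ranks = stats.rankdata(np.abs(d), method="average")
        w_plus = float(ranks[d > 0].sum())
        return _exact_signed_rank_p(ranks, w_plus), n_eff
    res = stats.wilcoxon(
        d, zero_method=zero_method, correction=True, method="approx",
        alternative="two-sided",
    )
    return float(res.pvalue), n_eff


def paired_t_test(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test; returns (mean change, two-sided p).

    Used e.g. for BMI change between enrollment and follow-up.  Zero
    variance of the differences is a degenerate input.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = after - before
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("zero variance of differences: paired t-test undefined")
    t_res = stats.ttest_rel(after, before)
    return float(diffs.mean()), float(t_res.pvalue)


def _iqr(values: pd.Series) -> float:
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q3 - q1)


def out_of_range_change_table(
    pairs: pd.DataFrame,
    rules: RangeRuleSet,
    participants: pd.DataFrame,
    min_group: int = 20,
    seasonal_models: Mapping[str, SeasonalModel] | None = None,
    raw_pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Change table for participants out-of-range at baseline.

    ``pairs`` should already carry any seasonal adjustment (pass the raw,
    unadjusted pairs as ``raw_pairs`` to also report unadjusted medians).
    One row per qualifying (biomarker, stratum): sex-stratified rules
    produce a male and a female row, each needing ``min_group`` members;
    everything else is pooled.  Medians/IQRs are computed on exactly the
    tested pairs; p-values are two-sided Wilcoxon signed-rank, uncorrected.
    Returns ``(table, log)`` where the log lists omitted groups.
    """
    flagged = flag_out_of_range(pairs, rules, participants)
    sex_by_pid = participants.set_index("participant_id")["sex"]
    raw_lookup = None
    if raw_pairs is not None:
        raw_lookup = raw_pairs.set_index(["participant_id", "biomarker"])

    records, log = [], []
    for biomarker in sorted(rules):
        rule = rules[biomarker]
        grp = flagged[(flagged["biomarker"] == biomarker) & (flagged["out_of_range"] == True)]  # noqa: E712
        if rule.sex_stratified:
            strata = [
                (sex, grp[grp["participant_id"].map(sex_by_pid) == sex])
                for sex in ("male", "female")
            ]
        else:
            strata = [("all", grp)]
        for stratum, sub in strata:
            if len(sub) < min_group:
                log.append(
                    f"{biomarker} [{stratum}]: {len(sub)} out-of-range at baseline "
                    f"(minimum {min_group}), omitted"
                )
                continue
            p, _ = wilcoxon_signed_rank(
                sub["baseline_value"].to_numpy(), sub["followup_value"].to_numpy()
            )
            if raw_lookup is not None:
                idx = list(zip(sub["participant_id"], sub["biomarker"]))
                raw_sub = raw_lookup.loc[idx]
                raw_base = float(raw_sub["baseline_value"].median())
                raw_foll = float(raw_sub["followup_value"].median())
            else:
                raw_base = float(sub["baseline_value"].median())
                raw_foll = float(sub["followup_value"].median())
            records.append(
                (
                    biomarker,
                    stratum,
                    "out_of_range",
                    len(sub),
                    float(sub["baseline_value"].median()),
                    _iqr(sub["baseline_value"]),
                    float(sub["followup_value"].median()),
                    _iqr(sub["followup_value"]),
                    raw_base,
                    raw_foll,
                    p,
                    "decrease" if rule.direction_of_risk == "high" else "increase",
                    rule.threshold_male if not rule.sex_specific else np.nan,
                )
            )
    table = pd.DataFrame(records, columns=CHANGE_TABLE_COLUMNS)
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True), log
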