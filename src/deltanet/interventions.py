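"""Association between intervention choice and biomarker improvement.

For a focal biomarker (vitamin D and LDL in practice), participants with a
delta are stratified into improved (any nonzero change opposite the
direction of risk) versus not improved, and for each of the most commonly
chosen interventions a 2x2 contingency table (improved x chose) is tested
with the Pearson chi-square statistic.  P-values come from Monte-Carlo
simulation of the margins-fixed null (multivariate hypergeometric); the
asymptotic chi-square(1 df) p is reported alongside as a cross-check.
Benjamini-Hochberg correction is applied across the scanned family, with
nominal (uncorrected p < 0.05) flags reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import RangeRuleSet
from .network import bh_adjust

__all__ = [
    "ImprovementDefinition",
    "definitions_from_rules",
    "improvement_flags",
    "chi2_monte_carlo",
    "intervention_scan",
    "SCAN_COLUMNS",
]

SCAN_COLUMNS = [
    "biomarker",
    "intervention_id",
    "n_improved_chose",
    "n_improved_not",
    "n_notimproved_chose",
    "n_notimproved_not",
    "chi2",
    "p_mc",
    "p_asymptotic",
    "q",
    "nominal_flag",
]


class UntestableTableError(ValueError):
    """A contingency table with a zero margin cannot be tested."""


@dataclass(frozen=True)
class ImprovementDefinition:
    """What counts as improvement for one biomarker.

    ``increase`` when the direction of risk is low (e.g. vitamin D),
    ``decrease`` when it is high (e.g. LDL).  A delta of exactly zero is
    never improvement.
    """

    biomarker: str
    improvement: Literal["increase", "decrease"]


def definitions_from_rules(
    rules: RangeRuleSet, biomarkers: Sequence[str]
) -> list[ImprovementDefinition]:
    """Improvement directions implied by the range rules' direction of risk."""
    return [
        ImprovementDefinition(
            b, "decrease" if rules[b].direction_of_risk == "high" else "increase"
        )
        for b in biomarkers
    ]


def improvement_flags(
    pairs: pd.DataFrame, definition: ImprovementDefinition
) -> pd.Series:
    """Per-participant improved/not flags for the definition's biomarker.

    Expects seasonal adjustment (if designated) to have been applied to
    ``pairs`` already.  Indexed by participant_id.
    """
    sub = pairs[pairs["biomarker"] == definition.biomarker]
    delta = sub.set_index("participant_id")["delta"]
    if definition.improvement == "increase":
        return delta > 0
    return delta < 0


def chi2_monte_carlo(
    table: np.ndarray, B: int = 10_000, seed: int | np.random.Generator = 0
) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table with a Monte-Carlo p-value.

    The null fixes both margins: simulated tables draw the top-left count
    from the hypergeometric distribution.  ``p_mc = (1 + #{simulated chi2 >=
    observed}) / (B + 1)``; the comparison is made on the integer statistic
    ``|n11*N - r1*c1|`` (chi-square is monotone in it at fixed margins) so
    ties are counted exactly.  Returns ``(chi2, p_mc, p_asymptotic)`` with
    the asymptotic p from chi-square(1 df), no continuity correction.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a nonnegative 2x2 count matrix")
    if B < 1:
        raise ValueError("B must be >= 1")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    n = int(t.sum())
    if min(r1, r2, c1, c2) == 0:
        raise UntestableTableError("zero row or column margin")
    cross = t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]
    chi2 = float(n * cross**2 / (r1 * r2 * c1 * c2))
    p_asym = float(stats.chi2.sf(chi2, df=1))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = abs(int(t[0, 0]) * n - int(r1) * int(c1))
    sim_n11 = rng.hypergeometric(ngood=c1, nbad=c2, nsample=r1, size=B).astype(np.int64)
    t_sim = np.abs(sim_n11 * n - int(r1) * int(c1))
    p_mc = float((1 + np.count_nonzero(t_sim >= t_obs)) / (B + 1))
    return chi2, p_mc, p_asym


def top_interventions(choices: pd.DataFrame, top_k: int = 10) -> list[str]:
    """The ``top_k`` most frequently chosen interventions, ties lexicographic."""
    counts = (
        choices.groupby("intervention_id")["participant_id"].nunique().reset_index()
    )
    counts = counts.sort_values(
        ["participant_id", "intervention_id"], ascending=[False, True], kind="mergesort"
    )
    return counts["intervention_id"].head(top_k).tolist()


def intervention_scan(
    pairs: pd.DataFrame,
    choices: pd.DataFrame,
    definitions: Sequence[ImprovementDefinition],
    top_k: int = 10,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan (biomarker, intervention) combinations for improvement association.

    The analysis population per biomarker is every participant with a delta
    for it (not just those out-of-range); participants with no recorded
    choices count as "did not choose" for every intervention.  Interventions
    are the ``top_k`` most frequently chosen overall.  BH correction is over
    the scanned family of testable tables; ``nominal_flag`` marks
    uncorrected p_mc < alpha.
    """
    rng = np.random.default_rng(seed)
    ranked = top_interventions(choices, top_k=top_k)
    chosen_by: dict[str, set[str]] = {
        iid: set(grp["participant_id"]) for iid, grp in choices.groupby("intervention_id")
    }
    records = []
    for definition in definitions:
        improved = improvement_flags(pairs, definition)
        participants = improved.index.to_numpy()
        for iid in ranked:
            chose = np.array([p in chosen_by.get(iid, set()) for p in participants])
            imp = improved.to_numpy()
            tab = np.array(
                [
                    [int((imp & chose).sum()), int((imp & ~chose).sum())],
                    [int((~imp & chose).sum()), int((~imp & ~chose).sum())],
                ]
            )
            try:
                chi2, p_mc, p_asym = chi2_monte_carlo(tab, B=B, seed=rng)
            except UntestableTableError:
                chi2 = p_mc = p_asym = np.nan
            records.append(
                (
                    definition.biomarker, iid,
                    tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1],
                    chi2, p_mc, p_asym,
                )
            )
    out = pd.DataFrame(records, columns=SCAN_COLUMNS[:9])
    testable = out["p_mc"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_adjust(out.loc[testable, "p_mc"].to_numpy())
    out["q"] = q
    out["nominal_flag"] = out["p_mc"] < alpha
    return out
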