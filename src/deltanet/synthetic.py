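"""Synthetic longitudinal cohorts with known planted structure.

Real cohorts of this kind (two blood draws per person, panel-based
missingness, block-correlated biomarker changes, a seasonal vitamin D
offset, intervention choices that shift specific deltas) are rarely
shareable, so every downstream analysis stage is exercised against
generated cohorts whose ground truth is recorded in a machine-readable
"truth record".

The generative model: baselines are independent normals per biomarker;
deltas are multivariate normal with a block-structured correlation matrix
(within-block Pearson ``r_within``, between-block ``r_between``).  Because
deltas are bivariate normal, the population Spearman correlation implied by
a Pearson correlation r is ``(6/pi) * asin(r/2)`` — tests and recovery
reports compare estimates against this transformed value, not r itself.
Each participant is measured on one of several panels (biomarker subsets);
a summer draw date adds the biomarker's seasonal offset to the measured
value; choosing an intervention adds its planted shift to the target
biomarker's delta.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import MeasurementTable, RangeRuleSet, default_range_rules

__all__ = [
    "BiomarkerSpec",
    "Block",
    "Panel",
    "InterventionSpec",
    "SyntheticConfig",
    "generate_cohort",
    "validate_truth",
    "spearman_from_pearson",
    "preset",
    "PRESETS",
    "block_design",
]

SUMMER_MONTHS = (6, 7, 8, 9)


def spearman_from_pearson(r: float) -> float:
    """Population Spearman correlation of a bivariate normal with Pearson r."""
    return (6.0 / math.pi) * math.asin(r / 2.0)


@dataclass(frozen=True)
class BiomarkerSpec:
    code: str
    baseline_mean: float
    baseline_sd: float
    delta_sd: float
    seasonal_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.delta_sd <= 0:
            raise ValueError(f"{self.code}: baseline_sd and delta_sd must be > 0")


@dataclass(frozen=True)
class Block:
    """A set of biomarkers whose deltas share Pearson correlation r_within."""

    biomarkers: tuple[str, ...]
    r_within: float

    def __post_init__(self) -> None:
        if not -1.0 < self.r_within < 1.0:
            raise ValueError("r_within must lie in (-1, 1)")


@dataclass(frozen=True)
class Panel:
    name: str
    biomarkers: tuple[str, ...]
    weight: float = 1.0


@dataclass(frozen=True)
class InterventionSpec:
    """A choosable intervention, optionally shifting one biomarker's delta.

    ``target`` None (or ``delta_shift`` 0) makes it a null intervention.
    ``base_rate`` is the choice probability for in-range participants; the
    log-odds are boosted by the config's ``oor_choice_boost`` when the
    target biomarker is out of range at baseline.
    """

    intervention_id: str
    target: str | None = None
    delta_shift: float = 0.0
    base_rate: float = 0.1


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic cohort."""

    biomarker_specs: list[BiomarkerSpec]
    blocks: list[Block]
    panels: list[Panel]
    n_participants: int
    r_between: float = 0.0
    summer_fraction: float = 0.33
    female_fraction: float = 0.35
    interventions: list[InterventionSpec] = field(default_factory=list)
    oor_choice_boost: float = 1.0
    range_rules: RangeRuleSet | None = None
    year: int = 2016
    gap_median_days: float = 150.0
    gap_log_sigma: float = 0.5
    bmi_change_mean: float = -0.22
    bmi_change_sd: float = 1.5
    bmi_followup_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [s.code for s in self.biomarker_specs]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate biomarker codes in biomarker_specs")
        in_blocks = [b for blk in self.blocks for b in blk.biomarkers]
        if len(set(in_blocks)) != len(in_blocks):
            raise ValueError("a biomarker appears in more than one block")
        unknown = set(in_blocks) - set(codes)
        if unknown:
            raise ValueError(f"blocks reference unknown biomarkers: {sorted(unknown)}")
        covered = set().union(*(set(p.biomarkers) for p in self.panels)) if self.panels else set()
        if covered != set(codes):
            raise ValueError("panels must cover every biomarker at least once")
        # fail before any sampling if the implied correlation matrix is not PSD
        eigmin = np.linalg.eigvalsh(self.delta_correlation_matrix()).min()
        if eigmin < -1e-8:
            raise ValueError(
                f"implied delta correlation matrix is not PSD (min eigenvalue {eigmin:.3g})"
            )

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.biomarker_specs]

    def block_labels(self) -> dict[str, int]:
        """Biomarker -> block index (unblocked biomarkers get singleton labels)."""
        labels = {}
        for k, blk in enumerate(self.blocks, start=1):
            for b in blk.biomarkers:
                labels[b] = k
        next_label = len(self.blocks) + 1
        for code in self.codes:
            if code not in labels:
                labels[code] = next_label
                next_label += 1
        return labels

    def delta_correlation_matrix(self) -> np.ndarray:
        codes = self.codes
        idx = {c: i for i, c in enumerate(codes)}
        corr = np.full((len(codes), len(codes)), self.r_between)
        for blk in self.blocks:
            ii = [idx[b] for b in blk.biomarkers]
            corr[np.ix_(ii, ii)] = blk.r_within
        np.fill_diagonal(corr, 1.0)
        return corr

    def planted_spearman(self, a: str, b: str) -> float:
        idx = {c: i for i, c in enumerate(self.codes)}
        r = self.delta_correlation_matrix()[idx[a], idx[b]]
        return spearman_from_pearson(float(r))


def _sample_dates(rng: np.random.Generator, n: int, year: int, summer_fraction: float
                  ) -> pd.Series:
    """Calendar dates with P(June-September) == summer_fraction."""
    summer_days = pd.date_range(f"{year}-06-01", f"{year}-09-30", freq="D")
    other_days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D").difference(
        summer_days
    )
    in_summer = rng.random(n) < summer_fraction
    picks_summer = rng.integers(0, len(summer_days), size=n)
    picks_other = rng.integers(0, len(other_days), size=n)
    dates = np.where(
        in_summer, summer_days.values[picks_summer], other_days.values[picks_other]
    )
    return pd.Series(pd.DatetimeIndex(dates))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[MeasurementTable, pd.DataFrame, dict]:
    """Sample a cohort; returns (measurements+roster, choices, truth record).

    Deterministic for a fixed config (the seed lives in the config).  The
    truth record holds the planted block labels, per-pair implied Spearman
    correlations' parameters, seasonal offsets, intervention effects, and
    each participant's panel, for use by :func:`validate_truth` and tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    codes = config.codes
    spec_by_code = {s.code: s for s in config.biomarker_specs}

    pids = [f"P{i:05d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(rng.normal(42, 13, size=n), 18, 80).round(1)
    bmi_base = np.clip(rng.normal(24.5, 3.8, size=n), 16, 45).round(1)
    bmi_foll = (bmi_base + rng.normal(config.bmi_change_mean, config.bmi_change_sd, n)).round(1)
    has_foll_bmi = rng.random(n) < config.bmi_followup_fraction
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": sex,
            "age": age,
            "bmi_baseline": bmi_base,
            "bmi_followup": np.where(has_foll_bmi, bmi_foll, np.nan),
        }
    )

    weights = np.array([p.weight for p in config.panels], dtype=float)
    panel_idx = rng.choice(len(config.panels), size=n, p=weights / weights.sum())

    baseline_dates = _sample_dates(rng, n, config.year, config.summer_fraction)
    gaps = np.clip(
        rng.lognormal(math.log(config.gap_median_days), config.gap_log_sigma, size=n),
        1, 1825,
    ).round()
    followup_dates = baseline_dates + pd.to_timedelta(gaps, unit="D")

    means = np.array([spec_by_code[c].baseline_mean for c in codes])
    base_sds = np.array([spec_by_code[c].baseline_sd for c in codes])
    delta_sds = np.array([spec_by_code[c].delta_sd for c in codes])
    seasonal = np.array([spec_by_code[c].seasonal_offset for c in codes])

    baseline = means + base_sds * rng.standard_normal((n, len(codes)))
    corr = config.delta_correlation_matrix()
    # tiny jitter keeps Cholesky stable for exactly-singular PSD configs
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(codes)))
    delta = (rng.standard_normal((n, len(codes))) @ chol.T) * delta_sds

    base_summer = baseline_dates.dt.month.isin(SUMMER_MONTHS).to_numpy()
    foll_summer = followup_dates.dt.month.isin(SUMMER_MONTHS).to_numpy()
    measured_baseline = baseline + np.outer(base_summer, seasonal)

    # intervention choices: logistic in baseline out-of-range status
    rule_set = config.range_rules
    code_idx = {c: i for i, c in enumerate(codes)}
    choice_rows = []
    shift = np.zeros((n, len(codes)))
    for spec in config.interventions:
        logit = math.log(spec.base_rate / (1 - spec.base_rate))
        boost = np.zeros(n)
        if spec.target is not None and rule_set is not None and spec.target in rule_set:
            rule = rule_set[spec.target]
            j = code_idx[spec.target]
            thr = np.where(sex == "female", rule.threshold_female, rule.threshold_male)
            if rule.direction_of_risk == "high":
                oor = measured_baseline[:, j] > thr
            else:
                oor = measured_baseline[:, j] < thr
            boost = config.oor_choice_boost * oor.astype(float)
        prob = 1.0 / (1.0 + np.exp(-(logit + boost)))
        chose = rng.random(n) < prob
        for pid in np.asarray(pids)[chose]:
            choice_rows.append((pid, spec.intervention_id))
        if spec.target is not None and spec.delta_shift != 0.0:
            shift[chose, code_idx[spec.target]] += spec.delta_shift
    choices = pd.DataFrame(choice_rows, columns=["participant_id", "intervention_id"])

    measured_followup = baseline + delta + shift + np.outer(foll_summer, seasonal)

    rows = []
    for i in range(n):
        panel = config.panels[panel_idx[i]]
        for code in panel.biomarkers:
            j = code_idx[code]
            rows.append((pids[i], code, measured_baseline[i, j], baseline_dates[i]))
            rows.append((pids[i], code, measured_followup[i, j], followup_dates[i]))
    measurements = pd.DataFrame(
        rows, columns=["participant_id", "biomarker", "value", "draw_date"]
    )
    table = MeasurementTable(measurements, participants)

    truth = {
        "seed": config.seed,
        "n_participants": n,
        "biomarkers": codes,
        "block_labels": config.block_labels(),
        "r_within": {str(k): blk.r_within for k, blk in enumerate(config.blocks, start=1)},
        "r_between": config.r_between,
        "planted_spearman_within": {
            str(k): spearman_from_pearson(blk.r_within)
            for k, blk in enumerate(config.blocks, start=1)
        },
        "planted_spearman_between": spearman_from_pearson(config.r_between),
        "seasonal_offsets": {c: spec_by_code[c].seasonal_offset for c in codes
                             if spec_by_code[c].seasonal_offset != 0.0},
        "intervention_effects": {
            s.intervention_id: {"target": s.target, "delta_shift": s.delta_shift}
            for s in config.interventions
        },
        "panel_by_participant": {pids[i]: config.panels[panel_idx[i]].name for i in range(n)},
        "bmi_change_mean": config.bmi_change_mean,
    }
    return table, choices, truth


def validate_truth(
    truth: dict,
    entries: pd.DataFrame | None = None,
    cluster_labels: dict[str, int] | None = None,
    seasonal_estimates: dict[str, float] | None = None,
    scan_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Score analysis outputs against a cohort's planted ground truth.

    Reports, for whichever outputs are supplied: the mean absolute error of
    estimated delta correlations against the planted (normal-theory
    Spearman) values; the adjusted Rand index of cluster labels against
    planted block labels; seasonal-offset estimation errors; and
    detected/undetected status per planted intervention effect (p_mc <
    alpha).  Outputs naming biomarkers outside the truth record raise
    ``ValueError``.
    """
    report: dict = {}
    known = set(truth["biomarkers"])
    labels = truth["block_labels"]

    if entries is not None:
        extra = (set(entries["biomarker_a"]) | set(entries["biomarker_b"])) - known
        if extra:
            raise ValueError(f"correlation entries for unknown biomarkers: {sorted(extra)}")
        errors = []
        for row in entries.itertuples(index=False):
            la, lb = labels[row.biomarker_a], labels[row.biomarker_b]
            if la == lb and str(la) in truth["planted_spearman_within"]:
                planted = truth["planted_spearman_within"][str(la)]
            else:
                planted = truth["planted_spearman_between"]
            errors.append(abs(row.rho - planted))
        report["mean_abs_rho_error"] = float(np.mean(errors)) if errors else float("nan")
        report["n_pairs_scored"] = len(errors)

    if cluster_labels is not None:
        extra = set(cluster_labels) - known
        if extra:
            raise ValueError(f"cluster labels for unknown biomarkers: {sorted(extra)}")
        shared = sorted(cluster_labels)
        report["cluster_ari"] = float(
            adjusted_rand_score(
                [labels[b] for b in shared], [cluster_labels[b] for b in shared]
            )
        )

    if seasonal_estimates is not None:
        report["seasonal_offset_errors"] = {
            b: float(est - truth["seasonal_offsets"].get(b, 0.0))
            for b, est in seasonal_estimates.items()
        }

    if scan_results is not None:
        detected = {}
        for iid, effect in truth["intervention_effects"].items():
            if effect["target"] is None or effect["delta_shift"] == 0.0:
                continue
            hit = scan_results[
                (scan_results["intervention_id"] == iid)
                & (scan_results["biomarker"] == effect["target"])
            ]
            detected[iid] = bool((hit["p_mc"] < alpha).any()) if len(hit) else False
        report["interventions_detected"] = detected

    return report


def save_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# presets

_BASELINES = {
    # code: (baseline_mean, baseline_sd, delta_sd)
    "LDL": (118, 30, 22), "HDL": (54, 14, 9), "CHOL": (195, 35, 25),
    "TRIG": (115, 55, 45), "ALT": (29, 13, 11), "AST": (27, 10, 9),
    "GGT": (25, 14, 10), "CK": (165, 95, 85), "MG": (2.05, 0.2, 0.16),
    "HSCRP": (1.9, 1.5, 1.2), "WBC": (6.0, 1.5, 1.1), "NEUT": (3.5, 1.2, 0.9),
    "LYMPH": (1.9, 0.6, 0.45), "MONO": (0.5, 0.15, 0.12), "FERR": (95, 70, 45),
    "IRON": (95, 30, 26), "TIBC": (330, 50, 38), "TSAT": (28, 10, 8.5),
    "HGB": (14.4, 1.3, 0.8), "GLU": (93, 10, 8), "HBA1C": (5.3, 0.4, 0.3),
    "INS": (8.5, 4.5, 3.8), "VITD": (33, 12, 8), "VITB12": (560, 190, 150),
    "FOL": (15, 6, 5), "TESTO": (480, 210, 120), "FTESTO": (11, 4.5, 3),
    "SHBG": (38, 16, 10), "CORT": (15, 5, 4.5), "RBC": (4.8, 0.45, 0.3),
    "HCT": (43, 4, 2.6), "MCV": (89, 5, 3), "MCHC": (33.4, 1.1, 0.9),
    "PLT": (250, 60, 40), "EOS": (185, 95, 75), "NA": (140, 2.5, 2.2),
    "K": (4.2, 0.35, 0.3), "CA": (9.5, 0.4, 0.35), "ALB": (4.5, 0.3, 0.25),
    "CREA": (0.95, 0.2, 0.13),
}

_BLOCKS = [
    (("LDL", "HDL", "CHOL", "TRIG"), 0.55),
    (("ALT", "AST", "GGT", "CK", "MG"), 0.5),
    (("HSCRP", "WBC", "NEUT", "LYMPH", "MONO"), 0.5),
    (("FERR", "IRON", "TIBC", "TSAT", "HGB"), 0.45),
    (("GLU", "HBA1C", "INS"), 0.4),
    (("VITD", "VITB12", "FOL"), 0.3),
    (("TESTO", "FTESTO", "SHBG", "CORT"), 0.4),
    (("RBC", "HCT", "MCV", "MCHC", "PLT", "EOS"), 0.35),
    (("NA", "K", "CA"), 0.3),
    (("ALB", "CREA"), 0.3),
]

_PANELS = [
    ("ultimate", tuple(_BASELINES), 0.30),   # everything
    ("essentials", ("LDL", "HDL", "CHOL", "TRIG", "GLU", "VITD", "HSCRP", "ALT",
                    "AST", "HGB", "FERR"), 0.16),
    ("performance", ("CK", "MG", "NA", "K", "CA", "CORT", "TESTO", "FTESTO",
                     "SHBG", "HGB", "VITD", "GLU"), 0.14),
    ("metabolism", ("GLU", "HBA1C", "INS", "TRIG", "HDL", "LDL", "CHOL",
                    "ALB", "CREA"), 0.12),
    ("vitality", ("VITD", "VITB12", "FOL", "FERR", "IRON", "TIBC", "TSAT",
                  "HGB", "MCV", "MCHC"), 0.11),
    ("immune", ("WBC", "NEUT", "LYMPH", "MONO", "EOS", "HSCRP", "RBC", "HCT",
                "PLT"), 0.09),
    ("liver", ("ALT", "AST", "GGT", "ALB", "CHOL", "TRIG", "CK"), 0.08),
]

_INTERVENTIONS = [
    # id, target biomarker, planted delta shift, base choice rate
    ("vitd_supplement", "VITD", 8.0, 0.18),
    ("oatmeal", "LDL", -6.0, 0.30),
    ("green_tea", "LDL", -4.0, 0.20),
    ("dairy", "LDL", -2.0, 0.12),
    ("fish_oil", None, 0.0, 0.22),
    ("exercise_more", None, 0.0, 0.25),
    ("sleep_hygiene", None, 0.0, 0.15),
    ("meditation", None, 0.0, 0.10),
    ("vitamin_c", None, 0.0, 0.12),
    ("magnesium_supplement", None, 0.0, 0.08),
]


def _specs(codes, seasonal: dict[str, float]) -> list[BiomarkerSpec]:
    return [
        BiomarkerSpec(c, *_BASELINES[c], seasonal_offset=seasonal.get(c, 0.0))
        for c in codes
    ]


def preset(name: str, seed: int = 0, n_participants: int | None = None) -> SyntheticConfig:
    """Named cohort configurations.

    ``paperlike``: 40 biomarkers on 7 partially overlapping panels,
    ~1000 participants, block-correlated deltas, a +2.5 summer offset on
    vitamin D, and ten choosable interventions (three with planted LDL
    shifts, one with a planted vitamin D shift, six null).
    ``tiny``: 6 biomarkers, 2 blocks, one panel, 50 participants — runs the
    full pipeline in seconds.
    """
    if name == "paperlike":
        codes = list(_BASELINES)
        return SyntheticConfig(
            biomarker_specs=_specs(codes, {"VITD": 2.5}),
            blocks=[Block(b, r) for b, r in _BLOCKS],
            panels=[Panel(n_, b, w) for n_, b, w in _PANELS],
            n_participants=n_participants or 1000,
            interventions=[InterventionSpec(*row) for row in _INTERVENTIONS],
            range_rules=default_range_rules(),
            seed=seed,
        )
    if name == "tiny":
        codes = ["VITD", "LDL", "HDL", "CHOL", "ALT", "AST"]
        return SyntheticConfig(
            biomarker_specs=_specs(codes, {"VITD": 2.5}),
            blocks=[Block(("LDL", "HDL", "CHOL"), 0.6), Block(("ALT", "AST"), 0.6)],
            panels=[Panel("all", tuple(codes), 1.0)],
            n_participants=n_participants or 50,
            interventions=[InterventionSpec("vitd_supplement", "VITD", 8.0, 0.25)],
            range_rules=default_range_rules(),
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


PRESETS = ("paperlike", "tiny")


def block_design(
    n_blocks: int = 4,
    block_size: int = 5,
    r_within: float = 0.7,
    r_between: float = 0.0,
    n_participants: int = 1000,
    seed: int = 0,
    delta_sd: float = 10.0,
) -> SyntheticConfig:
    """A minimal simulation-study design: equal blocks, one full panel.

    Biomarkers are named B00, B01, ...; baselines are N(100, 10); every
    participant is measured on everything.  Useful for calibration and
    recovery experiments where panel missingness and clinical rules are
    not the point.  ``r_within=0`` (with no blocks use ``n_blocks=0``)
    gives a global-null cohort.
    """
    codes = [f"B{i:02d}" for i in range(max(n_blocks, 1) * block_size)]
    specs = [BiomarkerSpec(c, 100.0, 10.0, delta_sd) for c in codes]
    blocks = [
        Block(tuple(codes[i * block_size : (i + 1) * block_size]), r_within)
        for i in range(n_blocks)
        if r_within != 0.0
    ]
    return SyntheticConfig(
        biomarker_specs=specs,
        blocks=blocks,
        panels=[Panel("all", tuple(codes), 1.0)],
        n_participants=n_participants,
        r_between=r_between,
        seed=seed,
    )
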