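"""End-to-end orchestration: QC -> deltas -> network -> clusters -> changes -> interventions.

Every stage writes its artifact to the output directory and records row
counts in a run manifest, because the credibility of this kind of analysis
hinges on filter accounting: how many rows were rejected at parse, how many
pairs each plausibility limit removed, how many participants were
out-of-range per biomarker, and which groups fell below the minimum size.
Re-running with an identical config and inputs reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import changes as changes_mod
from . import interventions as interventions_mod
from . import modules as modules_mod
from . import network as network_mod
from . import qc as qc_mod
from .io import (
    MeasurementTable,
    RangeRuleSet,
    default_range_rules,
    extract_pairs,
    load_range_rules,
    read_interventions,
    read_measurements,
    write_interventions,
    write_measurements,
)
from .synthetic import generate_cohort, preset, save_truth

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_demo_data"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


@dataclass
class RunConfig:
    measurements: str
    participants: str
    interventions: str
    out_dir: str
    seed: int
    range_rules: str | None = None      # None -> bundled defaults
    plausibility_limits: str | None = None
    min_gap_days: int = 30
    followup_strategy: str = "earliest"
    min_n: int = 10
    alpha: float = 0.05
    linkage: str = "average"
    min_cluster_size: int = 3
    cut_height_fraction: float = 0.99
    split_gap_fraction: float = 0.5
    min_group: int = 20
    focal_biomarkers: tuple[str, ...] = ("VITD", "LDL")
    top_k: int = 10
    mc_B: int = 10_000

    def validate(self) -> None:
        missing = [
            p
            for p in (self.measurements, self.participants, self.interventions,
                      self.range_rules, self.plausibility_limits)
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "version": __version__,
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, index=False, **kwargs)
        manifest["outputs"].append(name)

    stage = "load"
    try:
        table, rejects = read_measurements(config.measurements, config.participants)
        choices = read_interventions(config.interventions)
        rules = (
            load_range_rules(config.range_rules)
            if config.range_rules
            else default_range_rules()
        )
        limits = (
            qc_mod.load_limits(config.plausibility_limits)
            if config.plausibility_limits
            else qc_mod.default_limits()
        )
        emit("rejected_rows.csv", rejects)
        manifest["stages"][stage] = {
            "n_measurements": len(table.measurements),
            "n_participants": len(table.participants),
            "n_rejected_rows": len(rejects),
            "n_choices": len(choices),
        }

        stage = "qc"
        pairs = extract_pairs(table, config.min_gap_days, config.followup_strategy)
        pairs, qc_report = qc_mod.apply_limits(pairs, limits)
        emit("qc_report.csv", qc_report)
        emit("pairs.csv", pairs)
        manifest["stages"][stage] = {
            "n_pairs": len(pairs),
            "n_removed": int(qc_report["n_removed"].sum()),
        }

        stage = "seasonal"
        seasonal = changes_mod.default_seasonal_config()
        raw_pairs = pairs.copy()
        seasonal_fits = {}
        for biomarker, entry in seasonal.items():
            sub = table.measurements[table.measurements["biomarker"] == biomarker]
            if sub.empty:
                continue
            try:
                model = changes_mod.fit_seasonal_model(
                    sub["value"], sub["draw_date"], biomarker,
                    summer_months=entry["summer_months"],
                )
            except ValueError:
                continue  # one-season data: skip adjustment, noted in manifest
            pairs = changes_mod.apply_seasonal_adjustment(pairs, model)
            seasonal_fits[biomarker] = {
                "offset_estimate": model.offset_estimate,
                "n_summer": model.n_summer,
                "n_other": model.n_other,
            }
        manifest["stages"][stage] = seasonal_fits

        stage = "network"
        deltas = network_mod.delta_matrix(pairs)
        entries = network_mod.correlate_all(deltas, min_n=config.min_n)
        net = network_mod.build_network(entries, alpha=config.alpha)
        emit("correlations.csv", entries)
        network_mod.write_edge_list(net, out / "edges.tsv")
        manifest["outputs"].append("edges.tsv")
        manifest["stages"][stage] = {
            "n_biomarkers": len(net.nodes),
            "n_tested_pairs": len(entries),
            "n_edges": len(net.edges),
        }

        stage = "cluster"
        dist = modules_mod.distance_from_correlations(entries)
        dend = modules_mod.hierarchical_cluster(dist, linkage=config.linkage)
        assignment = modules_mod.dynamic_tree_cut(
            dend, dist,
            min_cluster_size=config.min_cluster_size,
            cut_height_fraction=config.cut_height_fraction,
            split_gap_fraction=config.split_gap_fraction,
        )
        modules_mod.write_assignment(assignment, out / "clusters.csv")
        manifest["outputs"].append("clusters.csv")
        network_mod.write_graphml(
            net, out / "network.graphml", node_attributes={"cluster": assignment.labels}
        )
        manifest["outputs"].append("network.graphml")
        manifest["stages"][stage] = {"n_clusters": assignment.n_clusters}

        stage = "changes"
        change_table, omitted = changes_mod.out_of_range_change_table(
            pairs, rules, table.participants,
            min_group=config.min_group, raw_pairs=raw_pairs,
        )
        emit("change_table.csv", change_table)
        bmi = table.participants.dropna(subset=["bmi_baseline", "bmi_followup"])
        bmi_result = None
        if len(bmi) >= 2 and bmi["bmi_followup"].sub(bmi["bmi_baseline"]).std() > 0:
            mean_change, p = changes_mod.paired_t_test(
                bmi["bmi_baseline"].to_numpy(), bmi["bmi_followup"].to_numpy()
            )
            bmi_result = {"n": len(bmi), "mean_change": mean_change, "p": p}
        manifest["stages"][stage] = {
            "n_rows": len(change_table),
            "omitted": omitted,
            "bmi_paired_t": bmi_result,
        }

        stage = "interventions"
        focal = [b for b in config.focal_biomarkers if b in set(pairs["biomarker"])]
        definitions = interventions_mod.definitions_from_rules(rules, focal)
        scan = interventions_mod.intervention_scan(
            pairs, choices, definitions,
            top_k=config.top_k, B=config.mc_B, seed=config.seed,
        )
        emit("intervention_scan.csv", scan)
        manifest["stages"][stage] = {
            "n_tests": len(scan),
            "n_nominal": int(scan["nominal_flag"].sum()),
            "n_q_significant": int((scan["q"] < config.alpha).sum()),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest["outputs"].append("manifest.json")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def make_demo_data(preset_name: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort + truth record in the pipeline's input formats."""
    config = preset(preset_name, seed=seed)
    table, choices, truth = generate_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "participants": out / "participants.csv",
        "interventions": out / "interventions.csv",
        "truth": out / "truth.json",
    }
    write_measurements(table, paths["measurements"], paths["participants"])
    write_interventions(choices, paths["interventions"])
    save_truth(truth, paths["truth"])
    return paths
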