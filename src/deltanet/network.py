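"""Biomarker-change correlation networks.

Each participant contributes a delta (follow-up minus baseline) per measured
biomarker; for every unordered biomarker pair a Spearman rank correlation is
computed over the pairwise-complete participants, two-sided p-values come
from the t approximation with n-2 degrees of freedom, and the family of
tested pairs is corrected with the Benjamini-Hochberg step-up procedure.
The significant edges (q < alpha) form an undirected network whose weights
are the signed correlations.

With a 40-biomarker panel and every pair testable the family has
C(40, 2) = 780 members; pairs with too few shared observations or a
degenerate (constant-rank) delta vector are flagged untestable and excluded
from both the network and the correction family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman_pair",
    "correlate_all",
    "bh_adjust",
    "CorrelationNetwork",
    "build_network",
    "neighborhood",
    "sensitivity_compare",
    "delta_matrix",
    "write_entries",
    "write_edge_list",
    "write_graphml",
    "UntestableError",
    "InsufficientOverlapError",
]

ENTRY_COLUMNS = ["biomarker_a", "biomarker_b", "rho", "n", "p", "q"]

DEFAULT_MIN_N = 10


class UntestableError(ValueError):
    """A correlation cannot be tested (too few pairs or zero rank variance)."""


class InsufficientOverlapError(ValueError):
    """Fewer than 3 shared testable pairs between two correlation tables."""


def delta_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pivot QC-passing pairs into a participants x biomarkers delta matrix.

    Entries are NaN where the participant has no pair for that biomarker
    (panel-based missingness).
    """
    return pairs.pivot(index="participant_id", columns="biomarker", values="delta")


def spearman_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[float, float, int]:
    """Spearman correlation of two paired vectors, dropping incomplete pairs.

    Returns ``(rho, p, n)`` where rho is the Pearson correlation of
    average-tied ranks and p the two-sided t-approximation p-value.
    Raises :class:`UntestableError` when fewer than ``min_n`` complete pairs
    remain or either vector has zero rank variance; |rho| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < max(min_n, 3):
        raise UntestableError(f"only {n} complete pairs (minimum {max(min_n, 3)})")
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise UntestableError("zero rank variance in one of the vectors")
    rho, p = stats.spearmanr(xs, ys)
    if np.isclose(abs(rho), 1.0, atol=1e-12):
        # perfectly monotone: the correlation of ranks is exactly +/-1
        rho, p = math.copysign(1.0, rho), 0.0
    return float(rho), float(p), n


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_all(
    deltas: pd.DataFrame, min_n: int = DEFAULT_MIN_N
) -> pd.DataFrame:
    """Pairwise-complete Spearman tests over all biomarker column pairs.

    One row per unordered pair with at least ``min_n`` shared participants
    and nondegenerate ranks; BH adjustment is applied over exactly this
    family of tested pairs.  Columns: biomarker_a, biomarker_b, rho, n, p, q
    (a < b lexicographically).
    """
    cols = sorted(deltas.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 biomarker columns")
    values = deltas[cols].to_numpy(dtype=float)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            try:
                rho, p, n = spearman_pair(values[:, i], values[:, j], min_n=min_n)
            except UntestableError:
                continue
            rows.append((cols[i], cols[j], rho, n, p))
    entries = pd.DataFrame(rows, columns=ENTRY_COLUMNS[:5])
    entries["q"] = bh_adjust(entries["p"].to_numpy()) if len(entries) else []
    return entries


@dataclass
class CorrelationNetwork:
    """Significant-edge graph: nodes are biomarkers, edges are q < alpha entries."""

    nodes: list[str]
    edges: pd.DataFrame  # ENTRY_COLUMNS subset with q < alpha
    alpha: float = 0.05

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(alpha=self.alpha)
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.biomarker_a, row.biomarker_b,
                weight=float(row.rho), n=int(row.n), p=float(row.p), q=float(row.q),
            )
        return g


def build_network(entries: pd.DataFrame, alpha: float = 0.05) -> CorrelationNetwork:
    """Keep edges with q < alpha; isolated biomarkers stay in the node set."""
    nodes = sorted(set(entries["biomarker_a"]) | set(entries["biomarker_b"]))
    edges = entries.loc[entries["q"] < alpha].reset_index(drop=True)
    return CorrelationNetwork(nodes=nodes, edges=edges, alpha=alpha)


def neighborhood(network: CorrelationNetwork, focus: str) -> CorrelationNetwork:
    """Induced star around ``focus``: its partners and focus-incident edges only."""
    if focus not in network.nodes:
        raise KeyError(f"unknown biomarker: {focus!r}")
    mask = (network.edges["biomarker_a"] == focus) | (network.edges["biomarker_b"] == focus)
    edges = network.edges.loc[mask].reset_index(drop=True)
    partners = sorted(
        set(edges["biomarker_a"]) | set(edges["biomarker_b"]) | {focus}
    )
    return CorrelationNetwork(nodes=partners, edges=edges, alpha=network.alpha)


def sensitivity_compare(
    entries_full: pd.DataFrame, entries_stratum: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between rho vectors of two correlation tables.

    Used for stratified sensitivity analyses (e.g. retest-within-2-years
    subsets, or per-sex strata): a high correlation between the stratum's
    correlation coefficients and the full population's indicates the network
    is not driven by the stratifying factor.  Restricted to pairs testable
    in both tables; fewer than 3 shared pairs raises
    :class:`InsufficientOverlapError`.
    """
    key = ["biomarker_a", "biomarker_b"]
    merged = entries_full.merge(
        entries_stratum, on=key, suffixes=("_full", "_stratum")
    )
    if len(merged) < 3:
        raise InsufficientOverlapError(
            f"only {len(merged)} shared testable pairs (need >= 3)"
        )
    r, _ = stats.pearsonr(merged["rho_full"], merged["rho_stratum"])
    return float(r), merged[key + ["rho_full", "rho_stratum", "n_full", "n_stratum"]]


def write_entries(entries: pd.DataFrame, path: str | Path) -> None:
    """Full correlation table CSV: biomarker_a,biomarker_b,rho,n,p,q."""
    entries.to_csv(path, index=False)


def write_edge_list(network: CorrelationNetwork, path: str | Path) -> None:
    """Cytoscape-loadable TSV edge list (source, target, rho, n, p, q)."""
    out = network.edges.rename(columns={"biomarker_a": "source", "biomarker_b": "target"})
    out.to_csv(path, sep="\t", index=False)


def write_graphml(
    network: CorrelationNetwork, path: str | Path,
    node_attributes: dict[str, dict] | None = None,
) -> None:
    """GraphML export; optional per-node attributes (e.g. cluster labels)."""
    g = network.to_networkx()
    if node_attributes:
        for attr, mapping in node_attributes.items():
            nx.set_node_attributes(g, mapping, attr)
    nx.write_graphml(g, path)
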