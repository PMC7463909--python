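"""Thresholded pairwise-correlation functional networks.

The functional network of a culture is the non-oriented graph whose nodes
are the cells and whose edges join pairs with Pearson correlation of their
ΔF/F traces strictly above a threshold (default ρ > 0.3, the ceiling of
distant-pair correlations observed in astrocyte monocultures).  Three
summary metrics are reported: mean functional connections per cell
(2E/N), the mean correlation over soma-adjacent pairs, and the percentage
of correlated connections among all N(N−1)/2 possible pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UndefinedMetricsError
from .events import BASELINE_WINDOW_S, compute_dff
from .synthetic import CellGeometry, Recording

__all__ = [
    "NetworkMetrics",
    "pairwise_correlation",
    "classify_adjacent",
    "build_graph",
    "network_metrics",
    "correlation_distance_profile",
    "CORRELATION_THRESHOLD",
    "ADJACENCY_EPSILON_UM",
    "DISTANT_CUTOFF_UM",
]

CORRELATION_THRESHOLD = 0.3
ADJACENCY_EPSILON_UM = 1.0
DISTANT_CUTOFF_UM = 100.0

#: columns of the pair-statistics table
PAIR_COLUMNS = ["cell_i", "cell_j", "distance", "radius_sum", "rho",
                "zero_variance", "adjacent", "distant"]


@dataclass(frozen=True)
class NetworkMetrics:
    """The three connectivity metrics of one culture."""

    n_cells: int
    n_edges: int
    connections_per_cell: float   # mean degree, 2E/N
    mean_adjacent_rho: float      # mean rho over soma-contact pairs
    percent_correlated: float     # 100·E / (N(N−1)/2)
    n_adjacent_pairs: int
    no_adjacent_flag: bool        # True when no pair qualified as adjacent


def pairwise_correlation(recording: Recording, use_dff: bool = True,
                         window_s: float = BASELINE_WINDOW_S,
                         method: str = "pearson") -> pd.DataFrame:
    """Correlation and distance for every unordered cell pair.

    Returns one row per pair (i < j by cell id) with Pearson (or Spearman)
    correlation of the full-length ΔF/F traces (raw traces when ``use_dff``
    is off), centroid distance and the sum of soma radii.  Zero-variance
    traces get rho = 0 for all their pairs, flagged in ``zero_variance`` —
    silent cells then show up as isolated nodes rather than being dropped.
    """
    if recording.n_cells < 2:
        raise UndefinedMetricsError("need at least 2 cells for pair statistics")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    if use_dff:
        sig = np.column_stack([
            compute_dff(recording.traces[:, i], recording.frame_rate,
                        window_s=window_s, cell_id=c.cell_id).dff
            for i, c in enumerate(recording.cells)])
    else:
        sig = recording.traces.astype(float)

    if method == "spearman":
        from scipy.stats import rankdata
        sig = np.apply_along_axis(rankdata, 0, sig)

    sd = sig.std(axis=0)
    flat = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(sig, rowvar=False)
    rho[np.ix_(flat, np.ones_like(flat, bool))] = 0.0
    rho[np.ix_(np.ones_like(flat, bool), flat)] = 0.0
    np.fill_diagonal(rho, 1.0)

    cells = recording.cells
    rows = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            ci, cj = cells[a], cells[b]
            if ci.cell_id > cj.cell_id:
                ci, cj = cj, ci
            d = float(np.hypot(ci.x - cj.x, ci.y - cj.y))
            rows.append((ci.cell_id, cj.cell_id, d, ci.radius + cj.radius,
                         float(rho[a, b]), bool(flat[a] or flat[b]),
                         False, False))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.sort_values(["cell_i", "cell_j"], ignore_index=True)


def classify_adjacent(pairs: pd.DataFrame,
                      cells: list[CellGeometry] | None = None,
                      epsilon_um: float = ADJACENCY_EPSILON_UM,
                      distant_cutoff_um: float = DISTANT_CUTOFF_UM,
                      ) -> pd.DataFrame:
    """Flag soma-contact pairs (and, for calibration analyses, distant pairs).

    A pair is adjacent iff centroid distance ≤ r_i + r_j + epsilon
    (boundary inclusive); distant iff distance > ``distant_cutoff_um``.
    If *cells* is given, radius sums are recomputed from it; otherwise the
    ``radius_sum`` column of the pair table is used.
    """
    pairs = pairs.copy()
    if cells is not None:
        radius = {c.cell_id: c.radius for c in cells}
        rs = pairs["cell_i"].map(radius) + pairs["cell_j"].map(radius)
        pairs["radius_sum"] = rs
    pairs["adjacent"] = pairs["distance"] <= pairs["radius_sum"] + epsilon_um
    pairs["distant"] = pairs["distance"] > distant_cutoff_um
    return pairs


def build_graph(pairs: pd.DataFrame,
                threshold: float = CORRELATION_THRESHOLD) -> nx.Graph:
    """Functional graph with an edge wherever rho > threshold (strict).

    All cells appear as nodes, including isolated ones.
    """
    g = nx.Graph(threshold=threshold)
    ids = sorted(set(pairs["cell_i"]).union(pairs["cell_j"]))
    g.add_nodes_from(ids)
    hits = pairs[pairs["rho"] > threshold]
    g.add_edges_from(
        (int(r.cell_i), int(r.cell_j), {"rho": float(r.rho)})
        for r in hits.itertuples())
    return g


def network_metrics(graph: nx.Graph, pairs: pd.DataFrame) -> NetworkMetrics:
    """The three connectivity metrics from a built graph and its pair table."""
    n = graph.number_of_nodes()
    if n < 2:
        raise UndefinedMetricsError(
            f"network metrics undefined for {n} cell(s)")
    e = graph.number_of_edges()
    adj = pairs[pairs["adjacent"]]
    no_adjacent = len(adj) == 0
    mean_adj = 0.0 if no_adjacent else float(adj["rho"].mean())
    return NetworkMetrics(
        n_cells=n, n_edges=e,
        connections_per_cell=2.0 * e / n,
        mean_adjacent_rho=mean_adj,
        percent_correlated=100.0 * e / (n * (n - 1) / 2.0),
        n_adjacent_pairs=int(len(adj)),
        no_adjacent_flag=no_adjacent)


def correlation_distance_profile(pairs: pd.DataFrame,
                                 bin_width_um: float = 50.0) -> pd.DataFrame:
    """Bin pair correlations by centroid distance.

    One row per populated bin [k·w, (k+1)·w): pair count, mean rho, 95th
    percentile of rho, and the same restricted to adjacent pairs.  An empty
    pair table yields an empty frame.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    cols = ["bin_left", "bin_right", "n_pairs", "mean_rho", "p95_rho",
            "n_adjacent", "mean_rho_adjacent"]
    if len(pairs) == 0:
        return pd.DataFrame(columns=cols)
    idx = np.floor(pairs["distance"].to_numpy() / bin_width_um).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sub = pairs[idx == k]
        sub_adj = sub[sub["adjacent"]]
        rows.append((k * bin_width_um, (k + 1) * bin_width_um, len(sub),
                     float(sub["rho"].mean()),
                     float(np.percentile(sub["rho"], 95)),
                     len(sub_adj),
                     float(sub_adj["rho"].mean()) if len(sub_adj) else np.nan))
    return pd.DataFrame(rows, columns=cols)
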