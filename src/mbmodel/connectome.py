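"""Connectome-style analysis of generic synapse tables and SWC skeletons.

The compensation models predict anatomical correlations: KCs with more PN
inputs should have fewer synapses per PN–KC connection (weight proxy), PN
input synapses farther from the spike initiation zone, and more total
excitatory input should come with more inhibitory (APL) input.  This module
tests such predictions on any synapse table with columns

    pre_id, post_id, pre_class, post_subtype, roi, synapse_count

plus optional neurite skeletons (SWC) for geodesic synapse-to-boundary
distances.  A synthetic generator emulates hemibrain-like statistics with
plantable couplings (and a null mode), so the pipeline is testable without
any connectome download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .stats import holm_adjust

__all__ = [
    "Skeleton",
    "SYNAPSE_COLUMNS",
    "DEFAULT_EXCLUDED_SUBTYPES",
    "filter_connections",
    "per_kc_stats",
    "geodesic_distance_to_boundary",
    "correlation_grid",
    "percent_slope",
    "synth_connectome",
]

SYNAPSE_COLUMNS = (
    "pre_id",
    "post_id",
    "pre_class",
    "post_subtype",
    "roi",
    "synapse_count",
)

# KC subtypes with significant nonolfactory input, dropped from aggregates
DEFAULT_EXCLUDED_SUBTYPES = ("g-d", "g-t", "ab-p", "a'b'-ap1")

CALYX_ROI = "CA(R)"


@dataclass
class Skeleton:
    """A neurite tree: SWC nodes with parent links and 3-D coordinates.

    ``boundary_point`` (e.g. the posterior peduncle boundary, the putative
    spike initiation zone) snaps to the nearest skeleton node and anchors
    geodesic distance measurements.
    """

    node_id: np.ndarray
    parent: np.ndarray            # -1 for the root
    xyz: np.ndarray               # (n, 3)
    radius: np.ndarray
    boundary_point: np.ndarray | None = None
    _graph: nx.Graph | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.xyz.shape != (len(self.node_id), 3):
            raise ValueError("xyz must be (n_nodes, 3)")

    def graph(self) -> nx.Graph:
        """Undirected tree with Euclidean edge lengths (cached)."""
        if self._graph is None:
            g = nx.Graph()
            pos = {int(i): self.xyz[k] for k, i in enumerate(self.node_id)}
            g.add_nodes_from(pos)
            for k, i in enumerate(self.node_id):
                p = int(self.parent[k])
                if p != -1:
                    length = float(np.linalg.norm(pos[int(i)] - pos[p]))
                    g.add_edge(int(i), p, length=length)
            if g.number_of_nodes() > 1 and not nx.is_connected(g):
                raise ValueError("skeleton is not a connected tree")
            self._graph = g
        return self._graph

    def nearest_node(self, point: np.ndarray) -> tuple[int, float]:
        """(node id, Euclidean distance) of the node closest to ``point``."""
        d = np.linalg.norm(self.xyz - np.asarray(point, dtype=float), axis=1)
        k = int(np.argmin(d))
        return int(self.node_id[k]), float(d[k])

    @classmethod
    def from_swc(cls, path: str | Path, boundary_point=None) -> "Skeleton":
        """Read standard 7-column SWC (id type x y z radius parent)."""
        ids, parents, coords, radii = [], [], [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            ids.append(int(parts[0]))
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        return cls(
            node_id=np.array(ids),
            parent=np.array(parents),
            xyz=np.array(coords),
            radius=np.array(radii),
            boundary_point=None if boundary_point is None else np.asarray(boundary_point),
        )

    def to_swc(self, path: str | Path) -> None:
        lines = ["# id type x y z radius parent"]
        for k, i in enumerate(self.node_id):
            x, y, z = self.xyz[k]
            lines.append(
                f"{int(i)} 0 {x:.3f} {y:.3f} {z:.3f} {self.radius[k]:.3f} "
                f"{int(self.parent[k])}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def filter_connections(
    table: pd.DataFrame,
    min_synapses: int = 3,
    pre_class: str | None = "PN",
) -> pd.DataFrame:
    """Drop weak connections (annotation-error candidates).

    The synapse count per PN–KC connection is bimodal with a trough around
    three to four; connections below ``min_synapses`` are removed.  Only
    rows of ``pre_class`` are affected (all rows when None).
    """
    if table.empty:
        return table.copy()
    weak = table["synapse_count"] < min_synapses
    if pre_class is not None:
        weak &= table["pre_class"] == pre_class
    return table.loc[~weak].reset_index(drop=True)


def per_kc_stats(
    table: pd.DataFrame,
    excluded_subtypes: tuple[str, ...] = DEFAULT_EXCLUDED_SUBTYPES,
    calyx_roi: str = CALYX_ROI,
) -> pd.DataFrame:
    """Per-KC aggregates from a filtered synapse table.

    For every postsynaptic KC (excluding subtypes with significant
    nonolfactory input): ``N`` PN partners, ``mean_syn`` synapses per PN
    connection, ``total_syn`` summed PN synapses, and ``apl_calyx_syn`` APL
    input synapses restricted to the calyx ROI.  KCs without any PN
    connection after filtering are dropped.
    """
    t = table.loc[~table["post_subtype"].isin(excluded_subtypes)]
    pn = t.loc[t["pre_class"] == "PN"]
    agg = pn.groupby("post_id").agg(
        N=("pre_id", "nunique"),
        total_syn=("synapse_count", "sum"),
        subtype=("post_subtype", "first"),
    )
    agg = agg.loc[agg["N"] > 0]
    agg["mean_syn"] = agg["total_syn"] / agg["N"]
    apl = (
        t.loc[(t["pre_class"] == "APL") & (t["roi"] == calyx_roi)]
        .groupby("post_id")["synapse_count"]
        .sum()
    )
    agg["apl_calyx_syn"] = apl.reindex(agg.index).fillna(0).astype(int)
    return agg.reset_index()


def geodesic_distance_to_boundary(
    skel: Skeleton,
    synapse_positions: np.ndarray,
    snap_radius: float = np.inf,
) -> np.ndarray:
    """Along-skeleton distance from each synapse to the boundary node.

    Positions snap to the nearest skeleton node (NaN beyond ``snap_radius``,
    counted as skipped); the distance is the summed edge length along the
    unique tree path to the node nearest ``skel.boundary_point``.
    """
    if skel.boundary_point is None:
        raise ValueError("skeleton has no boundary point")
    g = skel.graph()
    boundary_node, _ = skel.nearest_node(skel.boundary_point)
    dist_map = nx.single_source_dijkstra_path_length(g, boundary_node, weight="length")
    pos = np.atleast_2d(np.asarray(synapse_positions, dtype=float))
    tree = cKDTree(skel.xyz)
    snap_d, idx = tree.query(pos)
    out = np.full(len(pos), np.nan)
    for k, (d, i) in enumerate(zip(snap_d, idx)):
        if d <= snap_radius:
            out[k] = dist_map[int(skel.node_id[i])]
    return out


#: correlation pairs of the standard grid (extensible by the caller)
DEFAULT_PAIRS = (
    ("N", "mean_syn"),
    ("N", "mean_distance"),
    ("total_syn", "apl_calyx_syn"),
    ("N", "total_syn"),
    ("mean_syn", "apl_calyx_syn"),
)


def correlation_grid(
    kc_stats: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    by: str = "subtype",
    min_n: int = 10,
) -> pd.DataFrame:
    """Pearson correlations between per-KC quantities, per KC subtype.

    Holm–Bonferroni adjustment is applied across the whole grid.  Cells with
    fewer than ``min_n`` KCs or a constant column get NaN.
    """
    rows = []
    for subtype, sub in kc_stats.groupby(by):
        for x, y in pairs:
            if x not in sub or y not in sub:
                continue
            xv = sub[x].to_numpy(dtype=float)
            yv = sub[y].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(yv))
            xv, yv = xv[ok], yv[ok]
            if len(xv) < min_n or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(xv, yv)
            rows.append(
                {"subtype": subtype, "x": x, "y": y, "n": len(xv), "r": r, "p_raw": p}
            )
    df = pd.DataFrame(rows)
    adj = np.full(len(df), np.nan)
    defined = df["p_raw"].notna().to_numpy()
    if defined.any():
        adj[defined] = holm_adjust(df.loc[defined, "p_raw"])
    df["p_holm"] = adj
    df["significant"] = df["p_holm"] < 0.05
    return df


def percent_slope(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on x as percent change per unit x.

    The slope is divided by the fitted value at mean(x) — i.e. by the mean
    of y — and multiplied by 100; invariant to uniform rescaling of y.
    Requires at least three distinct x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least three distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    fitted_at_mean = intercept + slope * x.mean()
    if fitted_at_mean == 0:
        return float("nan")
    return float(100.0 * slope / fitted_at_mean)


def _chain_skeleton(
    n_nodes: int, step: float, rng: np.random.Generator
) -> Skeleton:
    """A mildly wiggly unbranched neurite rooted at the origin."""
    steps = rng.normal(0, 0.1 * step, size=(n_nodes - 1, 3))
    steps[:, 0] += step  # net growth along x
    xyz = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    return Skeleton(
        node_id=np.arange(1, n_nodes + 1),
        parent=np.concatenate([[-1], np.arange(1, n_nodes)]),
        xyz=xyz,
        radius=np.full(n_nodes, 0.1),
        boundary_point=np.zeros(3),
    )


def synth_connectome(
    n_kc: dict[str, int] | int = 200,
    coupling_w_n: float = -0.5,
    coupling_apl: float = 1.0,
    coupling_dist_n: float = 0.3,
    mean_syn: float = 8.0,
    n_mean: float = 6.0,
    n_pn: int = 24,
    error_rate: float = 0.15,
    rng_seed: int = 0,
    make_skeletons: bool = True,
) -> tuple[pd.DataFrame, dict, dict]:
    """Synthetic hemibrain-like synapse table with plantable couplings.

    Per KC: claw count N is Gaussian around ``n_mean`` (subtype-specific
    offsets when ``n_kc`` maps subtype -> count); per-connection synapse
    counts are Poisson around ``mean_syn * (N / n_mean) ** coupling_w_n``
    (shifted to >= 3); APL→KC calyx synapses are Poisson with rate
    proportional to ``total_syn ** coupling_apl``.  A fraction
    ``error_rate`` of spurious 1–2-synapse PN rows emulates annotation
    errors.  Simple chain skeletons place PN synapses at geodesic distances
    scaled by ``(N / n_mean) ** coupling_dist_n``.  Set all couplings to 0
    for the null mode.  Returns (table, skeletons, synapse_positions).
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(n_kc, int):
        n_kc = {"g-main": n_kc}
    rows = []
    skeletons: dict = {}
    positions: dict = {}
    kc_counter = 0
    for subtype, count in n_kc.items():
        for _ in range(count):
            kc_id = f"KC{kc_counter}"
            kc_counter += 1
            N = int(np.clip(round(rng.normal(n_mean, 2.0)), 2, min(12, n_pn)))
            pns = rng.choice(n_pn, size=N, replace=False)
            lam = mean_syn * (N / n_mean) ** coupling_w_n
            counts = 3 + rng.poisson(max(lam - 3, 0.1), size=N)
            for pn, cnt in zip(pns, counts):
                rows.append(
                    {
                        "pre_id": f"PN{pn}",
                        "post_id": kc_id,
                        "pre_class": "PN",
                        "post_subtype": subtype,
                        "roi": CALYX_ROI,
                        "synapse_count": int(cnt),
                    }
                )
            # spurious low-count rows (annotation errors, filtered downstream)
            n_err = rng.binomial(N, error_rate)
            if n_err:
                err_pns = rng.choice(np.setdiff1d(np.arange(n_pn), pns), size=min(n_err, n_pn - N), replace=False)
                for pn in err_pns:
                    rows.append(
                        {
                            "pre_id": f"PN{pn}",
                            "post_id": kc_id,
                            "pre_class": "PN",
                            "post_subtype": subtype,
                            "roi": CALYX_ROI,
                            "synapse_count": int(rng.integers(1, 3)),
                        }
                    )
            total = int(counts.sum())
            apl_rate = 2.0 + (
                0.3 * total ** coupling_apl if coupling_apl != 0 else 0.0
            )
            rows.append(
                {
                    "pre_id": "APL",
                    "post_id": kc_id,
                    "pre_class": "APL",
                    "post_subtype": subtype,
                    "roi": CALYX_ROI,
                    "synapse_count": int(1 + rng.poisson(apl_rate)),
                }
            )
            if make_skeletons:
                skel = _chain_skeleton(40, step=2.0, rng=rng)
                skeletons[kc_id] = skel
                # synapse positions along the distal part of the chain,
                # farther out for higher N when the coupling is planted
                scale = (N / n_mean) ** coupling_dist_n
                frac = np.clip(rng.uniform(0.4, 0.9, size=N) * scale, 0.05, 0.98)
                node_pick = (frac * (len(skel.node_id) - 1)).astype(int)
                positions[kc_id] = skel.xyz[node_pick] + rng.normal(
                    0, 0.05, size=(N, 3)
                )
    table = pd.DataFrame(rows, columns=list(SYNAPSE_COLUMNS))
    return table, skeletons, positions


def kc_mean_distances(
    skeletons: dict, positions: dict, snap_radius: float = np.inf
) -> pd.Series:
    """Per-KC mean geodesic synapse-to-boundary distance."""
    out = {}
    for kc_id, skel in skeletons.items():
        d = geodesic_distance_to_boundary(skel, positions[kc_id], snap_radius)
        out[kc_id] = float(np.nanmean(d))
    return pd.Series(out, name="mean_distance")
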