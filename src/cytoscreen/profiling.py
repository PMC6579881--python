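"""Per-subset profiling: sub-cluster each labeled subset and auto-name.

Each terminal cell subset is clustered separately (so profiling
clusters never mix biologically distinct subsets) and the resulting
clusters are named by the markers that separate them the most,
measured by the best achievable binarization MCC.  A CD8 T-cell
subset with a bimodal CD161 marker, for instance, yields two
profiling subsets named ``CD161hi`` and ``CD161lo``.

The number of clusters comes from a heuristic driven by subset size
and marker heterogeneity: a fine SOM partition of the subset probes
each marker's achievable MCC; every clearly bimodal marker (MCC at or
above a threshold) contributes one extra cluster, capped by subset
size and a hard maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs import EventMatrix
from .ekbalam import mcc_threshold, _derived_seed
from .som import fit_som, metacluster, assign

__all__ = [
    "ProfilingParams",
    "ProfilingCluster",
    "SubsetProfile",
    "ProfilingResult",
    "choose_k",
    "profile_subset",
    "name_clusters",
]


@dataclass(frozen=True)
class ProfilingParams:
    min_cells: int = 200         # below this a subset is never split
    mcc_threshold: float = 0.7   # a marker counts as heterogeneous at/above this
    k_max: int = 8
    probe_k: int = 8             # metaclusters used to probe marker heterogeneity
    het_min_gap: float = 1.2     # arcsinh gap required for real bimodality
    grid_rows: int = 8
    grid_cols: int = 8
    n_epochs: int = 10
    name_margin: float = 0.05    # markers within this of the best MCC share naming
    name_floor: float = 0.5      # below this no marker is considered name-worthy


@dataclass
class ProfilingCluster:
    cluster_id: int
    auto_name: str
    n_events: int


@dataclass
class SubsetProfile:
    subset: str
    clusters: list[ProfilingCluster]
    labels: np.ndarray             # per-event profiling name, within the subset
    marker_mcc: dict[str, float]   # best achievable binarization MCC per marker


@dataclass
class ProfilingResult:
    """Profiling output over all subsets."""

    profiles: dict[str, SubsetProfile] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for subset, prof in self.profiles.items():
            total = sum(c.n_events for c in prof.clusters) or 1
            for c in prof.clusters:
                full = c.auto_name if c.auto_name == subset else f"{c.auto_name} {subset}"
                rows.append(
                    {"subset": subset, "profiling_subset": full, "auto_name": c.auto_name,
                     "n_events": c.n_events, "frequency": c.n_events / total}
                )
        return pd.DataFrame(rows)


def choose_k(n_events: int, heterogeneity: list[float], params: ProfilingParams = ProfilingParams()) -> int:
    """Cluster-count heuristic from subset size and marker heterogeneity.

    k = 1 for small subsets or when no marker is clearly bimodal;
    otherwise 1 + (number of markers with achievable MCC >= threshold),
    capped at min(k_max, floor(n_events / min_cells)).
    """
    if n_events < params.min_cells:
        return 1
    n_het = sum(1 for h in heterogeneity if h >= params.mcc_threshold)
    if n_het == 0:
        return 1
    return max(1, min(1 + n_het, params.k_max, n_events // params.min_cells))


def name_clusters(
    cluster_values: dict[int, EventMatrix] | None = None,
    markers: list[str] | None = None,
    *,
    values: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    marker_names: list[str] | None = None,
    params: ProfilingParams = ProfilingParams(),
) -> tuple[dict[int, str], dict[str, float]]:
    """Name clusters by their most separating markers ("hi"/"lo" suffixes).

    ``values`` is an (n_events, n_markers) matrix aligned to
    ``marker_names``; ``clusters`` the per-event cluster id.  The
    marker(s) with the highest binarization MCC (all within
    ``name_margin`` of the maximum, at most two) name every cluster by
    their sign; ties and collisions are disambiguated with the
    next-best marker, and if no marker is informative the clusters
    fall back to ``C1..Ck``.
    """
    if cluster_values is not None or markers is not None:  # pragma: no cover
        raise TypeError("pass values/clusters/marker_names as keyword arguments")
    values = np.asarray(values, dtype=float)
    clusters = np.asarray(clusters)
    ids = sorted(int(c) for c in np.unique(clusters))
    fallback = {cid: f"C{i + 1}" for i, cid in enumerate(ids)}
    if len(ids) < 2:
        return {ids[0]: fallback[ids[0]]} if ids else {}, {}

    per_marker: dict[str, tuple[float, dict]] = {}
    for j, marker in enumerate(marker_names):
        _t, signs, score = mcc_threshold(values[:, j], clusters)
        per_marker[marker] = (score, signs)
    scores = {m: s for m, (s, _) in per_marker.items()}
    best = max(scores.values()) if scores else 0.0
    if best < params.name_floor:
        return dict(fallback), scores

    ranked = sorted(scores, key=lambda m: (-scores[m], marker_names.index(m)))
    chosen = [m for m in ranked if scores[m] >= best - params.name_margin][:2]
    remaining = [m for m in ranked if m not in chosen and scores[m] >= params.name_floor]

    def compose(markers_used: list[str]) -> dict[int, str]:
        names = {}
        for cid in ids:
            parts = []
            for m in markers_used:
                sign = per_marker[m][1].get(cid, "-")
                parts.append(f"{m}{'hi' if sign == '+' else 'lo'}")
            names[cid] = " ".join(parts)
        return names

    used = list(chosen)
    names = compose(used)
    while len(set(names.values())) < len(ids) and remaining:
        used.append(remaining.pop(0))
        names = compose(used)
    if len(set(names.values())) < len(ids):
        # Same sign vector on every informative marker: number the duplicates.
        seen: dict[str, int] = {}
        for cid in ids:
            base = names[cid]
            seen[base] = seen.get(base, 0) + 1
            if seen[base] > 1:
                names[cid] = f"{base} {seen[base]}"
    return names, scores


def profile_subset(
    subset_events: EventMatrix,
    subset_name: str,
    profiling_markers: list[str],
    params: ProfilingParams = ProfilingParams(),
    seed: int = 0,
) -> SubsetProfile:
    """Cluster one subset and auto-name its profiling clusters.

    A probe SOM partition measures each marker's achievable MCC (the
    heterogeneity input to :func:`choose_k`); the final k comes from
    the heuristic, and k = 1 collapses to a single cluster named after
    the parent subset.
    """
    if subset_events.scale != "arcsinh":
        raise ValueError("profiling expects arcsinh-transformed events")
    n = subset_events.n_events
    if n == 0:
        return SubsetProfile(subset_name, [], np.empty(0, dtype=object), {})

    marker_mcc: dict[str, float] = {}
    if n >= max(2, params.min_cells):
        model = fit_som(
            subset_events, profiling_markers, params.grid_rows, params.grid_cols,
            seed=_derived_seed(seed, 0), n_epochs=params.n_epochs,
        )
        probe = metacluster(model, min(params.probe_k, model.n_nodes, n))
        probe_clusters = assign(probe, subset_events)
        for m in profiling_markers:
            values = subset_events.column(m)
            _t, signs, score = mcc_threshold(values, probe_clusters)
            # Guard against quantization of a unimodal marker: only a split
            # with a real intensity gap between its signed groups counts as
            # marker heterogeneity.
            pos = np.isin(probe_clusters, [c for c, s in signs.items() if s == "+"])
            gap = (
                float(np.median(values[pos]) - np.median(values[~pos]))
                if 0 < pos.sum() < values.size
                else 0.0
            )
            marker_mcc[m] = score if gap >= params.het_min_gap else 0.0
    else:
        marker_mcc = {m: 0.0 for m in profiling_markers}

    k = choose_k(n, list(marker_mcc.values()), params)
    if k == 1:
        labels = np.full(n, subset_name, dtype=object)
        return SubsetProfile(
            subset_name,
            [ProfilingCluster(0, subset_name, n)],
            labels,
            marker_mcc,
        )

    final = metacluster(model, k)
    clusters = assign(final, subset_events)
    X = subset_events.subset_channels(profiling_markers)
    names, _scores = name_clusters(
        values=X, clusters=clusters, marker_names=list(profiling_markers), params=params
    )
    labels = np.array([f"{names[int(c)]} {subset_name}" for c in clusters], dtype=object)
    cluster_list = [
        ProfilingCluster(cid, name, int(np.sum(clusters == cid)))
        for cid, name in sorted(names.items())
    ]
    return SubsetProfile(subset_name, cluster_list, labels, marker_mcc)
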