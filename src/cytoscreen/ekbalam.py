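"""Hierarchy-based cell-subset labeling (the Ek'Balam algorithm).

The labeler combines knowledge-based gating with unbiased clustering.
Its input is a user-defined gating hierarchy: a tree of rules such as
"cells which are CD3+ are T Cells", organized into levels that mirror
parallel gating steps.  At each level, the events of each parent
subset are clustered (SOM + metaclustering) on the union of that
parent's rule markers only.  Each marker is then binarized at the
cutoff that maximizes the event-level Matthews correlation coefficient
between "event above cutoff" and "event's cluster median above
cutoff", searched greedily over midpoints of consecutive cluster
medians.  Each cluster thus gets a +/- sign per marker, and is
assigned to the child subset of the unique rule its sign vector
satisfies.  Iterating over levels drives every event to a terminal
label (a subset with no outgoing rules) or to Unassigned.

This greedy MCC labeling is this package's reconstruction of the
algorithm from its prose description; each step is brute-force
verifiable against exhaustive search on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fcs import EventMatrix
from .qc import ConfusionCounts, mcc
from .som import fit_som, metacluster, assign

__all__ = [
    "UNASSIGNED",
    "Rule",
    "GatingHierarchy",
    "HierarchyError",
    "ClusterParams",
    "SubsetLabeling",
    "mcc_threshold",
    "label_level",
    "label_events",
]

UNASSIGNED = "Unassigned"


class HierarchyError(ValueError):
    """Raised for invalid hierarchies or ambiguous (overlapping) rules."""


@dataclass(frozen=True)
class Rule:
    """parent --(conjunction of marker signs)--> child."""

    parent: str
    child: str
    terms: tuple[tuple[str, str], ...]  # ((marker, '+'|'-'), ...)

    def __post_init__(self) -> None:
        for marker, sign in self.terms:
            if sign not in ("+", "-"):
                raise HierarchyError(f"rule term sign must be '+' or '-', got {sign!r}")

    def satisfied_by(self, signs: dict[str, str]) -> bool:
        return all(signs.get(marker) == sign for marker, sign in self.terms)


@dataclass
class GatingHierarchy:
    """Leveled tree of gating rules rooted at ``root``."""

    root: str
    levels: list[list[Rule]]

    def __post_init__(self) -> None:
        produced = {self.root}
        seen_children: set[str] = set()
        for i, level in enumerate(self.levels):
            if not level:
                raise HierarchyError(f"level {i} has no rules")
            for rule in level:
                if rule.parent not in produced:
                    raise HierarchyError(
                        f"rule parent {rule.parent!r} not produced before level {i}"
                    )
                if rule.child in seen_children or rule.child == self.root:
                    raise HierarchyError(f"label {rule.child!r} produced twice (not a tree)")
                seen_children.add(rule.child)
            produced |= {r.child for r in level}

    @property
    def labels(self) -> set[str]:
        out = {self.root}
        for level in self.levels:
            out |= {r.child for r in level}
        return out

    @property
    def terminal_labels(self) -> set[str]:
        parents = {r.parent for level in self.levels for r in level}
        return self.labels - parents

    def markers(self) -> list[str]:
        seen: list[str] = []
        for level in self.levels:
            for rule in level:
                for marker, _ in rule.terms:
                    if marker not in seen:
                        seen.append(marker)
        return seen

    @classmethod
    def from_dict(cls, spec: dict) -> "GatingHierarchy":
        levels = [
            [
                Rule(
                    parent=r["parent"],
                    child=r["child"],
                    terms=tuple((t["marker"], t["sign"]) for t in r["terms"]),
                )
                for r in level
            ]
            for level in spec["levels"]
        ]
        return cls(root=spec.get("root", "Cell"), levels=levels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingHierarchy":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ClusterParams:
    """Per-level clustering configuration.

    ``min_marker_gap`` guards against signing clusters off quantization
    noise: a marker only separates clusters "for real" when the median
    intensity of events in its positive clusters exceeds that of the
    negative clusters by this many arcsinh units.  Markers below the
    gap are signed against ``positivity_anchor`` instead (absolute
    stained-vs-background boundary), so a parent whose events are
    uniformly positive or uniformly negative for a rule marker still
    matches the right rule.
    """

    grid_rows: int = 8
    grid_cols: int = 8
    n_epochs: int = 10
    meta_factor: int = 2  # metaclusters per child label...
    meta_cap: int = 20  # ...capped here
    min_marker_gap: float = 0.8  # arcsinh units between signed groups
    positivity_anchor: float = 1.0  # absolute fallback cutoff, arcsinh units


@dataclass
class SubsetLabeling:
    """Per-event labels plus the thresholds and clusters that produced them."""

    labels: np.ndarray  # (n_events,) object array of label strings
    level_clusters: list[np.ndarray] = field(default_factory=list)
    thresholds: dict[tuple[int, str, str], float] = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    @property
    def frequencies(self) -> pd.Series:
        return self.counts / max(len(self.labels), 1)


def mcc_threshold(values, clusters) -> tuple[float, dict, float]:
    """Greedy MCC-optimal binarization of a marker over clusters.

    Candidate cutoffs are midpoints between consecutive sorted cluster
    medians.  For a cutoff t, an event is positive when its value
    exceeds t and a cluster is positive when its median exceeds t; the
    chosen t* maximizes the event-level MCC between the two, ties
    broken toward the lowest t.  With a single cluster (or all medians
    equal) the marker is uninformative: all clusters sign '-', score 0.
    """
    values = np.asarray(values, dtype=float)
    clusters = np.asarray(clusters)
    if values.shape != clusters.shape:
        raise ValueError("values and clusters must have equal length")
    ids = pd.unique(clusters)
    medians = {cid: float(np.median(values[clusters == cid])) for cid in ids}
    distinct = sorted(set(medians.values()))
    if len(distinct) < 2:
        return float("nan"), {cid: "-" for cid in ids}, 0.0

    candidates = [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    best_t, best_score, best_signs = None, -np.inf, None
    for t in candidates:  # ascending: strict > keeps the lowest tied t
        e = values > t
        pos_clusters = {cid for cid, m in medians.items() if m > t}
        p = np.isin(clusters, list(pos_clusters))
        c = ConfusionCounts(
            TP=int(np.sum(e & p)),
            FP=int(np.sum(~e & p)),
            TN=int(np.sum(~e & ~p)),
            FN=int(np.sum(e & ~p)),
        )
        score = mcc(c)
        if score > best_score:
            best_t, best_score = t, score
            best_signs = {cid: ("+" if medians[cid] > t else "-") for cid in ids}
    return float(best_t), best_signs, float(best_score)


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


def label_level(
    events: EventMatrix,
    current_labels: np.ndarray,
    level_rules: list[Rule],
    params: ClusterParams = ClusterParams(),
    seed: int = 0,
    level_index: int = 0,
    labeling: SubsetLabeling | None = None,
) -> np.ndarray:
    """Refine one hierarchy level: cluster each parent group and label clusters.

    Clusters whose sign vector satisfies no rule become Unassigned;
    a sign vector satisfying more than one rule is a configuration
    error (rules within a level must be mutually exclusive).
    """
    labels = np.array(current_labels, dtype=object)
    parents = sorted({r.parent for r in level_rules})
    cluster_ids = np.full(len(labels), -1, dtype=int)
    for p_index, parent in enumerate(parents):
        rules = [r for r in level_rules if r.parent == parent]
        idx = np.flatnonzero(labels == parent)
        if idx.size == 0:
            continue
        markers: list[str] = []
        for r in rules:
            for m, _ in r.terms:
                if m not in markers:
                    markers.append(m)
        sub = events.take(idx)
        k = min(
            max(2, params.meta_factor * len(rules)),
            params.meta_cap,
            params.grid_rows * params.grid_cols,
            idx.size,
        )
        model = fit_som(
            sub, markers, params.grid_rows, params.grid_cols,
            seed=_derived_seed(seed, level_index, p_index), n_epochs=params.n_epochs,
        )
        model = metacluster(model, k)
        clusters = assign(model, sub)
        cluster_ids[idx] = clusters

        signs_by_cluster: dict[int, dict[str, str]] = {int(c): {} for c in np.unique(clusters)}
        for marker in markers:
            values = sub.column(marker)
            t_star, signs, score = mcc_threshold(values, clusters)
            pos_mask = np.isin(clusters, [c for c, s in signs.items() if s == "+"])
            gap = (
                float(np.median(values[pos_mask]) - np.median(values[~pos_mask]))
                if 0 < pos_mask.sum() < len(values)
                else 0.0
            )
            if score == 0.0 or gap < params.min_marker_gap:
                # No real modality structure across clusters: sign against
                # the absolute positive/background boundary instead.
                medians = {int(c): float(np.median(values[clusters == c]))
                           for c in np.unique(clusters)}
                signs = {c: ("+" if m > params.positivity_anchor else "-")
                         for c, m in medians.items()}
                t_star = params.positivity_anchor
            if labeling is not None:
                labeling.thresholds[(level_index, parent, marker)] = t_star
            for cid, sign in signs.items():
                signs_by_cluster[int(cid)][marker] = sign

        cluster_label: dict[int, str] = {}
        for cid, signs in signs_by_cluster.items():
            matched = [r for r in rules if r.satisfied_by(signs)]
            if len(matched) > 1:
                raise HierarchyError(
                    f"cluster sign vector {signs} under parent {parent!r} satisfies "
                    f"multiple rules: {[r.child for r in matched]}"
                )
            cluster_label[cid] = matched[0].child if matched else UNASSIGNED
        labels[idx] = np.array([cluster_label[int(c)] for c in clusters], dtype=object)
    if labeling is not None:
        labeling.level_clusters.append(cluster_ids)
    return labels


def label_events(
    events: EventMatrix,
    hierarchy: GatingHierarchy,
    params: ClusterParams = ClusterParams(),
    seed: int = 0,
) -> SubsetLabeling:
    """Run the full hierarchy over an arcsinh-scale event matrix."""
    if events.scale != "arcsinh":
        raise ValueError("label_events expects arcsinh-transformed events")
    labels = np.full(events.n_events, hierarchy.root, dtype=object)
    labeling = SubsetLabeling(labels=labels)
    if events.n_events == 0:
        labeling.labels = labels
        return labeling
    for i, level in enumerate(hierarchy.levels):
        labels = label_level(
            events, labels, level, params=params, seed=seed, level_index=i,
            labeling=labeling,
        )
    labeling.labels = labels
    return labeling
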