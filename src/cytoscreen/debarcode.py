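"""Assign pooled events back to their barcode codes.

Two routes implement the same contract.  The top-k assigner rescales
each barcode channel to [0, 1] (1st-99th percentile window), takes the
k brightest channels of each event as its candidate code, and accepts
the event when the candidate is a valid scheme code and the normalized
gap between the k-th and (k+1)-th channel (the separation) clears a
threshold -- ambiguous, doublet-like events are rejected rather than
forced to the nearest code.  The cluster route reuses the hierarchy
labeler: each code becomes a one-level gating rule (k positive,
n-k negative barcode channels) and events are clustered and labeled on
the barcode channels only.

For the two-tier screen design the outer (palladium, well-in-batch)
tier resolves first, then the inner (CD45, donor x treatment) tier; an
event is assigned only when both tiers resolve to a combination the
batch actually contains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BarcodeScheme, ExperimentManifest, expected_codes_per_batch
from .ekbalam import UNASSIGNED, ClusterParams, GatingHierarchy, Rule, label_events
from .fcs import EventMatrix

__all__ = [
    "UNASSIGNED_CODE",
    "DebarcodeResult",
    "debarcode_topk",
    "debarcode_cluster",
    "two_tier_debarcode",
    "DEFAULT_MIN_SEPARATION",
]

UNASSIGNED_CODE = -1
DEFAULT_MIN_SEPARATION = 0.3


@dataclass
class DebarcodeResult:
    """Per-event code assignment with separation scores."""

    assignment: np.ndarray  # (n_events,) int code_id, UNASSIGNED_CODE if rejected
    separation: np.ndarray  # (n_events,) float, 0 where undefined

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.assignment != UNASSIGNED_CODE))

    @property
    def per_code_counts(self) -> dict[int, int]:
        assigned = self.assignment[self.assignment != UNASSIGNED_CODE]
        ids, counts = np.unique(assigned, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def _rescale_barcode_channels(events: EventMatrix, channels: list[str]) -> np.ndarray:
    """Per-channel robust [0,1] rescale over the 1st-99th percentile window."""
    X = events.subset_channels(channels)
    lo = np.percentile(X, 1, axis=0)
    hi = np.percentile(X, 99, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((X - lo) / span, 0.0, 1.0)


def debarcode_topk(
    events: EventMatrix,
    scheme: BarcodeScheme,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> DebarcodeResult:
    """Per-event top-k barcode assignment with separation-based rejection."""
    if events.scale != "arcsinh":
        raise ValueError("debarcoding expects arcsinh-transformed events")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    channels = list(scheme.channels)
    if events.n_events == 0:
        return DebarcodeResult(np.empty(0, dtype=int), np.empty(0))
    X = _rescale_barcode_channels(events, channels)
    order = np.argsort(-X, axis=1, kind="stable")
    k, n = scheme.k, len(channels)
    sorted_vals = -np.sort(-X, axis=1)
    kth = sorted_vals[:, k - 1]
    next_val = sorted_vals[:, k] if k < n else np.zeros(X.shape[0])
    separation = kth - next_val

    assignment = np.full(X.shape[0], UNASSIGNED_CODE, dtype=int)
    top_idx = np.sort(order[:, :k], axis=1)
    # Group identical candidate codes to avoid per-event set lookups.
    codes_as_tuples = [tuple(row) for row in top_idx]
    lookup: dict[tuple, int] = {}
    for code_id, code in enumerate(scheme.codes):
        idx = tuple(sorted(channels.index(c) for c in code))
        lookup[idx] = code_id
    candidate = np.array([lookup.get(t, UNASSIGNED_CODE) for t in codes_as_tuples])
    ok = (candidate != UNASSIGNED_CODE) & (separation >= min_separation)
    assignment[ok] = candidate[ok]
    return DebarcodeResult(assignment=assignment, separation=separation)


def scheme_hierarchy(scheme: BarcodeScheme) -> GatingHierarchy:
    """One-level gating hierarchy whose children are the scheme's codes."""
    rules = []
    for code_id, code in enumerate(scheme.codes):
        terms = tuple(
            (ch, "+" if ch in code else "-") for ch in scheme.channels
        )
        rules.append(Rule(parent="Events", child=f"code_{code_id}", terms=terms))
    return GatingHierarchy(root="Events", levels=[rules])


def debarcode_cluster(
    events: EventMatrix,
    scheme: BarcodeScheme,
    cluster_params: ClusterParams | None = None,
    seed: int = 0,
) -> DebarcodeResult:
    """Cluster-then-label debarcoding via the hierarchy labeler."""
    if events.scale != "arcsinh":
        raise ValueError("debarcoding expects arcsinh-transformed events")
    if cluster_params is None:
        cluster_params = ClusterParams(meta_cap=max(20, 2 * scheme.n_codes))
    hierarchy = scheme_hierarchy(scheme)
    labeling = label_events(events, hierarchy, params=cluster_params, seed=seed)
    assignment = np.full(events.n_events, UNASSIGNED_CODE, dtype=int)
    for code_id in range(scheme.n_codes):
        assignment[labeling.labels == f"code_{code_id}"] = code_id
    return DebarcodeResult(assignment=assignment, separation=np.zeros(events.n_events))


def two_tier_debarcode(
    events: EventMatrix,
    manifest: ExperimentManifest,
    batch_id: str,
    method: str = "topk",
    min_separation: float = DEFAULT_MIN_SEPARATION,
    seed: int = 0,
) -> pd.DataFrame:
    """Resolve (donor, treatment, well) per event for one batch.

    The outer tier is debarcoded first, then the inner tier; the
    (inner, outer) code pair maps to a sample unit through the batch's
    expected code table.  Pairs outside the table -- e.g. an outer code
    beyond a partial batch's well count -- are left Unassigned.

    Returns a per-event frame with columns ``donor``, ``treatment``,
    ``well`` (Unassigned where unresolved), the per-tier code ids, and
    the minimum separation across tiers.
    """
    def run(scheme: BarcodeScheme, tier_seed: int) -> DebarcodeResult:
        if method == "topk":
            return debarcode_topk(events, scheme, min_separation=min_separation)
        if method == "cluster":
            return debarcode_cluster(events, scheme, seed=tier_seed)
        raise ValueError(f"unknown debarcoding method {method!r}")

    outer = run(manifest.outer_scheme, seed)
    inner = run(manifest.inner_scheme, seed + 1)

    expected = {
        (ic, oc): (donor, treatment, well)
        for ic, oc, donor, treatment, well in expected_codes_per_batch(manifest, batch_id)
    }
    n = events.n_events
    donors = np.full(n, UNASSIGNED, dtype=object)
    treatments = np.full(n, UNASSIGNED, dtype=object)
    wells = np.full(n, UNASSIGNED, dtype=object)
    both = (outer.assignment != UNASSIGNED_CODE) & (inner.assignment != UNASSIGNED_CODE)
    for i in np.flatnonzero(both):
        unit = expected.get((int(inner.assignment[i]), int(outer.assignment[i])))
        if unit is not None:
            donors[i], treatments[i], wells[i] = unit
    return pd.DataFrame(
        {
            "donor": donors,
            "treatment": treatments,
            "well": wells,
            "inner_code": inner.assignment,
            "outer_code": outer.assignment,
            "separation": np.minimum(outer.separation, inner.separation),
            "assigned": wells != UNASSIGNED,
        }
    )
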