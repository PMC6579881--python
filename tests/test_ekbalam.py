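"""Hierarchy labeling: MCC threshold search and level-wise cluster labeling."""

import numpy as np
import pytest

from cytoscreen.ekbalam import (
    UNASSIGNED,
    ClusterParams,
    GatingHierarchy,
    HierarchyError,
    Rule,
    label_events,
    label_level,
    mcc_threshold,
)
from cytoscreen.fcs import EventMatrix
from cytoscreen.qc import confusion, mcc

from conftest import mixture_events

HIERARCHY = GatingHierarchy(
    root="Cell",
    levels=[
        [
            Rule("Cell", "T Cells", (("CD3", "+"), ("CD19", "-"))),
            Rule("Cell", "B Cells", (("CD19", "+"), ("CD3", "-"))),
            Rule("Cell", "NK Cells", (("CD3", "-"), ("CD19", "-"), ("CD56", "+"))),
        ],
        [
            Rule("T Cells", "CD4 T", (("CD4", "+"), ("CD8", "-"))),
            Rule("T Cells", "CD8 T", (("CD8", "+"), ("CD4", "-"))),
        ],
    ],
)


def brute_force_mcc(values, clusters):
    """Independent oracle: exhaustively score every median-midpoint cutoff."""
    medians = {c: np.median(values[clusters == c]) for c in np.unique(clusters)}
    distinct = sorted(set(medians.values()))
    best = (None, -np.inf)
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = (a + b) / 2
        e = values > t
        p = np.array([medians[c] > t for c in clusters])
        score = mcc(confusion(e, p, True))
        if score > best[1]:
            best = (t, score)
    return best


class TestMccThreshold:
    def test_perfect_two_cluster_split(self):
        values = np.r_[np.zeros(50), np.full(50, 10.0)]
        clusters = np.r_[np.zeros(50, int), np.ones(50, int)]
        t, signs, score = mcc_threshold(values, clusters)
        assert t == pytest.approx(5.0)
        assert signs == {0: "-", 1: "+"}
        assert score == pytest.approx(1.0)

    def test_single_cluster_is_uninformative(self):
        t, signs, score = mcc_threshold(np.arange(10.0), np.zeros(10, int))
        assert score == 0.0
        assert set(signs.values()) == {"-"}
        assert np.isnan(t)

    def test_three_clusters_matches_brute_force(self):
        rng = np.random.default_rng(42)
        medians = [0.0, 1.0, 10.0]
        values = np.concatenate([rng.normal(m, 0.5, 200) for m in medians])
        clusters = np.repeat([0, 1, 2], 200)
        t, signs, score = mcc_threshold(values, clusters)
        t_oracle, score_oracle = brute_force_mcc(values, clusters)
        assert t == pytest.approx(t_oracle)
        assert score == pytest.approx(score_oracle)
        # The wide central gap wins over the noisy 0/1 boundary.
        assert t == pytest.approx(5.5, abs=0.1)
        assert signs == {0: "-", 1: "-", 2: "+"}

    def test_tie_breaks_toward_lowest_cutoff(self):
        # Two equally clean gaps (0|10 and 10|20) both reach MCC 1;
        # the lower cutoff must win.
        values = np.repeat([0.0, 10.0, 20.0], 30)
        clusters = np.repeat([0, 1, 2], 30)
        t, _signs, score = mcc_threshold(values, clusters)
        assert score == pytest.approx(1.0)
        assert t == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcc_threshold(np.zeros(3), np.zeros(4, int))


class TestLabelLevel:
    def test_two_subset_mixture_recovered(self):
        rng = np.random.default_rng(10)
        n = 2000
        truth = rng.integers(0, 2, n)
        cd3 = np.where(truth == 0, 2.3, 0.3) + rng.normal(0, 0.3, n)
        cd19 = np.where(truth == 1, 2.3, 0.3) + rng.normal(0, 0.3, n)
        em = EventMatrix(np.column_stack([cd3, cd19]), ["CD3", "CD19"], scale="arcsinh")
        rules = [
            Rule("Cell", "T Cells", (("CD3", "+"), ("CD19", "-"))),
            Rule("Cell", "B Cells", (("CD19", "+"), ("CD3", "-"))),
        ]
        labels = label_level(em, np.full(n, "Cell", dtype=object), rules, seed=1)
        truth_names = np.where(truth == 0, "T Cells", "B Cells")
        for name in ("T Cells", "B Cells"):
            assert mcc(confusion(truth_names, labels, name)) >= 0.95

    def test_unmatched_rule_gets_zero_events(self):
        rng = np.random.default_rng(0)
        em = EventMatrix(
            np.column_stack([rng.normal(2.3, 0.2, 500), rng.normal(0.3, 0.2, 500)]),
            ["CD3", "CD19"], scale="arcsinh",
        )
        rules = [
            Rule("Cell", "T Cells", (("CD3", "+"), ("CD19", "-"))),
            Rule("Cell", "B Cells", (("CD19", "+"), ("CD3", "-"))),
        ]
        labels = label_level(em, np.full(500, "Cell", dtype=object), rules, seed=1)
        assert np.sum(labels == "B Cells") == 0
        assert np.sum(labels == "T Cells") == 500

    def test_identical_events_go_to_one_bucket(self):
        em = EventMatrix(np.full((100, 2), 1.0), ["CD3", "CD19"], scale="arcsinh")
        rules = [Rule("Cell", "T Cells", (("CD3", "+"),))]
        labels = label_level(em, np.full(100, "Cell", dtype=object), rules, seed=1)
        assert len(set(labels)) == 1
        assert set(labels) <= {"T Cells", UNASSIGNED}

    def test_overlapping_rules_are_configuration_error(self):
        rng = np.random.default_rng(0)
        em = EventMatrix(rng.normal(2.3, 0.2, (300, 1)), ["CD3"], scale="arcsinh")
        em.values[:150] = rng.normal(0.3, 0.2, (150, 1))
        rules = [
            Rule("Cell", "X", (("CD3", "+"),)),
            Rule("Cell", "Y", (("CD3", "+"),)),
        ]
        with pytest.raises(HierarchyError, match="multiple rules"):
            label_level(em, np.full(300, "Cell", dtype=object), rules, seed=1)


class TestLabelEvents:
    def test_four_subset_two_level_recovery(self):
        events, sidecar = mixture_events(separation=2.0, seed=21)
        labeling = label_events(events, HIERARCHY, seed=21)
        for subset in ("CD4 T", "CD8 T", "B Cells", "NK Cells"):
            score = mcc(confusion(sidecar["subset"], labeling.labels, subset))
            assert score >= 0.9, f"{subset}: MCC {score:.3f}"

    def test_agrees_with_threshold_gating_oracle(self):
        events, _sidecar = mixture_events(separation=2.0, seed=8)
        mid = 0.3 + 1.0  # halfway between planted low and high levels
        cd3, cd19 = events.column("CD3") > mid, events.column("CD19") > mid
        cd56, cd4, cd8 = (events.column(m) > mid for m in ("CD56", "CD4", "CD8"))
        manual = np.select(
            [cd3 & ~cd19 & cd4 & ~cd8, cd3 & ~cd19 & cd8 & ~cd4,
             cd19 & ~cd3, ~cd3 & ~cd19 & cd56],
            ["CD4 T", "CD8 T", "B Cells", "NK Cells"], default=UNASSIGNED,
        )
        labeling = label_events(events, HIERARCHY, seed=8)
        for subset in ("CD4 T", "CD8 T", "B Cells", "NK Cells"):
            assert mcc(confusion(manual, labeling.labels, subset)) >= 0.9

    def test_recovery_degrades_monotonically_with_separation(self):
        scores = []
        for sep in (3.0, 2.0, 1.0, 0.5):
            events, sidecar = mixture_events(separation=sep, seed=13, n_events=2000)
            labeling = label_events(events, HIERARCHY, seed=13)
            per_subset = [
                mcc(confusion(sidecar["subset"], labeling.labels, s))
                for s in ("CD4 T", "CD8 T", "B Cells", "NK Cells")
            ]
            scores.append(np.mean(per_subset))
        for earlier, later in zip(scores, scores[1:]):
            assert later <= earlier + 0.02
        assert scores[0] - scores[-1] > 0.1

    def test_labels_partition_all_events(self):
        events, _sidecar = mixture_events(seed=2, n_events=1500)
        labeling = label_events(events, HIERARCHY, seed=2)
        assert labeling.counts.sum() == events.n_events
        assert labeling.frequencies.sum() == pytest.approx(1.0)

    def test_root_only_hierarchy_labels_everything_root(self):
        events, _sidecar = mixture_events(n_events=100)
        h = GatingHierarchy(root="Cell", levels=[])
        labeling = label_events(events, h, seed=0)
        assert set(labeling.labels) == {"Cell"}

    def test_empty_events(self):
        em = EventMatrix(np.empty((0, 2)), ["CD3", "CD19"], scale="arcsinh")
        labeling = label_events(em, HIERARCHY, seed=0)
        assert len(labeling.labels) == 0

    def test_raw_scale_rejected(self):
        em = EventMatrix(np.ones((5, 2)), ["CD3", "CD19"], scale="raw")
        with pytest.raises(ValueError, match="arcsinh"):
            label_events(em, HIERARCHY)

    def test_thresholds_recorded_per_level_marker(self):
        events, _sidecar = mixture_events(seed=4, n_events=1500)
        labeling = label_events(events, HIERARCHY, seed=4)
        markers_seen = {m for (_lvl, _parent, m) in labeling.thresholds}
        assert {"CD3", "CD19", "CD56", "CD4", "CD8"} <= markers_seen


class TestHierarchyValidation:
    def test_unknown_parent_rejected(self):
        with pytest.raises(HierarchyError, match="not produced"):
            GatingHierarchy(
                root="Cell",
                levels=[[Rule("Ghost", "X", (("CD3", "+"),))]],
            )

    def test_duplicate_child_rejected(self):
        with pytest.raises(HierarchyError, match="twice"):
            GatingHierarchy(
                root="Cell",
                levels=[[
                    Rule("Cell", "X", (("CD3", "+"),)),
                    Rule("Cell", "X", (("CD19", "+"),)),
                ]],
            )

    def test_terminal_labels(self):
        assert HIERARCHY.terminal_labels == {"CD4 T", "CD8 T", "B Cells", "NK Cells"}

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        spec = {
            "root": "Cell",
            "levels": [[{"parent": "Cell", "child": "T",
                         "terms": [{"marker": "CD3", "sign": "+"}]}]],
        }
        p = tmp_path / "h.yaml"
        p.write_text(yaml.safe_dump(spec))
        h = GatingHierarchy.from_yaml(p)
        assert h.terminal_labels == {"T"}
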