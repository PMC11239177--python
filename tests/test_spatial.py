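"""Empty-position insertion, nearest-neighbor distances, shuffle test."""

from dataclasses import replace

import numpy as np
import pytest

from dendrodomains import (
    DendriteTree,
    GeneratorConfig,
    ShuffleConfig,
    TreePosition,
    classify_high_activity,
    compute_frequencies,
    distance_to_high_activity,
    filter_active,
    generate_experiment,
    insert_empty_positions,
    nn_distances,
    shuffle_test,
)
from dendrodomains.morphology import path_distance


def line_positions(xs):
    return [TreePosition(2, float(x)) for x in xs]


class TestInsertEmptyPositions:
    def test_even_fill(self, line_tree):
        tree = DendriteTree.line(20.0)
        empties = insert_empty_positions(tree, line_positions([0.0, 20.0]), 4.0)
        assert sorted(round(p.offset, 6) for p in empties) == [4.0, 8.0, 12.0, 16.0]

    def test_short_gap_stays_empty(self):
        tree = DendriteTree.line(20.0)
        empties = insert_empty_positions(
            tree, line_positions([0.0, 3.5, 20.0]), 4.0
        )
        assert not any(0.0 < p.offset < 3.5 for p in empties)

    def test_terminal_segment_covered(self):
        # synapse at 0, empty 12 µm tail: 2-3 empties, gaps ≤ 4
        tree = DendriteTree.line(12.0)
        empties = insert_empty_positions(tree, line_positions([0.0]), 4.0)
        offs = sorted(p.offset for p in empties)
        assert 2 <= len(offs) <= 3
        gaps = np.diff([0.0] + offs + [12.0] if offs[-1] < 12.0 else [0.0] + offs)
        assert max(gaps) <= 4.0 + 1e-9

    def test_min_distance_to_real(self):
        tree = DendriteTree.line(100.0)
        real = line_positions([0.0, 7.0, 30.0, 71.0, 100.0])
        empties = insert_empty_positions(tree, real, 4.0)
        for e in empties:
            d = min(path_distance(tree, e, r) for r in real)
            assert d >= 2.0 - 1e-9

    def test_coverage_gaps_bounded(self):
        rng = np.random.default_rng(5)
        tree = DendriteTree.line(150.0)
        for _ in range(10):
            real = line_positions(np.sort(rng.uniform(0, 150, 15)))
            cand = real + insert_empty_positions(tree, real, 4.0)
            offs = np.sort([p.offset for p in cand])
            assert offs[0] <= 4.0 and offs[-1] >= 146.0
            assert np.diff(offs).max() <= 4.0 + 1e-9


class TestNNDistances:
    def test_line_example_pooled(self):
        tree = DendriteTree.line(30.0)
        df = nn_distances(tree, line_positions([0.0, 8.0, 25.0]))
        pooled = sorted(
            x for col in ("proximal_um", "distal_um") for x in df[col].dropna()
        )
        assert pooled == pytest.approx([8.0, 8.0, 17.0, 17.0])

    def test_two_synapses(self):
        tree = DendriteTree.line(30.0)
        df = nn_distances(tree, line_positions([5.0, 12.0]))
        assert df.loc[0, "distal_um"] == pytest.approx(7.0)
        assert np.isnan(df.loc[0, "proximal_um"])
        assert df.loc[1, "proximal_um"] == pytest.approx(7.0)

    def test_single_synapse_empty(self):
        tree = DendriteTree.line(30.0)
        assert nn_distances(tree, line_positions([5.0])).empty

    def test_branch_straddling_geodesic(self, y_tree):
        pts = [TreePosition(2, 15.0), TreePosition(3, 5.0), TreePosition(4, 6.0)]
        df = nn_distances(y_tree, pts)
        # from the trunk position, both children are distal: nearest is 10
        assert df.loc[0, "distal_um"] == pytest.approx(10.0)
        # child positions see each other across the branch as proximal side
        assert df.loc[1, "proximal_um"] == pytest.approx(10.0)
        assert df.loc[2, "proximal_um"] == pytest.approx(11.0)


class TestShuffleTest:
    def test_deterministic_given_seed(self):
        tree = DendriteTree.line(150.0)
        pos = line_positions(np.arange(5, 150, 11))
        a = shuffle_test(tree, pos, ShuffleConfig(seed=9))
        b = shuffle_test(tree, pos, ShuffleConfig(seed=9))
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_single_shuffle_reproducible(self):
        tree = DendriteTree.line(150.0)
        pos = line_positions(np.arange(5, 150, 11))
        a = shuffle_test(tree, pos, ShuffleConfig(n_shuffles=1, seed=3))
        b = shuffle_test(tree, pos, ShuffleConfig(n_shuffles=1, seed=3))
        assert a.statistic == b.statistic

    def test_candidate_conservation(self):
        tree = DendriteTree.line(150.0)
        pos = line_positions(np.arange(5, 150, 11))
        res = shuffle_test(tree, pos, ShuffleConfig(seed=1))
        assert res.n_candidates >= len(pos)
        # pooled null size = n_shuffles × pooled-sample size of one draw
        assert len(res.null_samples) == 100 * len(res.observed)

    def test_explicit_candidates_must_cover(self):
        tree = DendriteTree.line(150.0)
        pos = line_positions([10.0, 50.0])
        with pytest.raises(ValueError):
            shuffle_test(tree, pos, candidates=line_positions([10.0, 90.0]))

    def test_clustered_placement_rejected(self):
        rng = np.random.default_rng(8)
        tree = DendriteTree.line(150.0)
        hits = 0
        for k in range(10):
            pos = line_positions(np.sort(rng.uniform(0, 75, 20)))
            res = shuffle_test(tree, pos, ShuffleConfig(seed=100 + k))
            hits += res.p_value < 0.05
        assert hits >= 8

    def test_exchangeable_null_p_roughly_uniform(self):
        # observed drawn from its own null model (uniform over the
        # candidate grid at the minimal spacing): p must not concentrate
        rng = np.random.default_rng(2)
        tree = DendriteTree.line(150.0)
        ps = []
        for k in range(40):
            grid = line_positions(np.arange(rng.uniform(0.1, 4), 150, 4.0))
            sel = rng.choice(len(grid), 20, replace=False)
            pos = [grid[i] for i in sorted(sel)]
            res = shuffle_test(
                tree, pos, ShuffleConfig(seed=500 + k, mode="rank"),
                candidates=grid,
            )
            ps.append(res.p_value)
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.median(ps) > 0.2


class TestDistanceToHighActivity:
    @staticmethod
    def _experiment():
        cfg = replace(
            GeneratorConfig(seed=23),
            lone_high_fraction=0.0,
            synapses_per_domain_mean=6.0,
        )
        exp, truth = generate_experiment(cfg, "hd")
        compute_frequencies(exp)
        exp.synapses = filter_active(exp.synapses)
        return exp, truth

    def test_grouping_threshold(self):
        exp, _ = self._experiment()
        for s in exp.synapses:
            s.high_activity = False
        exp.synapses[0].high_activity = True
        df, _ = distance_to_high_activity(exp.tree, exp.synapses)
        assert set(df["group"]) <= {"near", "far"}
        for row in df.itertuples():
            assert (row.group == "near") == (row.distance_um < 10.0)

    def test_no_high_activity_empty(self):
        exp, _ = self._experiment()
        for s in exp.synapses:
            s.high_activity = False
        df, summary = distance_to_high_activity(exp.tree, exp.synapses)
        assert df.empty and summary == {}

    def test_domain_elevated_frequency_near_anchors(self):
        # paired anchors + domain-elevated firing: synapses close to a
        # high-activity synapse transmit more than distant ones
        from dendrodomains import generate_cohort

        near, far = [], []
        for k in range(8):
            cfg = replace(
                GeneratorConfig(seed=900 + k),
                synapses_per_domain_mean=6.0,
                lone_high_fraction=0.0,
                high_release_fraction=0.25,
            )
            exp, _ = generate_experiment(cfg, f"nf{k}")
            compute_frequencies(exp)
            exp.synapses = filter_active(exp.synapses)
            classify_high_activity([exp])
            df, _ = distance_to_high_activity(exp.tree, exp.synapses)
            near.extend(df.loc[df["group"] == "near", "f"])
            far.extend(df.loc[df["group"] == "far", "f"])
        assert np.mean(near) > np.mean(far)
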