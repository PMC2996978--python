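import numpy as np
import pytest

from ranksets import (
    ExpressionMatrix,
    GeneSetEnumerator,
    GridConfig,
    SentinelConfig,
    build_match_graph,
    components_at,
    consensus_samples,
    enumerate_grid,
    induce_partition,
    read_instances,
    spiral_search,
    t_max_for_s,
    write_instances,
)


def _partitions(values, s):
    return [
        induce_partition(values[i], s, f"p{i:03d}") for i in range(values.shape[0])
    ]


def _matrix(values):
    G, n = values.shape
    return ExpressionMatrix(
        probe_ids=[f"p{i:03d}" for i in range(G)],
        sample_ids=[f"s{j}" for j in range(n)],
        values=values,
    )


class TestBuildMatchGraph:
    def test_duplicated_rows_form_one_component(self, rng):
        row = rng.normal(size=12)
        values = np.vstack([row, row, rng.normal(size=12)])
        comps = build_match_graph(_partitions(values, 4), t=0)
        assert [0, 1] in comps and [2] in comps

    def test_all_distinct_at_zero_tolerance_gives_singletons(self):
        values = np.eye(5) * 10  # each probe tops a different sample
        comps = build_match_graph(_partitions(values, 1), t=0)
        assert comps == [[0], [1], [2], [3], [4]]

    def test_pruned_equals_naive_on_random_matrices(self, rng):
        for _ in range(25):
            G = int(rng.integers(5, 50))
            n = int(rng.integers(8, 20))
            s = int(rng.integers(2, n // 2 + 2))
            t = int(rng.integers(0, s))
            parts = _partitions(rng.normal(size=(G, n)), s)
            assert build_match_graph(parts, t, method="pruned") == build_match_graph(
                parts, t, method="naive"
            )

    def test_mixed_s_is_hard_error(self, rng):
        values = rng.normal(size=(3, 10))
        parts = _partitions(values, 3)[:2] + [_partitions(values, 4)[2]]
        with pytest.raises(ValueError):
            build_match_graph(parts, 1)


class TestConsensusSamples:
    def test_identical_partitions_return_their_set(self, rng):
        row = rng.normal(size=10)
        parts = [induce_partition(row, 4, f"p{i}") for i in range(3)]
        assert consensus_samples(parts) == parts[0].samples

    def test_majority_vote(self):
        # frequencies over n=6, s=2: sample0 x3, sample1 x2, sample2 x1
        vecs = [
            [9, 8, 0, 0, 0, 0],  # {0,1}
            [9, 8, 0, 0, 0, 0],  # {0,1}
            [9, 0, 8, 0, 0, 0],  # {0,2}
        ]
        parts = [induce_partition(v, 2, f"p{i}") for i, v in enumerate(vecs)]
        assert consensus_samples(parts) == frozenset({0, 1})

    def test_matches_exhaustive_frequency_oracle(self, rng):
        for _ in range(20):
            n, s, k = 12, 4, 5
            parts = [
                induce_partition(rng.normal(size=n), s, f"p{i}") for i in range(k)
            ]
            freq = {j: 0 for j in range(n)}
            score = {j: 0 for j in range(n)}
            for p in parts:
                for pos, j in enumerate(p.rank_order):
                    freq[j] += 1
                    score[j] += s - pos
            ranked = sorted(range(n), key=lambda j: (-freq[j], -score[j], j))
            assert consensus_samples(parts) == frozenset(ranked[:s])


class TestComponentsAt:
    def test_saturation_single_instance_when_t_at_least_s(self, rng):
        m = _matrix(rng.normal(size=(8, 10)))
        inst = components_at(m, s=3, t=3, cfg=GridConfig(min_set_size=2))
        assert len(inst) == 1
        assert inst[0].probes == tuple(sorted(m.probe_ids))

    def test_planted_block_recovered_exactly_at_t0(self, rng):
        n = 20
        values = rng.normal(size=(30, n))
        active = np.arange(5)
        values[np.ix_(np.arange(10), active)] += 50  # identical top-5 sets
        m = _matrix(values)
        inst = components_at(m, s=5, t=0)
        assert len(inst) == 1
        assert inst[0].probes == tuple(f"p{i:03d}" for i in range(10))
        assert inst[0].consensus_samples == frozenset(range(5))
        assert inst[0].cell_label == "5t0"

    def test_pure_noise_yields_no_sets_at_stringent_t(self):
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.normal(size=(100, 40)))
            for s in (6, 10, 15):
                assert components_at(m, s=s, t=0) == []


class TestTMaxForS:
    def _sentinel_matrix(self, rng):
        # sentinel block active on samples 0-5, foil block on 10-15; no
        # background probes, so no noise bridges between the two blocks
        values = rng.normal(size=(12, 24)) * 0.01
        values[np.ix_(range(6), range(6))] += 100
        values[np.ix_(range(6, 12), range(10, 16))] += 100
        return _matrix(values)

    def test_disjoint_supports_stay_separate(self, rng):
        m = self._sentinel_matrix(rng)
        cfg = GridConfig(
            sentinel=SentinelConfig(
                sentinel_probes=tuple(f"p{i:03d}" for i in range(6)),
                foil_probes=tuple(f"p{i:03d}" for i in range(6, 12)),
            )
        )
        t_max = t_max_for_s(m, 6, cfg)
        assert t_max >= 0
        # supports are disjoint: merging requires tolerance >= s (never here)
        assert t_max == 5

    def test_duplicated_sentinel_and_foil_merge_immediately(self, rng):
        row = rng.normal(size=16)
        values = np.vstack([row] * 4 + [rng.normal(size=16) for _ in range(4)])
        m = _matrix(values)
        cfg = GridConfig(
            sentinel=SentinelConfig(
                sentinel_probes=("p000", "p001"), foil_probes=("p002", "p003")
            )
        )
        assert t_max_for_s(m, 5, cfg) == -1

    def test_no_sentinel_falls_back_to_half_s(self, rng):
        m = _matrix(rng.normal(size=(5, 20)))
        assert t_max_for_s(m, 9, GridConfig()) == 4
        assert t_max_for_s(m, 9, GridConfig(t_cap=2)) == 2

    def test_absent_sentinel_probe_is_hard_error(self, rng):
        m = _matrix(rng.normal(size=(5, 20)))
        cfg = GridConfig(
            sentinel=SentinelConfig(
                sentinel_probes=("nope",), foil_probes=("p000",)
            )
        )
        with pytest.raises(ValueError, match="nope"):
            t_max_for_s(m, 6, cfg)


class TestEnumerateGrid:
    def test_three_planted_blocks_recovered_unmixed(self, three_block_fixture):
        m, _, truth = three_block_fixture
        instances = enumerate_grid(m, GridConfig())
        blocks = [set(p) for p in truth.planted_probes]
        recovered = [False] * 3
        for inst in instances:
            probes = set(inst.probes)
            for b, block in enumerate(blocks):
                if probes == block:
                    recovered[b] = True
            if inst.t == 0:
                # no instance mixes two blocks at perfect match
                touched = sum(1 for block in blocks if probes & block)
                assert touched <= 1
        assert all(recovered)

    def test_doubling_s_step_yields_subset(self, planted_fixture):
        m = planted_fixture[0]
        fine = {
            (i.s, i.t, i.probes) for i in enumerate_grid(m, GridConfig(t_cap=2))
        }
        coarse = {
            (i.s, i.t, i.probes)
            for i in enumerate_grid(m, GridConfig(t_cap=2, s_step=2))
        }
        assert coarse < fine

    def test_membership_varies_smoothly_near_planted_size(self):
        # strongly shifted block: in the detection region (s within +/-2 of
        # the planted support) membership changes by at most one probe
        # between adjacent tolerance cells
        from ranksets import PlantedSet, SynthConfig, generate

        m, _, truth = generate(
            SynthConfig(planted_sets=(PlantedSet(delta=10.0),), seed=1)
        )
        instances = enumerate_grid(m, GridConfig(t_cap=3))
        planted = set(truth.planted_probes[0])
        n_active = len(truth.active_samples[0])
        cells = {
            (i.s, i.t): set(i.probes)
            for i in instances
            if len(planted & set(i.probes)) >= 5
            and abs(i.s - n_active) <= 2
        }
        assert cells
        for (s, t), probes in cells.items():
            nxt = cells.get((s, t + 1))
            if nxt is not None:
                assert len(probes ^ nxt) <= 1

    def test_deterministic_across_runs(self, planted_fixture):
        m = planted_fixture[0]
        cfg = GridConfig(t_cap=2)
        assert enumerate_grid(m, cfg) == enumerate_grid(m, cfg)

    def test_edge_monotonicity_components_only_merge(self, rng):
        m = _matrix(rng.normal(size=(40, 16)))
        s = 6
        prev = None
        for t in range(0, 4):
            parts = _partitions(m.values, s)
            comps = build_match_graph(parts, t)
            label = {}
            for ci, comp in enumerate(comps):
                for i in comp:
                    label[i] = ci
            if prev is not None:
                # members of one old component stay together
                for comp in prev:
                    assert len({label[i] for i in comp}) == 1
            prev = comps


class TestSpiralSearch:
    def test_unit_steps_equal_exhaustive_scan(self, rng):
        values = rng.normal(size=(30, 18))
        values[np.ix_(range(8), range(6))] += 30
        m = _matrix(values)
        cfg = GridConfig(min_set_size=4, t_cap=2)
        spiral = spiral_search(m, cfg, 1, 1)
        exhaustive = [
            (s, t)
            for s in cfg.s_range(m.n_samples)
            for t in range(0, cfg.t_ceiling(s) + 1)
            if components_at(m, s, t, cfg)
        ]
        assert spiral == sorted(exhaustive)

    def test_refined_hits_cover_planted_cell(self, planted_fixture):
        m, _, truth = planted_fixture
        cells = spiral_search(m, GridConfig(t_cap=3), coarse_s_step=4,
                              coarse_t_step=2)
        s_star = len(truth.active_samples[0])
        assert any(s == s_star for s, _ in cells)

    def test_pure_noise_with_stringent_caps_is_empty(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(size=(80, 30)))
        assert spiral_search(m, GridConfig(t_cap=0), 3, 1) == []


class TestEstimatorAndIO:
    def test_estimator_params_roundtrip(self):
        est = GeneSetEnumerator(s_margin=10, min_set_size=8)
        params = est.get_params()
        assert params["s_margin"] == 10
        est2 = GeneSetEnumerator(**params)
        assert est2.get_params() == params

    def test_fit_on_plain_array(self, rng):
        values = rng.normal(size=(30, 20))
        values[np.ix_(range(8), range(7))] += 40
        est = GeneSetEnumerator(t_cap=1).fit(values)
        assert est.n_samples_ == 20
        assert any(len(i.probes) == 8 for i in est.instances_)

    def test_instance_table_roundtrip(self, tmp_path, planted_fixture):
        m = planted_fixture[0]
        instances = enumerate_grid(m, GridConfig(t_cap=1))
        path = tmp_path / "instances.tsv"
        write_instances(instances, m.sample_ids, path)
        assert read_instances(path, m.sample_ids) == instances
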