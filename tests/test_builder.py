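"""Model construction: loop sampling, geometry, bridges, perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import mitobrush as mb
from mitobrush.builder import expected_auto_bridges, lesion_bead_span, sample_loops
from mitobrush.errors import ConfigError
from mitobrush.state import BOND_CENTROMERE, BOND_LOOP, CoarseGrainingMap


class TestSampleLoops:
    def test_loop_lengths_within_configured_genomic_range(self):
        ann = sample_loops(600, (60_000, 120_000), seed=3)
        lengths = ann.loop_lengths_beads()
        body = lengths[:-1] if ann.truncated_last else lengths
        assert np.all((body >= 30) & (body <= 60))
        assert lengths.sum() == 600

    def test_single_degenerate_loop(self):
        ann = sample_loops(30, (60_000, 60_000), seed=0)
        assert ann.loops == ((0, 30),)
        assert ann.anchor_beads == frozenset({0, 29})
        assert ann.looping_springs == ((0, 29),)

    def test_mean_loop_count_matches_resampling_oracle(self):
        # Oracle: direct enumeration of the sampler's expected loop count.
        # E[L] = 45 beads (uniform on 30..60), so ~ n/E[L] loops.
        n_beads, n_seeds = 3000, 10
        counts = [sample_loops(n_beads, (60_000, 120_000), seed=s).n_loops for s in range(n_seeds)]
        oracle = [
            len(_enumerate_loops(np.random.default_rng(1000 + s), n_beads, 30, 60))
            for s in range(200)
        ]
        se = np.std(oracle, ddof=1) / np.sqrt(n_seeds)
        assert abs(np.mean(counts) - np.mean(oracle)) <= 3 * se + 0.5

    def test_sub_bead_range_rejected(self):
        with pytest.raises(ConfigError):
            sample_loops(100, (500, 1000), cg=CoarseGrainingMap(bp_per_bead=2000))

    def test_chain_shorter_than_min_loop_rejected(self):
        with pytest.raises(ConfigError):
            sample_loops(10, (60_000, 120_000))

    @given(st.integers(0, 2**31 - 1), st.integers(40, 400))
    @settings(max_examples=30, deadline=None)
    def test_tiling_and_anchor_invariants(self, seed, n_beads):
        ann = sample_loops(n_beads, (20_000, 70_000), seed=seed)
        # loops reconstruct [0, n) exactly
        pos = 0
        for s, e in ann.loops:
            assert s == pos
            pos = e
        assert pos == n_beads
        # shared boundary anchors: n loops -> n + 1 anchors, except when a
        # truncated terminal loop degenerates to a single bead (its two
        # roots coincide and it carries no spring)
        degenerate_last = ann.loops[-1][1] - ann.loops[-1][0] == 1
        assert len(ann.anchor_beads) == ann.n_loops + 1 - degenerate_last
        assert len(ann.looping_springs) == ann.n_loops - degenerate_last
        assert ann.attractive_anchors == ann.anchor_beads

    def test_determinism(self):
        a = sample_loops(500, (60_000, 120_000), seed=11)
        b = sample_loops(500, (60_000, 120_000), seed=11)
        assert a.loops == b.loops and a.looping_springs == b.looping_springs


def _enumerate_loops(rng, n_beads, lo, hi):
    loops, pos = [], 0
    while pos < n_beads:
        L = min(int(rng.integers(lo, hi + 1)), n_beads - pos)
        loops.append(L)
        pos += L
    return loops


class TestBuildBottlebrush:
    def test_constructor_contract(self):
        state = mb.build_bottlebrush(mb.BottlebrushConfig(n_beads=600, seed=1))
        assert state.n_chromatin == 600
        assert state.n_bridges == 0
        lengths = state.annotation.loop_lengths_beads()
        assert lengths.sum() == 600

    def test_seed_determinism(self):
        cfg = mb.BottlebrushConfig(n_beads=600, seed=1)
        a, b = mb.build_bottlebrush(cfg), mb.build_bottlebrush(cfg)
        np.testing.assert_array_equal(a.chromatin_coords, b.chromatin_coords)

    def test_bond_lengths_below_divergence_after_prerelaxation(self):
        # exhaustive scan of every bond against the FENE admissible range
        state = mb.build_bottlebrush(mb.BottlebrushConfig(n_beads=600, seed=5))
        params = mb.ForceFieldParams()
        d = np.linalg.norm(
            state.chromatin_coords[state.bonds[:, 0]] - state.chromatin_coords[state.bonds[:, 1]],
            axis=1,
        )
        assert d.max() < params.bond_maxlen
        assert d.min() > params.bond_r0 - params.bond_maxext

    def test_box_too_small_raises(self):
        with pytest.raises(mb.PackingError):
            mb.build_bottlebrush(mb.BottlebrushConfig(n_beads=600, seed=1, box_size=5.0))


class TestBuildSisters:
    def test_centromere_crosslink_count(self):
        cfg = mb.BottlebrushConfig(n_beads=600, seed=1)
        mid = 600 // 2
        state = mb.build_sisters(cfg, cfg.with_(seed=2), (mid - 10, mid + 10))
        cen = state.bonds[state.bond_kinds == BOND_CENTROMERE]
        assert len(cen) == 20
        np.testing.assert_array_equal(cen[:, 1] - cen[:, 0], 600)
        assert state.n_chromatin == 1200
        assert state.annotation.chain_ranges == ((0, 600), (600, 1200))

    def test_empty_span_gives_unlinked_chains(self):
        cfg = mb.BottlebrushConfig(n_beads=120, seed=1)
        state = mb.build_sisters(cfg, cfg.with_(seed=2), (60, 60))
        assert not np.any(state.bond_kinds == BOND_CENTROMERE)

    def test_invalid_span_rejected(self):
        cfg = mb.BottlebrushConfig(n_beads=120, seed=1)
        with pytest.raises(ConfigError):
            mb.build_sisters(cfg, cfg, (100, 130))

    def test_centromere_holds_through_short_run(self):
        cfg = mb.BottlebrushConfig(n_beads=120, seed=3)
        state = mb.build_sisters(cfg, cfg.with_(seed=4), (55, 65))
        state = mb.place_bridges(state, "auto", seed=3)
        traj = mb.run_schedule(
            state, mb.ForceFieldParams(), mb.EngineParams(seed=3),
            mb.Schedule(phase1_steps=200, phase2_steps=2000, snapshot_every=1100),
        )
        final = traj.final_state.chromatin_coords
        cen = state.bonds[state.bond_kinds == BOND_CENTROMERE]
        d = np.linalg.norm(final[cen[:, 0]] - final[cen[:, 1]], axis=1)
        assert np.all(d < 2.0 * mb.ForceFieldParams().bond_r0)


class TestPlaceBridges:
    def test_auto_count_equals_attractive_anchor_count(self):
        ann = sample_loops(630, (60_000, 60_000), seed=0)  # 21 loops of 30 beads
        assert ann.n_loops == 21
        state = mb.build_bottlebrush(
            mb.BottlebrushConfig(n_beads=630, loop_len_range_bp=(60_000, 60_000), seed=0)
        )
        placed = mb.place_bridges(state, "auto", seed=1)
        assert placed.n_bridges == len(state.annotation.attractive_anchors) == 22

    def test_zero_bridges_leaves_state_unchanged(self, mini_state):
        out = mb.place_bridges(mini_state, 0, seed=1)
        assert out.n_bridges == 0
        np.testing.assert_array_equal(out.chromatin_coords, mini_state.chromatin_coords)

    def test_no_steric_overlap_with_chromatin(self, mini_state):
        # brute-force all-pairs distance scan
        d = cKDTree(mini_state.chromatin_coords).query(mini_state.bridge_coords, k=1)[0]
        assert np.all(d >= 1.0)


class TestKnockout:
    def test_arithmetic_contract(self):
        cfg = mb.BottlebrushConfig(n_beads=1200)
        ko = mb.knockout_transform(cfg, "condensin_II", (0.5, 2.0))
        assert ko.loop_len_range_bp == (30_000, 60_000)
        assert ko.n_bridges == 2 * expected_auto_bridges(cfg)

    def test_identity_factors(self):
        cfg = mb.BottlebrushConfig(n_beads=1200)
        ko = mb.knockout_transform(cfg, "condensin_I", (1.0, 1.0))
        assert ko.loop_len_range_bp == cfg.loop_len_range_bp
        assert ko.n_bridges == expected_auto_bridges(cfg)

    def test_condensin_ii_halves_mean_loop_length(self):
        cfg = mb.BottlebrushConfig(n_beads=3000)
        ko = mb.knockout_transform(cfg, "condensin_II")
        wt_means, ko_means = [], []
        for s in range(10):
            wt_means.append(np.mean(sample_loops(3000, cfg.loop_len_range_bp, seed=s).loop_lengths_bp()))
            ko_means.append(np.mean(sample_loops(3000, ko.loop_len_range_bp, seed=s).loop_lengths_bp()))
        ratio = np.mean(ko_means) / np.mean(wt_means)
        assert abs(ratio - 0.5) < 0.05

    def test_sub_bead_factor_rejected(self):
        cfg = mb.BottlebrushConfig(n_beads=1200)
        with pytest.raises(ConfigError):
            mb.knockout_transform(cfg, "condensin_II", (0.01, 1.0))


class TestLesion:
    def test_noop_for_zero_loops(self):
        ann = sample_loops(600, (60_000, 120_000), seed=1)
        assert mb.apply_lesion(ann, 2, 0) is ann

    def test_interior_lesion_matches_set_difference_oracle(self):
        ann = sample_loops(600, (30_000, 30_000), seed=1)  # 40 loops of 15 beads
        k, first = 3, 10
        lesioned = mb.apply_lesion(ann, first, k)
        assert len(lesioned.looping_springs) == ann.n_loops - k
        # oracle: anchors interior to the excised block by direct set enumeration
        roots = [set(ann.loop_roots(i)) for i in range(ann.n_loops)]
        block = set().union(*roots[first:first + k])
        outside = set().union(*(roots[:first] + roots[first + k:]))
        exclusive = block - outside
        assert ann.attractive_anchors - lesioned.attractive_anchors == exclusive
        assert lesioned.anchor_beads == ann.anchor_beads  # structure untouched
        assert lesion_bead_span(lesioned) == (ann.loops[first][0], ann.loops[first + k - 1][1])

    def test_total_lesion_removes_everything(self):
        ann = sample_loops(600, (60_000, 120_000), seed=2)
        lesioned = mb.apply_lesion(ann, 0, ann.n_loops)
        assert lesioned.looping_springs == ()
        assert lesioned.attractive_anchors == frozenset()

    def test_out_of_range_rejected(self):
        ann = sample_loops(600, (60_000, 120_000), seed=1)
        with pytest.raises(ConfigError):
            mb.apply_lesion(ann, ann.n_loops - 1, 5)

    def test_lesion_applied_to_state_drops_springs(self, mini_state):
        lesioned = mb.apply_lesion_to_state(mini_state, 1, 1)
        assert (lesioned.bond_kinds == BOND_LOOP).sum() == (
            (mini_state.bond_kinds == BOND_LOOP).sum() - 1
        )


class TestBedRoundTrip:
    def test_annotation_round_trips_through_bed(self, tmp_path):
        from mitobrush.builder import annotation_from_bed, annotation_to_bed

        ann = sample_loops(600, (60_000, 120_000), seed=9)
        path = tmp_path / "loops.bed"
        annotation_to_bed(ann, path)
        back = annotation_from_bed(path)
        assert back.loops == ann.loops
        assert back.anchor_beads == ann.anchor_beads
        assert back.attractive_anchors == ann.attractive_anchors
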