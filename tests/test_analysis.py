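"""Observables: gyration shape, P(s), clustering, backbone, axial density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import mitobrush.analysis as an
from mitobrush.errors import AnalysisError
from mitobrush.fixtures import toy_cylinder_cloud, toy_linear_chain, toy_powerlaw_profile
from mitobrush.scenarios import density_gap_score


class TestGyrationTensor:
    def test_coincident_points(self):
        _, info = an.gyration_tensor(np.zeros((10, 3)))
        assert info["rg"] == 0.0 and info["acylindricity"] == 0.0

    def test_collinear_rod_is_perfectly_cylindrical(self):
        _, info = an.gyration_tensor(toy_linear_chain(50))
        assert np.allclose(info["eigenvalues"][1:], 0.0, atol=1e-12)
        assert info["acylindricity"] == pytest.approx(0.0, abs=1e-12)

    def test_planar_circle_matches_eigen_oracle(self):
        """1000 points on a circle of radius r: eigenvalues {r^2/2, r^2/2, 0}."""
        r = 3.0
        theta = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)], axis=1)
        tensor, info = an.gyration_tensor(pts)
        # independent oracle: direct eigen-decomposition of the covariance
        oracle = np.sort(np.linalg.eigvalsh(np.cov(pts.T, bias=True)))[::-1]
        np.testing.assert_allclose(info["eigenvalues"], oracle, atol=1e-12)
        np.testing.assert_allclose(info["eigenvalues"], [r**2 / 2, r**2 / 2, 0.0], atol=1e-9)
        assert info["acylindricity"] == pytest.approx(r**2 / 2, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            an.gyration_tensor(np.empty((0, 3)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rg_squared_equals_eigenvalue_sum_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((60, 3)) * [3.0, 1.5, 0.5]
        _, info = an.gyration_tensor(pts)
        assert info["rg"] ** 2 == pytest.approx(info["eigenvalues"].sum(), rel=1e-12)
        rot = Rotation.random(random_state=np.random.RandomState(seed % (2**32 - 1))).as_matrix()
        _, rotated = an.gyration_tensor(pts @ rot.T + rng.uniform(-5, 5, 3))
        assert rotated["acylindricity"] == pytest.approx(info["acylindricity"], rel=1e-9, abs=1e-12)
        assert rotated["rg"] == pytest.approx(info["rg"], rel=1e-12)


class TestContactProbability:
    def test_straight_chain_geometry_forced(self):
        profile = an.contact_probability(toy_linear_chain(100), cutoff=1.1, n_bins=99)
        # P = 1 at one-bead separation, 0 beyond
        assert profile.p_values[0] == pytest.approx(1.0)
        assert np.all(profile.p_values[1:] == 0.0)

    def test_saturated_globule(self, rng):
        pts = rng.uniform(0, 2.0, (60, 3))
        profile = an.contact_probability(pts, cutoff=10.0)
        assert np.all(profile.p_values == 1.0)

    def test_nearest_neighbour_contact_is_maximal(self, mini_traj):
        profile = an.contact_probability(mini_traj, cutoff=1.5, frames="last")
        assert profile.p_values[0] == profile.p_values.max()

    def test_invalid_cutoff_rejected(self, mini_traj):
        with pytest.raises(AnalysisError):
            an.contact_probability(mini_traj, cutoff=-1.0)

    def test_ideal_chain_exponent_matches_random_walk_oracle(self, rng):
        """Freely jointed chains: return probability ~ s^-3/2.

        The oracle IS the brute-force random-walk ensemble; the fitted
        exponent must agree with the ideal-chain value 1.5 within error.
        """
        n, n_chains = 200, 500
        steps = rng.standard_normal((n_chains, n, 3))
        steps /= np.linalg.norm(steps, axis=2, keepdims=True)
        chains = np.cumsum(steps, axis=1)
        profile = an.contact_probability(chains, cutoff=1.1, n_bins=30, bp_per_bead=2000)
        an.fit_exponent(profile, range_bp=(8 * 2000, 80 * 2000))
        assert profile.fitted_exponent == pytest.approx(1.5, abs=max(0.1, 2 * profile.fit_stderr))


class TestFitExponent:
    def test_exact_power_law_recovered_with_zero_residual(self):
        profile = toy_powerlaw_profile(exponent=0.5)
        an.fit_exponent(profile, range_bp=(10_000, 100_000))
        assert profile.fitted_exponent == pytest.approx(0.5, abs=1e-12)
        assert profile.fit_stderr == pytest.approx(0.0, abs=1e-10)

    def test_constant_profile_gives_zero(self):
        profile = toy_powerlaw_profile(exponent=0.0)
        an.fit_exponent(profile, range_bp=(10_000, 100_000))
        assert profile.fitted_exponent == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("true_exp", [0.3, 0.75, 1.2])
    def test_synthetic_exponent_recovery_within_stderr(self, rng, true_exp):
        profile = toy_powerlaw_profile(exponent=true_exp)
        noise = rng.normal(0, 0.01, profile.p_values.shape)
        profile.p_values = profile.p_values * 10 ** noise
        an.fit_exponent(profile, range_bp=(4_000, 500_000))
        assert profile.fitted_exponent == pytest.approx(
            true_exp, abs=max(3 * profile.fit_stderr, 0.02)
        )

    def test_insufficient_bins_rejected(self):
        profile = toy_powerlaw_profile(n_bins=5, s_min_bp=1_000, s_max_bp=2_000_000)
        with pytest.raises(AnalysisError):
            an.fit_exponent(profile, range_bp=(10_000, 20_000))


class TestClusterBridges:
    def test_one_tight_cluster(self, rng):
        pts = rng.normal(0, 0.2, (20, 3))
        rep = an.cluster_bridges(pts, 1.3)
        assert rep.n_clusters == 1 and rep.cluster_sizes.tolist() == [20]

    def test_two_separated_groups(self, rng):
        a = rng.normal(0, 0.2, (12, 3))
        b = rng.normal(0, 0.2, (7, 3)) + [50, 0, 0]
        rep = an.cluster_bridges(np.concatenate([a, b]), 1.3)
        assert rep.n_clusters == 2
        assert sorted(rep.cluster_sizes.tolist()) == [7, 12]
        # deterministic labels by lowest member index
        assert rep.labels[0] == 0 and rep.labels[-1] == 1

    def test_all_singletons(self):
        pts = np.arange(5)[:, None] * [10.0, 0, 0]
        rep = an.cluster_bridges(pts, 1.3)
        assert rep.n_clusters == 5
        assert rep.cluster_sizes.sum() == 5

    def test_invalid_cutoff(self):
        with pytest.raises(AnalysisError):
            an.cluster_bridges(np.zeros((3, 3)), 0.0)


class TestBackboneMetrics:
    def test_collinear_anchors_straightness_one(self, rng):
        from mitobrush.builder import sample_loops

        ann = sample_loops(100, (20_000, 20_000), seed=0)  # anchors every 10 beads
        coords = rng.standard_normal((100, 3))
        for i, a in enumerate(sorted(ann.anchor_beads)):
            coords[a] = [0, 0, 2.0 * i]
        m = an.backbone_metrics(coords, ann)
        assert m["straightness"] == pytest.approx(1.0)

    def test_semicircle_matches_geometric_oracle(self):
        """Anchors on a semicircle: straightness = diameter / arc = 2/pi."""
        from mitobrush.builder import sample_loops

        ann = sample_loops(1000, (2_000, 2_000), seed=0)  # every bead an anchor
        theta = np.linspace(0, np.pi, 1000)
        coords = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1) * 10
        m = an.backbone_metrics(coords, ann)
        assert m["straightness"] == pytest.approx(2 / np.pi, rel=1e-4)

    def test_too_few_anchors_rejected(self):
        from mitobrush.builder import sample_loops

        ann = sample_loops(30, (60_000, 60_000), seed=0)
        with pytest.raises(AnalysisError):
            an.backbone_metrics(np.zeros((30, 3)), _strip_anchors(ann))


def _strip_anchors(ann):
    import dataclasses

    return dataclasses.replace(ann, anchor_beads=frozenset({0}), attractive_anchors=frozenset())


class TestAxialDensityAndGapScore:
    def test_uniform_cylinder_scores_near_one_everywhere(self):
        cloud = toy_cylinder_cloud(seed=2, n_points=4000, radius=3.0, length=40.0)
        for centre in (-10.0, 0.0, 10.0):
            score = density_gap_score(cloud, (centre - 2, centre + 2))
            assert score == pytest.approx(1.0, abs=0.2)

    def test_carved_void_scores_much_less_than_one(self):
        cloud = toy_cylinder_cloud(seed=2, n_points=4000, radius=3.0, length=40.0, void=(-2, 2))
        score = density_gap_score(cloud, (-2.0, 2.0))
        # direct density-counting oracle
        axis = np.array([0.0, 0, 1.0])
        t = (cloud - cloud.mean(axis=0)) @ axis
        inside = np.count_nonzero((t >= -2) & (t < 2)) / 4.0
        flank = (np.count_nonzero((t >= -6) & (t < -2)) + np.count_nonzero((t >= 2) & (t < 6))) / 8.0
        assert score == pytest.approx(inside / flank, abs=0.05)
        assert score < 0.2
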