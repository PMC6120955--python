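"""Population covariation: classification, clustering, cross-area stats."""

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation as SkAP
from sklearn.metrics import adjusted_rand_score

from duofield.population import (
    ClusterResult,
    PopulationError,
    PopulationMatrix,
    affinity_propagation,
    behavior_property_clusters,
    brute_force_exemplars,
    build_population_matrix,
    classify_movement_related,
    cluster_distance_agreement,
    cross_area_intra_cluster_cc,
    inter_cluster_distances,
    trial_similarity_matrix,
)
from duofield.traces import EventMatrix


def _planted_similarity(labels, within=0.9, between=0.0, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    S = np.where(labels[:, None] == labels[None, :], within, between)
    S = S + rng.normal(0, noise, S.shape)
    return (S + S.T) / 2.0


class TestMovementClassification:
    def test_movement_locked_neuron_is_related(self):
        fs = 10.8
        n = 2000
        onsets = np.arange(100, 1900, 60) / fs
        values = np.zeros((1, n))
        for o in (onsets * fs).astype(int):
            values[0, o:o + 15] = 1.0
        ev = EventMatrix(values=values, frame_rate=fs)
        related, pvals, _ = classify_movement_related(ev, onsets)
        assert related[0] and pvals[0] < 1e-6

    def test_type_one_error_matches_alpha(self, rng):
        """i.i.d. null neurons are flagged at ~alpha (binomial CI, n=1000)."""
        fs = 10.8
        n_frames = 2500
        onsets = np.arange(100, 2400, 60) / fs
        values = np.abs(rng.normal(0, 1, (1000, n_frames)))  # continuous null
        ev = EventMatrix(values=values, frame_rate=fs)
        related, _, _ = classify_movement_related(ev, onsets, alpha=0.05)
        rate = related.mean()
        assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / 1000) + 0.005

    def test_edge_trials_dropped_with_warning(self, rng):
        fs = 10.8
        ev = EventMatrix(values=rng.random((3, 500)), frame_rate=fs)
        onsets = np.array([0.5, 20.0])  # first rest window leaves the recording
        with pytest.warns(UserWarning, match="dropped"):
            related, _, dropped = classify_movement_related(ev, onsets)
        assert dropped.size == 1


class TestPopulationMatrix:
    def test_hand_computed_toy(self):
        fs = 1.0
        values = np.array(
            [[0, 0, 2, 0, 0, 4, 0, 0, 6, 0, 0, 0],
             [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2]], dtype=float
        )
        ev = EventMatrix(values=values, frame_rate=fs)
        onsets = np.array([2.0, 5.0, 8.0])
        pm = build_population_matrix(
            ev, onsets, np.array([True, True]), move_win=(0, 1)
        )
        z0 = (values[0] - values[0].mean()) / values[0].std()
        z1 = (values[1] - values[1].mean()) / values[1].std()
        expected = np.array(
            [[z0[2:4].mean(), z0[5:7].mean(), z0[8:10].mean()],
             [z1[2:4].mean(), z1[5:7].mean(), z1[8:10].mean()]]
        )
        np.testing.assert_allclose(pm.matrix, expected, atol=1e-12)

    def test_identical_trials_identical_columns(self):
        fs = 1.0
        values = np.zeros((1, 30))
        values[0, [5, 15]] = 1.0
        ev = EventMatrix(values=values, frame_rate=fs)
        pm = build_population_matrix(
            ev, np.array([5.0, 15.0]), np.array([True]), move_win=(-1, 1)
        )
        np.testing.assert_allclose(pm.matrix[:, 0], pm.matrix[:, 1])

    def test_column_count_equals_trials(self, coupled_session):
        _, areas, truth = coupled_session
        ev = areas["RFA"].events_field
        related = np.ones(ev.n_units, dtype=bool)
        pm = build_population_matrix(ev, truth.onset_times, related)
        assert pm.matrix.shape[1] == truth.onset_times.size

    def test_zero_variance_neuron_excluded(self, rng):
        values = np.vstack([np.zeros(100), rng.random((1, 100))[0]])
        ev = EventMatrix(values=values, frame_rate=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            pm = build_population_matrix(
                ev, np.array([30.0, 60.0]), np.array([True, True]),
                move_win=(-2, 2),
            )
        assert pm.matrix.shape[0] == 1


class TestSimilarity:
    def test_self_similarity_and_scale_invariance(self, rng):
        m = rng.random((6, 4))
        pm = PopulationMatrix("A", m, np.arange(4), np.arange(6))
        S = trial_similarity_matrix(pm, "cc")
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)
        m2 = m.copy()
        m2[:, 1] = 2.5 * m[:, 0]  # scaled copy of trial 0
        pm2 = PopulationMatrix("A", m2, np.arange(4), np.arange(6))
        S2 = trial_similarity_matrix(pm2, "cc")
        assert S2[0, 1] == pytest.approx(1.0, abs=1e-10)
        E = trial_similarity_matrix(pm2, "neg_sq_euclidean")
        assert E[0, 1] < 0  # the two kinds diverge by design

    def test_matches_brute_force_formulas(self, rng):
        m = rng.random((5, 3))
        pm = PopulationMatrix("A", m, np.arange(3), np.arange(5))
        S = trial_similarity_matrix(pm, "cc")
        E = trial_similarity_matrix(pm, "neg_sq_euclidean")
        for i in range(3):
            for j in range(3):
                assert S[i, j] == pytest.approx(
                    np.corrcoef(m[:, i], m[:, j])[0, 1], abs=1e-10
                )
                assert E[i, j] == pytest.approx(
                    -np.sum((m[:, i] - m[:, j]) ** 2), abs=1e-10
                )


class TestAffinityPropagation:
    def test_three_planted_clusters_recovered(self):
        labels = np.repeat([0, 1, 2], 20)
        S = _planted_similarity(labels, noise=0.03)
        res = affinity_propagation(S)
        assert res.k == 3
        assert adjusted_rand_score(labels, res.labels) == 1.0
        assert res.converged

    def test_exemplars_label_themselves(self):
        labels = np.repeat([0, 1], 10)
        res = affinity_propagation(_planted_similarity(labels))
        for c, e in enumerate(res.exemplars):
            assert res.labels[e] == c

    def test_matches_brute_force_on_small_instances(self):
        """Balanced 2-cluster instances <= 12 trials: same partition, and
        the message-passing score ties the exhaustive optimum."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(8, 13))
            n1 = n // 2 + int(rng.integers(-1, 2))
            labels = np.array([0] * n1 + [1] * (n - n1))
            S = np.where(labels[:, None] == labels[None, :], 0.9, 0.0)
            S = S + rng.normal(0, 0.01, S.shape)
            S = (S + S.T) / 2
            ap = affinity_propagation(S)
            ex, lab, best = brute_force_exemplars(S)
            assert ap.k == 2
            assert adjusted_rand_score(ap.labels, lab) == 1.0

            def net_similarity(exemplars):
                Sd = S.copy()
                np.fill_diagonal(Sd, ap.preference)
                members = np.setdiff1d(np.arange(n), exemplars)
                return (
                    len(exemplars) * ap.preference
                    + Sd[np.ix_(members, exemplars)].max(axis=1).sum()
                )

            assert net_similarity(list(ap.exemplars)) == pytest.approx(
                best, abs=0.01
            )

    def test_invariant_to_constant_similarity_shift(self):
        labels = np.repeat([0, 1, 2], 8)
        S = _planted_similarity(labels, noise=0.02, seed=3)
        r1 = affinity_propagation(S)
        r2 = affinity_propagation(S + 11.3)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_preference_percentile_monotonicity(self):
        """Lower preference percentiles never increase the cluster count."""
        labels = np.repeat(np.arange(6), 10)
        S = _planted_similarity(labels, noise=0.05, seed=1)
        ks = [
            affinity_propagation(S, preference=f"{p}%").k
            for p in (70, 30, 10, 1)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_deterministic_given_inputs(self):
        labels = np.repeat([0, 1], 15)
        S = _planted_similarity(labels, noise=0.05, seed=5)
        r1 = affinity_propagation(S)
        r2 = affinity_propagation(S)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.iterations == r2.iterations

    def test_cross_check_against_sklearn(self):
        labels = np.repeat([0, 1, 2], 20)
        S = _planted_similarity(labels, noise=0.03, seed=2)
        ours = affinity_propagation(S)
        sk = SkAP(
            affinity="precomputed", damping=0.9, preference=ours.preference,
            random_state=0, max_iter=1000,
        ).fit(S)
        assert adjusted_rand_score(ours.labels, sk.labels_) == 1.0

    def test_nonconvergence_reported(self):
        labels = np.repeat([0, 1], 10)
        S = _planted_similarity(labels)
        with pytest.warns(UserWarning, match="converge"):
            res = affinity_propagation(S, max_iter=3, stable_iter=100)
        assert not res.converged

    def test_invalid_inputs_rejected(self):
        with pytest.raises(PopulationError):
            affinity_propagation(np.zeros((3, 4)))
        with pytest.raises(PopulationError):
            affinity_propagation(np.zeros((3, 3)), damping=0.3)
        S = np.zeros((3, 3))
        S[0, 1] = np.nan
        with pytest.raises(PopulationError):
            affinity_propagation(S)


def _pm_from_matrix(m, area="A"):
    return PopulationMatrix(area, m, np.arange(m.shape[1]), np.arange(m.shape[0]))


def _clusters_from_labels(labels):
    labels = np.asarray(labels)
    exemplars = np.array([np.flatnonzero(labels == c)[0]
                          for c in range(labels.max() + 1)])
    return ClusterResult(
        labels=labels, exemplars=exemplars, k=labels.max() + 1,
        similarity_kind="cc", preference=0.0, damping=0.9, iterations=1,
        converged=True,
    )


class TestCrossAreaIntraClusterCC:
    def test_identical_vectors_within_clusters_give_unity(self, rng):
        protos = rng.random((8, 3))
        labels = np.repeat([0, 1, 2], 4)
        m = protos[:, labels]
        res = cross_area_intra_cluster_cc(
            _clusters_from_labels(labels), _pm_from_matrix(m),
            n_shuffles=50, seed=0,
        )
        assert res.observed == pytest.approx(1.0, abs=1e-10)

    def test_self_consistency_same_area(self, coupled_session, rng):
        _, areas, truth = coupled_session
        ev = areas["RFA"].events_field
        pm = build_population_matrix(
            ev, truth.onset_times, np.ones(ev.n_units, dtype=bool), area="RFA"
        )
        S = trial_similarity_matrix(pm)
        clusters = affinity_propagation(S)
        res = cross_area_intra_cluster_cc(clusters, pm, n_shuffles=100, seed=0)
        # same-area observed statistic beats its own shuffle null clearly
        assert res.observed > res.null_mean + 3 * res.null_values.std()

    def test_all_singletons_rejected(self, rng):
        m = rng.random((5, 3))
        with pytest.raises(PopulationError):
            cross_area_intra_cluster_cc(
                _clusters_from_labels(np.array([0, 1, 2])),
                _pm_from_matrix(m), n_shuffles=10, seed=0,
            )

    def test_trial_count_mismatch_rejected(self, rng):
        m = rng.random((5, 6))
        with pytest.raises(PopulationError):
            cross_area_intra_cluster_cc(
                _clusters_from_labels(np.array([0, 0, 1, 1])),
                _pm_from_matrix(m), n_shuffles=10, seed=0,
            )

    def test_shuffle_modes_agree_in_distribution(self, rng):
        m = rng.random((6, 20))
        labels = np.repeat(np.arange(5), 4)
        r1 = cross_area_intra_cluster_cc(
            _clusters_from_labels(labels), _pm_from_matrix(m),
            n_shuffles=400, seed=1, shuffle_mode="labels",
        )
        r2 = cross_area_intra_cluster_cc(
            _clusters_from_labels(labels), _pm_from_matrix(m),
            n_shuffles=400, seed=1, shuffle_mode="trials",
        )
        assert r1.null_mean == pytest.approx(r2.null_mean, abs=0.02)


class TestInterClusterDistances:
    def test_toy_means_match_hand_computation(self):
        m = np.array(
            [[1.0, 2.0, 0.0, 0.0, 3.0],
             [0.0, 2.0, 1.0, 1.0, 2.0],
             [2.0, 0.0, 5.0, 4.0, 1.0]]
        )
        labels = np.array([0, 0, 1, 1, 2])
        clusters = _clusters_from_labels(labels)
        pm = _pm_from_matrix(m)
        cc = inter_cluster_distances(pm, clusters, metric="cc")
        means = np.stack(
            [m[:, :2].mean(axis=1), m[:, 2:4].mean(axis=1), m[:, 4]]
        )
        for i in range(3):
            for j in range(3):
                assert cc[i, j] == pytest.approx(
                    np.corrcoef(means[i], means[j])[0, 1], abs=1e-10
                )
        eu = inter_cluster_distances(pm, clusters, metric="euclidean")
        assert eu[0, 1] == pytest.approx(np.linalg.norm(means[0] - means[1]))

    def test_symmetric_with_unit_diagonal(self, rng):
        m = rng.random((6, 12))
        labels = np.repeat(np.arange(4), 3)
        cc = inter_cluster_distances(
            _pm_from_matrix(m), _clusters_from_labels(labels)
        )
        np.testing.assert_allclose(cc, cc.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cc), 1.0, atol=1e-12)

    def test_identical_cluster_means(self):
        m = np.array([[1.0, 1.0, 2.0], [0.0, 0.0, 1.0]])
        labels = np.array([0, 1, 2])
        cc = inter_cluster_distances(
            _pm_from_matrix(m), _clusters_from_labels(labels)
        )
        assert cc[0, 1] == pytest.approx(1.0)


class TestDistanceAgreement:
    def test_perfect_and_anti_agreement(self, rng):
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        assert cluster_distance_agreement(m, m)["r"] == pytest.approx(1.0)
        assert cluster_distance_agreement(m, -m)["r"] == pytest.approx(-1.0)

    def test_too_few_clusters_rejected(self):
        m = np.eye(2)
        with pytest.raises(PopulationError):
            cluster_distance_agreement(m, m)

    def test_agreement_increases_with_coupling(self):
        """Mean r rises across coupling levels (reduced sweep; the full
        5-level, 20-seed sweep runs in the acceptance suite)."""
        from duofield.pipeline import AnalysisConfig, run_covariation
        from duofield.synthetic import SessionSpec, gen_dual_area_session

        means = []
        for c in (0.0, 0.5, 1.0):
            rs = []
            for seed in range(5):
                spec = SessionSpec(coupling=c, seed=seed)
                areas, truth = gen_dual_area_session(spec)
                rep = run_covariation(
                    {a: areas[a].events_field for a in ("RFA", "CFA")},
                    truth.onset_times,
                    AnalysisConfig(seed=seed, n_shuffles=50),
                )
                rs.append(rep["distance_agreement_r"])
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.4


class TestBehaviorPropertyClusters:
    def _trials_frame(self, props):
        import pandas as pd

        return pd.DataFrame(
            props,
            columns=[
                "lever_pull_speed",
                "lever_correlation",
                "reaction_time",
                "time_from_prev_reward",
            ],
        )

    def test_two_archetypes_recovered(self, rng):
        a = np.array([30.0, 0.9, 0.15, 4.0])
        b = np.array([10.0, 0.6, 0.45, 12.0])
        rows = [a + rng.normal(0, 0.01, 4) * a for _ in range(10)]
        rows += [b + rng.normal(0, 0.01, 4) * b for _ in range(10)]
        trials = self._trials_frame(rows)
        res, used = behavior_property_clusters(trials)
        assert res.k == 2
        truth = np.repeat([0, 1], 10)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_undefined_properties_excluded(self, rng):
        rows = rng.random((10, 4))
        rows[3, 2] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            res, used = behavior_property_clusters(self._trials_frame(rows))
        assert 3 not in used

    def test_behavior_clusters_explain_less_when_behavior_decoupled(self):
        """Activity clusters beat behavior clusters when behavior carries no
        information about the latent activity cluster."""
        from duofield.pipeline import AnalysisConfig
        from duofield.synthetic import SessionSpec, gen_dual_area_session
        from duofield.traces import resample_to_clock, union_clock

        rng = np.random.default_rng(0)
        diffs = []
        for seed in range(3):
            spec = SessionSpec(coupling=1.0, seed=seed)
            areas, truth = gen_dual_area_session(spec)
            clocks = [areas[a].events_field.clock() for a in ("RFA", "CFA")]
            clock = union_clock(*clocks)
            clock = clock[(clock >= max(c[0] for c in clocks))
                          & (clock <= min(c[-1] for c in clocks))]
            pms = {}
            for a in ("RFA", "CFA"):
                ev = resample_to_clock(areas[a].events_field, clock)
                related, _, _ = classify_movement_related(ev, truth.onset_times)
                pms[a] = build_population_matrix(
                    ev, truth.onset_times, related, area=a
                )
            S = trial_similarity_matrix(pms["RFA"])
            act = affinity_propagation(S)
            # behavior properties independent of the activity clusters
            trials = self._trials_frame(
                rng.normal(1.0, 0.3, (truth.onset_times.size, 4))
            )
            beh, _ = behavior_property_clusters(trials)
            cc_act = cross_area_intra_cluster_cc(
                act, pms["CFA"], n_shuffles=10, seed=0
            )
            cc_beh = cross_area_intra_cluster_cc(
                beh, pms["CFA"], n_shuffles=10, seed=0
            )
            diffs.append(cc_act.observed - cc_beh.observed)
        assert np.mean(diffs) > 0.05

    def test_identical_trials_single_cluster(self):
        rows = np.tile([20.0, 0.9, 0.2, 5.0], (8, 1))
        res, _ = behavior_property_clusters(
            self._trials_frame(rows), kind="neg_sq_euclidean"
        )
        assert res.k == 1
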