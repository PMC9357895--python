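"""Temporal profile construction, k-means recovery and cluster diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stemtrace import (
    AbundanceMatrix,
    ClusterModel,
    ProfileSet,
    SimConfig,
    build_profiles,
    kmeans_profiles,
    make_sample_meta,
    peak_day_clusters,
    preprocess,
    replicate_composition,
    simulate_timecourse,
    top_shared_proteins,
)

DAYS = [0, 3, 5, 7, 10]


def _matrix(values: pd.DataFrame) -> AbundanceMatrix:
    missing = pd.DataFrame(False, index=values.index, columns=values.columns)
    return AbundanceMatrix(values, missing, pd.Series(3, index=values.index))


def _timecourse(values_by_protein, n_reps=1):
    """Build a matrix where every replicate repeats the given day profiles."""
    sample_ids = [f"d{d}_r{r}" for d in DAYS for r in range(1, n_reps + 1)]
    rows = {
        pid: [v for v in profile for _ in range(n_reps)]
        for pid, profile in values_by_protein.items()
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    values.index.name = "protein_id"
    meta = make_sample_meta(
        sample_ids,
        [d for d in DAYS for _ in range(n_reps)],
        [r for _ in DAYS for r in range(1, n_reps + 1)],
    )
    return _matrix(values), meta


class TestBuildProfiles:
    def test_unit_sum_normalization(self):
        m, meta = _timecourse({"PA": [2.0, 2.0, 2.0, 2.0, 2.0]})
        p = build_profiles(m, meta)
        assert p.profiles.loc[("PA", 1)].tolist() == [0.2] * 5

    def test_all_zero_row_excluded_and_counted(self):
        m, meta = _timecourse({"PA": [1, 1, 1, 1, 1], "PB": [0, 0, 0, 0, 0]})
        p = build_profiles(m, meta)
        assert p.n_dropped == 1
        assert ("PB", 1) not in p.profiles.index

    def test_row_count_is_proteins_times_replicates(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=100, markers_per_day=10, seed=0))
        proc, _ = preprocess(m, min_unique_peptides=0)
        p = build_profiles(proc, meta)
        assert len(p.profiles) + p.n_dropped == 100 * 3

    def test_profiles_sum_to_one(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=100, markers_per_day=10, seed=1))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        np.testing.assert_allclose(p.profiles.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_missing_day_replicate_combination_rejected(self):
        m, meta = _timecourse({"PA": [1, 1, 1, 1, 1]}, n_reps=2)
        short = meta.drop(index=["d10_r2"])
        sub = AbundanceMatrix(
            m.values.drop(columns=["d10_r2"]),
            m.missing.drop(columns=["d10_r2"]),
            m.unique_peptides,
        )
        with pytest.raises(ValueError, match="10"):
            build_profiles(sub, short)

    def test_max_normalization_option(self):
        m, meta = _timecourse({"PA": [1.0, 2.0, 4.0, 2.0, 1.0]})
        p = build_profiles(m, meta, norm="max")
        assert p.profiles.loc[("PA", 1)].max() == 1.0


class TestKMeans:
    def _two_archetypes(self):
        profiles = {}
        rng = np.random.default_rng(0)
        for i in range(10):
            profiles[f"E{i}"] = list(
                np.array([10, 1, 1, 1, 1]) + rng.uniform(0, 0.2, 5)
            )  # early peak
        for i in range(10):
            profiles[f"L{i}"] = list(
                np.array([1, 1, 1, 1, 10]) + rng.uniform(0, 0.2, 5)
            )  # late peak
        return _timecourse(profiles)

    def test_separated_archetypes_recovered_exactly(self):
        m, meta = self._two_archetypes()
        p = build_profiles(m, meta)
        model = kmeans_profiles(p, k=2, seed=0)
        truth = [pid[0] for pid, _ in model.assignment.index]
        assert adjusted_rand_score(truth, model.assignment.to_numpy()) == 1.0

    def test_k_one_centroid_is_mean_profile(self):
        m, meta = self._two_archetypes()
        p = build_profiles(m, meta)
        model = kmeans_profiles(p, k=1, seed=0)
        assert model.assignment.nunique() == 1
        np.testing.assert_allclose(
            model.centroids.iloc[0].to_numpy(),
            p.profiles.mean(axis=0).to_numpy(),
            atol=1e-12,
        )

    def test_restarts_never_worse_than_single_run(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=150, markers_per_day=10, seed=2))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        single = kmeans_profiles(p, k=8, seed=0, restarts=1)
        multi = kmeans_profiles(p, k=8, seed=0, restarts=10)
        assert multi.inertia <= single.inertia + 1e-9

    def test_deterministic_under_fixed_seed(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=120, markers_per_day=10, seed=3))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        m1 = kmeans_profiles(p, k=6, seed=7)
        m2 = kmeans_profiles(p, k=6, seed=7)
        assert (m1.assignment == m2.assignment).all()
        assert m1.inertia == m2.inertia

    def test_k_larger_than_rows_rejected(self):
        m, meta = _timecourse({"PA": [1, 1, 1, 1, 1]})
        p = build_profiles(m, meta)
        with pytest.raises(ValueError):
            kmeans_profiles(p, k=5, seed=0)


def _model_with_assignment(pairs, clusters, k, days=DAYS):
    index = pd.MultiIndex.from_tuples(pairs, names=["protein_id", "replicate"])
    assignment = pd.Series(clusters, index=index, name="cluster")
    centroids = pd.DataFrame(
        np.zeros((k, len(days))), columns=days, index=pd.RangeIndex(k, name="cluster")
    )
    return ClusterModel(
        k=k, assignment=assignment, centroids=centroids, inertia=0.0, seed=0, restarts=1
    )


class TestComposition:
    def test_fraction_counting(self):
        pairs = [("A", 1), ("B", 1), ("C", 2), ("D", 3)]
        model = _model_with_assignment(pairs, [0, 0, 0, 0], k=1)
        profiles = ProfileSet(
            profiles=pd.DataFrame(
                0.2, index=model.assignment.index, columns=DAYS
            ),
            n_dropped=0,
        )
        comp = replicate_composition(model, profiles)
        assert comp.loc[0].tolist() == [0.5, 0.25, 0.25]

    def test_single_replicate_dataset(self):
        pairs = [("A", 1), ("B", 1)]
        model = _model_with_assignment(pairs, [0, 1], k=2)
        profiles = ProfileSet(
            profiles=pd.DataFrame(0.2, index=model.assignment.index, columns=DAYS),
            n_dropped=0,
        )
        comp = replicate_composition(model, profiles)
        assert (comp[1] == 1.0).all()

    def test_rows_sum_to_one_or_zero(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=200, markers_per_day=10, seed=4))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        model = kmeans_profiles(p, k=10, seed=1)
        comp = replicate_composition(model, p)
        sums = comp.sum(axis=1).to_numpy()
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))


class TestPeakDay:
    def test_argmax_peak(self):
        model = _model_with_assignment([("A", 1)], [0], k=1)
        model.centroids.iloc[0] = [0.7, 0.1, 0.1, 0.05, 0.05]
        assert peak_day_clusters(model) == {0: [0], 3: [], 5: [], 7: [], 10: []}

    def test_uniform_centroid_ties_to_earliest_day(self):
        model = _model_with_assignment([("A", 1)], [0], k=1)
        model.centroids.iloc[0] = [0.2] * 5
        assert peak_day_clusters(model)[0] == [0]

    def test_planted_archetypes_give_bijection(self):
        cfg = SimConfig(n_proteins=250, markers_per_day=50, seed=5)
        m, meta, truth = simulate_timecourse(cfg)
        proc, _ = preprocess(m, min_unique_peptides=0)
        p = build_profiles(proc, meta)
        model = kmeans_profiles(p, k=5, seed=0)
        peaks = peak_day_clusters(model)
        assert sorted(len(v) for v in peaks.values()) == [1, 1, 1, 1, 1]


class TestTopShared:
    def test_protein_split_across_clusters_excluded(self):
        m, meta = _timecourse(
            {"PA": [5, 1, 1, 1, 1], "PB": [5, 1, 1, 1, 1]}, n_reps=2
        )
        p = build_profiles(m, meta)
        model = kmeans_profiles(p, k=2, seed=0)
        # force PB's replicate-2 row into the other cluster
        target = model.assignment[("PA", 1)]
        model.assignment[("PB", 2)] = 1 - target
        model.assignment[("PB", 1)] = target
        top = top_shared_proteins(model, p, m, meta, cluster=int(target), n=5)
        assert "PB" not in top.index and "PA" in top.index

    def test_truncation_and_ranking(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=80, markers_per_day=10, seed=6))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        model = kmeans_profiles(p, k=3, seed=0)
        cluster = int(model.assignment.mode()[0])
        top = top_shared_proteins(model, p, proc, meta, cluster, n=4)
        assert len(top) <= 4
        ranks = top["mean_abundance"].to_numpy()
        assert (np.diff(ranks) <= 0).all()

    def test_normalized_expression_peaks_at_one_unique_day(self):
        m, meta, _ = simulate_timecourse(SimConfig(n_proteins=80, markers_per_day=10, seed=7))
        proc, _ = preprocess(m)
        p = build_profiles(proc, meta)
        model = kmeans_profiles(p, k=3, seed=0)
        cluster = int(model.assignment.mode()[0])
        top = top_shared_proteins(model, p, proc, meta, cluster, n=10)
        days_part = top.drop(columns="mean_abundance")
        for _, row in days_part.iterrows():
            assert row.max() == pytest.approx(1.0)
            assert (row == row.max()).sum() == 1
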