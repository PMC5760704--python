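"""Dirichlet-process Gibbs clustering: recovery, filtering, counting."""

import numpy as np
import pytest

from umclone.cluster import (
    Cluster,
    assign_clusters,
    count_discrete_clusters,
    filter_low_ccf_clusters,
    gibbs_sample,
    gibbs_sample_counts,
)


def _mk_cluster(cid, ccf, members, occupancy=1.0):
    n = len(members)
    return Cluster(
        id=cid,
        mean_ccf=ccf,
        ccf_ci95=(ccf - 0.05, ccf + 0.05),
        n_mutations_point=n,
        n_mutations_ci95=(max(0, n - 3), n + 3),
        members=list(members),
        occupancy=occupancy,
    )


class TestGibbs:
    def test_single_mutation_always_one_cluster(self):
        trace = gibbs_sample_counts(
            np.array([30.0]), np.array([60.0]), np.array([0.5]),
            n_iter=200, burn_in=100, seed=1,
        )
        assert trace.n_retained == 100
        # exactly one occupied cluster (rank 0) in every retained iteration
        assert np.all(trace.assignments == 0)
        clusters = assign_clusters(trace)
        assert len(clusters) == 1 and clusters[0].members == [0]

    def test_identical_seed_identical_trace(self, two_cluster_sample):
        m, s, p, _t = two_cluster_sample
        kw = dict(n_iter=300, burn_in=100, seed=5)
        t1 = gibbs_sample(m, s, p, **kw)
        t2 = gibbs_sample(m, s, p, **kw)
        assert np.array_equal(t1.assignments, t2.assignments)
        assert np.array_equal(t1.locations, t2.locations, equal_nan=True)
        assert np.array_equal(t1.alpha, t2.alpha)

    def test_two_cluster_recovery_single_seed(self, two_cluster_sample):
        m, s, p, truth = two_cluster_sample
        trace = gibbs_sample(m, s, p, seed=7)
        clusters = filter_low_ccf_clusters(assign_clusters(trace))
        means = sorted((c.mean_ccf for c in clusters), reverse=True)
        assert abs(means[0] - 1.0) <= 0.05
        assert min(abs(mc - 0.4) for mc in means[1:]) <= 0.05
        # >= 90% of mutations assigned with their true companions
        labels = m["label"].tolist()
        correct = sum(
            1
            for c in clusters
            for i in c.members
            if (c.id == 0) == (truth.cluster_of[labels[i]] == 0)
        )
        assert correct / len(labels) >= 0.9
        sizes = sorted((c.n_mutations_point for c in clusters), reverse=True)
        assert abs(sizes[0] - 100) <= 10 and abs(sizes[1] - 100) <= 10

    def test_cluster_size_interval_brackets_point(self, two_cluster_sample):
        m, s, p, _ = two_cluster_sample
        clusters = assign_clusters(gibbs_sample(m, s, p, n_iter=600, burn_in=200, seed=3))
        top = clusters[0]
        lo, hi = top.n_mutations_ci95
        assert lo <= top.n_mutations_point + 5 and hi >= top.n_mutations_point - 5

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            gibbs_sample_counts(
                np.array([0.0]), np.array([0.0]), np.array([0.5]),
                n_iter=10, burn_in=5, seed=0,
            )

    def test_fifty_fifty_split_goes_to_higher_ccf_cluster(self):
        # symmetric trace built by hand: mutation 2 alternates between the
        # cluster at 1.0 and the cluster at 0.4 in exactly half the sweeps
        T = 100
        assignments = np.zeros((T, 3), dtype=np.int16)
        assignments[:, 1] = 1
        assignments[: T // 2, 2] = 0
        assignments[T // 2 :, 2] = 1
        locations = np.full((T, 10), np.nan)
        locations[:, 0] = 1.0
        locations[:, 1] = 0.4
        mloc = np.empty((T, 3), dtype=np.float32)
        mloc[:, 0] = 1.0
        mloc[:, 1] = 0.4
        mloc[: T // 2, 2] = 1.0
        mloc[T // 2 :, 2] = 0.4
        from umclone.cluster import PosteriorTrace

        trace = PosteriorTrace(
            assignments=assignments, locations=locations,
            mutation_locations=mloc, alpha=np.ones(T), burn_in=0, seed=0,
        )
        clusters = assign_clusters(trace)
        by_ccf = sorted(clusters, key=lambda c: -c.mean_ccf)
        assert 2 in by_ccf[0].members


class TestFiltering:
    def test_low_cluster_dissolved_into_smallest_survivor(self):
        clusters = [
            _mk_cluster(0, 1.0, range(0, 100)),
            _mk_cluster(1, 0.4, range(100, 150)),
            _mk_cluster(2, 0.05, range(150, 160)),
        ]
        out = filter_low_ccf_clusters(clusters, threshold=0.10)
        assert [round(c.mean_ccf, 2) for c in out] == [1.0, 0.4]
        assert set(range(100, 160)) == set(out[1].members)

    def test_single_cluster_unchanged(self):
        out = filter_low_ccf_clusters([_mk_cluster(0, 1.0, range(10))])
        assert len(out) == 1 and out[0].n_mutations_point == 10

    def test_all_small_clusters_collapse_into_top(self):
        clusters = [
            _mk_cluster(0, 1.0, range(0, 50)),
            _mk_cluster(1, 0.08, range(50, 60)),
            _mk_cluster(2, 0.05, range(60, 70)),
        ]
        out = filter_low_ccf_clusters(clusters, threshold=0.10)
        assert len(out) == 1
        assert set(out[0].members) == set(range(70))

    def test_top_cluster_never_dissolved(self):
        out = filter_low_ccf_clusters([_mk_cluster(0, 0.05, range(5))], threshold=0.10)
        assert len(out) == 1

    def test_membership_conserved_through_filtering(self):
        clusters = [
            _mk_cluster(0, 1.0, range(0, 80)),
            _mk_cluster(1, 0.30, range(80, 120)),
            _mk_cluster(2, 0.07, range(120, 133)),
            _mk_cluster(3, 0.03, range(133, 140)),
        ]
        out = filter_low_ccf_clusters(clusters)
        all_members = sorted(i for c in out for i in c.members)
        assert all_members == list(range(140))


class TestCounting:
    def test_one_cluster_counts_one(self):
        assert count_discrete_clusters([_mk_cluster(0, 1.0, range(10))]) == 1

    def test_two_real_clusters_count_two(self):
        clusters = [_mk_cluster(0, 1.0, range(100)), _mk_cluster(1, 0.4, range(100, 200))]
        assert count_discrete_clusters(clusters) == 2

    def test_singleton_clusters_not_counted(self):
        clusters = [_mk_cluster(0, 1.0, range(100)), _mk_cluster(1, 0.5, [100])]
        assert count_discrete_clusters(clusters) == 1

    def test_borderline_occupancy_resolved_upward(self):
        # a cluster present in only half the posterior sweeps still counts
        clusters = [
            _mk_cluster(0, 1.0, range(100)),
            _mk_cluster(1, 0.5, range(100, 110), occupancy=0.5),
        ]
        assert count_discrete_clusters(clusters) == 2
        # but one that almost never stands apart does not
        clusters[1].occupancy = 0.2
        assert count_discrete_clusters(clusters) == 1


def test_single_clone_rarely_oversegmented():
    """On simulated single-clone tumors, >= 90% of seeds report one cluster."""
    from umclone.simulate import SimulationConfig, generate_sample

    hits = 0
    n_seeds = 20
    for seed in range(1, n_seeds + 1):
        cfg = SimulationConfig(
            purity=1.0, mean_depth=100, n_clonal_mutations=150,
            neutral_mu_over_beta=0.0, seed=seed,
        )
        m, s, p, _ = generate_sample(cfg)
        clusters = filter_low_ccf_clusters(assign_clusters(gibbs_sample(m, s, p, seed=seed)))
        if count_discrete_clusters(clusters) == 1:
            hits += 1
    assert hits / n_seeds >= 0.9


def test_top_cluster_mean_near_one_on_clonal_data():
    from umclone.simulate import SimulationConfig, generate_sample

    cfg = SimulationConfig(purity=0.8, n_clonal_mutations=150, neutral_mu_over_beta=0.0, seed=21)
    m, s, p, _ = generate_sample(cfg)
    clusters = assign_clusters(gibbs_sample(m, s, p, seed=21))
    assert abs(clusters[0].mean_ccf - 1.0) <= 0.05
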