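"""Community detection, participation, module-degree z, profiles, occupancy."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dynet.mtd import DynamicConnectivity, mtd_tensor
from dynet.synthetic import StateModel, simulate_subject
from dynet.topology import (
    TopologySeries,
    cartographic_profile,
    detect_communities,
    module_degree_z,
    participation,
    segregated_occupancy,
    topology_series,
)


def as_dc(slices):
    """Stack one or more weight matrices into a DynamicConnectivity."""
    tensor = np.stack(slices, axis=2)
    n = tensor.shape[0]
    return DynamicConnectivity(
        tensor=tensor,
        window_length=15,
        window_centres=np.arange(tensor.shape[2], dtype=float),
        parcel_labels=[f"R{i}" for i in range(n)],
    )


def naive_participation(w, part):
    """Direct-summation oracle for the participation coefficient."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    out = np.zeros(n)
    for i in range(n):
        k = sum(wp[i, j] for j in range(n))
        if k == 0:
            continue
        acc = 0.0
        for s in np.unique(part):
            kappa = sum(wp[i, j] for j in range(n) if part[j] == s)
            acc += (kappa / k) ** 2
        out[i] = 1.0 - acc
    return out


def naive_module_z(w, part):
    """Direct z-score oracle for within-module strength."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    kappa = np.array(
        [sum(wp[i, j] for j in range(n) if part[j] == part[i]) for i in range(n)]
    )
    out = np.zeros(n)
    for s in np.unique(part):
        members = np.flatnonzero(part == s)
        if members.size < 2:
            continue
        vals = kappa[members]
        sd = vals.std()
        if sd > 0:
            out[members] = (vals - vals.mean()) / sd
    return out


class TestDetectCommunities:
    def test_two_disconnected_cliques(self):
        w = np.zeros((20, 20))
        w[:10, :10] = 1.0
        w[10:, 10:] = 1.0
        np.fill_diagonal(w, 0.0)
        assign = detect_communities(as_dc([w]), seed=0)
        labels = assign.labels[:, 0]
        assert adjusted_rand_score(np.repeat([0, 1], 10), labels) == 1.0

    def test_seed_determinism(self, rng):
        w = rng.random((30, 30))
        w = (w + w.T) / 2
        dc = as_dc([w, w * 0.5])
        a = detect_communities(dc, seed=3)
        b = detect_communities(dc, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.modularity, b.modularity)

    def test_empty_slice_single_module(self):
        with pytest.warns(UserWarning, match="single-module"):
            assign = detect_communities(as_dc([np.zeros((5, 5))]), seed=0)
        assert np.all(assign.labels == 0)

    def test_planted_partition_recovered_across_windows(self):
        # crisp 3-module structure: the per-window Louvain partitions
        # should match the planted modules in at least 90% of windows
        part = np.repeat(np.arange(3), 15)
        model = StateModel(45, 1, [part], 0.9, 0.0, 5, 0.1, seed=1)
        sim = simulate_subject(model, 2000)
        dc = mtd_tensor(sim.ts, 15)
        assign = detect_communities(dc, seed=0)
        aris = np.array(
            [adjusted_rand_score(part, assign.labels[:, t]) for t in range(dc.n_windows)]
        )
        assert (aris > 0.9).mean() >= 0.9


class TestParticipation:
    def test_within_module_only_gives_zero(self):
        w = np.zeros((8, 8))
        w[:4, :4] = 0.7
        w[4:, 4:] = 0.7
        np.fill_diagonal(w, 0.0)
        part = np.repeat([0, 1], 4)
        np.testing.assert_allclose(participation(w, part), 0.0, atol=1e-12)

    def test_uniform_spread_over_four_modules(self):
        # region 0 connects with equal strength into each of 4 modules
        w = np.zeros((9, 9))
        part = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3])
        w[0, [1, 3, 5, 7]] = 1.0
        w[[1, 3, 5, 7], 0] = 1.0
        assert participation(w, part)[0] == pytest.approx(1 - 1 / 4)

    def test_isolated_region_is_zero(self):
        w = np.zeros((4, 4))
        w[1, 2] = w[2, 1] = 1.0
        part = np.array([0, 0, 1, 1])
        assert participation(w, part)[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(0, 1, (12, 12))
        w = (w + w.T) / 2
        part = rng.integers(0, 4, 12)
        np.testing.assert_allclose(
            participation(w, part), naive_participation(w, part), atol=1e-12
        )

    def test_bounded_by_realised_module_count(self, rng):
        w = np.abs(rng.normal(0, 1, (20, 20)))
        w = (w + w.T) / 2
        part = rng.integers(0, 3, 20)
        b = participation(w, part)
        assert np.all(b <= 1 - 1 / 3 + 1e-12)


class TestModuleDegreeZ:
    def test_regular_within_module_graph_gives_zero(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 0.5
        w[3:, 3:] = 0.5
        np.fill_diagonal(w, 0.0)
        part = np.repeat([0, 1], 3)
        np.testing.assert_allclose(module_degree_z(w, part), 0.0)

    def test_hub_positive_peers_negative(self):
        n = 10
        w = np.full((n, n), 0.2)
        np.fill_diagonal(w, 0.0)
        w[0, 1:] = 0.4  # hub with double the within-module strength
        w[1:, 0] = 0.4
        part = np.zeros(n, dtype=int)
        z = module_degree_z(w, part)
        assert z[0] > 0
        assert np.all(z[1:] < 0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = rng.normal(0, 1, (12, 12))
        w = (w + w.T) / 2
        part = rng.integers(0, 4, 12)
        np.testing.assert_allclose(
            module_degree_z(w, part), naive_module_z(w, part), atol=1e-12
        )

    def test_z_sums_to_zero_within_modules(self, rng):
        w = np.abs(rng.normal(0, 1, (15, 15)))
        w = (w + w.T) / 2
        part = rng.integers(0, 3, 15)
        z = module_degree_z(w, part)
        for s in np.unique(part):
            members = part == s
            if members.sum() >= 2:
                assert z[members].sum() == pytest.approx(0.0, abs=1e-10)


class TestCartographicProfile:
    def test_constant_values_land_in_single_bin(self):
        topo = TopologySeries(
            participation=np.full((6, 9), 0.42), module_z=np.full((6, 9), 1.3)
        )
        prof = cartographic_profile(topo, n_bins=50)
        assert prof.counts.sum() == 6 * 9
        assert (prof.counts > 0).sum() == 1

    def test_counts_conserved_under_any_binning(self, rng):
        topo = TopologySeries(
            participation=rng.random((10, 20)),
            module_z=rng.normal(0, 3, (10, 20)),  # values outside clip range included
        )
        for bins in (10, 100):
            prof = cartographic_profile(topo, n_bins=bins)
            assert prof.counts.sum() == 200
        assert cartographic_profile(topo, normalise=True).counts.sum() == pytest.approx(1.0)


class TestSegregatedOccupancy:
    def test_bimodal_planted_values_recovered(self, rng):
        n_r, n_w = 10, 40
        low = rng.normal(0.1, 0.01, (n_r, n_w // 2))
        high = rng.normal(0.7, 0.01, (n_r, n_w // 2))
        b = np.concatenate([low, high], axis=1)
        topo = TopologySeries(participation=b, module_z=np.zeros_like(b))
        occ = segregated_occupancy(topo, seed=0)
        np.testing.assert_allclose(occ.centroids, [0.1, 0.7], atol=0.02)
        np.testing.assert_allclose(occ.occupancy, 0.5, atol=1e-12)

    def test_fully_segregated_region(self, rng):
        b = np.vstack([rng.normal(0.1, 0.01, 30), rng.normal(0.7, 0.01, 30)])
        topo = TopologySeries(participation=b, module_z=np.zeros_like(b))
        occ = segregated_occupancy(topo, seed=0)
        assert occ.occupancy[0] == 1.0
        assert occ.occupancy[1] == 0.0

    def test_window_order_invariance(self, rng):
        b = rng.random((8, 30))
        topo = TopologySeries(participation=b, module_z=np.zeros_like(b))
        perm = rng.permutation(30)
        topo_p = TopologySeries(participation=b[:, perm], module_z=np.zeros_like(b))
        a = segregated_occupancy(topo, seed=1)
        c = segregated_occupancy(topo_p, seed=1)
        np.testing.assert_allclose(a.occupancy, c.occupancy)

    def test_degenerate_input_rejected(self):
        topo = TopologySeries(
            participation=np.full((3, 5), 0.5), module_z=np.zeros((3, 5))
        )
        with pytest.raises(ValueError, match="distinct"):
            segregated_occupancy(topo)


def test_topology_series_shapes(rng):
    part = np.repeat(np.arange(3), 10)
    model = StateModel(30, 1, [part], 0.7, 0.1, 5, 0.4, seed=2)
    sim = simulate_subject(model, 100)
    dc = mtd_tensor(sim.ts)
    assign = detect_communities(dc, seed=0)
    topo = topology_series(dc, assign)
    assert topo.participation.shape == (30, dc.n_windows)
    assert np.all(topo.participation >= 0) and np.all(topo.participation <= 1)
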