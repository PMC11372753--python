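"""RDF, cutoff selection, same-type graphs, degree and connectivity metrics."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import brute_force_pairs
from monomix.network import (NoCutoffError, RDFProfile, build_same_type_graph,
                             compute_rdf, mean_connectivity, mean_node_degree,
                             metrics_over_trajectory, min_edge_cut_per_node,
                             select_cutoff)
from monomix.synth import (MonolayerFrame, apply_staggering,
                           build_hexagonal_monolayer, demix_labels, desorb,
                           hexagonal_lattice_constant, make_trajectory)


def poisson_frame(n=800, L=60.0, seed=0, species="LA"):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(0, L, n), rng.uniform(0, L, n), np.full(n, 120.0)])
    return MonolayerFrame(
        ids=np.arange(n), species=np.full(n, species), protonated=np.ones(n, bool),
        positions=pos, box=np.array([L, L, 160.0]), leaflet=np.full(n, "upper"),
        present=np.ones(n, bool),
    )


class TestRDF:
    def test_poisson_points_give_unity(self):
        # ideal-gas g(r) = 1 within 5% beyond the first couple of bins
        frames = [poisson_frame(seed=s) for s in range(20)]
        rdf = compute_rdf(frames, ("all", "all"), r_max=25.0, bin_width=0.5)
        far = rdf.r > 2 * rdf.bin_width
        assert np.all(np.abs(rdf.g[far] - 1.0) < 0.05)

    def test_hexagonal_lattice_first_shell_peak(self, pure_la):
        frame = build_hexagonal_monolayer(1024, 20.0, pure_la, seed=0)
        a = hexagonal_lattice_constant(20.0)
        rdf = compute_rdf(frame, ("LA", "LA"), r_max=12.0, bin_width=0.1)
        # first nonzero bin contains r = a; nothing between the shells
        nonzero = np.flatnonzero(rdf.g > 0)
        first = nonzero[0]
        assert rdf.r[first] == pytest.approx(a, abs=rdf.bin_width)
        between = (rdf.r > a + 0.2) & (rdf.r < math.sqrt(3) * a - 0.2)
        assert np.all(rdf.g[between] == 0)

    def test_single_molecule_all_zero(self, pure_la):
        frame = build_hexagonal_monolayer(1, 20.0, pure_la, seed=0)
        rdf = compute_rdf(frame, ("LA", "LA"), r_max=1.5, bin_width=0.1)
        assert np.all(rdf.g == 0)

    def test_rmax_beyond_half_box_rejected(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        with pytest.raises(ValueError):
            compute_rdf(frame, ("LA", "LA"), r_max=100.0)

    def test_profile_invariants(self):
        rdf = compute_rdf(poisson_frame(), ("all", "all"), r_max=20.0, bin_width=0.5)
        assert np.all(np.diff(rdf.r) > 0)
        assert np.all(rdf.g >= 0)


class TestCutoffSelection:
    def test_jittered_lattice_cutoff_between_shells(self, pure_la):
        frame = build_hexagonal_monolayer(1024, 20.0, pure_la, seed=1)
        traj = make_trajectory(frame, 5, xy_jitter_sd=0.4, seed=2)
        rdf = compute_rdf(traj, ("all", "all"), r_max=15.0, bin_width=0.1)
        cutoff = select_cutoff(rdf)
        a = hexagonal_lattice_constant(20.0)
        assert a < cutoff < math.sqrt(3) * a  # 4.81 .. 8.33 Å

    def test_structureless_profile_signals_no_cutoff(self):
        r = np.arange(0.05, 10.0, 0.1)
        flat = RDFProfile(r=r, g=np.ones_like(r), bin_width=0.1, selection="flat")
        with pytest.raises(NoCutoffError):
            select_cutoff(flat)

    def test_smoothing_window_validated(self):
        r = np.arange(0.05, 10.0, 0.1)
        prof = RDFProfile(r=r, g=np.ones_like(r), bin_width=0.1, selection="x")
        with pytest.raises(ValueError):
            select_cutoff(prof, smooth_window=4)


class TestSameTypeGraph:
    def test_pure_hexagonal_lattice_is_6_regular(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        g = build_same_type_graph(frame, "LA", 7.2)
        degrees = [d for _, d in g.graph.degree()]
        assert degrees == [6] * 100
        assert mean_node_degree(g) == 6.0

    def test_matches_brute_force_oracle(self, binary_la_pa):
        # exhaustive O(n²) minimum-image check on frames up to 500 nodes,
        # including jittered, demixed and partially desorbed configurations
        for seed, jitter, des in [(0, 0.0, 0.0), (1, 0.5, 0.0), (2, 0.4, 0.3)]:
            frame = build_hexagonal_monolayer(400, 20.0, binary_la_pa, seed=seed)
            if jitter:
                frame = make_trajectory(frame, 2, xy_jitter_sd=jitter, seed=seed)[1]
            if des:
                frame = desorb(frame, des, "LA", seed=seed)
            for sp in ("LA", "PA"):
                g = build_same_type_graph(frame, sp, 7.2)
                assert set(map(tuple, map(sorted, g.graph.edges()))) == \
                    set(map(tuple, map(sorted, brute_force_pairs(frame, sp, 7.2))))

    def test_absent_species_gives_empty_graph(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        g = build_same_type_graph(frame, "SA", 7.2)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_desorbed_molecules_excluded(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        half = desorb(frame, 0.5, "LA", seed=3)
        g = build_same_type_graph(half, "LA", 7.2)
        assert g.n_nodes == 50

    def test_invariant_under_translation_and_wrapping(self, binary_la_pa):
        frame = build_hexagonal_monolayer(144, 20.0, binary_la_pa, seed=5)
        ref = build_same_type_graph(frame, "LA", 7.2)
        for shift in [(3.7, -11.2), (100.5, 42.0)]:
            moved = frame.copy()
            moved.positions[:, 0] += shift[0]
            moved.positions[:, 1] += shift[1]
            moved.wrap()
            g = build_same_type_graph(moved, "LA", 7.2)
            assert set(g.graph.edges()) == set(ref.graph.edges())

    def test_nonpositive_cutoff_rejected(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        with pytest.raises(ValueError):
            build_same_type_graph(frame, "LA", 0.0)

    def test_random_equimolar_expected_degree(self, binary_la_pa):
        # random labels on an n-site 6-coordinated lattice: E[same-type
        # degree] = 6·(n/2−1)/(n−1) → 3; checked at n=1024 over 50 seeds
        vals = []
        for s in range(50):
            frame = build_hexagonal_monolayer(1024, 20.0, binary_la_pa, seed=s)
            for sp in ("LA", "PA"):
                vals.append(mean_node_degree(build_same_type_graph(frame, sp, 7.2)))
        expected = 6 * (512 - 1) / 1023
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)


class TestConnectivity:
    def test_complete_graph(self):
        assert mean_connectivity(nx.complete_graph(4)) == pytest.approx(3.0)

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        # 2 connected pairs contribute 1 each; 4 cross pairs contribute 0
        assert mean_connectivity(g) == pytest.approx(1.0 / 3.0)

    def test_path_graph_degree(self):
        g = nx.path_graph(3)
        assert mean_node_degree(g) == pytest.approx(4.0 / 3.0)

    def test_fully_disconnected_is_zero(self):
        g = nx.empty_graph(10)
        assert mean_connectivity(g) == 0.0
        assert mean_node_degree(g) == 0.0

    def test_empty_graph_conventions(self):
        g = nx.Graph()
        assert mean_connectivity(g) == 0.0
        assert mean_node_degree(g) == 0.0

    def test_whitney_bound_on_random_graphs(self):
        # Whitney: local connectivity κ(u,v) ≤ min(deg u, deg v), so the
        # pair average is bounded by the pair average of min degrees
        rng = np.random.default_rng(0)
        from itertools import combinations
        for trial in range(5):
            g = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(1 << 16)))
            if g.number_of_edges() == 0:
                continue
            deg = dict(g.degree())
            bound = np.mean([min(deg[u], deg[v])
                             for u, v in combinations(g.nodes, 2)])
            assert mean_connectivity(g) <= bound + 1e-9

    def test_min_edge_cut_reading_equals_component_degree(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        g = build_same_type_graph(frame, "LA", 7.2)
        assert min_edge_cut_per_node(g) == pytest.approx(6.0)


class TestTrajectoryMetrics:
    def test_static_trajectory_zero_sd(self, binary_la_pa):
        frame = build_hexagonal_monolayer(144, 20.0, binary_la_pa, seed=0)
        traj = make_trajectory(frame, 4, xy_jitter_sd=0.0, seed=1)
        series = metrics_over_trajectory(traj, ["LA", "PA"], cutoff=7.2,
                                         connectivity=False)
        for sp in ("LA", "PA"):
            assert series.summary[sp]["mean_degree"][1] == pytest.approx(0.0)

    def test_demixed_exceeds_mixed_for_both_species(self, binary_la_pa):
        frame = build_hexagonal_monolayer(256, 20.0, binary_la_pa, seed=2)
        mixed = metrics_over_trajectory([frame], ["LA", "PA"], cutoff=7.2,
                                        connectivity=False)
        demixed_frame = demix_labels(frame, J=5.0, n_sweeps=3000, seed=3)
        demixed = metrics_over_trajectory([demixed_frame], ["LA", "PA"], cutoff=7.2,
                                          connectivity=False)
        for sp in ("LA", "PA"):
            assert demixed.summary[sp]["mean_degree"][0] > \
                mixed.summary[sp]["mean_degree"][0]

    def test_desorbed_species_loses_connectivity(self, binary_la_pa):
        frame = build_hexagonal_monolayer(144, 20.0, binary_la_pa, seed=4)
        gone = desorb(frame, 0.6, "LA", seed=5)
        series = metrics_over_trajectory([gone], ["LA", "PA"], cutoff=7.2)
        assert series.summary["LA"]["mean_connectivity"][0] < \
            series.summary["PA"]["mean_connectivity"][0]

    def test_auto_cutoff_matches_manual_selection(self, pure_la):
        frame = build_hexagonal_monolayer(256, 20.0, pure_la, seed=6)
        traj = make_trajectory(frame, 3, xy_jitter_sd=0.4, seed=7)
        series = metrics_over_trajectory(traj, ["LA"], cutoff="auto",
                                         connectivity=False)
        a = hexagonal_lattice_constant(20.0)
        assert a < series.cutoff < math.sqrt(3) * a
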