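"""Synthetic monolayer generator: lattice geometry, demixing, staggering, desorption."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from monomix.network import build_same_type_graph, mean_node_degree
from monomix.synth import (MonolayerFrame, Trajectory, apply_staggering,
                           build_hexagonal_monolayer, demix_labels, desorb,
                           hexagonal_lattice_constant,
                           hexagonal_neighbor_table, make_trajectory,
                           valid_lattice_sizes)


class TestHexagonalLattice:
    def test_lattice_constant_at_mma20(self):
        # a = sqrt(2*20/sqrt(3)) = 4.806 Å
        assert hexagonal_lattice_constant(20.0) == pytest.approx(4.8056, abs=1e-3)

    def test_nearest_neighbor_distance(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        a = hexagonal_lattice_constant(20.0)
        # every site's nearest neighbor sits exactly one lattice constant away
        i, j = np.triu_indices(100, k=1)
        d = frame.pair_distances_xy(i, j)
        assert d.min() == pytest.approx(a, rel=1e-9)

    def test_every_site_has_six_first_shell_neighbors(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        table = hexagonal_neighbor_table(frame, cutoff=7.2)
        assert table.shape == (100, 6)
        assert (table >= 0).all()
        a = hexagonal_lattice_constant(20.0)
        for i in range(100):
            d = frame.pair_distances_xy(np.full(6, i), table[i])
            assert np.allclose(d, a, rtol=1e-9)

    def test_site_density_matches_mma_within_one_percent(self, binary_la_pa):
        for n, mma in [(100, 20.0), (144, 23.0), (1024, 20.0)]:
            frame = build_hexagonal_monolayer(n, mma, binary_la_pa, seed=1)
            density = n / (frame.box[0] * frame.box[1])
            assert density == pytest.approx(1.0 / mma, rel=0.01)

    def test_untileable_n_lists_alternatives(self, pure_la):
        with pytest.raises(ValueError, match="valid nearby"):
            build_hexagonal_monolayer(101, 20.0, pure_la, seed=0)
        assert 100 in valid_lattice_sizes(101)

    def test_single_molecule_frame(self, pure_la):
        frame = build_hexagonal_monolayer(1, 20.0, pure_la, seed=0)
        assert frame.n_molecules == 1
        g = build_same_type_graph(frame, "LA", 7.2)
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_species_assignment_follows_mole_fractions(self, binary_la_pa):
        frame = build_hexagonal_monolayer(1024, 20.0, binary_la_pa, seed=2)
        frac_la = np.mean(frame.species == "LA")
        assert frac_la == pytest.approx(0.5, abs=0.06)

    def test_protonation_states_drawn_at_ph(self, species, pure_la):
        # LA at pH 7: protonated fraction 0.7336
        frame = build_hexagonal_monolayer(1024, 20.0, pure_la, seed=3, pH=7.0)
        assert np.mean(frame.protonated) == pytest.approx(0.7336, abs=0.05)

    def test_same_seed_reproducible(self, binary_la_pa):
        f1 = build_hexagonal_monolayer(100, 20.0, binary_la_pa, seed=9)
        f2 = build_hexagonal_monolayer(100, 20.0, binary_la_pa, seed=9)
        assert (f1.species == f2.species).all()
        assert np.array_equal(f1.positions, f2.positions)


class TestDemixing:
    def test_zero_sweeps_is_identity(self, binary_la_pa):
        frame = build_hexagonal_monolayer(64, 20.0, binary_la_pa, seed=0)
        out = demix_labels(frame, J=2.0, n_sweeps=0, seed=1)
        assert (out.species == frame.species).all()

    def test_species_counts_conserved(self, binary_la_pa):
        frame = build_hexagonal_monolayer(144, 20.0, binary_la_pa, seed=4)
        out = demix_labels(frame, J=3.0, n_sweeps=500, seed=5)
        for sp in ("LA", "PA"):
            assert (out.species == sp).sum() == (frame.species == sp).sum()

    def test_j0_mean_same_type_degree_near_three(self, binary_la_pa):
        # well-mixed equimolar binary on a 6-coordinated lattice: ~3 same-type
        frame = build_hexagonal_monolayer(1024, 20.0, binary_la_pa, seed=6)
        out = demix_labels(frame, J=0.0, n_sweeps=50, seed=7)
        degs = [mean_node_degree(build_same_type_graph(out, sp, 7.2))
                for sp in ("LA", "PA")]
        assert np.mean(degs) == pytest.approx(3.0, abs=0.3)

    def test_strong_affinity_forms_domains(self, binary_la_pa):
        # J=5, 1e4 sweeps on 1024 sites: same-type degree well above random
        frame = build_hexagonal_monolayer(1024, 20.0, binary_la_pa, seed=8)
        out = demix_labels(frame, J=5.0, n_sweeps=10_000, seed=9)
        for sp in ("LA", "PA"):
            assert mean_node_degree(build_same_type_graph(out, sp, 7.2)) > 4.5

    def test_j0_preserves_label_measure(self, binary_la_pa):
        # chi-square on per-site LA occupancy over 200 seeds: J=0 swaps must
        # leave every site equally likely to hold either label
        frame = build_hexagonal_monolayer(36, 20.0, binary_la_pa, seed=10)
        n_seeds = 200
        occ = np.zeros(36)
        for s in range(n_seeds):
            out = demix_labels(frame, J=0.0, n_sweeps=20, seed=1000 + s)
            occ += out.species == "LA"
        expected = n_seeds * np.mean(frame.species == "LA")
        stat, p = chisquare(occ, f_exp=np.full(36, expected))
        assert p > 0.01

    def test_negative_inputs_rejected(self, binary_la_pa):
        frame = build_hexagonal_monolayer(64, 20.0, binary_la_pa, seed=0)
        with pytest.raises(ValueError):
            demix_labels(frame, J=-1.0, n_sweeps=10)
        with pytest.raises(ValueError):
            demix_labels(frame, J=1.0, n_sweeps=-1)


class TestStaggering:
    def test_zero_offsets_leave_frame_flat(self, binary_la_pa):
        frame = build_hexagonal_monolayer(64, 20.0, binary_la_pa, seed=0)
        out = apply_staggering(frame, {True: 0.0, False: 0.0}, jitter_sd=0.0)
        assert np.array_equal(out.positions, frame.positions)

    def test_offsets_move_only_z(self, pure_la):
        frame = build_hexagonal_monolayer(64, 20.0, pure_la, seed=0)
        out = apply_staggering(frame, {True: 0.7, False: -1.0}, jitter_sd=0.2, seed=3)
        assert np.array_equal(out.positions[:, :2], frame.positions[:, :2])
        assert not np.array_equal(out.positions[:, 2], frame.positions[:, 2])

    def test_deprotonated_sits_lower(self, pure_la):
        frame = build_hexagonal_monolayer(256, 20.0, pure_la, seed=1, pH=7.44)
        out = apply_staggering(frame, {True: 0.0, False: -1.0}, jitter_sd=0.1, seed=2)
        z_prot = out.positions[out.protonated, 2].mean()
        z_deprot = out.positions[~out.protonated, 2].mean()
        assert z_deprot < z_prot

    def test_missing_offset_key_rejected(self, binary_la_pa):
        frame = build_hexagonal_monolayer(64, 20.0, binary_la_pa, seed=0)
        with pytest.raises(KeyError):
            apply_staggering(frame, {("LA", True): 0.0}, jitter_sd=0.0)

    def test_species_specific_offsets_applied(self, binary_la_pa):
        frame = build_hexagonal_monolayer(144, 20.0, binary_la_pa, seed=2)
        out = apply_staggering(frame, {("LA", True): 0.5, ("PA", True): -0.5})
        z0 = frame.positions[0, 2]
        assert np.allclose(out.positions[out.species == "LA", 2], z0 + 0.5)
        assert np.allclose(out.positions[out.species == "PA", 2], z0 - 0.5)


class TestDesorption:
    def test_zero_fraction_is_identity(self, binary_la_pa):
        frame = build_hexagonal_monolayer(100, 20.0, binary_la_pa, seed=0)
        out = desorb(frame, 0.0, "LA", seed=1)
        assert out.present.all()

    def test_exact_count_removed(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        out = desorb(frame, 0.3, "LA", seed=1)
        assert (~out.present).sum() == 30

    def test_full_desorption_empties_graph(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        out = desorb(frame, 1.0, "LA", seed=1)
        g = build_same_type_graph(out, "LA", 7.2)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_identity_preserved(self, binary_la_pa):
        frame = build_hexagonal_monolayer(100, 20.0, binary_la_pa, seed=0)
        out = desorb(frame, 0.5, "LA", seed=1)
        assert np.array_equal(out.ids, frame.ids)
        assert np.array_equal(out.positions, frame.positions)
        # only LA molecules were flagged
        assert out.present[out.species == "PA"].all()

    def test_unknown_species_rejected(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        with pytest.raises(ValueError):
            desorb(frame, 0.5, "XX", seed=1)

    def test_fraction_out_of_range_rejected(self, pure_la):
        frame = build_hexagonal_monolayer(100, 20.0, pure_la, seed=0)
        with pytest.raises(ValueError):
            desorb(frame, 1.5, "LA")


class TestTrajectory:
    def test_single_frame(self, pure_la):
        frame = build_hexagonal_monolayer(64, 20.0, pure_la, seed=0)
        traj = make_trajectory(frame, 1, seed=1)
        assert len(traj) == 1

    def test_frame0_equals_input_and_box_constant(self, binary_la_pa):
        frame = build_hexagonal_monolayer(64, 20.0, binary_la_pa, seed=0)
        traj = make_trajectory(frame, 20, xy_jitter_sd=0.4, seed=1)
        assert np.array_equal(traj[0].positions, frame.positions)
        for f in traj:
            assert np.array_equal(f.box, frame.box)
            assert np.array_equal(f.ids, frame.ids)

    def test_same_seed_identical(self, pure_la):
        frame = build_hexagonal_monolayer(64, 20.0, pure_la, seed=0)
        t1 = make_trajectory(frame, 5, xy_jitter_sd=0.4, seed=7)
        t2 = make_trajectory(frame, 5, xy_jitter_sd=0.4, seed=7)
        for f1, f2 in zip(t1, t2):
            assert np.array_equal(f1.positions, f2.positions)

    def test_nonpositive_length_rejected(self, pure_la):
        frame = build_hexagonal_monolayer(64, 20.0, pure_la, seed=0)
        with pytest.raises(ValueError):
            make_trajectory(frame, 0)
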