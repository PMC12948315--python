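import numpy as np
import pytest
from dataclasses import replace

from cortexcaps import (
    Connectome,
    ModelParameters,
    SyntheticSpec,
    attractor_sweep,
    basin_occupancy_and_templates,
    canonicalize_cycle,
    default_parameters,
    detect_attractors,
    enumerate_attractors,
    interhemispheric_hamming,
    is_homotopic,
    load_attractor_set,
    mirror_pairs,
    mirror_state,
    run_to_attractor,
    save_attractor_set,
    synthetic_connectome,
)
from cortexcaps.attractors import Attractor, mirror_attractor

from conftest import exact_basin_occupancy, oracle_orbits


def _two_unit_not_loop():
    """Two regions whose E populations each flip the other (period-2)."""
    # E0 drives E1 and vice versa with weight 1; each unit also receives
    # self-inhibition via its I population wired to fire whenever E fired.
    c = Connectome(
        weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
        region_labels=("L0", "R0"),
        hemisphere=("L", "R"),
    )
    p = ModelParameters(g=1.0, j_ei=0.0, j_ie=0.0, j_ii=0.0,
                        v_thr=0.5, sigma=0.0)
    return c, p


class TestRunToAttractor:
    def test_fixed_point_detected_as_stationary(self):
        c, p = _two_unit_not_loop()
        a = run_to_attractor(np.array([1.0, 1.0, 0.0, 0.0]), c, p)
        assert a.kind == "stationary"
        np.testing.assert_array_equal(a.cycle[0][:2], [1, 1])

    def test_not_loop_gives_period_two_oscillation(self):
        c, p = _two_unit_not_loop()
        a = run_to_attractor(np.array([1.0, 0.0, 0.0, 0.0]), c, p)
        assert a.kind == "oscillatory"
        assert a.period == 2
        # the two states are (E0 on) and (E1 on), alternating
        e_states = {tuple(row[:2]) for row in a.cycle}
        assert e_states == {(1, 0), (0, 1)}

    def test_linear_variant_rejected(self):
        c, p = _two_unit_not_loop()
        with pytest.raises(ValueError):
            run_to_attractor(np.zeros(4), c, replace(p, activation="linear"))


class TestCanonicalization:
    @pytest.mark.parametrize("rotation", [0, 1, 2, 3])
    def test_any_rotation_canonicalizes_identically(self, rotation):
        rng = np.random.default_rng(7)
        cycle = rng.integers(0, 2, size=(4, 6)).astype(np.uint8)
        while len({row.tobytes() for row in cycle}) < 4:
            cycle = rng.integers(0, 2, size=(4, 6)).astype(np.uint8)
        rotated = np.roll(cycle, rotation, axis=0)
        np.testing.assert_array_equal(
            canonicalize_cycle(cycle), canonicalize_cycle(rotated)
        )


class TestDetection:
    def test_dead_network_has_single_silent_attractor(self):
        c = Connectome(weights=np.zeros((2, 2)), region_labels=("a", "b"),
                       hemisphere=("L", "R"))
        p = ModelParameters(g=1.0, j_ei=0.0, j_ie=0.0, j_ii=0.0,
                            v_thr=0.5, sigma=0.05)
        s = detect_attractors(c, p, n_restarts=50, seed=0)
        assert len(s) == 1
        assert s.attractors[0].kind == "stationary"
        assert np.all(s.attractors[0].cycle == 0)

    def test_same_seed_identical_sets(self, small_net):
        c, p = small_net
        a = detect_attractors(c, p, n_restarts=100, seed=5)
        b = detect_attractors(c, p, n_restarts=100, seed=5)
        assert [x.key for x in a.attractors] == [x.key for x in b.attractors]
        np.testing.assert_array_equal(a.restart_hits, b.restart_hits)

    def test_stationary_listed_before_oscillatory(self):
        c, p = _two_unit_not_loop()
        s = enumerate_attractors(c, p)
        kinds = [a.kind for a in s.attractors]
        assert kinds == sorted(kinds, key=lambda k: k != "stationary")

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_exhaustive_detection_matches_independent_orbit_oracle(self, seed):
        c = synthetic_connectome(SyntheticSpec(n_regions=4, seed=seed))
        p = default_parameters(c)
        detected = enumerate_attractors(c, p)
        oracle = oracle_orbits(c, p)
        got = {
            tuple(tuple(float(x) for x in row) for row in a.cycle)
            for a in detected.attractors
        }
        # oracle cycles are rotated to start at the minimal state tuple;
        # compare as rotation-equivalence classes via canonicalization
        def canon(cycle):
            arr = np.array(cycle, dtype=np.uint8)
            return canonicalize_cycle(arr).tobytes()

        assert {canon(cyc) for cyc in oracle} == {canon(cyc) for cyc in got}


class TestHomotopicity:
    def test_uniform_states_are_homotopic(self):
        mm = np.array([2, 3, 0, 1])
        all_on = Attractor(cycle=np.ones((1, 8), dtype=np.uint8))
        assert is_homotopic(all_on, mm)

    def test_one_sided_state_is_not_homotopic(self):
        mm = np.array([2, 3, 0, 1])
        left_only = np.zeros((1, 8), dtype=np.uint8)
        left_only[0, :2] = 1  # E populations of the left hemisphere only
        assert not is_homotopic(Attractor(cycle=left_only), mm)

    def test_mirrored_attractor_is_attractor_on_symmetric_connectome(
        self, small_net
    ):
        c, p = small_net
        s = enumerate_attractors(c, p)
        keys = {a.key for a in s.attractors}
        for a in s.attractors:
            assert mirror_attractor(a, c.mirror_map).key in keys

    def test_mirror_pairs_involution_and_self_pairing(self, small_net):
        c, p = small_net
        s = enumerate_attractors(c, p)
        pairs = dict(mirror_pairs(s, c.mirror_map))
        for i, j in pairs.items():
            assert pairs[j] == i
            assert (i == j) == is_homotopic(s.attractors[i], c.mirror_map)

    def test_two_region_symmetric_net_pairs_one_sided_fixed_points(self):
        # mutual excitation too weak to ignite the other side, strong
        # self-loops: (1,0) and (0,1) are both fixed and mirror-paired
        c = Connectome(weights=np.array([[1.0, 0.2], [0.2, 1.0]]),
                       region_labels=("L0", "R0"), hemisphere=("L", "R"))
        p = ModelParameters(g=1.0, j_ei=0.0, j_ie=0.0, j_ii=0.0,
                            v_thr=0.5, sigma=0.0)
        s = enumerate_attractors(c, p)
        one_sided = [
            i for i, a in enumerate(s.attractors)
            if a.kind == "stationary" and a.cycle[0, :2].sum() == 1
        ]
        assert len(one_sided) == 2
        pairs = dict(mirror_pairs(s, c.mirror_map))
        assert pairs[one_sided[0]] == one_sided[1]


class TestHamming:
    def test_homotopic_trajectory_zero(self):
        mm = np.array([2, 3, 0, 1])
        states = np.tile([1, 0, 1, 0, 0, 1, 0, 1], (5, 1))
        assert interhemispheric_hamming(states, mm) == 0.0

    def test_complementary_hemispheres_one(self):
        mm = np.array([2, 3, 0, 1])
        states = np.tile([1, 1, 0, 0, 0, 0, 0, 0], (5, 1))
        assert interhemispheric_hamming(states, mm) == 1.0

    def test_single_mismatch_half(self):
        mm = np.array([2, 3, 0, 1])
        # L E = (1, 0), R E = (1, 1): one of two pairs differs
        states = np.array([[1, 0, 1, 1, 0, 0, 0, 0]])
        assert interhemispheric_hamming(states, mm) == 0.5


class TestOccupancy:
    def test_noise_free_run_from_attractor_occupies_its_basin(self):
        c, p = _two_unit_not_loop()
        s = enumerate_attractors(c, p)
        silent = next(
            i for i, a in enumerate(s.attractors)
            if a.kind == "stationary" and np.all(a.cycle == 0)
        )
        filled = basin_occupancy_and_templates(
            c, p, s, n_steps=50, n_reps=1, seed=0,
            collapse_oscillatory=False, init=np.zeros(4),
        )
        assert filled.occupancy[silent] == 1.0

    def test_occupancy_normalized_and_matches_exact_chain(self, small_net):
        c, p = small_net
        s = enumerate_attractors(c, p)
        filled = basin_occupancy_and_templates(
            c, p, s, n_steps=40_000, seed=3, collapse_oscillatory=False
        )
        assert filled.occupancy.sum() == pytest.approx(1.0)
        exact = exact_basin_occupancy(c, p, s)
        overlap = np.minimum(exact, filled.occupancy).sum()
        assert overlap > 0.95

    def test_collapse_merges_all_oscillatory_basins(self):
        c, p = _two_unit_not_loop()
        s = enumerate_attractors(c, p)
        filled = basin_occupancy_and_templates(
            c, replace(p, sigma=0.1), s, n_steps=500, seed=1,
            collapse_oscillatory=True,
        )
        osc_basins = [
            g for g in filled.basin_members
            if filled.attractors[g[0]].kind == "oscillatory"
        ]
        assert len(osc_basins) <= 1


class TestSweep:
    def test_sweep_returns_row_per_grid_value(self, small_net):
        c, p = small_net
        table = attractor_sweep(
            c, p, "W", [0.0, 1.0], n_restarts=50, occupancy_steps=500, seed=0
        )
        assert list(table["W"]) == [0.0, 1.0]
        assert set(table.columns) >= {
            "n_stationary", "n_oscillatory", "p_stationary", "p_oscillatory"
        }
        prob = table["p_stationary"] + table["p_oscillatory"]
        np.testing.assert_allclose(prob, 1.0)

    def test_z_sweep_scales_couplings(self, small_net):
        c, p = small_net
        table = attractor_sweep(
            c, p, "z", [0.0, 1.0], n_restarts=50, occupancy_steps=500, seed=0
        )
        assert len(table) == 2


class TestSerialization:
    def test_round_trip_bit_exact(self, small_net, tmp_path):
        c, p = small_net
        s = detect_attractors(c, p, n_restarts=200, seed=1)
        filled = basin_occupancy_and_templates(c, p, s, n_steps=2000, seed=2)
        path = tmp_path / "aset.json"
        save_attractor_set(filled, path)
        loaded = load_attractor_set(path)
        assert [a.key for a in loaded.attractors] == [
            a.key for a in filled.attractors
        ]
        np.testing.assert_array_equal(loaded.occupancy, filled.occupancy)
        np.testing.assert_array_equal(loaded.templates, filled.templates)
        assert loaded.basin_members == filled.basin_members
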