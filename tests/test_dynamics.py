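import numpy as np
import pytest

from cortexcaps import (
    BOLD_KERNEL,
    Connectome,
    ModelParameters,
    SyntheticSpec,
    activation,
    bold_convolve,
    simulate,
    step,
    synaptic_signal,
    synthetic_connectome,
)
from cortexcaps.attractors import mirror_state


def _one_region(w_self, j_ei=0.0, j_ie=0.0, j_ii=0.0, v_thr=0.5, sigma=0.0):
    c = Connectome(
        weights=np.array([[0.0, 0.0], [0.0, 0.0]]),
        region_labels=("L0", "R0"),
        hemisphere=("L", "R"),
    )
    # 2-region connectome with only self-loops so each region acts alone
    c = c.with_weights(np.diag([w_self, w_self]))
    p = ModelParameters(g=1.0, j_ei=j_ei, j_ie=j_ie, j_ii=j_ii,
                        v_thr=v_thr, sigma=sigma)
    return c, p


class TestActivation:
    @pytest.mark.parametrize(
        "x,variant,expected",
        [(-0.5, "heaviside", 0.0), (0.0, "heaviside", 1.0),
         (2.0, "heaviside", 1.0), (0.37, "linear", 0.37)],
    )
    def test_values(self, x, variant, expected):
        assert activation(x, variant) == expected


class TestStep:
    def test_zero_weights_positive_threshold_silences_everything(self):
        c, p = _one_region(w_self=0.0, v_thr=0.2)
        for init in ([1, 1, 1, 1], [0, 1, 0, 1]):
            out = step(np.array(init, dtype=float), c, p)
            assert np.all(out == 0)

    def test_self_sustaining_unit_stays_on(self):
        # g*J_EE = 1 on the diagonal, threshold 0.5: V = 1 >= 0.5
        c, p = _one_region(w_self=1.0, v_thr=0.5)
        state = np.array([1.0, 1.0, 0.0, 0.0])
        out = step(state, c, p)
        np.testing.assert_array_equal(out[:2], [1.0, 1.0])

    def test_silent_unit_stays_off(self):
        c, p = _one_region(w_self=1.0, v_thr=0.5)
        out = step(np.zeros(4), c, p)
        assert np.all(out == 0)

    def test_synchronous_update_uses_old_state_only(self):
        # a 2-unit E chain: region 1 copies region 0's previous state
        c = Connectome(
            weights=np.array([[0.0, 0.0], [1.0, 0.0]]),
            region_labels=("L0", "R0"),
            hemisphere=("L", "R"),
        )
        p = ModelParameters(g=1.0, j_ei=0.0, j_ie=0.0, j_ii=0.0,
                            v_thr=0.5, sigma=0.0)
        out = step(np.array([1.0, 0.0, 0.0, 0.0]), c, p)
        # region 1 sees region 0 on; region 0 sees nothing
        np.testing.assert_array_equal(out[:2], [0.0, 1.0])

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        c = synthetic_connectome(SyntheticSpec(n_regions=6, seed=4))
        p = ModelParameters(g=0.7, j_ei=rng.uniform(-0.5, 0, 6), j_ie=0.4,
                            j_ii=-0.2, v_thr=0.3, sigma=0.0)
        state = rng.integers(0, 2, 12).astype(float)
        # permute regions (same permutation on E and I blocks and on W, J_EI)
        perm = np.array([2, 0, 1, 5, 3, 4])
        cp = Connectome(
            weights=c.weights[np.ix_(perm, perm)],
            region_labels=tuple(c.region_labels[i] for i in perm),
            hemisphere=tuple(c.hemisphere[i] for i in perm),
            mirror_map=np.argsort(perm)[c.mirror_map[perm]],
        )
        pp = ModelParameters(g=0.7, j_ei=np.asarray(p.j_ei)[perm], j_ie=0.4,
                             j_ii=-0.2, v_thr=0.3, sigma=0.0)
        sp = np.concatenate([state[:6][perm], state[6:][perm]])
        out = step(state, c, p)
        out_p = step(sp, cp, pp)
        np.testing.assert_array_equal(
            out_p, np.concatenate([out[:6][perm], out[6:][perm]])
        )


class TestSimulate:
    def test_fixed_point_constant_under_zero_noise(self):
        c, p = _one_region(w_self=1.0, v_thr=0.5)
        init = np.array([1.0, 1.0, 0.0, 0.0])
        traj = simulate(c, p, n_steps=20, init=init)
        assert np.all(traj.states == init)

    def test_default_length_matches_nine_minute_recording(self):
        c, p = _one_region(w_self=1.0, v_thr=0.5, sigma=0.1)
        traj = simulate(c, p, seed=0)
        assert traj.n_steps == 450

    def test_same_seed_bit_identical(self):
        c = synthetic_connectome(SyntheticSpec(n_regions=6, seed=1))
        p = ModelParameters(g=0.8, j_ei=-0.3, j_ie=0.5, j_ii=-0.1,
                            v_thr=0.35, sigma=0.15)
        a = simulate(c, p, n_steps=100, seed=42)
        b = simulate(c, p, n_steps=100, seed=42)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.syn, b.syn)

    def test_mirror_equivariance_of_noise_free_trajectories(self):
        c = synthetic_connectome(SyntheticSpec(n_regions=8, seed=3))
        assert c.is_mirror_symmetric()
        p = ModelParameters(g=0.8, j_ei=np.full(8, -0.3), j_ie=0.5,
                            j_ii=-0.1, v_thr=0.35, sigma=0.0)
        rng = np.random.default_rng(9)
        init = rng.integers(0, 2, 16).astype(float)
        traj = simulate(c, p, n_steps=30, init=init)
        traj_m = simulate(c, p, n_steps=30,
                          init=mirror_state(init, c.mirror_map))
        np.testing.assert_array_equal(
            traj_m.states, mirror_state(traj.states, c.mirror_map)
        )

    def test_homotopic_initial_state_stays_homotopic(self):
        c = synthetic_connectome(SyntheticSpec(n_regions=8, seed=3))
        p = ModelParameters(g=0.8, j_ei=np.full(8, -0.3), j_ie=0.5,
                            j_ii=-0.1, v_thr=0.35, sigma=0.0)
        # non-trivial homotopic state: random left hemisphere, mirrored right
        rng = np.random.default_rng(5)
        init = rng.integers(0, 2, 16).astype(float)
        init[4:8] = init[:4]
        init[12:16] = init[8:12]
        traj = simulate(c, p, n_steps=30, init=init)
        np.testing.assert_array_equal(
            traj.states, mirror_state(traj.states, c.mirror_map)
        )


class TestSynapticSignal:
    def test_silent_network_zero_signal(self):
        c, p = _one_region(w_self=0.8, j_ei=-0.3)
        syn = synaptic_signal(np.zeros((5, 4)), c, p)
        assert np.all(syn == 0)

    def test_hand_computed_value(self):
        # one active E-I pair: 0.8 * 1 + (-0.3) * 1 = 0.5
        c, p = _one_region(w_self=0.8, j_ei=-0.3)
        syn = synaptic_signal(np.array([1.0, 0.0, 1.0, 0.0]), c, p)
        assert syn[0, 0] == pytest.approx(0.5)
        assert syn[0, 1] == pytest.approx(0.0)

    def test_linear_in_g(self):
        c = synthetic_connectome(SyntheticSpec(n_regions=6, seed=2))
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, (20, 12)).astype(float)
        p1 = ModelParameters(g=0.5, j_ei=0.0, j_ie=0.4, j_ii=-0.2,
                             v_thr=0.3, sigma=0.0)
        p2 = ModelParameters(g=1.5, j_ei=0.0, j_ie=0.4, j_ii=-0.2,
                             v_thr=0.3, sigma=0.0)
        np.testing.assert_allclose(
            synaptic_signal(states, c, p2), 3 * synaptic_signal(states, c, p1)
        )


class TestBoldConvolve:
    def test_delta_kernel_is_identity(self):
        rng = np.random.default_rng(1)
        syn = rng.normal(size=(30, 4))
        np.testing.assert_allclose(bold_convolve(syn, kernel=[1.0]), syn)

    def test_constant_input_steady_state_is_kernel_gain(self):
        syn = np.ones((40, 2))
        out = bold_convolve(syn)
        assert out[-1, 0] == pytest.approx(1.436)
        assert BOLD_KERNEL.sum() == pytest.approx(1.436)

    def test_zero_input_zero_output(self):
        assert np.all(bold_convolve(np.zeros((20, 3))) == 0)

    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError):
            bold_convolve(np.ones((10, 1)), kernel=[])

    def test_kernel_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            bold_convolve(np.ones((3, 1)))
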