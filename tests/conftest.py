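"""Shared fixtures and independent oracles.

The oracles here re-derive the model's update rule and its exact
stationary behavior with deliberately naive code (explicit loops, full
transition matrices) so the package's vectorized implementations are
checked against an independent route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from cortexcaps import (
    default_parameters,
    study_connectome,
    synthetic_connectome,
    SyntheticSpec,
)


@pytest.fixture(scope="session")
def study_net():
    """The reference 10-region synthetic connectome and its parameters."""
    c = study_connectome()
    return c, default_parameters(c)


@pytest.fixture()
def small_net():
    """A 4-region (8-unit) mirror-symmetric net, exhaustively analyzable."""
    c = synthetic_connectome(SyntheticSpec(n_regions=4, seed=100))
    return c, default_parameters(c)


# ---------------------------------------------------------------------------
# Oracle: naive scalar-loop implementation of one deterministic update
# ---------------------------------------------------------------------------

def oracle_step(state, weights, g, j_ei, j_ie, j_ii, v_thr, z=1.0):
    """Hand-rolled Eq.-by-Eq. update of the 2N binary state (no noise)."""
    n = len(weights)
    new = [0.0] * (2 * n)
    for i in range(n):
        v_e = sum(g * weights[i][j] * state[j] for j in range(n))
        v_e += z * j_ei[i] * state[n + i]
        new[i] = 1.0 if v_e - v_thr >= 0 else 0.0
        v_i = z * j_ie * state[i] + j_ii * state[n + i]
        new[n + i] = 1.0 if v_i - v_thr >= 0 else 0.0
    return tuple(new)


def oracle_orbits(c, p):
    """All attractors by following every state's orbit with oracle_step.

    Returns a set of canonical cycles, each a frozenset-free tuple of
    state tuples rotated so the minimal state tuple comes first.
    """
    n = c.n_regions
    j_ei = list(np.atleast_1d(p.j_ei)) * (n if np.ndim(p.j_ei) == 0 else 1)
    attractors = set()
    for bits in itertools.product((0.0, 1.0), repeat=2 * n):
        seen = {}
        s = bits
        while s not in seen:
            seen[s] = len(seen)
            s = oracle_step(s, c.weights.tolist(), p.g, j_ei, p.j_ie,
                            p.j_ii, p.v_thr, p.z)
        # walk the cycle from the revisited state
        cycle = [s]
        nxt = oracle_step(s, c.weights.tolist(), p.g, j_ei, p.j_ie,
                          p.j_ii, p.v_thr, p.z)
        while nxt != s:
            cycle.append(nxt)
            nxt = oracle_step(nxt, c.weights.tolist(), p.g, j_ei, p.j_ie,
                              p.j_ii, p.v_thr, p.z)
        k = cycle.index(min(cycle))
        attractors.add(tuple(cycle[k:] + cycle[:k]))
    return attractors


# ---------------------------------------------------------------------------
# Oracle: exact stationary distribution of the full 2^(2N)-state chain
# ---------------------------------------------------------------------------

def exact_basin_occupancy(c, p, attractor_set):
    """Exact basin occupancy from the chain's stationary distribution.

    Builds the full transition matrix (unit k fires independently with
    probability Phi((V_k - V_thr)/sigma)), solves for the stationary
    distribution by power iteration, and sums probability mass over each
    attractor's basin (basins resolved per attractor, uncollapsed).
    """
    from cortexcaps.attractors import run_to_attractor

    n = c.n_regions
    n_units = 2 * n
    n_states = 1 << n_units
    states = ((np.arange(n_states)[:, None] >> np.arange(n_units)[None, :]) & 1
              ).astype(float)
    gw = p.g * c.weights
    zjei = p.z * p.j_ei_vector(n)
    v = np.concatenate(
        [states[:, :n] @ gw.T + zjei * states[:, n:],
         p.z * p.j_ie * states[:, :n] + p.j_ii * states[:, n:]],
        axis=1,
    )
    p_fire = norm.cdf((v - p.v_thr) / p.sigma)
    log1 = np.log(np.clip(p_fire, 1e-300, 1.0))
    log0 = np.log(np.clip(1.0 - p_fire, 1e-300, 1.0))
    transition = np.exp(log1 @ states.T + log0 @ (1.0 - states).T)
    pi = np.full(n_states, 1.0 / n_states)
    for _ in range(5000):
        nxt = pi @ transition
        if np.abs(nxt - pi).max() < 1e-14:
            pi = nxt
            break
        pi = nxt
    keys = attractor_set.keys()
    cache: dict[bytes, bytes] = {}
    occupancy = np.zeros(len(attractor_set))
    for s in range(n_states):
        a = run_to_attractor(states[s], c, p, _cache=cache)
        occupancy[keys[a.key]] += pi[s]
    return occupancy
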