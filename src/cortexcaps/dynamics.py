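"""Synchronous binary excitatory-inhibitory network dynamics.

Each of the ``N`` cortical regions contains one excitatory (E) and one
inhibitory (I) binary population.  The 2N-dimensional activation state
``A = [A_E, A_I]`` (E populations first) is updated synchronously at
discrete steps of one fMRI repetition time (TR = 1.2 s):

    V_E,i(t) = sum_j g * W[i, j] * A_E,j(t) + z * J_EI[i] * A_I,i(t) + noise
    V_I,i(t) = z * J_IE * A_E,i(t) + J_II * A_I,i(t) + noise
    A_k(t+1) = H(V_k(t) - V_thr)

with H the Heaviside step function (H(0) = 1).  Only excitatory
populations project between regions, through the directed anatomical
matrix ``W`` scaled by the global synaptic efficacy ``g``.  The scalar
``z`` rescales the local E-to-I and I-to-E couplings and equals 1 for the
unperturbed model.  A linear variant replaces H by the identity.

The simulated fMRI signal of region ``i`` is the noise-free total input
current to its excitatory population,

    Syn_i(t) = sum_j g * W[i, j] * A_E,j(t) + z * J_EI[i] * A_I,i(t),

optionally convolved with a short synaptic-to-BOLD kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectome import Connectome

__all__ = [
    "TR_SECONDS",
    "BOLD_KERNEL",
    "ModelParameters",
    "Trajectory",
    "activation",
    "step",
    "deterministic_step",
    "simulate",
    "synaptic_signal",
    "bold_convolve",
]

#: fMRI repetition time; one model update step corresponds to one TR.
TR_SECONDS: float = 1.2

#: Synaptic-to-BOLD convolution kernel over 6 lags of one TR each,
#: estimated from simultaneous intracranial LFP and BOLD recordings.
BOLD_KERNEL: np.ndarray = np.array([0.116, 0.461, 0.572, 0.212, 0.067, 0.008])

#: Lag (in TR) of the kernel maximum; used to back-shift convolved BOLD
#: for visual alignment with the unconvolved signal.
BOLD_KERNEL_PEAK_LAG: int = 3


@dataclass(frozen=True)
class ModelParameters:
    """Free parameters of the binary E-I network.

    Parameters
    ----------
    g
        Global synaptic efficacy multiplying the anatomical E-to-E matrix.
    j_ei
        I-to-E coupling; scalar or length-N vector (may differ across
        regions), expected <= 0.
    j_ie
        E-to-I coupling, one scalar shared by all regions, expected >= 0.
    j_ii
        I-to-I coupling, one scalar shared by all regions, expected <= 0.
    v_thr
        Firing threshold of the membrane potential.
    sigma
        Standard deviation of the i.i.d. Gaussian noise injected into
        every population at every step (>= 0).
    z
        Scaling of the local E<->I couplings (multiplies ``j_ei`` and
        ``j_ie`` but not ``j_ii``); 1 for the unperturbed model.
    activation
        ``"heaviside"`` (binary model) or ``"linear"``.
    """

    g: float
    j_ei: float | np.ndarray
    j_ie: float
    j_ii: float
    v_thr: float
    sigma: float
    z: float = 1.0
    activation: str = "heaviside"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if self.activation not in ("heaviside", "linear"):
            raise ValueError("activation must be 'heaviside' or 'linear'")
        if np.ndim(self.j_ei) == 1:
            object.__setattr__(self, "j_ei", np.asarray(self.j_ei, dtype=float))
        elif np.ndim(self.j_ei) != 0:
            raise ValueError("j_ei must be a scalar or a length-N vector")

    def j_ei_vector(self, n_regions: int) -> np.ndarray:
        """Per-region I-to-E weights broadcast to length ``n_regions``."""
        j = np.asarray(self.j_ei, dtype=float)
        if j.ndim == 0:
            return np.full(n_regions, float(j))
        if j.shape != (n_regions,):
            raise ValueError(
                f"j_ei has length {j.shape[0]} but the connectome has "
                f"{n_regions} regions"
            )
        return j

    def noiseless(self) -> "ModelParameters":
        return replace(self, sigma=0.0)


@dataclass(frozen=True)
class Trajectory:
    """A simulated run: binary states and matching synaptic currents.

    ``states`` is ``(n_steps, 2N)`` (E populations in columns ``:N``,
    I populations in ``N:``); ``syn`` is the ``(n_steps, N)`` noise-free
    input current to the excitatory populations, the model's fMRI signal.
    One row per TR.
    """

    states: np.ndarray
    syn: np.ndarray
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_regions(self) -> int:
        return self.states.shape[1] // 2


def activation(x, variant: str = "heaviside"):
    """Population input-output function: Heaviside step (H(0)=1) or identity."""
    if variant == "heaviside":
        return (np.asarray(x, dtype=float) >= 0).astype(float)
    if variant == "linear":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown activation variant {variant!r}")


def _effective(c: Connectome, p: ModelParameters):
    """Precompute effective couplings: (gW, z*J_EI, z*J_IE, J_II)."""
    gw = p.g * c.weights
    zjei = p.z * p.j_ei_vector(c.n_regions)
    return gw, zjei, p.z * p.j_ie, p.j_ii


def step(
    state: np.ndarray,
    c: Connectome,
    p: ModelParameters,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update of the full 2N activation vector.

    ``noise`` is a 2N vector added to the membrane potentials (E entries
    first); pass None for the deterministic (noise-free) map.  All 2N
    entries are computed from the same old state.
    """
    n = c.n_regions
    state = np.asarray(state, dtype=float)
    if state.shape != (2 * n,):
        raise ValueError(f"state must have length {2 * n}, got {state.shape}")
    gw, zjei, zjie, jii = _effective(c, p)
    a_e, a_i = state[:n], state[n:]
    v_e = gw @ a_e + zjei * a_i
    v_i = zjie * a_e + jii * a_i
    v = np.concatenate([v_e, v_i])
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (2 * n,):
            raise ValueError("noise must be a 2N vector")
        v = v + noise
    return activation(v - p.v_thr, p.activation)


def deterministic_step(state: np.ndarray, c: Connectome, p: ModelParameters) -> np.ndarray:
    """The noise-free update map (used for attractor analysis)."""
    return step(state, c, p, noise=None)


def random_state(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random binary 2N activation vector."""
    return rng.integers(0, 2, size=2 * n_regions).astype(float)


def simulate(
    c: Connectome,
    p: ModelParameters,
    n_steps: int = 450,
    seed: int | None = None,
    init: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate ``n_steps`` states of the noisy network.

    Noise is i.i.d. N(0, sigma^2), drawn independently for every
    population and step in population-major order, so runs with the same
    seed are bit-identical.  The initial state (first row of the output)
    is a uniform random binary vector unless ``init`` is given.

    The default length of 450 steps matches a 9-minute recording at
    TR = 1.2 s.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = c.n_regions
    state = random_state(n, rng) if init is None else np.asarray(init, dtype=float)
    if state.shape != (2 * n,):
        raise ValueError("init must be a 2N vector")

    gw, zjei, zjie, jii = _effective(c, p)
    heaviside = p.activation == "heaviside"
    if p.sigma > 0:
        noise = rng.normal(0.0, p.sigma, size=(n_steps - 1, 2 * n))
    else:
        noise = None

    states = np.empty((n_steps, 2 * n), dtype=float)
    states[0] = state
    v = np.empty(2 * n, dtype=float)
    for t in range(1, n_steps):
        a_e, a_i = state[:n], state[n:]
        v[:n] = gw @ a_e + zjei * a_i
        v[n:] = zjie * a_e + jii * a_i
        if noise is not None:
            v += noise[t - 1]
        if heaviside:
            state = (v >= p.v_thr).astype(float)
        else:
            state = v - p.v_thr
        states[t] = state
    return Trajectory(states=states, syn=_syn_from_states(states, gw, zjei), seed=seed)


def _syn_from_states(states: np.ndarray, gw: np.ndarray, zjei: np.ndarray) -> np.ndarray:
    n = gw.shape[0]
    return states[:, :n] @ gw.T + states[:, n:] * zjei[None, :]


def synaptic_signal(states: np.ndarray, c: Connectome, p: ModelParameters) -> np.ndarray:
    """Noise-free input current to the E populations, frame by frame.

    ``Syn_i(t) = sum_j g W[i,j] A_E,j(t) + z J_EI[i] A_I,i(t)``; this is
    the model's simulated fMRI signal (no noise term enters).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    gw, zjei, _, _ = _effective(c, p)
    return _syn_from_states(states, gw, zjei)


def bold_convolve(
    syn: np.ndarray,
    kernel: np.ndarray | None = None,
    back_shift: int = 0,
) -> np.ndarray:
    """Causal discrete convolution of the synaptic signal with a BOLD kernel.

    ``BOLD_i(t) = sum_s K(t - s) Syn_i(s)`` per region, truncated to the
    input length.  ``back_shift`` advances the output by that many lags
    (padding the tail by its last value), which aligns the convolved
    signal with the unconvolved one when set to the kernel's peak lag.
    """
    if kernel is None:
        kernel = BOLD_KERNEL
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("kernel must be non-empty")
    syn = np.atleast_2d(np.asarray(syn, dtype=float))
    if kernel.size > syn.shape[0]:
        raise ValueError("kernel support exceeds series length")
    out = np.empty_like(syn)
    for j in range(syn.shape[1]):
        out[:, j] = np.convolve(syn[:, j], kernel)[: syn.shape[0]]
    if back_shift:
        out = np.concatenate(
            [out[back_shift:], np.repeat(out[-1:], back_shift, axis=0)], axis=0
        )
    return out
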