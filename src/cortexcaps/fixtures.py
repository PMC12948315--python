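"""Seeded generators for synthetic connectomes, parameters and recordings.

The generators emulate the structural features of a mammalian cortical
connectome that matter for the model's dynamics: directed, non-negative,
mirror-symmetric across the sagittal plane (right-hemisphere outgoing
connectivity is the reflection of the left's), with heavy-tailed
(log-normal) weights so that a strong-connection backbone coexists with
many weak links.  They make every other module testable without any
external data.  They do not emulate atlas geometry or realistic fMRI
noise spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, symmetrize
from .dynamics import ModelParameters, Trajectory, bold_convolve, simulate

__all__ = [
    "SyntheticSpec",
    "synthetic_connectome",
    "default_parameters",
    "study_connectome",
    "STUDY_SEED",
    "synthetic_recording",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic mirror-symmetric directed connectome.

    Weights are log-normal (parameters ``lognorm_mu``, ``lognorm_sigma``)
    and rescaled so the maximum entry is 1; inter-hemispheric entries are
    additionally multiplied by ``inter_strength``.  ``intra_density`` /
    ``inter_density`` set the fraction of nonzero links in the
    within- and between-hemisphere blocks.  Mirror symmetry generates the
    left hemisphere's outgoing blocks and reflects them onto the right.
    """

    n_regions: int = 10
    intra_density: float = 0.6
    inter_density: float = 0.3
    inter_strength: float = 0.6
    lognorm_mu: float = -1.0
    lognorm_sigma: float = 1.0
    mirror_symmetric: bool = True
    directed: bool = True
    self_loops: bool = True
    self_strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even number >= 2")
        for name in ("intra_density", "inter_density"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.inter_strength < 0:
            raise ValueError("inter_strength must be >= 0")


def _block(rng: np.random.Generator, shape, density, mu, sigma) -> np.ndarray:
    w = rng.lognormal(mean=mu, sigma=sigma, size=shape)
    mask = rng.random(shape) < density
    return w * mask


def synthetic_connectome(spec: SyntheticSpec) -> Connectome:
    """Generate a directed non-negative connectome from a spec.

    Region order is left hemisphere first (``0 .. N/2-1``) then right;
    the mirror map pairs ``i`` with ``i + N/2``.  When
    ``spec.mirror_symmetric`` the intra-left (LL) and right-to-left (LR)
    blocks are drawn and copied onto RR and RL, which makes
    ``W[i, j] == W[mirror(i), mirror(j)]`` hold exactly.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.n_regions // 2
    ll = _block(rng, (h, h), spec.intra_density, spec.lognorm_mu, spec.lognorm_sigma)
    lr = _block(rng, (h, h), spec.inter_density, spec.lognorm_mu, spec.lognorm_sigma)
    lr *= spec.inter_strength
    if spec.self_loops:
        # intra-regional connectivity is typically the densest: keep the
        # diagonal present and boost it so regions can sustain themselves
        diag = rng.lognormal(spec.lognorm_mu, spec.lognorm_sigma, size=h)
        np.fill_diagonal(ll, spec.self_strength * diag)
    else:
        np.fill_diagonal(ll, 0.0)
    if spec.mirror_symmetric:
        rr, rl = ll.copy(), lr.copy()
    else:
        rr = _block(rng, (h, h), spec.intra_density, spec.lognorm_mu, spec.lognorm_sigma)
        rl = _block(rng, (h, h), spec.inter_density, spec.lognorm_mu, spec.lognorm_sigma)
        rl *= spec.inter_strength
        if not spec.self_loops:
            np.fill_diagonal(rr, 0.0)
    w = np.block([[ll, lr], [rl, rr]])
    peak = w.max()
    if peak > 0:
        w = w / peak
    labels = tuple(f"L{i:02d}" for i in range(h)) + tuple(f"R{i:02d}" for i in range(h))
    hemis = ("L",) * h + ("R",) * h
    c = Connectome(weights=w, region_labels=labels, hemisphere=hemis)
    if not spec.directed:
        c = symmetrize(c)
    return c


def default_parameters(
    c: Connectome, sigma: float = 0.18, activation: str = "heaviside"
) -> ModelParameters:
    """Fitted-like parameters producing multistable E-I dynamics.

    The regime is chosen so that stationary and oscillatory attractors
    coexist and the noisy dynamics keeps wandering between basins:

    * an active E population reliably recruits its interneuron
      (``j_ie >= v_thr``) and the recruited E-I pair can persist
      (``j_ie + j_ii >= v_thr``);
    * local inhibition shuts down marginally driven excitatory
      populations — regions whose recurrent input falls in the band
      ``[v_thr, v_thr + |j_ei|)`` oscillate, regions above it stay on;
    * the global efficacy ``g`` is normalized per connectome so the mean
      fully active row input is ``3.6 * v_thr``, placing a sizable
      fraction of regions near that band;
    * the noise SD is about half the threshold, large enough to drive
      transitions between basins on the timescale of tens of frames.
    """
    n = c.n_regions
    row_mean = float(c.weights.sum(axis=1).mean())
    v_thr = 0.35
    g = 3.6 * v_thr / max(row_mean, 1e-12)
    return ModelParameters(
        g=g,
        j_ei=np.full(n, -0.3),
        j_ie=0.5,
        j_ii=-0.1,
        v_thr=v_thr,
        sigma=sigma,
        activation=activation,
    )


#: Seed of the reference synthetic connectome realization used throughout
#: the package's worked examples: under `default_parameters` it yields a
#: rich attractor structure (a dozen-odd stationary attractors, part
#: homotopic and part in mirror pairs, coexisting with oscillations, with
#: basin occupancy spread over many basins).
STUDY_SEED: int = 16


def study_connectome(n_regions: int = 10) -> Connectome:
    """The designated reference synthetic connectome (seeded realization)."""
    return synthetic_connectome(SyntheticSpec(n_regions=n_regions, seed=STUDY_SEED))


def synthetic_recording(
    c: Connectome,
    p: ModelParameters,
    n_subjects: int = 15,
    n_steps: int = 450,
    seed: int = 0,
    convolve: bool = False,
) -> list[np.ndarray]:
    """Simulate ``n_subjects`` independent fMRI sessions.

    Each subject is an independent seeded run of the network; the
    returned series are the synaptic fMRI signals (frames x regions),
    optionally convolved with the BOLD kernel.  Defaults match a
    15-subject, 450-frame study.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        traj: Trajectory = simulate(c, p, n_steps=n_steps, rng=rng)
        sig = bold_convolve(traj.syn) if convolve else traj.syn
        out.append(sig)
    return out
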