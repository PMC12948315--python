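"""Attractor structure of the noise-free binary network.

With the Heaviside activation the state space is finite (``2^(2N)``
states), so every noise-free trajectory eventually revisits a state and
from then on repeats a cycle: a *stationary* attractor (cycle length 1)
or an *oscillatory* attractor (length > 1).  This module enumerates
attractors by noisy restarts (or exhaustively on small networks),
canonicalizes cycles, classifies their mirror symmetry (homotopicity),
estimates how often the noisy dynamics visits each basin of attraction,
and computes the per-basin mean z-scored fMRI templates used by the
mapping algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome import Connectome, scale_interhemispheric, sparsify
from .dynamics import ModelParameters, deterministic_step, simulate, synaptic_signal

__all__ = [
    "Attractor",
    "AttractorSet",
    "canonicalize_cycle",
    "run_to_attractor",
    "detect_attractors",
    "enumerate_attractors",
    "mirror_state",
    "is_homotopic",
    "mirror_pairs",
    "basin_occupancy_and_templates",
    "interhemispheric_hamming",
    "attractor_sweep",
    "save_attractor_set",
    "load_attractor_set",
]


@dataclass(frozen=True)
class Attractor:
    """A stationary state or canonical oscillation cycle.

    ``cycle`` is an ``(L, 2N)`` binary array; applying one noise-free
    step to row ``k`` gives row ``(k+1) mod L``.  The cycle is stored in
    canonical rotation: the one whose concatenated bit-string is
    lexicographically minimal, so equal attractors compare bit-equal.
    """

    cycle: np.ndarray
    index: int | None = None

    def __post_init__(self) -> None:
        cyc = np.asarray(self.cycle, dtype=np.uint8)
        if cyc.ndim != 2:
            raise ValueError("cycle must be a 2-D (length x 2N) array")
        object.__setattr__(self, "cycle", cyc)

    @property
    def kind(self) -> str:
        return "stationary" if len(self.cycle) == 1 else "oscillatory"

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def key(self) -> bytes:
        return self.cycle.tobytes()

    def states(self) -> np.ndarray:
        return self.cycle.astype(float)


@dataclass(frozen=True)
class AttractorSet:
    """Detected attractors plus (optionally) basin occupancy and templates.

    Attractors are sorted stationary-first, then by period and canonical
    bit-string, and numbered by ``index``.  After occupancy estimation,
    ``basin_members[b]`` lists the attractor indices merged into basin
    ``b`` (singletons for stationary attractors; all oscillatory
    attractors may be collapsed into one macroscopic basin),
    ``occupancy[b]`` is the fraction of simulated time spent there and
    ``templates[b]`` the basin-mean z-scored model fMRI vector.
    """

    attractors: tuple[Attractor, ...]
    n_restarts: int = 0
    n_noisy_steps: int = 0
    seed: int | None = None
    restart_hits: np.ndarray | None = None
    basin_members: tuple[tuple[int, ...], ...] | None = None
    occupancy: np.ndarray | None = None
    templates: np.ndarray | None = None

    @property
    def n_stationary(self) -> int:
        return sum(1 for a in self.attractors if a.kind == "stationary")

    @property
    def n_oscillatory(self) -> int:
        return len(self.attractors) - self.n_stationary

    def __len__(self) -> int:
        return len(self.attractors)

    def keys(self) -> dict[bytes, int]:
        return {a.key: i for i, a in enumerate(self.attractors)}


# ---------------------------------------------------------------------------
# Cycle detection and canonicalization
# ---------------------------------------------------------------------------

def canonicalize_cycle(cycle: np.ndarray) -> np.ndarray:
    """Rotate a cycle to its lexicographically minimal bit-string."""
    cyc = np.asarray(cycle, dtype=np.uint8)
    if len(cyc) == 1:
        return cyc
    rotations = [np.roll(cyc, -k, axis=0).tobytes() for k in range(len(cyc))]
    best = rotations.index(min(rotations))
    return np.roll(cyc, -best, axis=0)


def run_to_attractor(
    state: np.ndarray,
    c: Connectome,
    p: ModelParameters,
    _cache: dict[bytes, bytes] | None = None,
) -> Attractor:
    """Iterate the noise-free map until a state repeats; return the cycle.

    Noise is ignored regardless of ``p.sigma``.  Visited states are
    hashed, the first revisit delimits the cycle, and the cycle is
    returned in canonical rotation.  An optional cache maps visited
    states to the canonical cycle key of their attractor, with path
    compression, to amortize repeated basin look-ups.
    """
    if p.activation != "heaviside":
        raise ValueError("attractor analysis requires the heaviside variant")
    p0 = p.noiseless()
    s = np.asarray(state, dtype=float)
    path: list[bytes] = []
    seen: dict[bytes, int] = {}
    cycle_states: dict[bytes, np.ndarray] = {}
    while True:
        key = s.astype(np.uint8).tobytes()
        if _cache is not None and key in _cache:
            # already-resolved state: the whole path drains into its attractor
            canon_key = _cache[key]
            for k in path:
                _cache[k] = canon_key
            cyc = np.frombuffer(canon_key, dtype=np.uint8).reshape(-1, 2 * c.n_regions)
            return Attractor(cycle=cyc)
        if key in seen:
            start = seen[key]
            cyc = np.stack(
                [np.frombuffer(k, dtype=np.uint8) for k in path[start:]]
            )
            canon = canonicalize_cycle(cyc)
            if _cache is not None:
                canon_key = canon.tobytes()
                for k in path:
                    _cache[k] = canon_key
            return Attractor(cycle=canon)
        seen[key] = len(path)
        path.append(key)
        s = deterministic_step(s, c, p0)


def _sorted_set(
    found: dict[bytes, Attractor], **meta
) -> AttractorSet:
    order = sorted(
        found.values(), key=lambda a: (a.kind != "stationary", a.period, a.key)
    )
    hits = meta.pop("hits", None)
    attractors = tuple(replace(a, index=i) for i, a in enumerate(order))
    restart_hits = None
    if hits is not None:
        restart_hits = np.array([hits[a.key] for a in attractors], dtype=float)
    return AttractorSet(attractors=attractors, restart_hits=restart_hits, **meta)


def detect_attractors(
    c: Connectome,
    p: ModelParameters,
    n_restarts: int = 1000,
    n_noisy_steps: int = 100,
    seed: int | None = None,
) -> AttractorSet:
    """Detect attractors by repeated noisy restarts.

    Each restart starts from a uniform random activation vector, runs
    ``n_noisy_steps`` stochastic steps (so the network statistics become
    stationary), then switches the noise off and descends to an
    attractor.  Attractors are deduplicated by canonical cycle.  The set
    of oscillatory attractors is typically reconstructed only partially,
    so oscillatory counts should be read together with ``n_restarts``.
    ``restart_hits`` records how many restarts drained into each
    attractor (an alternative occupancy estimate).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    cache: dict[bytes, bytes] = {}
    found: dict[bytes, Attractor] = {}
    hits: dict[bytes, int] = {}
    n = c.n_regions
    for _ in range(n_restarts):
        init = rng.integers(0, 2, size=2 * n).astype(float)
        if n_noisy_steps > 0 and p.sigma > 0:
            traj = simulate(c, p, n_steps=n_noisy_steps + 1, init=init, rng=rng)
            init = traj.states[-1]
        a = run_to_attractor(init, c, p, _cache=cache)
        found.setdefault(a.key, a)
        hits[a.key] = hits.get(a.key, 0) + 1
    return _sorted_set(
        found,
        n_restarts=n_restarts,
        n_noisy_steps=n_noisy_steps,
        seed=seed,
        hits=hits,
    )


def enumerate_attractors(
    c: Connectome, p: ModelParameters, max_units: int = 20
) -> AttractorSet:
    """Exhaustive attractor detection from every one of the 2^(2N) states.

    Feasible only for small networks; guarded at ``2N <= max_units``.
    """
    n_units = 2 * c.n_regions
    if n_units > max_units:
        raise ValueError(
            f"exhaustive enumeration over 2^{n_units} states refused "
            f"(limit 2^{max_units})"
        )
    cache: dict[bytes, bytes] = {}
    found: dict[bytes, Attractor] = {}
    hits: dict[bytes, int] = {}
    for code in range(2 ** n_units):
        state = _int_to_state(code, n_units)
        a = run_to_attractor(state, c, p, _cache=cache)
        found.setdefault(a.key, a)
        hits[a.key] = hits.get(a.key, 0) + 1
    return _sorted_set(
        found, n_restarts=2 ** n_units, n_noisy_steps=0, seed=None, hits=hits
    )


def _int_to_state(code: int, n_units: int) -> np.ndarray:
    return np.array([(code >> k) & 1 for k in range(n_units)], dtype=float)


# ---------------------------------------------------------------------------
# Homotopicity
# ---------------------------------------------------------------------------

def mirror_state(state: np.ndarray, mirror_map: np.ndarray) -> np.ndarray:
    """Swap mirror-paired regions (E with E, I with I) in a 2N vector."""
    state = np.asarray(state)
    n = state.shape[-1] // 2
    mm = np.asarray(mirror_map, dtype=int)
    return np.concatenate([state[..., :n][..., mm], state[..., n:][..., mm]], axis=-1)


def mirror_attractor(a: Attractor, mirror_map: np.ndarray) -> Attractor:
    """The attractor's cycle reflected across the sagittal plane."""
    return Attractor(cycle=canonicalize_cycle(mirror_state(a.cycle, mirror_map)))


def is_homotopic(a: Attractor, mirror_map: np.ndarray) -> bool:
    """True iff the attractor is mirror-symmetric across hemispheres.

    A stationary state is homotopic when invariant under swapping
    mirror-paired populations; an oscillation when the mirrored cycle
    equals the original up to rotation.
    """
    return mirror_attractor(a, mirror_map).key == a.key


def mirror_pairs(
    s: AttractorSet, mirror_map: np.ndarray
) -> list[tuple[int, int]]:
    """Pair every attractor with its mirrored counterpart in the set.

    Homotopic attractors are self-paired.  On a mirror-symmetric
    connectome the mirrored cycle of every attractor is itself an
    attractor; an unpaired one signals incomplete detection and produces
    a warning (the attractor is then self-paired as a fallback).
    """
    keys = s.keys()
    pairs: list[tuple[int, int]] = []
    for i, a in enumerate(s.attractors):
        j = keys.get(mirror_attractor(a, mirror_map).key)
        if j is None:
            warnings.warn(
                f"attractor {i} has no mirrored counterpart in the set; "
                "detection is likely incomplete",
                stacklevel=2,
            )
            j = i
        pairs.append((i, j))
    return pairs


def interhemispheric_hamming(
    states: np.ndarray, mirror_map: np.ndarray
) -> float:
    """Mean normalized Hamming distance between hemispheres' E activity.

    For each frame, the fraction of left-hemisphere excitatory
    populations whose activation differs from their right homologue's;
    averaged over frames.  0 for perfectly homotopic activity, 1 when
    the hemispheres are exactly complementary.
    """
    states = np.atleast_2d(np.asarray(states))
    n = states.shape[1] // 2
    mm = np.asarray(mirror_map, dtype=int)
    e = states[:, :n]
    mismatch = e != e[:, mm[:n]]
    return float(mismatch.mean())


# ---------------------------------------------------------------------------
# Basin occupancy and templates
# ---------------------------------------------------------------------------

def basin_occupancy_and_templates(
    c: Connectome,
    p: ModelParameters,
    attractor_set: AttractorSet,
    n_steps: int = 10_000,
    n_reps: int = 1,
    seed: int | None = None,
    collapse_oscillatory: bool = True,
    transient: int = 0,
    init: np.ndarray | None = None,
) -> AttractorSet:
    """Estimate basin occupancy and per-basin fMRI templates by simulation.

    Runs ``n_reps`` noisy trajectories of ``n_steps`` frames, assigns
    every visited state to its basin by noise-free descent (memoized),
    and computes

    * occupancy: the fraction of frames per basin, and
    * templates: the basin-mean of the per-region z-scored synaptic fMRI
      signal (z-scored over all pooled frames).

    With ``collapse_oscillatory`` (the mapping default) all oscillatory
    basins are merged into a single macroscopic basin, since individual
    oscillation basins have vanishing occupancy; stationary basins stay
    separate.  States draining into attractors absent from the detected
    set are added to it.  Basins visited by no frame get a NaN template.
    """
    cache: dict[bytes, bytes] = {}
    found: dict[bytes, Attractor] = {a.key: a for a in attractor_set.attractors}
    ss = np.random.SeedSequence(seed)
    frame_keys: list[bytes] = []
    syn_blocks: list[np.ndarray] = []
    for child in ss.spawn(max(n_reps, 1)):
        rng = np.random.default_rng(child)
        traj = simulate(c, p, n_steps=n_steps + transient, init=init, rng=rng)
        states = traj.states[transient:]
        syn_blocks.append(traj.syn[transient:])
        frame_keys.extend(s.astype(np.uint8).tobytes() for s in states)

    # resolve each distinct visited state to its attractor
    state_to_attr: dict[bytes, bytes] = {}
    n_units = 2 * c.n_regions
    for key in set(frame_keys):
        state = np.frombuffer(key, dtype=np.uint8).astype(float)
        a = run_to_attractor(state, c, p, _cache=cache)
        if a.key not in found:
            found[a.key] = a
        state_to_attr[key] = a.key

    new_set = _sorted_set(
        found,
        n_restarts=attractor_set.n_restarts,
        n_noisy_steps=attractor_set.n_noisy_steps,
        seed=attractor_set.seed,
    )
    key_to_index = new_set.keys()

    # basin structure: stationary singletons (+ optional oscillatory macro)
    if collapse_oscillatory:
        members: list[tuple[int, ...]] = [
            (i,) for i, a in enumerate(new_set.attractors) if a.kind == "stationary"
        ]
        osc = tuple(
            i for i, a in enumerate(new_set.attractors) if a.kind == "oscillatory"
        )
        if osc:
            members.append(osc)
    else:
        members = [(i,) for i in range(len(new_set))]
    attr_to_basin = {
        ai: b for b, group in enumerate(members) for ai in group
    }

    labels = np.array(
        [attr_to_basin[key_to_index[state_to_attr[k]]] for k in frame_keys]
    )
    n_basins = len(members)
    counts = np.bincount(labels, minlength=n_basins).astype(float)
    occupancy = counts / counts.sum()

    syn = np.vstack(syn_blocks)
    mu, sd = syn.mean(axis=0), syn.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (syn - mu) / sd
    templates = np.full((n_basins, c.n_regions), np.nan)
    for b in range(n_basins):
        mask = labels == b
        if mask.any():
            templates[b] = z[mask].mean(axis=0)
    return replace(
        new_set,
        basin_members=tuple(tuple(g) for g in members),
        occupancy=occupancy,
        templates=templates,
    )


# ---------------------------------------------------------------------------
# Connectivity sweeps
# ---------------------------------------------------------------------------

def attractor_sweep(
    c: Connectome,
    p: ModelParameters,
    param: str,
    grid,
    n_restarts: int = 500,
    n_noisy_steps: int = 100,
    occupancy_steps: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attractor counts and stationary/oscillatory occupancy along a grid.

    ``param`` selects the perturbation: ``"W"`` scales inter-hemispheric
    connectivity, ``"T"`` sparsifies links below a threshold, ``"z"``
    scales the local E<->I couplings.  For every grid value the function
    re-detects attractors and estimates the total occupancy of stationary
    vs oscillatory basins, returning one row per value.
    """
    if param not in ("W", "T", "z"):
        raise ValueError("param must be one of 'W', 'T', 'z'")
    rows = []
    for k, value in enumerate(grid):
        if param == "W":
            ck, pk = scale_interhemispheric(c, value), p
        elif param == "T":
            ck, pk = sparsify(c, value)[0], p
        else:
            ck, pk = c, replace(p, z=value)
        sub_seed = None if seed is None else seed + k
        aset = detect_attractors(
            ck, pk, n_restarts=n_restarts, n_noisy_steps=n_noisy_steps, seed=sub_seed
        )
        filled = basin_occupancy_and_templates(
            ck, pk, aset, n_steps=occupancy_steps, seed=sub_seed,
            collapse_oscillatory=True,
        )
        p_osc = 0.0
        for b, group in enumerate(filled.basin_members):
            if filled.attractors[group[0]].kind == "oscillatory":
                p_osc += float(filled.occupancy[b])
        rows.append(
            {
                param: value,
                "n_stationary": aset.n_stationary,
                "n_oscillatory": aset.n_oscillatory,
                "p_stationary": 1.0 - p_osc,
                "p_oscillatory": p_osc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _attractor_to_json(a: Attractor) -> dict:
    return {
        "kind": a.kind,
        "cycle": ["".join(map(str, row)) for row in a.cycle],
    }


def save_attractor_set(s: AttractorSet, path) -> None:
    """Serialize an attractor set (cycles as bit-strings) to JSON."""
    doc = {
        "n_restarts": s.n_restarts,
        "n_noisy_steps": s.n_noisy_steps,
        "seed": s.seed,
        "attractors": [_attractor_to_json(a) for a in s.attractors],
        "restart_hits": None if s.restart_hits is None else s.restart_hits.tolist(),
        "basin_members": None
        if s.basin_members is None
        else [list(g) for g in s.basin_members],
        "occupancy": None if s.occupancy is None else s.occupancy.tolist(),
        "templates": None if s.templates is None else s.templates.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_attractor_set(path) -> AttractorSet:
    """Inverse of :func:`save_attractor_set`; round-trips bit-exactly."""
    with open(path) as fh:
        doc = json.load(fh)
    attractors = tuple(
        Attractor(
            cycle=np.array([[int(ch) for ch in row] for row in a["cycle"]],
                           dtype=np.uint8),
            index=i,
        )
        for i, a in enumerate(doc["attractors"])
    )
    return AttractorSet(
        attractors=attractors,
        n_restarts=doc["n_restarts"],
        n_noisy_steps=doc["n_noisy_steps"],
        seed=doc["seed"],
        restart_hits=None
        if doc.get("restart_hits") is None
        else np.asarray(doc["restart_hits"], dtype=float),
        basin_members=None
        if doc.get("basin_members") is None
        else tuple(tuple(g) for g in doc["basin_members"]),
        occupancy=None
        if doc.get("occupancy") is None
        else np.asarray(doc["occupancy"], dtype=float),
        templates=None
        if doc.get("templates") is None
        else np.asarray(doc["templates"], dtype=float),
    )
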