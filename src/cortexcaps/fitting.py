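"""Parameter estimation against static fMRI statistics.

The free parameters (g, J_EI, J_IE, J_II, V_thr, sigma) are chosen to
minimize the equally weighted mean squared error between model and
target first- and second-order statistics: the normalized across-region
mean-signal distribution and the static FC matrix, both averaged over
repeated seeded simulations.  Fitting proceeds in two phases, a coarse
grid search over scalar parameters (J_EI uniform across regions) and a
local steepest-descent refinement in which the per-region J_EI entries
are freed.  The loss is stochastic, so every evaluation during a fit
reuses the same random numbers (common random numbers), making descent
well defined and runs reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np

from .connectome import Connectome
from .dynamics import ModelParameters, simulate
from .statistics import normalized_mean_signal, static_fc

__all__ = ["FitTarget", "FitResult", "loss", "grid_search", "local_refine", "fit"]

#: Penalty returned when the model output is degenerate (e.g. constant
#: signals make the statistics undefined).  Large but finite so the
#: optimizer can move away from dead regions of parameter space.
DEGENERATE_PENALTY = 1e6

# sign of each scalar parameter, enforced as a box constraint
_SIGNS = {"g": +1, "j_ei": -1, "j_ie": +1, "j_ii": -1, "sigma": +1, "v_thr": 0}


@dataclass(frozen=True)
class FitTarget:
    """Target statistics: normalized mean signal and FC matrix."""

    mean_signal: np.ndarray               # (N,), in [-1, 1]
    fc: np.ndarray                        # (N, N) correlation matrix
    weight_mean: float = 1.0
    weight_fc: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_signal, dtype=float)
        f = np.asarray(self.fc, dtype=float)
        if np.abs(m).max() > 1 + 1e-9:
            raise ValueError("target mean signal must lie in [-1, 1]")
        if f.shape != (m.size, m.size):
            raise ValueError("target FC shape must match the mean signal length")
        object.__setattr__(self, "mean_signal", m)
        object.__setattr__(self, "fc", f)

    @classmethod
    def from_series(cls, series_list) -> "FitTarget":
        """Build the target from (empirical or synthetic) recordings."""
        if isinstance(series_list, np.ndarray) and series_list.ndim == 2:
            series_list = [series_list]
        means = np.mean([normalized_mean_signal(s) for s in series_list], axis=0)
        return cls(mean_signal=means, fc=static_fc(series_list))


@dataclass(frozen=True)
class FitResult:
    """Best parameters with the (non-increasing) accepted loss trace."""

    params: ModelParameters
    loss_trace: tuple[float, ...]
    n_reps: int
    n_steps: int
    seed: int | None

    @property
    def loss(self) -> float:
        return self.loss_trace[-1]

    def to_json(self, path) -> None:
        p = self.params
        doc = {
            "params": {
                "g": p.g,
                "j_ei": np.asarray(p.j_ei).tolist(),
                "j_ie": p.j_ie,
                "j_ii": p.j_ii,
                "v_thr": p.v_thr,
                "sigma": p.sigma,
                "z": p.z,
                "activation": p.activation,
            },
            "loss_trace": list(self.loss_trace),
            "n_reps": self.n_reps,
            "n_steps": self.n_steps,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _model_statistics(c, p, n_reps, n_steps, seed):
    ss = np.random.SeedSequence(seed)
    series = []
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        series.append(simulate(c, p, n_steps=n_steps, rng=rng).syn)
    mean = np.mean([normalized_mean_signal(s) for s in series], axis=0)
    return mean, static_fc(series)


def loss(
    p: ModelParameters,
    c: Connectome,
    target: FitTarget,
    n_reps: int = 10,
    n_steps: int = 450,
    seed: int = 0,
) -> float:
    """Equally weighted MSE of the mean-signal and FC statistics.

    Model statistics are averaged over ``n_reps`` seeded simulations of
    ``n_steps`` frames each; the FC term uses the off-diagonal upper
    triangle (the matrix is symmetric and its diagonal is trivially 1).
    Degenerate model output (constant signals, undefined statistics)
    yields a large finite penalty rather than an exception.  With the
    same seed the loss is deterministic.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    try:
        mean, fc = _model_statistics(c, p, n_reps, n_steps, seed)
    except ValueError:
        return DEGENERATE_PENALTY
    iu = np.triu_indices(c.n_regions, k=1)
    mse_mean = float(np.mean((mean - target.mean_signal) ** 2))
    mse_fc = float(np.mean((fc[iu] - target.fc[iu]) ** 2))
    return target.weight_mean * mse_mean + target.weight_fc * mse_fc


def _clip(name: str, value: float) -> float:
    sign = _SIGNS[name]
    if sign > 0:
        return max(value, 0.0)
    if sign < 0:
        return min(value, 0.0)
    return value


def _with_scalar(p: ModelParameters, name: str, value: float) -> ModelParameters:
    return replace(p, **{name: _clip(name, value)})


def grid_search(
    c: Connectome,
    target: FitTarget,
    grid_spec: dict[str, list[float]],
    seed: int = 0,
    n_reps: int = 10,
    n_steps: int = 450,
    base: ModelParameters | None = None,
) -> tuple[ModelParameters, float]:
    """Coarse global search over a grid of scalar parameters.

    ``grid_spec`` maps parameter names (``g``, ``j_ei``, ``j_ie``,
    ``j_ii``, ``v_thr``, ``sigma``) to candidate values; ``j_ei`` is a
    single scalar applied uniformly to all regions in this phase.  The
    grid is traversed in the order given by ``itertools.product`` over
    the spec's insertion order, and ties break to the first point
    encountered.  Every point is evaluated with the same seed.
    """
    names = list(grid_spec)
    if not names or any(len(v) == 0 for v in grid_spec.values()):
        raise ValueError("grid must be non-empty")
    unknown = set(names) - set(_SIGNS)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    if base is None:
        base = ModelParameters(
            g=1.0, j_ei=-0.5, j_ie=0.5, j_ii=-0.5, v_thr=0.5, sigma=0.1
        )
    best: tuple[float, ModelParameters] | None = None
    for values in itertools.product(*(grid_spec[n] for n in names)):
        p = base
        for name, value in zip(names, values):
            p = _with_scalar(p, name, value)
        score = loss(p, c, target, n_reps=n_reps, n_steps=n_steps, seed=seed)
        if best is None or score < best[0]:
            best = (score, p)
    return best[1], best[0]


def local_refine(
    start: ModelParameters,
    c: Connectome,
    target: FitTarget,
    step_sizes: dict[str, float] | None = None,
    max_iter: int = 50,
    seed: int = 0,
    n_reps: int = 10,
    n_steps: int = 450,
    per_region_j_ei: bool = True,
    min_step_factor: float = 0.25,
) -> FitResult:
    """Steepest-descent refinement with common random numbers.

    From the grid winner, repeatedly probes every free parameter with a
    finite-difference step in both directions — the scalars g, J_IE,
    J_II, V_thr, sigma and (with ``per_region_j_ei``) each of the N
    per-region J_EI entries — and accepts the single move with the
    largest loss decrease.  When no move improves the loss, all steps
    are halved; the search stops at ``max_iter`` accepted moves or once
    steps shrink below ``min_step_factor`` of their initial size.  Sign
    constraints (J_EI <= 0, J_IE >= 0, J_II <= 0, g >= 0, sigma >= 0)
    are enforced by clipping.  The accepted-loss trace is non-increasing.
    """
    if step_sizes is None:
        step_sizes = {
            "g": 0.1 * max(abs(start.g), 1e-3),
            "j_ei": 0.05,
            "j_ie": 0.05,
            "j_ii": 0.05,
            "v_thr": 0.05,
            "sigma": 0.02,
        }
    n = c.n_regions
    p = replace(start, j_ei=start.j_ei_vector(n)) if per_region_j_ei else start
    current = loss(p, c, target, n_reps=n_reps, n_steps=n_steps, seed=seed)
    trace = [current]
    steps = dict(step_sizes)
    scale = 1.0
    for _ in range(max_iter):
        candidates: list[ModelParameters] = []
        for name in ("g", "j_ie", "j_ii", "v_thr", "sigma"):
            h = steps[name] * scale
            value = getattr(p, name)
            candidates.append(_with_scalar(p, name, value + h))
            candidates.append(_with_scalar(p, name, value - h))
        if per_region_j_ei:
            h = steps["j_ei"] * scale
            vec = np.asarray(p.j_ei, dtype=float)
            for i in range(n):
                for direction in (+h, -h):
                    new = vec.copy()
                    new[i] = min(new[i] + direction, 0.0)
                    candidates.append(replace(p, j_ei=new))
        else:
            h = steps["j_ei"] * scale
            value = float(np.atleast_1d(p.j_ei)[0])
            candidates.append(replace(p, j_ei=min(value + h, 0.0)))
            candidates.append(replace(p, j_ei=min(value - h, 0.0)))

        scores = [
            loss(q, c, target, n_reps=n_reps, n_steps=n_steps, seed=seed)
            for q in candidates
        ]
        best_idx = int(np.argmin(scores))
        if scores[best_idx] < current:
            p = candidates[best_idx]
            current = scores[best_idx]
            trace.append(current)
        else:
            scale *= 0.5
            if scale < min_step_factor:
                break
    return FitResult(
        params=p, loss_trace=tuple(trace), n_reps=n_reps, n_steps=n_steps, seed=seed
    )


def fit(
    c: Connectome,
    target: FitTarget,
    grid_spec: dict[str, list[float]],
    seed: int = 0,
    n_reps: int = 10,
    n_steps: int = 450,
    max_iter: int = 50,
    per_region_j_ei: bool = True,
) -> FitResult:
    """Grid search followed by local refinement (the full fitting recipe)."""
    start, _ = grid_search(
        c, target, grid_spec, seed=seed, n_reps=n_reps, n_steps=n_steps
    )
    return local_refine(
        start,
        c,
        target,
        max_iter=max_iter,
        seed=seed,
        n_reps=n_reps,
        n_steps=n_steps,
        per_region_j_ei=per_region_j_ei,
    )
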