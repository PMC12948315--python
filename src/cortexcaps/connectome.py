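"""Directed inter-regional connectivity matrices.

A :class:`Connectome` stores the anatomical connectivity between ``N``
cortical regions as a dense non-negative matrix of connection densities.
The orientation convention is fixed throughout the package:

    ``weights[i, j]`` is the strength of the projection from *source*
    region ``j`` to *target* region ``i`` (row = target, column = source),

so that the recurrent input to excitatory population ``i`` is the row-wise
product ``weights[i, :] @ A_E``.

Regions are split into two hemispheres.  By convention regions
``0 .. N/2-1`` belong to the left hemisphere and ``N/2 .. N-1`` to the
right, and the mirror map pairs region ``i`` with ``i ± N/2``; arbitrary
orderings are supported through an explicit mirror map and per-region
hemisphere tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "load_connectome",
    "save_connectome",
    "scale_interhemispheric",
    "sparsify",
    "symmetrize",
]


@dataclass(frozen=True)
class Connectome:
    """Directed anatomical connectivity between cortical regions.

    Parameters
    ----------
    weights
        ``(N, N)`` non-negative matrix, entry ``(i, j)`` = projection
        strength from source region ``j`` to target region ``i``
        (connection-density units, before multiplication by the global
        synaptic efficacy ``g``).
    region_labels
        ``N`` region names.
    hemisphere
        Per-region tag, ``"L"`` or ``"R"``.
    mirror_map
        Permutation of ``range(N)`` mapping every region to its homologue
        in the opposite hemisphere.  Must be an involution.
    """

    weights: np.ndarray
    region_labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    mirror_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        n = w.shape[0]
        if np.any(w < 0):
            raise ValueError("connectome weights must be non-negative")
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {n} regions"
            )
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere tags must match the number of regions")
        if any(h not in ("L", "R") for h in self.hemisphere):
            raise ValueError("hemisphere tags must be 'L' or 'R'")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        if self.mirror_map is None:
            object.__setattr__(self, "mirror_map", _default_mirror_map(self.hemisphere))
        mm = np.asarray(self.mirror_map, dtype=int)
        if sorted(mm.tolist()) != list(range(n)):
            raise ValueError("mirror_map must be a permutation of the regions")
        if not np.array_equal(mm[mm], np.arange(n)):
            raise ValueError("mirror_map must be an involution")
        for i, j in enumerate(mm):
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(
                    "mirror_map must pair regions across hemispheres"
                )
        object.__setattr__(self, "mirror_map", mm)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def interhemispheric_mask(self) -> np.ndarray:
        """Boolean ``(N, N)`` mask of entries linking the two hemispheres."""
        hemi = np.asarray(self.hemisphere)
        return hemi[:, None] != hemi[None, :]

    def is_mirror_symmetric(self, atol: float = 0.0) -> bool:
        """True iff ``weights[i, j] == weights[mirror(i), mirror(j)]`` for all i, j.

        A mirror-symmetric connectome has right-hemisphere outgoing
        connectivity identical to the reflected left-hemisphere one, i.e.
        R-to-R equals L-to-L and R-to-L equals L-to-R.
        """
        mm = self.mirror_map
        mirrored = self.weights[np.ix_(mm, mm)]
        return bool(np.allclose(self.weights, mirrored, rtol=0.0, atol=atol))

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return replace(self, weights=np.asarray(weights, dtype=float))


def _default_mirror_map(hemisphere: tuple[str, ...]) -> np.ndarray:
    """Pair region i with i +/- N/2 (left block first, then right block)."""
    n = len(hemisphere)
    if n % 2 != 0:
        raise ValueError("default mirror map needs an even number of regions")
    half = n // 2
    if tuple(hemisphere) != ("L",) * half + ("R",) * half:
        raise ValueError(
            "default mirror map expects left-hemisphere regions first; "
            "pass an explicit mirror_map for other orderings"
        )
    return np.concatenate([np.arange(half, n), np.arange(half)])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_connectome(path, labels_path, delimiter: str | None = None) -> Connectome:
    """Load a connectome from a delimited weight matrix and a labels table.

    ``path`` holds an ``N x N`` numeric matrix (no header), row = target,
    column = source.  ``labels_path`` holds two delimited columns: region
    name and hemisphere tag (``L``/``R``), one row per region in matrix
    order.  With ``delimiter=None`` commas are auto-detected, otherwise
    whitespace is assumed.
    """
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        if "," in first:
            delimiter = ","
    w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    tab = pd.read_csv(
        labels_path, sep=delimiter or r"\s+|,", engine="python", header=None
    )
    if tab.shape[1] < 2:
        raise ValueError("labels file must have two columns: name, hemisphere")
    labels = tuple(str(x) for x in tab.iloc[:, 0])
    hemis = tuple(str(x).strip().upper() for x in tab.iloc[:, 1])
    return Connectome(weights=w, region_labels=labels, hemisphere=hemis)


def save_connectome(c: Connectome, path, labels_path, delimiter: str = ",") -> None:
    """Write the weight matrix and labels table back to delimited text."""
    np.savetxt(path, c.weights, delimiter=delimiter)
    with open(labels_path, "w") as fh:
        for name, hemi in zip(c.region_labels, c.hemisphere):
            fh.write(f"{name}{delimiter}{hemi}\n")


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def scale_interhemispheric(c: Connectome, w_scale: float) -> Connectome:
    """Multiply every inter-hemispheric connection by ``w_scale``.

    ``w_scale=1`` returns the connectome unchanged (bit-exactly);
    ``w_scale=0`` anatomically disconnects the hemispheres.
    """
    if w_scale < 0:
        raise ValueError("inter-hemispheric scaling coefficient must be >= 0")
    if w_scale == 1.0:
        return c
    out = c.weights.copy()
    mask = c.interhemispheric_mask
    out[mask] *= w_scale
    return c.with_weights(out)


def sparsify(c: Connectome, threshold: float) -> tuple[Connectome, int]:
    """Remove every link strictly below ``threshold``.

    The threshold is applied on the stored (raw connection-density) weight
    scale, before the global efficacy ``g``.  Returns the thresholded
    connectome and the number of removed (nonzero) links.
    """
    if threshold < 0:
        raise ValueError("sparsification threshold must be >= 0")
    if threshold == 0.0:
        return c, 0
    out = c.weights.copy()
    removed = (out > 0) & (out < threshold)
    out[out < threshold] = 0.0
    return c.with_weights(out), int(removed.sum())


def symmetrize(c: Connectome) -> Connectome:
    """Make the connectivity undirected by averaging W with its transpose.

    The arithmetic mean preserves the total connection weight; applying
    the operation twice is a no-op.
    """
    return c.with_weights(0.5 * (c.weights + c.weights.T))
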