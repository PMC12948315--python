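"""Attractor mapping: classify fMRI frames into model basins.

The mapping algorithm z-scores an (empirical or simulated) fMRI series
per region, computes the Euclidean distance of every frame to the
per-basin mean z-scored model fMRI templates, and labels each frame with
the nearest basin.  Counting labels gives the reconstructed basin
occupancy; averaging the z-scored frames per label gives the
reconstructed basin topography.  Because mapping starts from a z-score,
labels are invariant to any per-region affine rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameLabeling",
    "zscore_frames",
    "classify_frames",
    "pool_homotopic",
    "occupancy_overlap",
]


@dataclass(frozen=True)
class FrameLabeling:
    """Per-frame basin labels with reconstructed occupancy and topography."""

    labels: np.ndarray                    # (frames,) basin index per frame
    occupancy: np.ndarray                 # (n_basins,) label frequencies
    topography: np.ndarray                # (n_basins, N) mean z-scored frame
    zero_variance_regions: tuple[int, ...] = ()

    @property
    def n_basins(self) -> int:
        return self.occupancy.shape[0]


def zscore_frames(series: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Per-region z-score over frames (population SD); flag zero-variance.

    Regions with zero variance get z = 0 and are reported.
    """
    series = np.asarray(series, dtype=float)
    mu = series.mean(axis=0)
    sd = series.std(axis=0)
    degenerate = sd <= 1e-12 * (1.0 + np.abs(mu))
    flat = tuple(int(i) for i in np.where(degenerate)[0])
    safe = np.where(degenerate, 1.0, sd)
    z = (series - mu) / safe
    z[:, list(flat)] = 0.0
    return z, flat


def classify_frames(series: np.ndarray, templates: np.ndarray) -> FrameLabeling:
    """Label every frame with the basin of the nearest template.

    ``series`` is frames x regions (z-scored internally); ``templates``
    is basins x regions.  Ties in Euclidean distance break to the lowest
    basin index.  Basins that receive no frame get occupancy 0 and a NaN
    topography row.
    """
    series = np.asarray(series, dtype=float)
    templates = np.asarray(templates, dtype=float)
    if series.ndim != 2 or series.shape[0] == 0:
        raise ValueError("series must be a non-empty frames x regions matrix")
    if templates.ndim != 2 or templates.shape[1] != series.shape[1]:
        raise ValueError(
            f"templates have {templates.shape[-1]} regions, "
            f"series has {series.shape[1]}"
        )
    z, flat = zscore_frames(series)
    # squared Euclidean distance to every template; argmin ties -> lowest index.
    # Basins whose template is undefined (NaN: never visited during template
    # estimation) cannot attract any frame.
    d2 = ((z[:, None, :] - templates[None, :, :]) ** 2).sum(axis=2)
    d2[:, np.isnan(templates).any(axis=1)] = np.inf
    labels = np.argmin(d2, axis=1)
    n_basins = templates.shape[0]
    counts = np.bincount(labels, minlength=n_basins).astype(float)
    occupancy = counts / counts.sum()
    topo = np.full((n_basins, series.shape[1]), np.nan)
    for b in range(n_basins):
        mask = labels == b
        if mask.any():
            topo[b] = z[mask].mean(axis=0)
    return FrameLabeling(
        labels=labels,
        occupancy=occupancy,
        topography=topo,
        zero_variance_regions=flat,
    )


def classify_subjects(
    series_list, templates: np.ndarray, pool: bool = True
) -> FrameLabeling | list[FrameLabeling]:
    """Map several subjects' series; pool labels for a study-level result.

    Each subject is z-scored and labeled separately; with ``pool`` the
    per-subject labels are concatenated into one labeling whose occupancy
    and topography are computed over all subjects' frames.
    """
    per_subject = [classify_frames(s, templates) for s in series_list]
    if not pool:
        return per_subject
    labels = np.concatenate([fl.labels for fl in per_subject])
    z_all = np.vstack([zscore_frames(np.asarray(s, float))[0] for s in series_list])
    n_basins = templates.shape[0]
    counts = np.bincount(labels, minlength=n_basins).astype(float)
    topo = np.full((n_basins, templates.shape[1]), np.nan)
    for b in range(n_basins):
        mask = labels == b
        if mask.any():
            topo[b] = z_all[mask].mean(axis=0)
    return FrameLabeling(
        labels=labels, occupancy=counts / counts.sum(), topography=topo
    )


def pool_homotopic(
    templates: np.ndarray,
    pairs: list[tuple[int, int]],
    occupancy: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Merge mirror-paired basins to enforce a homotopic attractor structure.

    Every non-homotopic pair ``(a, b)``, ``a != b``, is replaced by a
    single basin whose template is the occupancy-weighted mean of the two
    (plain mean if ``occupancy`` is None); self-paired (homotopic) basins
    pass through unchanged.  Returns the pooled template matrix and, for
    each pooled basin, the tuple of original basin indices it contains.
    """
    templates = np.asarray(templates, dtype=float)
    n = templates.shape[0]
    seen: set[int] = set()
    groups: list[tuple[int, ...]] = []
    for a, b in pairs:
        if a in seen or b in seen:
            continue
        groups.append((a,) if a == b else tuple(sorted((a, b))))
        seen.update(groups[-1])
    for i in range(n):  # basins not mentioned in any pair pass through
        if i not in seen:
            groups.append((i,))
            seen.add(i)
    groups.sort()
    pooled = np.empty((len(groups), templates.shape[1]))
    for gi, group in enumerate(groups):
        if occupancy is None:
            w = np.ones(len(group))
        else:
            w = np.asarray([occupancy[i] for i in group], dtype=float)
            if w.sum() == 0:
                w = np.ones(len(group))
        pooled[gi] = (templates[list(group)] * w[:, None]).sum(axis=0) / w.sum()
    return pooled, groups


def occupancy_overlap(p: np.ndarray, q: np.ndarray, tol: float = 1e-8) -> float:
    """Overlap sum_i min(p_i, q_i) between two basin distributions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must be over the same basin index set")
    for name, d in (("p", p), ("q", q)):
        if abs(d.sum() - 1.0) > tol:
            raise ValueError(f"distribution {name} is not normalized")
    return float(np.minimum(p, q).sum())
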