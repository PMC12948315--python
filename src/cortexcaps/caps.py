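"""Co-activation patterns (CAPs): correlation-distance k-means and
reconstruction of CAP topographies from attractor basins.

A CAP is a recurring frame-wise whole-cortex activation pattern obtained
by clustering individual fMRI frames.  Following the standard rodent CAP
pipeline, frames are clustered with k-means++ under the correlation
distance d(x, y) = 1 - Pearson(x, y), k = 6 clusters, several restarts,
and the best restart by total within-cluster distance.  Because the
distance only sees the *shape* of a frame across regions, the clustering
is invariant to per-frame affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CAPSet",
    "extract_caps",
    "reconstruct_caps_from_attractors",
    "compare_caps",
    "anti_cap_pairs",
]


@dataclass(frozen=True)
class CAPSet:
    """k CAP centroids over regions, with per-frame assignments.

    Centroids are ordered by descending occurrence frequency.  ``inertia``
    is the total within-cluster correlation distance of the winning
    restart; ``labels`` may be absent for CAP sets reconstructed from
    attractors rather than clustered from frames.
    """

    centroids: np.ndarray                 # (k, N)
    labels: np.ndarray | None = None      # (frames,)
    inertia: float | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def frequencies(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("this CAP set carries no frame assignments")
        return np.bincount(self.labels, minlength=self.k) / self.labels.size


def _center_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def _corr_distance(frames_c: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - Pearson(frame, centroid); ``frames_c`` must be row-centered."""
    cc = _center_rows(centroids)
    fn = np.linalg.norm(frames_c, axis=1, keepdims=True)
    cn = np.linalg.norm(cc, axis=1, keepdims=True)
    corr = (frames_c @ cc.T) / (fn * cn.T)
    return 1.0 - corr


def _kmeanspp_init(frames_c, k, rng) -> np.ndarray:
    """k-means++ seeding under the correlation distance."""
    n = frames_c.shape[0]
    idx = [int(rng.integers(n))]
    d = _corr_distance(frames_c, frames_c[idx])[:, 0]
    for _ in range(1, k):
        prob = np.maximum(d, 0.0) ** 2
        total = prob.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=prob / total)))
        d = np.minimum(d, _corr_distance(frames_c, frames_c[[idx[-1]]])[:, 0])
    return frames_c[idx].copy()


def extract_caps(
    frames: np.ndarray,
    k: int = 6,
    replicates: int = 15,
    max_iter: int = 500,
    seed: int | None = None,
    zscore: bool = True,
) -> CAPSet:
    """Cluster fMRI frames into k CAPs by correlation-distance k-means.

    Runs ``replicates`` k-means++ restarts of at most ``max_iter`` Lloyd
    iterations each and keeps the restart with the smallest total
    within-cluster correlation distance.  Frames with zero variance
    across regions (undefined correlation) are excluded with a warning
    and labeled -1.  With ``zscore`` the concatenated frames are first
    z-scored per region.  CAPs are ordered by descending frequency.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValueError("frames must be a frames x regions matrix")
    if zscore:
        mu, sd = frames.mean(axis=0), frames.std(axis=0)
        frames = (frames - mu) / np.where(sd == 0, 1.0, sd)
    valid = frames.std(axis=1) > 0
    if not valid.all():
        import warnings

        warnings.warn(
            f"excluding {np.sum(~valid)} zero-variance frame(s) from CAP "
            "clustering",
            stacklevel=2,
        )
    x = frames[valid]
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} non-degenerate frames")
    xc = _center_rows(x)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(replicates):
        centroids = _kmeanspp_init(xc, k, rng)
        labels = np.full(x.shape[0], -1)
        for _ in range(max_iter):
            d = _corr_distance(xc, centroids)
            new_labels = np.argmin(d, axis=1)
            for j in range(k):  # re-seed empty clusters from the farthest frame
                if not np.any(new_labels == j):
                    far = int(np.argmax(d[np.arange(len(new_labels)), new_labels]))
                    new_labels[far] = j
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids = np.stack([x[labels == j].mean(axis=0) for j in range(k)])
        d = _corr_distance(xc, centroids)
        inertia = float(d[np.arange(len(labels)), labels].sum())
        if best is None or inertia < best[0]:
            best = (inertia, labels.copy(), centroids.copy())

    inertia, labels, centroids = best
    # order CAPs by descending occurrence frequency
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centroids = centroids[order]

    full_labels = np.full(frames.shape[0], -1)
    full_labels[valid] = labels
    return CAPSet(centroids=centroids, labels=full_labels, inertia=inertia)


def reconstruct_caps_from_attractors(
    cap_labels: np.ndarray,
    basin_labels: np.ndarray,
    basin_topographies: np.ndarray,
) -> CAPSet:
    """Rebuild CAP topographies as basin mixtures from joint frame labels.

    For CAP ``c`` the reconstructed topography is
    ``sum_b P(basin b | frame in CAP c) * topography_b``: the
    basin-usage-weighted mean of basin topographies, with the weights
    estimated from the frames jointly labeled by both pipelines.  Frames
    with a negative CAP label (excluded from clustering) are ignored.
    """
    cap_labels = np.asarray(cap_labels)
    basin_labels = np.asarray(basin_labels)
    if cap_labels.shape != basin_labels.shape:
        raise ValueError("cap_labels and basin_labels must cover the same frames")
    topo = np.asarray(basin_topographies, dtype=float)
    keep = cap_labels >= 0
    cap_labels, basin_labels = cap_labels[keep], basin_labels[keep]
    k = int(cap_labels.max()) + 1
    n_basins = topo.shape[0]
    centroids = np.empty((k, topo.shape[1]))
    for c in range(k):
        mask = cap_labels == c
        if not mask.any():
            raise ValueError(f"CAP {c} has no frames")
        w = np.bincount(basin_labels[mask], minlength=n_basins).astype(float)
        w /= w.sum()
        centroids[c] = w @ np.nan_to_num(topo)
    return CAPSet(centroids=centroids)


def compare_caps(
    a: CAPSet, b: CAPSet, match: str = "index"
) -> np.ndarray:
    """Per-CAP Pearson correlation between two CAP sets' topographies.

    With ``match="index"`` CAP ``i`` of ``a`` is compared with CAP ``i``
    of ``b`` (correspondence known, e.g. from joint frame labels); with
    ``match="greedy"`` pairs are resolved by repeatedly taking the
    highest remaining correlation.
    """
    if a.k != b.k or a.centroids.shape[1] != b.centroids.shape[1]:
        raise ValueError("CAP sets must share k and the region space")
    ac, bc = _center_rows(a.centroids), _center_rows(b.centroids)
    an = np.linalg.norm(ac, axis=1, keepdims=True)
    bn = np.linalg.norm(bc, axis=1, keepdims=True)
    corr = (ac @ bc.T) / (an * bn.T)
    if match == "index":
        return np.diag(corr).copy()
    if match != "greedy":
        raise ValueError("match must be 'index' or 'greedy'")
    out = np.empty(a.k)
    free_a, free_b = set(range(a.k)), set(range(a.k))
    masked = corr.copy()
    for _ in range(a.k):
        i, j = np.unravel_index(np.nanargmax(masked), masked.shape)
        out[i] = corr[i, j]
        free_a.discard(int(i)), free_b.discard(int(j))
        masked[i, :] = np.nan
        masked[:, j] = np.nan
    return out


def anti_cap_pairs(caps: CAPSet) -> list[tuple[int, int, float]]:
    """Pair each CAP with its anti-CAP: the most negatively correlated one.

    An anti-CAP is a mirror motif with strongly negative spatial
    similarity to its CAP.  Returns (cap, anti_cap, correlation) with
    each unordered pair reported once.
    """
    c = _center_rows(caps.centroids)
    n = np.linalg.norm(c, axis=1, keepdims=True)
    corr = (c @ c.T) / (n * n.T)
    np.fill_diagonal(corr, np.inf)
    out = []
    for i in range(caps.k):
        j = int(np.argmin(corr[i]))
        if i < j:
            out.append((i, j, float(corr[i, j])))
    return out
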