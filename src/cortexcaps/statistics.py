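"""Static summaries of fMRI series and model/data comparisons.

First-order statistic: the across-region distribution of the
time-averaged signal, centered on the global (across-region) mean and
normalized to the maximum absolute value, so every entry lies in [-1, 1].
Second-order statistic: the static functional connectivity (FC) matrix,
the across-region Pearson correlation over the whole series, averaged
entrywise across subjects or simulation repetitions.  The module also
provides global signal regression, histogram overlap of FC value
distributions, (partial) correlations between vectorized matrices, and
leading-eigenvector community detection on thresholded FC graphs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "normalized_mean_signal",
    "static_fc",
    "global_signal_regress",
    "pdf_overlap",
    "fc_similarity",
    "partial_fc_similarity",
    "detect_communities",
]


def normalized_mean_signal(series: np.ndarray) -> np.ndarray:
    """Across-region distribution of the time-averaged signal, in [-1, 1].

    Subtracts the global signal (the across-region mean of the regional
    time averages) from every region's time average and divides by the
    maximum absolute value, so at least one entry touches +/-1.  Adding a
    constant to all signals leaves the result unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] == 0:
        raise ValueError("series must be a non-empty frames x regions matrix")
    m = series.mean(axis=0)
    centered = m - m.mean()
    peak = np.abs(centered).max()
    if peak == 0:
        raise ValueError("all region means are equal; normalization undefined")
    return centered / peak


def _fc_one(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 frames to correlate")
    if np.any(series.std(axis=0) == 0):
        raise ValueError("zero-variance region; FC undefined")
    return np.corrcoef(series, rowvar=False)


def static_fc(series_list, fisher: bool = False) -> np.ndarray:
    """Subject-averaged static FC matrix.

    ``series_list`` is one frames x regions matrix or a list of them (one
    per subject / repetition).  Per-series Pearson FC matrices are
    averaged entrywise; with ``fisher`` the average is taken on Fisher
    z-transformed values and mapped back.
    """
    if isinstance(series_list, np.ndarray) and series_list.ndim == 2:
        series_list = [series_list]
    mats = [_fc_one(s) for s in series_list]
    if fisher:
        zs = [np.arctanh(np.clip(m, -1 + 1e-12, 1 - 1e-12)) for m in mats]
        out = np.tanh(np.mean(zs, axis=0))
        np.fill_diagonal(out, 1.0)
        return out
    return np.mean(mats, axis=0)


def global_signal_regress(series: np.ndarray) -> np.ndarray:
    """Regress the across-region mean time series out of every region.

    Per region, returns the ordinary-least-squares residual of the
    region's series on the global signal (with intercept); residuals are
    exactly uncorrelated with the global signal.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("series must have at least 2 frames")
    gs = series.mean(axis=1)
    if gs.std() == 0:
        raise ValueError("constant global signal; regression undefined")
    design = np.column_stack([np.ones_like(gs), gs])
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def pdf_overlap(x, y, n_bins: int = 30) -> float:
    """Overlap between the empirical PDFs of two samples, in [0, 1].

    Both samples are histogrammed on the same ``n_bins`` equi-spaced bins
    spanning their joint range; the overlap is the summed bin-wise
    minimum of the two normalized histograms.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    return float(np.minimum(px / px.sum(), py / py.sum()).sum())


def _vectorize(a: np.ndarray, part: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if part == "upper":
        return a[np.triu_indices_from(a, k=1)]
    if part == "lower":
        return a[np.tril_indices_from(a, k=-1)]
    if part == "full":
        return a.ravel()
    raise ValueError("part must be 'upper', 'lower' or 'full'")


def fc_similarity(a: np.ndarray, b: np.ndarray, part: str = "upper"):
    """Pearson r (and p) between two matrices' vectorized entries.

    For symmetric comparisons the entries above the main diagonal are
    arranged as vectors (``part="upper"``); asymmetric blocks use the
    full set of entries (``part="full"``).
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    return stats.pearsonr(_vectorize(a, part), _vectorize(b, part))


def partial_fc_similarity(
    model_fc: np.ndarray, emp_fc: np.ndarray, anatomy: np.ndarray
) -> tuple[float, float]:
    """Partial correlation of model and empirical FC given the anatomy.

    Vectorizes the three matrices, residualizes model and empirical FC on
    the anatomical connectivity (OLS with intercept), and correlates the
    residuals; computed separately on the upper and lower triangles
    (which differ when the anatomy is directed).  Returns
    ``(r_upper, r_lower)``.
    """
    if not (np.asarray(model_fc).shape == np.asarray(emp_fc).shape
            == np.asarray(anatomy).shape):
        raise ValueError("matrices must have the same shape")

    def _partial(part: str) -> float:
        x = _vectorize(model_fc, part)
        y = _vectorize(emp_fc, part)
        w = _vectorize(anatomy, part)
        design = np.column_stack([np.ones_like(w), w])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        # FC exactly explained by the anatomy leaves a zero residual: no
        # variance beyond the common anatomical driver, partial r = 0
        if (np.linalg.norm(rx) <= 1e-10 * np.linalg.norm(x)
                or np.linalg.norm(ry) <= 1e-10 * np.linalg.norm(y)):
            return 0.0
        return float(stats.pearsonr(rx, ry).statistic)

    return _partial("upper"), _partial("lower")


def detect_communities(fc: np.ndarray, threshold: float) -> list[set[int]]:
    """Leading-eigenvector modularity communities of a thresholded FC graph.

    Keeps edges with weight >= ``threshold`` (typically a fraction of the
    maximum off-diagonal FC entry), drops the diagonal, and partitions
    the resulting weighted undirected graph with Newman's
    leading-eigenvector method.  Returns the communities as sets of
    region indices.
    """
    import igraph

    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != fc.shape[1] or not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("fc must be a symmetric square matrix")
    adj = 0.5 * (fc + fc.T)  # exact symmetry for the graph constructor
    np.fill_diagonal(adj, 0.0)
    adj[adj < threshold] = 0.0
    if not np.any(adj > 0):
        raise ValueError("no edges survive the threshold")
    g = igraph.Graph.Weighted_Adjacency(adj.tolist(), mode="undirected")
    clusters = g.community_leading_eigenvector(weights="weight")
    return [set(c) for c in clusters]
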