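"""Correlation-distance functional connectivity.

The dissimilarity between channels i and j is ``D_ij = 1 - |r_ij|`` with r
the sample Pearson correlation over the analysis window.  Strong coupling —
positive or negative — therefore means *small* distance, which is what the
Vietoris-Rips filtration consumes.  D is a valid bounded dissimilarity
(symmetric, zero diagonal, values in [0, 1]) but not necessarily a metric;
the filtration does not need the triangle inequality.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BandSignal

__all__ = ["DistanceMatrix", "CorrelationDistance", "correlation_distance", "heatmap_render"]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric channel-by-channel correlation distance in [0, 1]."""

    D: np.ndarray
    node_names: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = self.D.shape[0]
        if self.D.ndim != 2 or self.D.shape[1] != n:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.D.min() < 0 or self.D.max() > 1:
            raise ValueError("distances must lie in [0, 1]")
        if len(self.node_names) != n:
            raise ValueError("node_names length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.D.shape[0]


class CorrelationDistance(BaseEstimator, TransformerMixin):
    """Transform channels x samples arrays into 1 - |Pearson r| matrices.

    ``transform`` accepts a single 2-D array or a sequence of them and
    returns the corresponding distance matrix / list of matrices as plain
    ndarrays; :func:`correlation_distance` wraps a single
    :class:`~eegtopo.preprocess.BandSignal` into a typed
    :class:`DistanceMatrix`.
    """

    def fit(self, X=None, y=None):
        return self

    def _one(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a channels x samples matrix")
        sd = X.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                f"channel index {flat[0]} is constant over the window; "
                "Pearson correlation is undefined"
            )
        r = np.corrcoef(X)
        D = 1.0 - np.abs(r)
        # rounding can push values a hair outside [0, 1]
        np.clip(D, 0.0, 1.0, out=D)
        np.fill_diagonal(D, 0.0)
        return (D + D.T) / 2.0

    def transform(self, X):
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self._one(X)
        return [self._one(x) for x in X]


def correlation_distance(sig: BandSignal) -> DistanceMatrix:
    """Correlation distance of one band signal, with channel names attached."""
    D = CorrelationDistance().fit().transform(sig.data)
    names = [f"ch{i}" for i in range(sig.n_channels)]
    return DistanceMatrix(D=D, node_names=names)


def heatmap_render(dm: DistanceMatrix, path, cmap: str = "viridis"):
    """Render the distance matrix as an n x n raster with a colorbar."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dm.D, cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    fig.colorbar(im, ax=ax, label="1 - |r|")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
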