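"""Vectorizations of persistence diagrams and their norm amplitudes.

Four families are implemented, each per homology dimension:

* persistence landscape — the k-th largest tent function over the diagram;
* Betti curve — number of classes alive at each grid value;
* heat kernel — Gaussian smoothing of the diagram minus its reflection
  across the diagonal of the (birth, death) plane;
* persistence entropy — Shannon entropy of lifetimes normalized by total
  persistence.

Curves and rasters are sampled on an ``n_bins`` grid spanning the diagram's
own range (minimum birth to maximum finite death, both dimensions pooled)
and summarized by 1- and 2-norm amplitudes scaled with the grid measure so
they approximate function-space L_p norms.  Essential (infinite-death)
classes are excluded everywhere.  The full per-diagram feature vector holds
22 amplitudes: 8 landscape (p x layers x dim), 4 Betti (p x dim), 8 heat
(p x sigma x dim) and 2 entropy (dim), plus the frequency-band index.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import PipelineConfig
from .homology import PersistenceDiagram

__all__ = [
    "make_grid",
    "landscape",
    "betti_curve",
    "heat_kernel",
    "persistence_entropy",
    "amplitude",
    "assemble_features",
    "feature_names",
    "DiagramFeaturizer",
]

_DIMS = (0, 1)


def make_grid(pd_obj: PersistenceDiagram, n_bins: int = 100) -> np.ndarray:
    """Evenly spaced sample points over the diagram's finite extent.

    The range is [min birth, max finite death] over both homology
    dimensions.  Degenerate diagrams (no finite pairs, or zero extent) get
    a unit-length fallback range so downstream code stays defined; every
    vectorization of such a diagram is zero anyway.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    finite = pd_obj.finite_pairs
    if len(finite) == 0:
        return np.linspace(0.0, 1.0, n_bins)
    lo = float(finite[:, 0].min())
    hi = float(finite[:, 1].max())
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins)


def _finite_of_dim(pd_obj: PersistenceDiagram, dim: int) -> np.ndarray:
    if dim not in _DIMS:
        raise ValueError("dim must be 0 or 1")
    return pd_obj.of_dim(dim, finite_only=True)


def landscape(
    pd_obj: PersistenceDiagram, dim: int, n_layers: int, grid: np.ndarray
) -> np.ndarray:
    """Persistence landscape layers, shape (n_layers, n_bins).

    Layer k at t is the k-th largest tent value over the diagram's pairs of
    the given dimension; the tent of (b, d) rises with slope 1 from b to
    (b+d)/2 and falls back to zero at d.
    """
    pairs = _finite_of_dim(pd_obj, dim)
    out = np.zeros((n_layers, len(grid)))
    if len(pairs) == 0:
        return out
    b = pairs[:, 0][:, None]
    d = pairs[:, 1][:, None]
    t = grid[None, :]
    tents = np.maximum(np.minimum(t - b, d - t), 0.0)  # (n_pairs, n_bins)
    k = min(n_layers, tents.shape[0])
    # descending sort along the pair axis gives the k-th max per column
    ordered = -np.sort(-tents, axis=0)
    out[:k] = ordered[:k]
    return out


def betti_curve(pd_obj: PersistenceDiagram, dim: int, grid: np.ndarray) -> np.ndarray:
    """Number of dim-classes alive at each grid value (birth <= t < death)."""
    pairs = _finite_of_dim(pd_obj, dim)
    if len(pairs) == 0:
        return np.zeros(len(grid))
    b = pairs[:, 0][:, None]
    d = pairs[:, 1][:, None]
    t = grid[None, :]
    return ((b <= t) & (t < d)).sum(axis=0).astype(float)


def heat_kernel(
    pd_obj: PersistenceDiagram, dim: int, sigma: float, grid: np.ndarray
) -> np.ndarray:
    """Diagonally antisymmetrized Gaussian raster of the diagram.

    Each pair (b, d) contributes an isotropic Gaussian at (b, d) minus one
    at the mirrored point (d, b), sampled on grid x grid.  ``sigma`` is in
    grid-pixel units and converted to filtration units via the grid
    spacing, so the kernel bandwidth tracks the diagram's own scale.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pairs = _finite_of_dim(pd_obj, dim)
    n_bins = len(grid)
    raster = np.zeros((n_bins, n_bins))
    if len(pairs) == 0:
        return raster
    dt = grid[1] - grid[0]
    s = sigma * dt
    for b, d in pairs:
        gb = np.exp(-((grid - b) ** 2) / (2 * s * s))
        gd = np.exp(-((grid - d) ** 2) / (2 * s * s))
        raster += np.outer(gb, gd) - np.outer(gd, gb)
    return raster


def persistence_entropy(pd_obj: PersistenceDiagram, dim: int) -> float:
    """Shannon entropy (natural log) of normalized finite lifetimes.

    Defined as 0 for diagrams with fewer than one positive-lifetime pair of
    the dimension; zero-lifetime pairs contribute nothing (0 log 0 = 0).
    """
    pairs = _finite_of_dim(pd_obj, dim)
    if len(pairs) == 0:
        return 0.0
    lifetimes = pairs[:, 1] - pairs[:, 0]
    lifetimes = lifetimes[lifetimes > 0]
    total = lifetimes.sum()
    if total <= 0:
        return 0.0
    p = lifetimes / total
    return float(-(p * np.log(p)).sum())


def amplitude(values: np.ndarray, p: int, grid: np.ndarray, raster: bool = False) -> float:
    """Grid-measure-scaled p-norm of a sampled curve, layer stack or raster.

    The sum of |v|^p is weighted by the grid cell measure (spacing for
    curves and layer stacks, spacing squared when ``raster`` is true) so
    the result approximates the function's L_p norm by a Riemann sum.
    """
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    values = np.asarray(values, dtype=float)
    dt = float(grid[1] - grid[0])
    measure = dt * dt if raster else dt
    return float((np.abs(values) ** p).sum() * measure) ** (1.0 / p)


def feature_names(config: PipelineConfig | None = None) -> list[str]:
    """Frozen amplitude ordering; defaults give the canonical 22 features."""
    config = config or PipelineConfig()
    names = []
    for p, n_layers in config.landscape_params:
        for dim in _DIMS:
            names.append(f"PL_p{p}_layers{n_layers}_H{dim}")
    for p in config.betti_params:
        for dim in _DIMS:
            names.append(f"BC_p{p}_H{dim}")
    for p, sigma in config.heat_params:
        for dim in _DIMS:
            names.append(f"HK_p{p}_sigma{sigma:g}_H{dim}")
    for dim in _DIMS:
        names.append(f"PE_H{dim}")
    return names


def assemble_features(
    pd_obj: PersistenceDiagram,
    band_index: int,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """All amplitude features of one diagram, band index appended last.

    With the default configuration the layout is the canonical 22-vector:
    features 1-8 landscape amplitudes (p in {1,2} x layers in {1,2} x
    H0/H1), 9-12 Betti amplitudes, 13-20 heat-kernel amplitudes
    (p x sigma in {1.6, 3.2} x dim) and 21-22 persistence entropies.
    """
    config = config or PipelineConfig()
    grid = make_grid(pd_obj, config.n_bins)
    feats: list[float] = []
    # landscape layers are cached per (dim, max layer count)
    max_layers = max((nl for _, nl in config.landscape_params), default=0)
    land = {dim: landscape(pd_obj, dim, max_layers, grid) for dim in _DIMS} if max_layers else {}
    for p, n_layers in config.landscape_params:
        for dim in _DIMS:
            feats.append(amplitude(land[dim][:n_layers], p, grid))
    betti = {dim: betti_curve(pd_obj, dim, grid) for dim in _DIMS}
    for p in config.betti_params:
        for dim in _DIMS:
            feats.append(amplitude(betti[dim], p, grid))
    for p, sigma in config.heat_params:
        for dim in _DIMS:
            feats.append(amplitude(heat_kernel(pd_obj, dim, sigma, grid), p, grid, raster=True))
    for dim in _DIMS:
        feats.append(persistence_entropy(pd_obj, dim))
    return np.array(feats + [float(band_index)])


class DiagramFeaturizer(BaseEstimator, TransformerMixin):
    """Transform diagrams into amplitude feature matrices.

    ``transform`` maps a sequence of (diagram, band_index) pairs — or plain
    diagrams, in which case ``band_index`` defaults to 1 — to an
    (n, n_features + 1) array whose last column is the band index.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None):
        self.config_ = self.config or PipelineConfig()
        self.feature_names_ = feature_names(self.config_) + ["band_index"]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        rows = []
        for item in X:
            if isinstance(item, PersistenceDiagram):
                pd_obj, band_index = item, 1
            else:
                pd_obj, band_index = item
            rows.append(assemble_features(pd_obj, band_index, self.config_))
        return np.array(rows).reshape(len(rows), -1)
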