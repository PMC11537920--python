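"""Pipeline configuration.

One :class:`PipelineConfig` object carries every tunable of the feature
pipeline: the EEG frequency bands, the analysis window, the vectorization
grid and parameter lists, the feature-selection threshold, the number of CV
folds and the master seed.  All randomness downstream (CV splits, synthetic
cohorts, permutation controls) flows from that single seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

__all__ = ["PipelineConfig", "DEFAULT_BANDS"]

# canonical clinical EEG bands used throughout
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 49.0),
}


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of the full feature pipeline.

    Attributes
    ----------
    bands : dict
        Ordered map band name -> (low Hz, high Hz).  Band index 1..n follows
        insertion order.
    window : tuple of float
        (start s, end s) analysis window, half-open ``[start, end)``.
    n_bins : int
        Grid resolution for curve/raster vectorizations.
    landscape_params : list of (p, n_layers)
        Norm order and layer count combinations for landscape amplitudes.
    betti_params : list of int
        Norm orders for Betti-curve amplitudes.
    heat_params : list of (p, sigma)
        Norm order and Gaussian bandwidth (in grid-pixel units) combinations
        for heat-kernel amplitudes.
    selection_threshold : float
        Univariate accuracy cut for feature selection, in (0.5, 1).
    cv_folds : int
        Cross-validation folds.
    seed : int
        Master seed for every stochastic step.
    """

    bands: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    window: tuple[float, float] = (126.0, 150.0)
    n_bins: int = 100
    landscape_params: list[tuple[int, int]] = dataclasses.field(
        default_factory=lambda: [(1, 1), (1, 2), (2, 1), (2, 2)]
    )
    betti_params: list[int] = dataclasses.field(default_factory=lambda: [1, 2])
    heat_params: list[tuple[int, float]] = dataclasses.field(
        default_factory=lambda: [(1, 1.6), (1, 3.2), (2, 1.6), (2, 3.2)]
    )
    selection_threshold: float = 0.6
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one frequency band is required")
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r}: need 0 < low < high, got ({lo}, {hi})")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0.5 < self.selection_threshold < 1):
            raise ValueError("selection_threshold must lie in (0.5, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    @property
    def n_features(self) -> int:
        """Number of amplitude features (both homology dimensions)."""
        n_dims = 2
        return n_dims * (
            len(self.landscape_params) + len(self.betti_params) + len(self.heat_params) + 1
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["bands"] = {k: tuple(v) for k, v in payload["bands"].items()}
        payload["window"] = tuple(payload["window"])
        payload["landscape_params"] = [tuple(v) for v in payload["landscape_params"]]
        payload["heat_params"] = [tuple(v) for v in payload["heat_params"]]
        return cls(**payload)
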