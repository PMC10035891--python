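"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionTimeSeries:
    """A parcellated region-by-time signal matrix.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_regions, n_frames)`` in arbitrary signal
        units.
    tr
        Sampling interval (repetition time) in seconds.
    region_labels
        One name per region; generated as ``R001..`` when omitted.
    """

    values: np.ndarray
    tr: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        n = self.values.shape[0]
        if not self.region_labels:
            self.region_labels = [f"R{i + 1:03d}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


@dataclass
class AnalyticSeries:
    """Amplitude/phase decomposition of a band-limited signal.

    ``phase`` is wrapped to ``(-pi, pi]``; ``amplitude`` is non-negative.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    tr: float
    band: tuple[float, float]
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        if not self.region_labels:
            self.region_labels = [
                f"R{i + 1:03d}" for i in range(self.amplitude.shape[0])
            ]

    @property
    def n_regions(self) -> int:
        return self.phase.shape[0]

    @property
    def n_frames(self) -> int:
        return self.phase.shape[1]
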