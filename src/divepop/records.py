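"""Core in-memory containers shared across the pipeline.

Depth is positive downward (metres below the surface).  Vertical speed is
the forward finite difference of depth over time, so it is positive while
the animal descends and negative while it ascends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DepthRecord:
    """Uniformly sampled depth time series from a time-depth recorder.

    Attributes
    ----------
    time : ndarray
        Seconds since deployment start, strictly increasing, uniform step.
    depth : ndarray
        Depth in metres, >= 0 after zero-offset correction.
    """

    time: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.time.size != self.depth.size:
            raise ValueError("time and depth must have equal length")
        if self.time.size >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            raise ValueError("record too short to define a sampling interval")
        return float(self.time[1] - self.time[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.time.size < 3:
            return True
        steps = np.diff(self.time)
        return bool(np.allclose(steps, steps[0], rtol=rtol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "depth_m": self.depth})


@dataclass
class TemperatureRecord:
    """Uniformly sampled (oesophageal or water) temperature series."""

    time: np.ndarray
    temperature: np.ndarray
    resolution: float = 0.01  # deg C, sensor resolution recorded as metadata

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.time.size != self.temperature.size:
            raise ValueError("time and temperature must have equal length")
        if self.resolution < 0:
            raise ValueError("resolution must be >= 0")

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            raise ValueError("record too short to define a sampling interval")
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "temp_c": self.temperature})


@dataclass
class Dive:
    """A single dive with phase boundaries (indices into the parent record).

    Phases partition [start, end]: descent = [start, bottom_start),
    bottom = [bottom_start, bottom_end], ascent = (bottom_end, end].
    The bottom phase is where depth >= 80% of the dive's maximum depth.
    """

    start: int
    end: int
    bottom_start: int
    bottom_end: int
    max_depth: float
    duration: float
    descent_rate: float
    ascent_rate: float
    post_dive_surface: float  # s at surface until the next dive (nan if last)

    def __post_init__(self) -> None:
        if not (self.start <= self.bottom_start <= self.bottom_end <= self.end):
            raise ValueError("phase boundaries must be ordered within the dive")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")


@dataclass
class FeedingEvent:
    """A qualifying oesophageal temperature drop (prey ingestion proxy)."""

    onset: float  # s
    drop_rate: float  # deg C / s, maximum descending rate within the drop
    amplitude: float  # deg C, peak-to-trough
    duration: float  # s

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class DiveBout:
    """A consecutive run of foraging dives separated by short surface gaps."""

    dive_indices: list
    n_dives: int
    covariates: dict = field(default_factory=dict)  # per-dive means
    n_feeding_events: int = 0


@dataclass
class ThermoclineEstimate:
    """Depth of maximum vertical temperature gradient."""

    depth: float  # m
    gradient: float  # deg C / m (signed, at the maximum of |dT/dz|)
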