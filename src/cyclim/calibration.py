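"""Camera and optics calibration models shared by the simulator and the
correction pipeline.

The camera is described by a Gaussian read-noise model: a frame records

    counts = offset + gain * exposure * flatfield * rate + N(0, read_sigma)

clipped to ``[0, saturation_level]``, where ``rate`` is the true photon-
equivalent intensity rate (per ms) at the pixel.  Spectral crosstalk between
fluorescence channels is linear and described by a square mixing matrix
applied to the vector of true per-fluorophore rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError

__all__ = ["NoiseModel", "CrosstalkMatrix", "CalibrationSet"]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian read-noise camera model.

    Parameters
    ----------
    read_offset : float
        Constant readout offset added to every pixel, in camera counts.
    read_sigma : float
        Standard deviation of the Gaussian read noise, in camera counts.
    gain : float
        Camera counts per detected photon-equivalent per ms of exposure.
    saturation_level : float
        Full-well clip level in camera counts.
    hot_rate, cold_rate : float
        Fractions of sensor pixels stuck at saturation / at zero.  Defective
        pixel positions are a fixed property of the simulated sensor, drawn
        from ``sensor_seed``.
    """

    read_offset: float = 100.0
    read_sigma: float = 2.0
    gain: float = 1.0
    saturation_level: float = 65535.0
    hot_rate: float = 0.0
    cold_rate: float = 0.0
    sensor_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_sigma <= 0:
            raise ConfigError("read_sigma must be > 0")
        if not (0 <= self.hot_rate < 0.01 and 0 <= self.cold_rate < 0.01):
            raise ConfigError("hot_rate and cold_rate must lie in [0, 0.01)")
        if self.saturation_level <= self.read_offset:
            raise ConfigError("saturation_level must exceed read_offset")

    def defect_masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (hot, cold) pixel masks for a sensor of the given shape.

        The masks depend only on ``sensor_seed`` and the shape, so every
        frame rendered through one model shares the same defective pixels.
        """
        rng = np.random.default_rng(self.sensor_seed)
        u = rng.random(shape)
        hot = u < self.hot_rate
        cold = (u >= self.hot_rate) & (u < self.hot_rate + self.cold_rate)
        return hot, cold


@dataclass
class CrosstalkMatrix:
    """Linear spectral mixing between fluorescence channels.

    ``matrix[i, j]`` is the contribution of true fluorophore ``channels[j]``
    to the signal observed in ``channels[i]``.
    """

    matrix: np.ndarray
    channels: list[str]
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise CalibrationError("crosstalk matrix must be square")
        if len(self.channels) != self.matrix.shape[0]:
            raise CalibrationError("channel list does not match matrix dimension")
        if np.any(np.diag(self.matrix) <= 0):
            raise CalibrationError("crosstalk matrix diagonal must be positive")

    @classmethod
    def identity(cls, channels: list[str]) -> "CrosstalkMatrix":
        return cls(np.eye(len(channels)), list(channels))

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def check_invertible(self) -> None:
        cond = self.condition_number
        if not np.isfinite(cond) or cond > self.max_condition:
            raise CalibrationError(
                f"crosstalk matrix condition number {cond:.3g} exceeds "
                f"bound {self.max_condition:.3g}"
            )

    def mix(self, true_rates: np.ndarray) -> np.ndarray:
        """Apply the mixing to a (channels, H, W) stack of true rates."""
        true_rates = np.asarray(true_rates, dtype=float)
        return np.einsum("ij,j...->i...", self.matrix, true_rates)


@dataclass
class CalibrationSet:
    """Everything needed to correct one acquisition: flatfields, readout
    offset, crosstalk matrix and the camera noise model."""

    flatfield: dict[str, np.ndarray] = field(default_factory=dict)
    readout_offset: float | np.ndarray = 0.0
    crosstalk: CrosstalkMatrix | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        for channel, ff in self.flatfield.items():
            ff = np.asarray(ff, dtype=float)
            if np.any(ff <= 0):
                raise CalibrationError(f"flatfield for channel {channel!r} has "
                                       "nonpositive pixels")
            self.flatfield[channel] = ff
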