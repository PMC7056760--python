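"""Acquisition geometry shared by the simulator and the projector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import EnergyWindow, standard_windows


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Rotating parallel-beam camera geometry.

    120 angles over 360 degrees by default, matching the 8-subsets-of-15
    ordered-subset structure used downstream. The detector is a plane of
    ``(nu, nv)`` square bins of ``pitch_cm``, its collimator face at
    ``radius_cm`` from the isocenter; u lies in the transaxial plane, v is
    the scanner axis.
    """

    n_angles: int = 120
    arc_deg: float = 360.0
    radius_cm: float = 25.0
    nu: int = 64
    nv: int = 48
    pitch_cm: float = 0.48
    windows: tuple[EnergyWindow, ...] = field(
        default_factory=lambda: tuple(standard_windows().values()))
    time_per_angle_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_angles <= 0 or self.radius_cm <= 0 or self.pitch_cm <= 0:
            raise ValueError("geometry parameters must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.arc_deg / self.n_angles

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)

    def window(self, label: str) -> EnergyWindow:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"window {label!r} not in geometry")

    def detector_axes_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin-center coordinates (cm) of the detector grid, 0 at center."""
        u = (np.arange(self.nu) - (self.nu - 1) / 2.0) * self.pitch_cm
        v = (np.arange(self.nv) - (self.nv - 1) / 2.0) * self.pitch_cm
        return u, v
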