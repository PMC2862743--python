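"""Gaussian confocal illumination profile."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: default axial-to-radial aspect ratio wz/w0 (typical confocal value)
DEFAULT_KAPPA = 5.0


@dataclass(frozen=True)
class PSFModel:
    """3D Gaussian detection/illumination profile.

    W(r) = exp(-2 (x^2 + y^2) / w0^2 - 2 z^2 / wz^2)

    ``w0_um`` is the radial 1/e^2 waist and ``wz_um`` the axial one; when
    ``wz_um`` is omitted it defaults to ``DEFAULT_KAPPA * w0_um``.
    """

    w0_um: float
    wz_um: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w0_um) and self.w0_um > 0):
            raise ValidationError(f"w0_um must be positive, got {self.w0_um!r}")
        if self.wz_um is None:
            object.__setattr__(self, "wz_um", DEFAULT_KAPPA * self.w0_um)
        if self.wz_um < self.w0_um:
            raise ValidationError("wz_um must be >= w0_um (elongated focal volume)")

    @property
    def kappa(self) -> float:
        return self.wz_um / self.w0_um

    @property
    def focal_volume_um3(self) -> float:
        """Effective 1/e^2 Gaussian observation volume pi^(3/2) w0^2 wz."""
        return float(np.pi ** 1.5 * self.w0_um**2 * self.wz_um)

    def value(self, dx, dy, dz):
        """Profile value at displacement (dx, dy, dz) from the beam center."""
        return np.exp(
            -2.0 * (np.asarray(dx) ** 2 + np.asarray(dy) ** 2) / self.w0_um**2
            - 2.0 * np.asarray(dz) ** 2 / self.wz_um**2
        )
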