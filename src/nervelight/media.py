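"""Optical media and the cylindrical nerve analog.

The simulated tissue is a homogeneous cylinder of myelinated white matter
embedded in a lower-index surround (air by default).  Default optical
constants are those commonly tabulated for white matter at blue
wavelengths: scattering coefficient ``mu_s`` = 43 mm^-1, absorption
coefficient ``mu_a`` = 0.35 mm^-1, anisotropy ``g`` = 0.8, refractive
index 1.32 against air (1.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class OpticalMedium:
    """Bulk optical constants of a homogeneous turbid medium.

    Parameters
    ----------
    mu_s : float
        Scattering coefficient in mm^-1 (inverse mean free path).
    mu_a : float
        Absorption coefficient in mm^-1.
    g : float
        Scattering anisotropy, the mean cosine of the Henyey-Greenstein
        deflection angle.  0 is isotropic; white matter is strongly
        forward-peaked (0.8).
    n : float
        Refractive index of the tissue.
    """

    mu_s: float = 43.0
    mu_a: float = 0.35
    g: float = 0.8
    n: float = 1.32

    def __post_init__(self) -> None:
        if not self.mu_s > 0:
            raise ValueError(f"mu_s must be positive, got {self.mu_s}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mean_free_path(self) -> float:
        """Mean scattering free path 1/mu_s, in mm."""
        return 1.0 / self.mu_s

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient, mm^-1.

        Diffusion-theory decay rate ``sqrt(3 mu_a (mu_a + mu_s (1 - g)))``
        used for the packet-intensity decay law I = I0 exp(-mu_eff t).
        """
        return mu_eff(self.mu_a, self.mu_s, self.g)


def mu_eff(mu_a: float, mu_s: float, g: float) -> float:
    """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s (1-g)))."""
    return math.sqrt(3.0 * mu_a * (mu_a + mu_s * (1.0 - g)))


# Canonical white-matter analog at blue wavelengths.
WHITE_MATTER = OpticalMedium(mu_s=43.0, mu_a=0.35, g=0.8, n=1.32)


@dataclass(frozen=True)
class NerveModel:
    """Cylindrical nerve analog.

    The nerve axis is the z-axis; cross sections lie in the x-y plane.
    The cylinder spans z in [0, length] with the side wall at
    x^2 + y^2 = radius^2.  ``external_n`` is the refractive index of the
    surrounding medium (air unless an immersion medium is modelled).
    """

    radius: float = 0.5
    length: float = 2.0
    medium: OpticalMedium = field(default_factory=lambda: WHITE_MATTER)
    external_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not self.length > 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.external_n < 1.0:
            raise ValueError(
                f"external refractive index must be >= 1, got {self.external_n}"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def critical_angle(self) -> float | None:
        """Total-internal-reflection critical angle in radians.

        ``asin(n_external / n_tissue)``; ``None`` when the surround has the
        higher index, in which case no incidence angle is totally reflected.
        """
        ratio = self.external_n / self.medium.n
        if ratio >= 1.0:
            return None
        return math.asin(ratio)

    def contains(self, point, tol: float = 1e-12) -> bool:
        x, y, z = point
        return (
            x * x + y * y <= self.radius**2 + tol
            and -tol <= z <= self.length + tol
        )

    def with_length(self, length: float) -> "NerveModel":
        return replace(self, length=length)
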