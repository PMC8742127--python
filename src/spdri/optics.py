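"""Optical-property primitives shared by the whole package.

All coefficients are expressed per millimetre (the convention of the tissue-optics
literature), lengths in micrometres unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one medium at a single wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1. Non-negative.
    mu_s : float
        Scattering coefficient, mm^-1. Non-negative.
    g : float
        Scattering anisotropy factor (mean cosine of the single-scattering
        deflection angle), strictly inside (-1, 1).
    n : float
        Refractive index, >= 1.

    The reduced scattering coefficient ``mu_s_prime = mu_s * (1 - g)`` is
    derived, never stored, so it can not drift out of sync.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)

    def replace(self, **kwargs) -> "OpticalProperties":
        vals = dict(mu_a=self.mu_a, mu_s=self.mu_s, g=self.g, n=self.n)
        vals.update(kwargs)
        return OpticalProperties(**vals)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mu_a, self.mu_s, self.g, self.n)
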