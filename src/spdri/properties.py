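"""Random perturbation of the optical properties and the 24-predictor view.

Every scalar optical property of every medium is drawn independently from a
Gaussian centred on its base value: sigma = 30% of the base for mu_a and mu_s,
sigma = 3% for g and n.  Draws that violate the physical bounds
(mu_a, mu_s >= 0; -1 < g < 1; n >= 1) are rejected and redrawn, which keeps
the Gaussian shape away from the bounds without clipping artefacts.

For analysis, mu_s and g are collapsed into the reduced scattering
coefficient mu_s' = mu_s * (1 - g), giving 24 predictors: (mu_a, mu_s', n)
for each of the seven skin layers and for blood, in medium-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalProperties
from .presets import (
    HEMOGLOBIN_CONCENTRATION_G_DL,
    REFERENCE_WAVELENGTH_NM,
    base_media,
)
from .skin_model import MEDIA_NAMES

#: fixed, documented predictor ordering: medium-major, then (mu_a, mu_s', n)
PREDICTOR_NAMES: tuple[str, ...] = tuple(
    f"{quantity}[{medium}]"
    for medium in MEDIA_NAMES
    for quantity in ("mu_a", "mu_s_prime", "n")
)

SIGMA_MU_DEFAULT = 0.30
SIGMA_GN_DEFAULT = 0.03


@dataclass(frozen=True)
class BasePropertySet:
    """Base optical properties of the 8 media at the reference wavelength."""

    media: dict[str, OpticalProperties]
    reference_wavelength_nm: float = REFERENCE_WAVELENGTH_NM
    hemoglobin_concentration_g_dl: float = HEMOGLOBIN_CONCENTRATION_G_DL

    def __post_init__(self) -> None:
        if tuple(self.media.keys()) != MEDIA_NAMES:
            missing = set(MEDIA_NAMES) - set(self.media)
            if missing:
                raise ValueError(f"media missing entries: {sorted(missing)}")
            # reorder into canonical order
            object.__setattr__(
                self, "media", {m: self.media[m] for m in MEDIA_NAMES}
            )

    @classmethod
    def default(cls) -> "BasePropertySet":
        return cls(media=base_media())


@dataclass(frozen=True)
class SampledPropertySet:
    """One perturbed draw of all 8 media plus its seed."""

    media: dict[str, OpticalProperties]
    seed: int | None = None

    @property
    def predictors(self) -> np.ndarray:
        return reduce_predictors(self)

    def media_list(self) -> list[OpticalProperties]:
        return [self.media[m] for m in MEDIA_NAMES]


def _draw_positive(rng: np.random.Generator, base: float, sigma_frac: float,
                   lower: float, upper: float = np.inf,
                   lower_open: bool = False) -> float:
    """Gaussian draw N(base, sigma_frac*base), rejection-resampled to bounds."""
    if sigma_frac == 0.0:
        return base
    sd = sigma_frac * abs(base)
    for _ in range(10_000):
        x = rng.normal(base, sd)
        if (x > lower if lower_open else x >= lower) and x < upper:
            return float(x)
    raise RuntimeError("rejection sampling failed to find an in-bounds draw")


def sample_property_set(base: BasePropertySet,
                        sigma_mu: float = SIGMA_MU_DEFAULT,
                        sigma_gn: float = SIGMA_GN_DEFAULT,
                        rng: np.random.Generator | int | None = None,
                        ) -> SampledPropertySet:
    """Draw one perturbed property set, element-wise and independently.

    Parameters
    ----------
    base : BasePropertySet
    sigma_mu : float
        Fractional Gaussian SD applied to mu_a and mu_s (default 0.30).
    sigma_gn : float
        Fractional Gaussian SD applied to g and n (default 0.03).
    rng : numpy Generator or seed

    Raises
    ------
    ValueError
        If a base mu_a/mu_s is <= 0 while its sigma is > 0 (the perturbation
        is multiplicative in scale and cannot be centred on zero).
    """
    if not 0 <= sigma_mu < 1 or not 0 <= sigma_gn < 1:
        raise ValueError("sigmas must lie in [0, 1)")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    media: dict[str, OpticalProperties] = {}
    for name, props in base.media.items():
        if sigma_mu > 0 and (props.mu_a <= 0 or props.mu_s <= 0):
            raise ValueError(
                f"base mu_a/mu_s of {name!r} must be > 0 to perturb them"
            )
        mu_a = _draw_positive(gen, props.mu_a, sigma_mu, 0.0)
        mu_s = _draw_positive(gen, props.mu_s, sigma_mu, 0.0)
        g = _draw_positive(gen, props.g, sigma_gn, -1.0, 1.0, lower_open=True)
        n = _draw_positive(gen, props.n, sigma_gn, 1.0)
        media[name] = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)
    return SampledPropertySet(media=media, seed=seed)


def reduce_predictors(sampled: SampledPropertySet) -> np.ndarray:
    """24-vector (mu_a, mu_s', n) per medium, in ``PREDICTOR_NAMES`` order."""
    out = np.empty(len(PREDICTOR_NAMES))
    for i, name in enumerate(MEDIA_NAMES):
        p = sampled.media[name]
        out[3 * i] = p.mu_a
        out[3 * i + 1] = p.mu_s_prime
        out[3 * i + 2] = p.n
    return out


def property_set_to_frame(sampled: SampledPropertySet | BasePropertySet,
                          ) -> pd.DataFrame:
    """One row per medium with the raw (mu_a, mu_s, g, n) values."""
    rows = []
    for name in MEDIA_NAMES:
        p = sampled.media[name]
        rows.append({"medium": name, "mu_a": p.mu_a, "mu_s": p.mu_s,
                     "g": p.g, "n": p.n})
    return pd.DataFrame(rows)


def frame_to_property_set(df: pd.DataFrame) -> SampledPropertySet:
    media = {
        row["medium"]: OpticalProperties(row["mu_a"], row["mu_s"],
                                         row["g"], row["n"])
        for _, row in df.iterrows()
    }
    return SampledPropertySet(media={m: media[m] for m in MEDIA_NAMES})
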