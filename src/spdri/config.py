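"""YAML round-trip for the configurable study constants.

The base optical properties and layer thicknesses shipped in
:mod:`spdri.presets` are placeholders; measured tables are supplied through
a structured YAML file::

    reference_wavelength_nm: 424
    hemoglobin_concentration_g_dl: 15
    layer_thickness_um:
      stratum_corneum: 20
      ...
    media:
      stratum_corneum: {mu_a: 1.0, mu_s: 70.0, g: 0.86, n: 1.50}
      ...
      blood: {mu_a: 150.0, mu_s: 80.0, g: 0.98, n: 1.37}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .optics import OpticalProperties
from .presets import _LAYER_THICKNESS_UM, default_layers
from .properties import BasePropertySet
from .skin_model import LAYER_NAMES, MEDIA_NAMES, SkinLayer


def dump_study_config(path, base: BasePropertySet | None = None,
                      layer_thickness_um: dict[str, float] | None = None,
                      ) -> None:
    """Write the current (or default) study constants to YAML."""
    base = base or BasePropertySet.default()
    thick = layer_thickness_um or dict(_LAYER_THICKNESS_UM)
    payload = {
        "reference_wavelength_nm": base.reference_wavelength_nm,
        "hemoglobin_concentration_g_dl": base.hemoglobin_concentration_g_dl,
        "layer_thickness_um": {n: float(thick[n]) for n in LAYER_NAMES},
        "media": {
            name: {"mu_a": p.mu_a, "mu_s": p.mu_s, "g": p.g, "n": p.n}
            for name, p in base.media.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_study_config(path) -> tuple[BasePropertySet, list[SkinLayer]]:
    """Read base properties and the layer stack from a YAML config."""
    data = yaml.safe_load(Path(path).read_text())
    media = {
        name: OpticalProperties(**data["media"][name])
        for name in MEDIA_NAMES
    }
    base = BasePropertySet(
        media=media,
        reference_wavelength_nm=float(
            data.get("reference_wavelength_nm", 424.0)),
        hemoglobin_concentration_g_dl=float(
            data.get("hemoglobin_concentration_g_dl", 15.0)),
    )
    thick = data.get("layer_thickness_um", _LAYER_THICKNESS_UM)
    layers = [
        SkinLayer(name, float(thick[name]), media[name])
        for name in LAYER_NAMES
    ]
    return base, layers
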