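"""Study presets: default geometry, layer stack, base optical properties.

Two presets are shipped:

``paper``
    The full-scale study volume: 950 x 950 x 2000 voxels at 1 um, six
    capillary loops on two superficial-vascular-plexus legs, loops spanning
    z = 150-300 voxels, plexus centred at z = 300, light source at
    (250, 250) / (250, 360), cross-section column x = 570, Gaussian
    smoothing sigma = 10 px, Savitzky-Golay frame 151 px.

``desk``
    A proportionally scaled 240 x 240 x 500 volume with two capillary loops,
    intended for single-CPU runs at ~1e6 photons.  Smoothing sigma and the
    Savitzky-Golay frame scale with the lateral extent (ratios 10/950 and
    151/950) so the signal processing stays comparable.

The per-layer thicknesses and the base optical properties at 424 nm are
configurable, literature-style placeholder values (the study's exact table is
not distributed with the package); every algorithm takes them as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .optics import OpticalProperties
from .skin_model import (
    LAYER_NAMES,
    GeometryConfig,
    SkinLayer,
    VesselElement,
)

#: reference wavelength of the base optical properties (nm); local maximum of
#: the oxyhaemoglobin absorption spectrum
REFERENCE_WAVELENGTH_NM = 424.0

#: haemoglobin concentration the blood mu_a refers to (g/dl); metadata only
HEMOGLOBIN_CONCENTRATION_G_DL = 15.0

# Placeholder base optical properties at 424 nm: (mu_a, mu_s, g, n), mm^-1 for
# the coefficients.  Chosen to be representative of published skin values in
# the blue; the stratum corneum / epidermis dominate mu_s', blood absorbs
# strongly near the oxyhaemoglobin Soret band.
_BASE_PROPS: dict[str, tuple[float, float, float, float]] = {
    "stratum_corneum": (1.0, 70.0, 0.86, 1.50),
    "epidermis": (1.5, 45.0, 0.80, 1.40),
    "papillary_dermis": (0.5, 35.0, 0.85, 1.39),
    "upper_blood_net_dermis": (0.7, 40.0, 0.88, 1.40),
    "reticular_dermis": (0.5, 30.0, 0.85, 1.39),
    "deep_blood_net_dermis": (0.6, 35.0, 0.88, 1.40),
    "subcutaneous_tissue": (0.3, 15.0, 0.80, 1.44),
    "blood": (150.0, 80.0, 0.98, 1.37),
}

# Layer thicknesses (um) at full scale.  Only the subcutis thickness (6000 um,
# trimmed to the volume depth) is fixed by the study description; the others
# are placeholders consistent with the stated vessel depths: capillary loops
# span z = 150-300 um and the plexus sits at z = 300 um, inside the upper
# blood net dermis.
_LAYER_THICKNESS_UM: dict[str, float] = {
    "stratum_corneum": 20.0,
    "epidermis": 100.0,
    "papillary_dermis": 150.0,
    "upper_blood_net_dermis": 80.0,
    "reticular_dermis": 1450.0,
    "deep_blood_net_dermis": 100.0,
    "subcutaneous_tissue": 6000.0,
}

#: capillary diameters simulated in the study (um)
DIAMETER_GRID_UM: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0, 14.0)

#: diameter of the superficial vascular plexus (um)
PLEXUS_DIAMETER_UM = 30.0

#: number of randomly perturbed optical-property sets in the study
N_PROPERTY_SETS = 236

# Table of lateral anchor coordinates (voxels, full scale): each capillary
# loop has two limb positions, each plexus leg two axis endpoints.
_LOOPS_FULL = [
    ((550.0, 550.0), (250.0, 295.0)),
    ((550.0, 550.0), (450.0, 495.0)),
    ((550.0, 550.0), (650.0, 695.0)),
    ((700.0, 700.0), (250.0, 295.0)),
    ((700.0, 700.0), (450.0, 495.0)),
    ((700.0, 700.0), (650.0, 695.0)),
]
_PLEXUS_FULL = [
    ((550.0, 550.0), (0.0, 950.0)),
    ((700.0, 700.0), (0.0, 950.0)),
]
_SOURCE_FULL = ((250.0, 250.0), (250.0, 360.0))
_LOOP_Z_FULL = (150.0, 300.0)
_CROSS_SECTION_X_FULL = 570.0
_SMOOTH_SIGMA_FULL = 10.0
_SAVGOL_FRAME_FULL = 151
_SAVGOL_ORDER = 5


def default_layers() -> list[SkinLayer]:
    """The seven-layer stack with placeholder thicknesses and properties."""
    return [
        SkinLayer(name, _LAYER_THICKNESS_UM[name],
                  OpticalProperties(*_BASE_PROPS[name]))
        for name in LAYER_NAMES
    ]


def default_blood() -> OpticalProperties:
    return OpticalProperties(*_BASE_PROPS["blood"])


def base_media() -> dict[str, OpticalProperties]:
    """Base optical properties for the 8 media (7 layers + blood)."""
    return {name: OpticalProperties(*vals) for name, vals in _BASE_PROPS.items()}


@dataclass(frozen=True)
class AnalysisConfig:
    """Signal-processing constants tied to a geometry preset."""

    source_shift: tuple[int, int]          # pixel shift between the two runs
    cross_section_x: int                   # profile column
    smoothing_sigma: float                 # Gaussian kernel sigma (px)
    savgol_frame: int                      # odd frame length (px)
    savgol_order: int = _SAVGOL_ORDER
    capillary_y_positions: tuple[float, ...] = ()   # loop centres on the column
    search_window: float | None = None     # extremum search half-window (px)


@dataclass(frozen=True)
class StudyPreset:
    """Geometry factory plus analysis constants for one scale."""

    name: str
    dims: tuple[int, int, int]
    voxel_size_um: float
    loops: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    plexus: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    loop_z: tuple[float, float]
    source_positions: tuple[tuple[float, float], tuple[float, float]]
    analysis: AnalysisConfig
    default_photons: int
    diameters_um: tuple[float, ...] = DIAMETER_GRID_UM
    layer_scale: float = 1.0  # thickness multiplier relative to full scale
    #: transport boundary on the side/deep faces ("mirror" lets a reduced
    #: box emulate the lateral extent of the full-scale volume)
    mc_boundary: str = "absorb"

    def geometry(self, capillary_diameter_um: float) -> GeometryConfig:
        """Geometry for one capillary diameter (loops share the diameter)."""
        vessels = [
            VesselElement("capillary_loop", xr, yr, self.loop_z,
                          capillary_diameter_um)
            for xr, yr in self.loops
        ]
        vessels += [
            VesselElement("plexus_leg", xr, yr,
                          (self.loop_z[1], self.loop_z[1]), PLEXUS_DIAMETER_UM)
            for xr, yr in self.plexus
        ]
        return GeometryConfig(
            dims=self.dims,
            voxel_size_um=self.voxel_size_um,
            vessels=tuple(vessels),
            source_positions=self.source_positions,
        )

    def layers(self) -> list[SkinLayer]:
        return [
            replace(l, thickness_um=l.thickness_um * self.layer_scale)
            for l in default_layers()
        ]


def _loop_centre_y(yr: tuple[float, float]) -> float:
    return 0.5 * (yr[0] + yr[1])


def paper_preset() -> StudyPreset:
    """Full-scale study volume (950 x 950 x 2000 voxels, six loops)."""
    # capillaries on the left plexus leg, intersected by the cross-section
    caps_on_column = tuple(
        _loop_centre_y(yr) for xr, yr in _LOOPS_FULL if xr[0] == 550.0
    )
    analysis = AnalysisConfig(
        source_shift=(0, 110),
        cross_section_x=int(_CROSS_SECTION_X_FULL),
        smoothing_sigma=_SMOOTH_SIGMA_FULL,
        savgol_frame=_SAVGOL_FRAME_FULL,
        capillary_y_positions=caps_on_column,
    )
    return StudyPreset(
        name="paper",
        dims=(950, 950, 2000),
        voxel_size_um=1.0,
        loops=tuple(_LOOPS_FULL),
        plexus=tuple(_PLEXUS_FULL),
        loop_z=_LOOP_Z_FULL,
        source_positions=_SOURCE_FULL,
        analysis=analysis,
        default_photons=10**10,
    )


def _round_odd(x: float) -> int:
    k = int(round(x))
    return k if k % 2 == 1 else k + 1


def desk_preset(n_loops: int = 2) -> StudyPreset:
    """Scaled-down single-CPU volume (240 x 240 x 500 voxels).

    Lateral coordinates shrink by 240/950, depths by 500/2000; vessel
    diameters stay physical (they are the quantity under study).  Source
    positions are rounded to integer pixels so the image shift is exact.
    """
    s_xy = 240.0 / 950.0
    s_z = 500.0 / 2000.0
    loops_left = [lp for lp in _LOOPS_FULL if lp[0][0] == 550.0][:n_loops]
    loops = tuple(
        (tuple(np.round(np.array(xr) * s_xy, 1)),
         tuple(np.round(np.array(yr) * s_xy, 1)))
        for xr, yr in loops_left
    )
    plexus = (((round(550 * s_xy, 1), round(550 * s_xy, 1)), (0.0, 240.0)),)
    src = ((63.0, 63.0), (63.0, 91.0))  # 250*s ~ 63.2, 360*s ~ 91.0
    loop_z = (_LOOP_Z_FULL[0] * s_z, _LOOP_Z_FULL[1] * s_z)  # (37.5, 75)
    caps_on_column = tuple(_loop_centre_y(yr) for _, yr in loops)
    analysis = AnalysisConfig(
        source_shift=(0, 28),
        cross_section_x=int(round(_CROSS_SECTION_X_FULL * s_xy)),  # 144
        smoothing_sigma=_SMOOTH_SIGMA_FULL * s_xy,                 # ~2.53
        savgol_frame=_round_odd(_SAVGOL_FRAME_FULL * s_xy),        # 39
        capillary_y_positions=caps_on_column,
    )
    return StudyPreset(
        name="desk",
        dims=(240, 240, 500),
        voxel_size_um=1.0,
        loops=loops,
        plexus=plexus,
        loop_z=loop_z,
        source_positions=src,
        analysis=analysis,
        default_photons=10**6,
        layer_scale=s_z,
        mc_boundary="mirror",
    )


def get_preset(name: str) -> StudyPreset:
    if name == "paper":
        return paper_preset()
    if name == "desk":
        return desk_preset()
    raise ValueError(f"unknown preset {name!r}; expected 'paper' or 'desk'")
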