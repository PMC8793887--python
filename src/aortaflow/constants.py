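"""Physical constants used by the hemodynamic maps.

All voxel-wise energetics use a unit voxel volume of 1 mm^3, which is the
voxel size after isotropic re-interpolation; kinetic energy is therefore
reported per 1 mm^3 of blood.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the blood-flow model.

    Attributes
    ----------
    blood_density:
        Density of whole blood in kg/m^3. Default 1060.
    voxel_volume:
        Unit voxel volume in m^3 (1 mm^3 after isotropic resampling).
    stasis_threshold:
        Speed below which a voxel counts as slow flow, in m/s. Default 0.1.
    viscosity:
        Dynamic viscosity of whole blood in Pa*s, used only for the
        Reynolds number. Default 3.5e-3.
    """

    blood_density: float = 1060.0
    voxel_volume: float = 1e-9
    stasis_threshold: float = 0.1
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        for name in ("blood_density", "voxel_volume", "stasis_threshold", "viscosity"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


DEFAULT_CONSTANTS = PhysicalConstants()

#: The five analysis regions, ordered from the aortic valve downstream.
REGIONS = ("LVOT", "AAo", "Arch", "PDAo", "DDAo")
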