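"""Crystal and beam geometry for the response-function simulation."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["CrystalGeometry", "BeamGeometry", "BROAD_BEAM_CM", "PENCIL_BEAM_CM"]

#: Beam diameters used throughout: a broad beam covering the full crystal
#: face, and the collimated pencil beam of the spectrometry setup.
BROAD_BEAM_CM = 7.6
PENCIL_BEAM_CM = 0.5


@dataclass(frozen=True)
class CrystalGeometry:
    """Cylindrical NaI(Tl) crystal, beam incident on the flat face.

    Defaults describe the 7.6 cm diameter x 7.6 cm thick detector.
    """

    radius: float = 3.8  # cm
    thickness: float = 7.6  # cm
    density: float = 3.67  # g/cm^3
    material: str = "NaI"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.thickness <= 0 or self.density <= 0:
            raise ValidationError("crystal radius, thickness, density must be > 0")


@dataclass(frozen=True)
class BeamGeometry:
    """Parallel photon beam along the cylinder axis.

    Entry points are sampled uniformly over a disc of ``diameter`` centered
    ``lateral_offset`` cm off the crystal axis.
    """

    diameter: float = PENCIL_BEAM_CM  # cm
    lateral_offset: float = 0.0  # cm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValidationError("beam diameter must be > 0")

    def validate_against(self, crystal: CrystalGeometry) -> None:
        if self.diameter / 2 + abs(self.lateral_offset) > crystal.radius + 1e-12:
            raise ValidationError("beam must be fully contained within the crystal face")
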