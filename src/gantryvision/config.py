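"""Gantry and camera configuration.

The virtual rig mirrors a three-axis gantry carrying a pan-tilt camera head:
the optical center can be placed anywhere inside a cuboid travel volume
(default 1150 x 840 x 718 mm) and rotated through any pan/tilt combination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

#: Travel volume of the gantry head, millimeters.
DEFAULT_VOLUME_MM = (1150.0, 840.0, 718.0)

#: Native camera resolution (pixels) and diagonal field of view (degrees)
#: of the rig's camera in linear (rectilinear) mode.
DEFAULT_RESOLUTION = (4000, 3000)
DEFAULT_FOV_DIAGONAL_DEG = 98.7

#: Hard limit of the pulse generator driving the stepper motors.
MAX_PULSE_RATE = 4000.0


@dataclass(frozen=True)
class TravelVolume:
    """Cuboid the gantry head can reach, anchored at the world origin."""

    x_size: float = DEFAULT_VOLUME_MM[0]
    y_size: float = DEFAULT_VOLUME_MM[1]
    z_size: float = DEFAULT_VOLUME_MM[2]

    def contains(self, x: float, y: float, z: float, tol: float = 1e-9) -> bool:
        return (
            -tol <= x <= self.x_size + tol
            and -tol <= y <= self.y_size + tol
            and -tol <= z <= self.z_size + tol
        )

    @property
    def center(self) -> tuple[float, float, float]:
        return (self.x_size / 2.0, self.y_size / 2.0, self.z_size / 2.0)


@dataclass
class RigConfig:
    """Static rig description: travel volume, camera intrinsics, head geometry.

    Parameters
    ----------
    head_offset_mm
        Displacement from the gantry-head attachment point to the optical
        center, world-frame millimeters at the reference orientation.
    margin_exclusion
        Fraction of the image border inside which bounding boxes are
        rejected (a countermeasure against uncorrected lens distortion at
        the frame margins). 0 disables the filter.
    """

    volume: TravelVolume = field(default_factory=TravelVolume)
    width_px: int = DEFAULT_RESOLUTION[0]
    height_px: int = DEFAULT_RESOLUTION[1]
    fov_diagonal_deg: float = DEFAULT_FOV_DIAGONAL_DEG
    head_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    margin_exclusion: float = 0.0

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigConfig":
        data = json.loads(Path(path).read_text())
        vol = TravelVolume(**data.pop("volume"))
        data["head_offset_mm"] = tuple(data.get("head_offset_mm", (0.0, 0.0, 0.0)))
        return cls(volume=vol, **data)
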