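"""Synthetic scenes: parametric plants on a floor, imaged against keying blue.

The renderer emulates the rig's study conditions: small seedlings placed at
marked floor positions inside the travel volume, photographed from arbitrary
pan/tilt poses against a uniform blue keying background.  Plants are drawn
as seeded, lobed rosette sprites lying flat on the floor plane — adequate
because the labeling pipeline needs only geometry and color contrast, not
botanical realism.  Rendering is exact inverse ray casting: every pixel ray
is intersected with the floor plane and tested against each plant's sprite
function, which yields per-pixel ground-truth masks for free and guarantees
that rendered plant pixels stay inside the plant's bounding sphere.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .config import TravelVolume
from .geometry import (
    BoundingSphere,
    CameraModel,
    CameraPose,
    PointBehindCameraError,
    WorldPoint,
    project_sphere,
)

__all__ = [
    "SpriteParams",
    "PlantTarget",
    "SceneSpec",
    "MarkedPosition",
    "SPECIES_TABLE",
    "MARKED_POSITIONS",
    "position_classes",
    "random_scene",
    "render_master",
    "render_background_only",
    "TooManyPlantsError",
]

#: Default keying-background color: saturated blue, far down the CIELAB b axis.
DEFAULT_BACKGROUND_RGB = (20, 60, 200)

#: Default bounding-sphere radius for a seedling, mm ("large enough" to
#: absorb pose/position error; sprites stay strictly inside it).
DEFAULT_SPHERE_RADIUS_MM = 90.0

#: (common-name label, scientific name) of the eight weed species the rig's
#: proof-of-concept dataset covers; grasses (monocots) are barnyard grass,
#: wild oat and yellow foxtail.
SPECIES_TABLE: list[tuple[str, str]] = [
    ("BarnyardGrass", "Echinochloa crus-galli"),
    ("CanadaThistle", "Cirsium arvense"),
    ("VolunteerCanola", "Brassica napus"),
    ("Dandelion", "Taraxacum officinale"),
    ("Smartweed", "Persicaria spp."),
    ("WildBuckwheat", "Fallopia convolvulus"),
    ("WildOat", "Avena fatua"),
    ("YellowFoxtail", "Setaria pumila"),
]


def species_id_prefix(scientific_name: str) -> str:
    """'Echinochloa crus-galli' -> 'echcru': three letters of genus + epithet."""
    parts = scientific_name.lower().replace("-", " ").split()
    genus = parts[0][:3]
    epithet = parts[1][:3] if len(parts) > 1 else "spp"
    return genus + epithet


@dataclass(frozen=True)
class MarkedPosition:
    """A measured-and-marked floor location plants are placed at repeatedly."""

    position_id: int
    x: float
    y: float
    position_class: str  # "edge" | "interior"


def _default_marked_positions() -> list[MarkedPosition]:
    vol = TravelVolume()
    edge_y = 40.0
    interior_rows = (320.0, 560.0)
    xs = [vol.x_size * (i + 1) / 5.0 for i in range(4)]  # 230, 460, 690, 920
    marked = [MarkedPosition(i + 1, x, edge_y, "edge") for i, x in enumerate(xs)]
    pid = 5
    for y in interior_rows:
        for x in xs:
            marked.append(MarkedPosition(pid, x, y, "interior"))
            pid += 1
    return marked


#: Twelve marked floor positions: four along the near edge of the travel
#: volume (half-cylinder of viewpoints) and eight interior (full circles).
MARKED_POSITIONS: list[MarkedPosition] = _default_marked_positions()


def position_classes() -> dict[int, str]:
    """position_id -> 'edge' | 'interior' for the marked positions."""
    return {m.position_id: m.position_class for m in MARKED_POSITIONS}


@dataclass(frozen=True)
class SpriteParams:
    """Appearance of one rendered rosette: hue, lobe structure, orientation."""

    hue: float = 0.30  # green-ish, HSV hue in [0, 1]
    leaf_count: int = 6
    lobe_sharpness: float = 1.5
    rotation_deg: float = 0.0
    radius_fraction: float = 0.85  # sprite radius / bounding-sphere radius, < 1
    seed: int = 0


@dataclass(frozen=True)
class PlantTarget:
    """One plant: identity, marked floor position, bounding sphere, sprite."""

    plant_id: str
    label: str
    scientific_name: str
    position_id: int
    position: WorldPoint
    sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM
    date_planted: date = date(2020, 1, 1)
    sprite: SpriteParams = field(default_factory=SpriteParams)

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be > 0")

    @property
    def bounding_sphere(self) -> BoundingSphere:
        return BoundingSphere(center=self.position, radius=self.sphere_radius)


@dataclass(frozen=True)
class SceneSpec:
    """A full scene: plants at distinct positions, background, floor height."""

    plants: tuple[PlantTarget, ...] = ()
    background_rgb: tuple[int, int, int] = DEFAULT_BACKGROUND_RGB
    floor_z: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [p.plant_id for p in self.plants]
        if len(set(ids)) != len(ids):
            raise ValueError("plant_id values must be unique within a scene")
        coords = [(p.position.x, p.position.y) for p in self.plants]
        if len(set(coords)) != len(coords):
            raise ValueError("plant positions must be pairwise distinct")

    def without_plants(self) -> "SceneSpec":
        return replace(self, plants=())


class TooManyPlantsError(ValueError):
    """More plants requested than marked positions available."""


def random_scene(
    n_plants: int,
    species_table: list[tuple[str, str]] | None = None,
    seed: int = 0,
    positions: list[MarkedPosition] | None = None,
    tight_packing: bool = False,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM,
    floor_z: float = 0.0,
) -> SceneSpec:
    """Deterministically draw a scene: species, positions, sprite parameters.

    Positions are sampled without replacement from the marked floor
    positions.  ``tight_packing`` instead packs plants on a compact grid with
    spacing below twice the sphere radius, so neighboring bounding boxes
    overlap in the images — the trade-off of imaging at maximal rates.
    """
    rng = np.random.default_rng(seed)
    table = species_table if species_table is not None else SPECIES_TABLE
    if tight_packing:
        vol = TravelVolume()
        pitch = 1.2 * sphere_radius  # < 2R: neighboring spheres overlap
        per_row = max(2, math.ceil(math.sqrt(n_plants)))
        cx, cy = vol.x_size / 2.0, vol.y_size / 2.0
        marked = []
        for i in range(n_plants):
            r, c = divmod(i, per_row)
            marked.append(
                MarkedPosition(
                    100 + i,
                    cx + (c - (per_row - 1) / 2.0) * pitch,
                    cy + (r - (per_row - 1) / 2.0) * pitch,
                    "interior",
                )
            )
    else:
        marked = positions if positions is not None else MARKED_POSITIONS
    if n_plants > len(marked):
        raise TooManyPlantsError(f"{n_plants} plants requested but only {len(marked)} marked positions")

    chosen_idx = rng.choice(len(marked), size=n_plants, replace=False)
    plants = []
    counters: dict[str, int] = {}
    for idx in sorted(chosen_idx):
        pos = marked[idx]
        label, sci = table[int(rng.integers(len(table)))]
        prefix = species_id_prefix(sci)
        counters[prefix] = counters.get(prefix, 0) + 1
        sprite = SpriteParams(
            hue=float(rng.uniform(0.22, 0.38)),
            leaf_count=int(rng.integers(4, 10)),
            lobe_sharpness=float(rng.uniform(0.8, 2.5)),
            rotation_deg=float(rng.uniform(0.0, 360.0)),
            radius_fraction=float(rng.uniform(0.6, 0.9)),
            seed=int(rng.integers(2**31)),
        )
        plants.append(
            PlantTarget(
                plant_id=f"{prefix}{counters[prefix]:03d}",
                label=label,
                scientific_name=sci,
                position_id=pos.position_id,
                position=WorldPoint(pos.x, pos.y, floor_z),
                sphere_radius=sphere_radius,
                date_planted=date(2020, 1, 1) + timedelta(days=int(rng.integers(0, 60))),
                sprite=sprite,
            )
        )
    return SceneSpec(plants=tuple(plants), floor_z=floor_z, seed=seed)


def _sprite_boundary(params: SpriteParams, sprite_radius: float, phi: np.ndarray) -> np.ndarray:
    """Polar boundary radius of the lobed rosette at angles ``phi``."""
    k = params.leaf_count
    rot = math.radians(params.rotation_deg)
    lobes = np.abs(np.cos(k * (phi - rot) / 2.0)) ** params.lobe_sharpness
    return sprite_radius * (0.45 + 0.55 * lobes)


def _base_rgb(params: SpriteParams) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb(params.hue, 0.85, 0.55)
    return np.array([r, g, b]) * 255.0


def render_master(
    scene: SceneSpec,
    pose: CameraPose,
    model: CameraModel,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render the scene from a pose; return (H x W x 3 uint8, per-plant masks).

    Masks are boolean rasters, pairwise disjoint, and together equal the
    non-background pixel set.  Where two sprites overlap (tight packing) the
    pixel goes to the plant whose normalized radial coordinate is smaller.
    """
    H, W = model.height, model.width
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.asarray(scene.background_rgb, dtype=np.uint8)

    claim = np.full((H, W), -1, dtype=np.int32)
    score = np.full((H, W), np.inf, dtype=np.float64)

    f = model.focal_px
    R = pose.rotation_world_to_camera()
    cam = pose.position.as_array()

    for i, plant in enumerate(scene.plants):
        try:
            box = project_sphere(pose, model, plant.bounding_sphere)
        except PointBehindCameraError:
            continue
        if box is None:
            continue
        r0 = max(0, math.floor(box.y_min * H))
        r1 = min(H, math.ceil(box.y_max * H) + 1)
        c0 = max(0, math.floor(box.x_min * W))
        c1 = min(W, math.ceil(box.x_max * W) + 1)
        if r0 >= r1 or c0 >= c1:
            continue

        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        u = (cols + 0.5) / W
        v = (rows + 0.5) / H
        d_cam = np.stack(
            [
                np.ones_like(u),
                -(u - 0.5) * W / f,
                -(v - 0.5) * H / f,
            ],
            axis=-1,
        )
        d_world = d_cam @ R  # row-vector transform by R^T
        dz = d_world[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (scene.floor_z - cam[2]) / dz
        valid = (np.abs(dz) > 1e-15) & (t > 0)
        wx = cam[0] + t * d_world[..., 0]
        wy = cam[1] + t * d_world[..., 1]
        dx = wx - plant.position.x
        dy = wy - plant.position.y
        rho = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        sprite_radius = plant.sprite.radius_fraction * plant.sphere_radius
        boundary = _sprite_boundary(plant.sprite, sprite_radius, phi)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(boundary > 0, rho / boundary, np.inf)
        inside = valid & (frac <= 1.0)

        sub_claim = claim[r0:r1, c0:c1]
        sub_score = score[r0:r1, c0:c1]
        take = inside & (frac < sub_score)
        sub_claim[take] = i
        sub_score[take] = frac[take]

    masks: dict[str, np.ndarray] = {}
    for i, plant in enumerate(scene.plants):
        mask = claim == i
        masks[plant.plant_id] = mask
        if mask.any():
            shade = np.clip(1.35 - 0.55 * score[mask], 0.6, 1.35)
            rgb = np.clip(_base_rgb(plant.sprite)[None, :] * shade[:, None], 0, 255)
            img[mask] = rgb.astype(np.uint8)
    return img, masks


def render_background_only(
    scene: SceneSpec,
    pose: CameraPose,
    model: CameraModel,
) -> np.ndarray:
    """The same capture with every plant removed: pixel-identical background."""
    img, _ = render_master(scene.without_plants(), pose, model)
    return img
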