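"""End-to-end production pipeline: simulate -> plan -> capture -> label.

One run places plants at marked floor positions, generates aimed camera
poses on rings around every plant, orders all poses with the nested zig-zag
planner, renders a master image per pose, projects every plant's bounding
sphere to a labeled box, crops subimages, and writes v1.5 metadata plus a
run manifest.  Runs are fully reproducible from (config, seed): wall-clock
fields come from a clock abstraction so tests can inject a fixed clock and
obtain byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import geometry, labeler, planner, scene as scene_mod
from .config import MAX_PULSE_RATE, RigConfig
from .geometry import CameraModel, PointBehindCameraError
from .planner import MotionProfile, ProductionLog, build_route, production_rates, schedule
from .stats import dataset_summary

__all__ = ["RunConfig", "Clock", "FixedClock", "SystemClock", "run_pipeline", "report", "RunResult"]

log = logging.getLogger("gantryvision")

#: Per-image time costs of the bulk-download and cropping stages (s),
#: calibrated from a measured production run: 46 min over 2149 masters and
#: 34 min over 3494 subimages.
DEFAULT_DOWNLOAD_S_PER_MASTER = 46.0 * 60.0 / 2149.0
DEFAULT_CROP_S_PER_SUBIMAGE = 34.0 * 60.0 / 3494.0


class Clock:
    """Source of capture timestamps."""

    def start_time(self) -> datetime:
        raise NotImplementedError


class SystemClock(Clock):
    def start_time(self) -> datetime:
        return datetime.now()


class FixedClock(Clock):
    """Deterministic clock for reproducible runs."""

    def __init__(self, start: datetime | None = None):
        self._start = start or datetime(2020, 6, 1, 9, 0, 0)

    def start_time(self) -> datetime:
        return self._start


class RunConfig(BaseModel):
    """Production settings for one run.

    Defaults mirror a conservative daily production setup: 9 locations
    imaged, sequential axis movement, 3000 pulses/s peak rate at half-steps,
    10000 pulses/s^2 acceleration, a 3 s settling pause and 2.7 s capture
    per image, nested zig-zag routing.
    """

    model_config = ConfigDict(extra="forbid")

    locations_imaged: int = 9
    #: (height, radius, count) viewpoint rings; the default radius keeps every
    #: candidate viewpoint of every marked position inside the travel volume.
    rings: list[tuple[float, float, int]] = Field(default_factory=lambda: [(450.0, 140.0, 4)])
    pulse_rate: float = 3000.0
    acceleration: float = 10000.0
    stepping_mode: str = "half"
    parallel_axes: bool = False
    pause_before_trigger: float = 3.0
    imaging_time: float = 2.7
    routing_algorithm: str = "nested-zigzag"
    seed: int = 0
    render_width: int = 400
    render_height: int = 300
    fov_diagonal_deg: float = 98.7
    sphere_radius_mm: float = scene_mod.DEFAULT_SPHERE_RADIUS_MM
    tight_packing: bool = False
    margin_exclusion: float = 0.0
    #: Drop pairs of boxes that intersect in the image before cropping, so a
    #: labeled subimage never contains material of a neighboring plant.  When
    #: None, resolved to ``not tight_packing``: tight packing deliberately
    #: trades label purity for imaging rate and keeps (but flags) overlaps.
    skip_overlapping_boxes: bool | None = None
    box_origin: str = "upper-right"
    image_format: str = "jpg"
    room: str = "simlab"
    institute: str = "virtual"
    camera: str = "GoPro"
    lens: str = "Hero 7 Black"
    download_s_per_master: float = DEFAULT_DOWNLOAD_S_PER_MASTER
    crop_s_per_subimage: float = DEFAULT_CROP_S_PER_SUBIMAGE

    @field_validator("pulse_rate")
    @classmethod
    def _pulse(cls, v: float) -> float:
        if not 0 < v <= MAX_PULSE_RATE:
            raise ValueError(f"pulse_rate must be in (0, {MAX_PULSE_RATE}] pulses/s")
        return v

    @field_validator("stepping_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("half", "full"):
            raise ValueError("stepping_mode must be 'half' or 'full'")
        return v

    @field_validator("routing_algorithm")
    @classmethod
    def _routing(cls, v: str) -> str:
        if v != "nested-zigzag":
            raise ValueError("only 'nested-zigzag' routing is available")
        return v

    @field_validator("locations_imaged")
    @classmethod
    def _locations(cls, v: int) -> int:
        if v < 1:
            raise ValueError("locations_imaged must be >= 1")
        return v

    @field_validator("image_format")
    @classmethod
    def _fmt(cls, v: str) -> str:
        if v not in ("jpg", "png"):
            raise ValueError("image_format must be 'jpg' or 'png'")
        return v

    def motion_profile(self) -> MotionProfile:
        return MotionProfile(
            pulse_rate=self.pulse_rate,
            acceleration=self.acceleration,
            step_mode_factor=0.5 if self.stepping_mode == "half" else 1.0,
            parallel_axes=self.parallel_axes,
        )

    def camera_model(self) -> CameraModel:
        return CameraModel(self.render_width, self.render_height, self.fov_diagonal_deg)


@dataclass
class RunResult:
    run_dir: Path
    n_masters: int
    n_subimages: int
    t_p: float
    records: list[labeler.MetadataRecord]


def _save(img: np.ndarray, path: Path) -> None:
    Image.fromarray(img).save(path, quality=92) if path.suffix in (".jpg", ".jpeg") else Image.fromarray(img).save(path)


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    clock: Clock | None = None,
    rig: RigConfig | None = None,
) -> RunResult:
    """Execute a full simulated production run into ``out_dir``."""
    clock = clock or SystemClock()
    rig = rig or RigConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.camera_model()
    profile = config.motion_profile()

    log.info("generating scene: %d locations, seed %d", config.locations_imaged, config.seed)
    scene = scene_mod.random_scene(
        config.locations_imaged,
        seed=config.seed,
        tight_packing=config.tight_packing,
        sphere_radius=config.sphere_radius_mm,
    )
    classes = scene_mod.position_classes()
    for p in scene.plants:
        classes.setdefault(p.position_id, "interior")  # tight-packing grid ids

    # one viewpoint ring set per plant, aimed at its floor position
    all_poses: list[geometry.CameraPose] = []
    for plant in scene.plants:
        all_poses.extend(
            geometry.generate_pose_set(
                plant.position, classes[plant.position_id], config.rings, rig.volume
            )
        )

    ordered = planner.plan_zigzag(all_poses, rig.volume.x_size / 4.0, rig.volume.y_size / 4.0)
    route = build_route(ordered, profile, config.pause_before_trigger, config.imaging_time)
    t_p = schedule(route)
    log.info("route planned: %d poses, simulated imaging time %.1f s", len(ordered), t_p)

    start = clock.start_time()
    ext = config.image_format
    records: list[labeler.MetadataRecord] = []
    n_sub = 0
    n_overlaps_flagged = 0
    used_names: set[str] = set()
    elapsed = 0.0
    for pose_num, (pose, leg) in enumerate(zip(route.poses, [0.0] + route.leg_times), start=1):
        elapsed += leg + route.pause_before_trigger + route.imaging_time
        stamp = start + timedelta(seconds=elapsed)
        ts = stamp.strftime("%Y%m%d%H%M%S")
        master_name = f"{ts}-pose{pose_num}.{ext}"
        if master_name in used_names:
            raise labeler.LabelerError(f"timestamp collision for {master_name}")
        used_names.add(master_name)

        img, masks = scene_mod.render_master(scene, pose, model)
        boxes: list[geometry.ImageBox | None] = []
        kept_plants = []
        for plant in scene.plants:
            try:
                box = geometry.project_sphere(pose, model, plant.bounding_sphere)
            except (PointBehindCameraError, geometry.CameraInsideSphereError):
                box = None
            boxes.append(box)
            kept_plants.append(plant)
        boxes = geometry.filter_margin(boxes, config.margin_exclusion)

        # overlapping boxes would leak neighboring-plant pixels into crops;
        # flag them, and outside tight packing exclude both members
        present = [(i, b) for i, b in enumerate(boxes) if b is not None]
        overlap_idx = labeler.find_box_overlaps([b for _, b in present])
        flagged = {present[i][0] for i, j in overlap_idx} | {present[j][0] for i, j in overlap_idx}
        n_overlaps_flagged += len(overlap_idx)
        skip_overlaps = (
            config.skip_overlapping_boxes
            if config.skip_overlapping_boxes is not None
            else not config.tight_packing
        )
        if skip_overlaps:
            boxes = [None if i in flagged else b for i, b in enumerate(boxes)]

        entries = []
        sub_crops = []
        for plant, box in zip(kept_plants, boxes):
            if box is None or box.width == 0.0 or box.height == 0.0:
                continue
            sub_name = f"{ts}{plant.position_id}.{ext}"
            xmn, xmx, ymn, ymx = labeler.to_record_fractions(box, config.box_origin)
            entries.append(
                labeler.BoxEntry(
                    plant_id=plant.plant_id,
                    label=plant.label,
                    scientific_name=plant.scientific_name,
                    position_id=plant.position_id,
                    subimage_file_name=sub_name,
                    date_planted=plant.date_planted.isoformat(),
                    x_min=xmn,
                    x_max=xmx,
                    y_min=ymn,
                    y_max=ymx,
                )
            )
            sub_crops.append((sub_name, box))

        bb_name = f"{ts}-pose{pose_num}-bb.{ext}"
        record = labeler.MetadataRecord(
            file_name=master_name,
            bb_file_name=bb_name,
            date=stamp.strftime("%Y-%m-%d"),
            time=stamp.strftime("%H:%M:%S"),
            room=config.room,
            institute=config.institute,
            camera=config.camera,
            lens=config.lens,
            camera_pose=labeler.CameraPoseMeta(
                x=pose.position.x,
                y=pose.position.y,
                z=pose.position.z,
                polar_angle=90.0 + pose.tilt,
                azimuthal_angle=pose.pan,
            ),
            bounding_boxes=entries,
            box_origin=config.box_origin,
        )

        _save(img, out / master_name)
        internal_boxes = [labeler.from_record_fractions(e, config.box_origin) for e in entries]
        _save(labeler.draw_overlay(img, internal_boxes), out / bb_name)
        for crop, (sub_name, _) in zip(labeler.crop_subimages(img, internal_boxes), sub_crops):
            _save(crop, out / sub_name)
        labeler.write_metadata(record, out / (master_name + ".json"))
        records.append(record)
        n_sub += len(entries)

    class_counts = labeler.organize_outputs(records, out, classes)
    n_m = len(records)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "n_masters": n_m,
        "n_subimages": n_sub,
        "t_p_s": t_p,
        "t_d_s": config.download_s_per_master * n_m,
        "t_c_s": config.crop_s_per_subimage * n_sub,
        "class_counts": class_counts,
        "n_overlap_pairs_flagged": n_overlaps_flagged,
        "routing_algorithm": "Nested Zig-Zag",
        "start_time": start.isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %d masters, %d subimages", n_m, n_sub)
    return RunResult(run_dir=out, n_masters=n_m, n_subimages=n_sub, t_p=t_p, records=records)


class IncompleteRunError(RuntimeError):
    pass


def report(run_dir: str | Path) -> str:
    """Production report of a completed run: counts, times, rates, species."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise IncompleteRunError(f"no manifest.json in {run}")
    manifest = json.loads(manifest_path.read_text())
    n_m, n_s = manifest["n_masters"], manifest["n_subimages"]
    lines = [
        "Production report",
        "=================",
        f"Routing Algorithm\t{manifest['routing_algorithm']}",
        f"Masters\t{n_m}",
        f"Subimages\t{n_s}",
        f"Imaging time t_p (s)\t{manifest['t_p_s']:.1f}",
        f"Download time t_d (s)\t{manifest['t_d_s']:.1f}",
        f"Cropping time t_c (s)\t{manifest['t_c_s']:.1f}",
    ]
    if n_m > 0 and n_s > 0:
        plog = ProductionLog(manifest["t_p_s"], manifest["t_d_s"], manifest["t_c_s"], n_m, n_s)
        t_m, t_s = production_rates(plog)
        lines += [f"t_m (s/master)\t{t_m:.2f}", f"t_s (s/subimage)\t{t_s:.2f}"]
    else:
        lines += ["t_m (s/master)\t0", "t_s (s/subimage)\t0"]
    summary = dataset_summary(run)
    lines += ["", "Subimages per species", "---------------------", repr(summary)]
    return "\n".join(lines)
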