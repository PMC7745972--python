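"""Transform chain: world -> camera -> image, sphere boxes, back-projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gantryvision.config import TravelVolume
from gantryvision.geometry import (
    BoundingSphere,
    CameraFramePoint,
    CameraModel,
    CameraPose,
    CameraInsideSphereError,
    EmptyPoseSetError,
    GeometryError,
    ImageBox,
    NoGroundIntersectionError,
    PointBehindCameraError,
    WorldPoint,
    aim_at,
    camera_to_image,
    filter_margin,
    generate_pose_set,
    image_to_ground,
    project_sphere,
    world_to_camera,
)
from conftest import random_visible_pose


def rotation_oracle(pan_deg: float, tilt_deg: float) -> np.ndarray:
    """Independent world->camera rotation: Ry(-tilt) composed with Rz(-pan)."""
    p, t = math.radians(pan_deg), math.radians(tilt_deg)
    rz = np.array(
        [[math.cos(-p), -math.sin(-p), 0.0], [math.sin(-p), math.cos(-p), 0.0], [0.0, 0.0, 1.0]]
    )
    ry = np.array(
        [[math.cos(-t), 0.0, math.sin(-t)], [0.0, 1.0, 0.0], [-math.sin(-t), 0.0, math.cos(-t)]]
    )
    return ry @ rz


class TestWorldToCamera:
    def test_identity_orientation_keeps_forward_point(self):
        pose = CameraPose(WorldPoint(0, 0, 0), pan=0, tilt=0)
        q = world_to_camera(pose, WorldPoint(100, 0, 0))
        assert np.allclose([q.x_f, q.y_f, q.z_f], [100, 0, 0])

    def test_own_position_maps_to_origin(self):
        pose = CameraPose(WorldPoint(12.5, -3.0, 44.0), pan=123, tilt=-10)
        q = world_to_camera(pose, pose.position)
        assert np.allclose([q.x_f, q.y_f, q.z_f], [0, 0, 0])

    def test_generic_pose_matches_matrix_composition_oracle(self):
        pose = CameraPose(WorldPoint(10, 20, 30), pan=30, tilt=20)
        p = WorldPoint(137.0, -42.0, 88.5)
        expected = rotation_oracle(30, 20) @ (p.as_array() - pose.position.as_array())
        q = world_to_camera(pose, p)
        assert np.allclose([q.x_f, q.y_f, q.z_f], expected, atol=1e-12)

    @given(
        pan=st.floats(0, 360), tilt=st.floats(-90, 90),
        ax=st.floats(-500, 500), ay=st.floats(-500, 500), az=st.floats(-500, 500),
        bx=st.floats(-500, 500), by=st.floats(-500, 500), bz=st.floats(-500, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_rigid_transform_preserves_distances(self, pan, tilt, ax, ay, az, bx, by, bz):
        pose = CameraPose(WorldPoint(100, 200, 300), pan=pan, tilt=tilt)
        a, b = WorldPoint(ax, ay, az), WorldPoint(bx, by, bz)
        d_world = np.linalg.norm(a.as_array() - b.as_array())
        qa, qb = world_to_camera(pose, a), world_to_camera(pose, b)
        d_cam = np.linalg.norm(qa.as_array() - qb.as_array())
        assert d_cam == pytest.approx(d_world, rel=1e-9, abs=1e-9)

    def test_tilt_outside_span_rejected(self):
        with pytest.raises(GeometryError):
            CameraPose(WorldPoint(0, 0, 0), tilt=91)


class TestCameraToImage:
    def test_optical_axis_hits_image_center(self, default_model):
        for d in (1.0, 250.0, 9000.0):
            assert camera_to_image(default_model, CameraFramePoint(d, 0, 0)) == (0.5, 0.5)

    def test_half_fov_ray_maps_to_border(self, default_model):
        half_h = math.radians(default_model.fov_horizontal_deg / 2)
        u, v = camera_to_image(default_model, CameraFramePoint(math.cos(half_h), -math.sin(half_h), 0))
        assert u == pytest.approx(1.0, abs=1e-9)
        assert v == pytest.approx(0.5, abs=1e-9)
        half_v = math.radians(default_model.fov_vertical_deg / 2)
        u, v = camera_to_image(default_model, CameraFramePoint(math.cos(half_v), 0, math.sin(half_v)))
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_generic_bearing_elevation_matches_tan_oracle(self, default_model):
        bearing, elevation = math.radians(10), math.radians(5)
        # direction with bearing right of axis and elevation above it
        q = CameraFramePoint(1.0, -math.tan(bearing), math.tan(elevation))
        f = math.hypot(default_model.width, default_model.height) / 2 / math.tan(
            math.radians(default_model.fov_diagonal_deg) / 2
        )
        u_expect = 0.5 + f * math.tan(bearing) / default_model.width
        v_expect = 0.5 - f * math.tan(elevation) / default_model.height
        u, v = camera_to_image(default_model, q)
        assert (u, v) == pytest.approx((u_expect, v_expect), abs=1e-12)

    def test_point_behind_camera_raises(self, default_model):
        with pytest.raises(PointBehindCameraError):
            camera_to_image(default_model, CameraFramePoint(0.0, 10, 10))
        with pytest.raises(PointBehindCameraError):
            camera_to_image(default_model, CameraFramePoint(-5.0, 0, 0))


class TestProjectSphere:
    def test_zero_radius_gives_point_box(self, default_model):
        pose = CameraPose(WorldPoint(0, 0, 500), pan=0, tilt=30)
        center = WorldPoint(400, 100, 100)
        box = project_sphere(pose, default_model, BoundingSphere(center, 0.0))
        u, v = camera_to_image(default_model, world_to_camera(pose, center))
        assert (box.x_min, box.x_max) == (u, u)
        assert (box.y_min, box.y_max) == (v, v)

    def test_half_fov_sphere_spans_full_image_axis(self, default_model):
        # a sphere on the optical axis subtending the horizontal half-FOV
        half_h = math.radians(default_model.fov_horizontal_deg / 2)
        D = 1000.0
        pose = CameraPose(WorldPoint(0, 0, 0), pan=0, tilt=0)
        box = project_sphere(pose, default_model, BoundingSphere(WorldPoint(D, 0, 0), D * math.sin(half_h)))
        assert box.x_min == 0.0 and box.x_max == 1.0

    def test_camera_inside_sphere_raises(self, default_model):
        pose = CameraPose(WorldPoint(0, 0, 0))
        with pytest.raises(CameraInsideSphereError):
            project_sphere(pose, default_model, BoundingSphere(WorldPoint(50, 0, 0), 80.0))

    def test_center_behind_camera_raises(self, default_model):
        pose = CameraPose(WorldPoint(0, 0, 0), pan=0, tilt=0)
        with pytest.raises(PointBehindCameraError):
            project_sphere(pose, default_model, BoundingSphere(WorldPoint(-500, 0, 0), 10.0))

    def test_dense_surface_sampling_contained_and_tight(self, default_model, rng):
        """10^4 surface-point projections per sphere stay inside the box;
        the box is tight to within 1% of the image width."""
        checked = 0
        while checked < 100:
            pose = random_visible_pose(rng)
            sphere = BoundingSphere(
                WorldPoint(rng.uniform(200, 900), rng.uniform(150, 650), 0.0),
                rng.uniform(20, 120),
            )
            try:
                box = project_sphere(pose, default_model, sphere)
            except GeometryError:
                continue
            if box is None:
                continue
            checked += 1
            th = np.arccos(rng.uniform(-1, 1, 10_000))
            ph = rng.uniform(0, 2 * np.pi, 10_000)
            pts = sphere.center.as_array() + sphere.radius * np.stack(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)], axis=1
            )
            R = pose.rotation_world_to_camera()
            q = (pts - pose.position.as_array()) @ R.T
            vis = q[:, 0] > 0
            f = default_model.focal_px
            u = 0.5 + f * (-q[vis, 1] / q[vis, 0]) / default_model.width
            v = 0.5 + f * (-q[vis, 2] / q[vis, 0]) / default_model.height
            uc, vc = np.clip(u, 0, 1), np.clip(v, 0, 1)
            assert (uc >= box.x_min - 1e-12).all() and (uc <= box.x_max + 1e-12).all()
            assert (vc >= box.y_min - 1e-12).all() and (vc <= box.y_max + 1e-12).all()
            for lo, hi, blo, bhi in ((u, u, box.x_min, box.x_max), (v, v, box.y_min, box.y_max)):
                assert abs(np.clip(lo.min(), 0, 1) - blo) < 0.01
                assert abs(np.clip(hi.max(), 0, 1) - bhi) < 0.01


class TestImageToGround:
    def test_nadir_center_pixel_lands_below_camera(self, default_model):
        pose = CameraPose(WorldPoint(300, 400, 555), pan=77, tilt=90)
        p = image_to_ground(pose, default_model, 0.5, 0.5, ground_z=0.0)
        assert (p.x, p.y, p.z) == pytest.approx((300, 400, 0), abs=1e-9)

    def test_round_trip_identity_on_ground_plane(self, default_model, rng):
        done = 0
        while done < 1000:
            pose = random_visible_pose(rng)
            g = WorldPoint(rng.uniform(0, 1150), rng.uniform(0, 840), 0.0)
            q = world_to_camera(pose, g)
            if q.x_f <= 1e-6:
                continue
            u, v = camera_to_image(default_model, q)
            p = image_to_ground(pose, default_model, u, v, 0.0)
            assert abs(p.x - g.x) < 1e-6 and abs(p.y - g.y) < 1e-6
            done += 1

    def test_oblique_corner_pixel_matches_ray_marching_oracle(self, default_model):
        pose = CameraPose(WorldPoint(575, 420, 600), pan=211, tilt=48)
        u, v = 0.999, 0.999
        p = image_to_ground(pose, default_model, u, v, ground_z=0.0)
        # independent oracle: bisection on the ray's z coordinate
        f = default_model.focal_px
        d_cam = np.array(
            [1.0, -(u - 0.5) * default_model.width / f, -(v - 0.5) * default_model.height / f]
        )
        d_world = pose.rotation_world_to_camera().T @ d_cam
        lo, hi = 0.0, 1e7
        origin = pose.position.as_array()
        for _ in range(200):
            mid = (lo + hi) / 2
            if (origin + mid * d_world)[2] > 0.0:
                lo = mid
            else:
                hi = mid
        expected = origin + ((lo + hi) / 2) * d_world
        assert (p.x, p.y) == pytest.approx((expected[0], expected[1]), abs=1e-4)

    def test_ray_missing_plane_raises(self, default_model):
        looking_up = CameraPose(WorldPoint(100, 100, 500), pan=0, tilt=-45)
        with pytest.raises(NoGroundIntersectionError):
            image_to_ground(looking_up, default_model, 0.5, 0.5, ground_z=0.0)
        level = CameraPose(WorldPoint(100, 100, 500), pan=0, tilt=0)
        with pytest.raises(NoGroundIntersectionError):
            image_to_ground(level, default_model, 0.5, 0.5, ground_z=0.0)


class TestPoseSets:
    def test_single_pose_aims_through_target(self):
        target = WorldPoint(575, 420, 0)
        poses = generate_pose_set(target, "interior", [(450.0, 200.0, 1)])
        assert len(poses) == 1
        q = world_to_camera(poses[0], target)
        assert abs(q.y_f) < 1e-6 and abs(q.z_f) < 1e-6
        assert q.x_f > 0

    def test_edge_class_restricted_to_inward_half_range(self):
        target = WorldPoint(460, 0, 0)  # on the y=0 boundary
        poses = generate_pose_set(target, "edge", [(450.0, 150.0, 12)])
        for pose in poses:
            az = math.degrees(
                math.atan2(pose.position.y - target.y, pose.position.x - target.x)
            )
            assert 0.0 < az < 180.0  # the half facing into the volume

    def test_counts_sum_without_volume_clipping(self):
        target = WorldPoint(575, 420, 0)
        rings = [(400.0, 120.0, 5), (550.0, 100.0, 3)]
        poses = generate_pose_set(target, "interior", rings)
        assert len(poses) == 8

    def test_all_returned_positions_inside_volume(self):
        vol = TravelVolume()
        target = WorldPoint(100, 100, 0)
        poses = generate_pose_set(target, "interior", [(450.0, 300.0, 16)], vol)
        assert 0 < len(poses) < 16  # some candidates clipped
        for pose in poses:
            assert pose.position.in_volume(vol)

    def test_empty_result_raises(self):
        with pytest.raises(EmptyPoseSetError):
            generate_pose_set(WorldPoint(575, 420, 0), "interior", [(450.0, 5000.0, 8)])

    def test_unknown_class_rejected(self):
        with pytest.raises(GeometryError):
            generate_pose_set(WorldPoint(575, 420, 0), "corner", [(450.0, 100.0, 1)])


def test_margin_exclusion_drops_touching_boxes():
    inner = ImageBox(0.2, 0.4, 0.3, 0.5)
    touching = ImageBox(0.01, 0.3, 0.3, 0.5)
    kept = filter_margin([inner, touching, None], margin=0.05)
    assert kept == [inner, None, None]
    assert filter_margin([touching], margin=0.0) == [touching]


def test_aim_at_own_position_rejected():
    p = WorldPoint(1, 2, 3)
    with pytest.raises(GeometryError):
        aim_at(p, p)
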