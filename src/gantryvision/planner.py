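"""Route planning and motion timing for the gantry head.

Speeds follow the stepper-drive chain: v = p_r * d * s * r * m, where p_r is
the pulse rate, d = 105 mm of travel per actuator revolution, s = 1.8/360
revolution per motor step, r = 0.2 gearbox reduction, and m the stepping-mode
factor (1 full-step, 0.5 half-step) — 0.105 mm per pulse at defaults.

Visiting order uses a nested zig-zag: the travel volume is cut into slabs
along x, each slab into columns along y; slabs are walked in +x order,
columns serpentine in y (direction alternating per slab), and positions
within a column ordered by z with the direction alternating between
consecutive columns, starting ascending in the column containing the origin.
This keeps successive hops short without solving a traveling-salesman
problem.  Pan/tilt moves run in parallel with xyz travel and are faster, so
they are neglected in timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .geometry import CameraPose

__all__ = [
    "MotionProfile",
    "RoutePlan",
    "ProductionLog",
    "axis_speed",
    "plan_zigzag",
    "leg_time",
    "schedule",
    "production_rates",
    "build_route",
]

#: Pause after each move before triggering the camera (vibration settling), s.
DEFAULT_PAUSE_S = 3.0
#: Time the camera needs to capture one image at ISO <= 200 indoors, s.
DEFAULT_IMAGING_S = 2.7


@dataclass(frozen=True)
class MotionProfile:
    """Stepper-drive parameters of one gantry axis.

    ``parallel_axes`` selects whether the three axes move simultaneously
    (leg time = max over axes) or one after another (sum).
    """

    pulse_rate: float = 3000.0
    acceleration: float = 10000.0
    distance_per_rev: float = 105.0
    step_fraction: float = 1.8 / 360.0
    gear_ratio: float = 0.2
    step_mode_factor: float = 0.5
    parallel_axes: bool = False

    def __post_init__(self) -> None:
        if self.pulse_rate < 0:
            raise ValueError("pulse_rate must be >= 0")
        if self.acceleration <= 0:
            raise ValueError("acceleration must be > 0")
        if self.step_mode_factor not in (1.0, 0.5):
            raise ValueError("step_mode_factor must be 1 (full) or 0.5 (half)")

    @property
    def mm_per_pulse(self) -> float:
        return self.distance_per_rev * self.step_fraction * self.gear_ratio * self.step_mode_factor


def axis_speed(profile: MotionProfile) -> float:
    """Steady-state axis speed in mm/s: v = p_r * d * s * r * m."""
    return profile.pulse_rate * profile.mm_per_pulse


def leg_time(distances_mm: Sequence[float], profile: MotionProfile) -> float:
    """Travel time (s) for per-axis distances under a linear accel/decel profile.

    Each axis distance converts to pulses; a move long enough to reach the
    peak pulse rate follows the trapezoidal formula D/p_r + p_r/a, shorter
    moves the triangular formula 2*sqrt(D/a).  The two agree at the regime
    boundary D = p_r^2/a.
    """
    times = []
    for dist in distances_mm:
        if dist < 0:
            raise ValueError("distances must be >= 0")
        if dist == 0.0:
            times.append(0.0)
            continue
        pulses = dist / profile.mm_per_pulse
        if profile.pulse_rate > 0 and pulses >= profile.pulse_rate**2 / profile.acceleration:
            times.append(pulses / profile.pulse_rate + profile.pulse_rate / profile.acceleration)
        else:
            times.append(2.0 * math.sqrt(pulses / profile.acceleration))
    return max(times, default=0.0) if profile.parallel_axes else sum(times)


def plan_zigzag(
    positions: Sequence[CameraPose],
    slab_width: float,
    column_width: float,
) -> list[CameraPose]:
    """Order camera positions by the nested zig-zag traversal.

    The output is always a permutation of the input; ties in z within a
    column are resolved deterministically by (y, x) ascending.
    """
    if slab_width <= 0 or column_width <= 0:
        raise ValueError("slab and column widths must be > 0")
    if not positions:
        return []

    def slab_of(p: CameraPose) -> int:
        return int(p.position.x // slab_width)

    def col_of(p: CameraPose) -> int:
        return int(p.position.y // column_width)

    buckets: dict[tuple[int, int], list[CameraPose]] = {}
    for pose in positions:
        buckets.setdefault((slab_of(pose), col_of(pose)), []).append(pose)

    ordered: list[CameraPose] = []
    ascending = True  # first column starts at the bottom (origin corner)
    slab_ids = sorted({s for s, _ in buckets})
    for slab_rank, s in enumerate(slab_ids):
        cols = sorted({c for s2, c in buckets if s2 == s})
        # serpentine: odd-ranked slabs walk columns in -y
        if slab_rank % 2 == 1:
            cols = cols[::-1]
        for c in cols:
            group = buckets[(s, c)]
            group.sort(key=lambda p: (p.position.z, p.position.y, p.position.x))
            ordered.extend(group if ascending else group[::-1])
            ascending = not ascending
    return ordered


@dataclass
class RoutePlan:
    """An ordered visiting plan with per-leg travel times and capture constants."""

    poses: list[CameraPose] = field(default_factory=list)
    leg_times: list[float] = field(default_factory=list)
    pause_before_trigger: float = DEFAULT_PAUSE_S
    imaging_time: float = DEFAULT_IMAGING_S

    def __post_init__(self) -> None:
        if self.poses and len(self.leg_times) != len(self.poses) - 1:
            raise ValueError("leg count must equal pose count - 1")
        if any(t < 0 for t in self.leg_times):
            raise ValueError("leg times must be >= 0")
        if self.pause_before_trigger < 0 or self.imaging_time < 0:
            raise ValueError("capture time constants must be >= 0")


def build_route(
    poses: Sequence[CameraPose],
    profile: MotionProfile,
    pause_before_trigger: float = DEFAULT_PAUSE_S,
    imaging_time: float = DEFAULT_IMAGING_S,
) -> RoutePlan:
    """Compute per-leg travel times between consecutive poses."""
    legs = []
    for a, b in zip(poses, poses[1:]):
        dists = (
            abs(b.position.x - a.position.x),
            abs(b.position.y - a.position.y),
            abs(b.position.z - a.position.z),
        )
        legs.append(leg_time(dists, profile))
    return RoutePlan(
        poses=list(poses),
        leg_times=legs,
        pause_before_trigger=pause_before_trigger,
        imaging_time=imaging_time,
    )


def schedule(route: RoutePlan) -> float:
    """Total run time (s): travel legs plus per-pose settling pause and capture."""
    per_pose = route.pause_before_trigger + route.imaging_time
    return sum(route.leg_times) + per_pose * len(route.poses)


@dataclass(frozen=True)
class ProductionLog:
    """Timings and counts of one production run.

    t_p: total imaging time including robot movement (s); t_d: bulk download
    time (s); t_c: subimage cropping time (s); n_master / n_sub: image counts.
    """

    t_p: float
    t_d: float
    t_c: float
    n_master: int
    n_sub: int

    def __post_init__(self) -> None:
        if min(self.t_p, self.t_d, self.t_c) < 0:
            raise ValueError("times must be >= 0")
        if self.n_master < 0 or self.n_sub < 0:
            raise ValueError("counts must be >= 0")


def production_rates(log: ProductionLog) -> tuple[float, float]:
    """Average production times (s/image) for master images and subimages.

    t_m = (t_p + t_d) / N_m and t_s = (t_p + t_d + t_c) / N_s.
    """
    if log.n_master <= 0:
        raise ZeroDivisionError("n_master must be > 0")
    if log.n_sub <= 0:
        raise ZeroDivisionError("n_sub must be > 0")
    t_m = (log.t_p + log.t_d) / log.n_master
    t_s = (log.t_p + log.t_d + log.t_c) / log.n_sub
    return t_m, t_s
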