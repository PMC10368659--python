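"""Synthetic hand-marker point clouds from a planar trunk–arm–forearm chain.

The generator emulates sagittal-plane motion-capture trials of a person
seated in a manual wheelchair.  All coordinates are millimetres in the
wheel-axis frame: origin at the rear-wheel axis of rotation, y up, x
positive toward the rear of the chair (the backrest plane sits at
x = +80 mm for the default geometry), so forward reach has negative x.

Four manipulation areas are distinguished by how much of the kinematic
chain is mobilised:

* ``AoC`` (comfort)   — elbow only; the arm hangs parallel to the trunk.
* ``AoA`` (approval)  — elbow and shoulder; trunk rests on the backrest.
* ``AoR`` (risk)      — elbow, shoulder and hip (forward trunk flexion).
* ``AoP`` (propulsion)— the hand follows push arcs on the handrim, an
  annular band about the wheel axis.

Joint angles are sampled quasi-uniformly over the mobilised joint box
(half of the samples on a regular grid that includes the box corners,
half uniformly at random) and mapped through planar forward kinematics;
isotropic Gaussian noise models marker/detection jitter.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError

__all__ = [
    "AreaKind",
    "KinematicChain",
    "SubjectSpec",
    "PointCloud",
    "simulate_trial",
    "simulate_propulsion",
    "make_cohort",
    "default_chain",
    "analytic_forward_extent",
]

# 50th-percentile targets: arm + forearm reach 753 mm, forearm 441 mm.
P50_FOREARM_MM = 441.0
P50_ARM_MM = 312.0
P50_TRUNK_MM = 540.0


class AreaKind(str, enum.Enum):
    """The four reach areas, ordered by the length of the mobilised chain."""

    AoP = "AoP"
    AoC = "AoC"
    AoA = "AoA"
    AoR = "AoR"

    @classmethod
    def coerce(cls, value: "AreaKind | str") -> "AreaKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError as exc:
            raise ConfigError(f"unknown area kind: {value!r}") from exc


@dataclass(frozen=True)
class KinematicChain:
    """Planar trunk–arm–forearm chain anchored at the hip.

    Angle conventions: the trunk tilt is measured from the vertical,
    positive toward the front of the chair (-x).  At rest the trunk leans
    on the backrest, i.e. tilts ``backrest_angle`` degrees backward.
    Shoulder flexion is measured relative to the trunk axis (0 = arm
    hanging along the trunk, positive = forward raise) and elbow flexion
    relative to the arm (0 = straight).
    """

    trunk_length: float = P50_TRUNK_MM
    arm_length: float = P50_ARM_MM
    forearm_length: float = P50_FOREARM_MM
    hip_pivot: tuple[float, float] = (50.0, 190.0)
    backrest_angle: float = 4.0
    shoulder_offset: float | None = None
    joint_limits: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hip": (0.0, 40.0),
            "shoulder": (-30.0, 170.0),
            "elbow": (0.0, 150.0),
        }
    )

    def __post_init__(self) -> None:
        for name in ("trunk_length", "arm_length", "forearm_length"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        for joint in ("hip", "shoulder", "elbow"):
            lo, hi = self.joint_limits[joint]
            if not lo < hi:
                raise ConfigError(f"empty joint interval for {joint!r}")

    @property
    def trunk_offset(self) -> float:
        return self.trunk_length if self.shoulder_offset is None else self.shoulder_offset

    def rest_tilt(self) -> float:
        """Trunk tilt (deg, forward positive) with the trunk on the backrest."""
        return -self.backrest_angle

    def shoulder_position(self, trunk_tilt_deg: float) -> np.ndarray:
        t = math.radians(trunk_tilt_deg)
        up = np.array([-math.sin(t), math.cos(t)])
        return np.asarray(self.hip_pivot, dtype=float) + self.trunk_offset * up

    def hand_position(
        self,
        trunk_tilt_deg: np.ndarray,
        shoulder_deg: np.ndarray,
        elbow_deg: np.ndarray,
    ) -> np.ndarray:
        """Vectorised forward kinematics; returns (n, 2) hand positions."""
        tau = np.radians(np.asarray(trunk_tilt_deg, dtype=float))
        sig = np.radians(np.asarray(shoulder_deg, dtype=float))
        eps = np.radians(np.asarray(elbow_deg, dtype=float))
        tau, sig, eps = np.broadcast_arrays(tau, sig, eps)

        hip = np.asarray(self.hip_pivot, dtype=float)
        shoulder = hip + self.trunk_offset * np.stack([-np.sin(tau), np.cos(tau)], axis=-1)
        # absolute segment angles from straight-down, forward (-x) positive
        psi_arm = sig - tau
        psi_fore = psi_arm + eps
        elbow = shoulder + self.arm_length * np.stack(
            [-np.sin(psi_arm), -np.cos(psi_arm)], axis=-1
        )
        return elbow + self.forearm_length * np.stack(
            [-np.sin(psi_fore), -np.cos(psi_fore)], axis=-1
        )

    def elbow_rest_position(self) -> np.ndarray:
        """Elbow pivot with the arm hanging along the trunk (AoC posture)."""
        tau = math.radians(self.rest_tilt())
        shoulder = self.shoulder_position(self.rest_tilt())
        psi = -tau  # arm along trunk: absolute angle equals -tilt
        return shoulder + self.arm_length * np.array([-math.sin(psi), -math.cos(psi)])


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: a chain, a noise level and a private seed."""

    subject_id: str
    chain: KinematicChain
    noise_sd: float = 5.0
    seed: int = 0


@dataclass
class PointCloud:
    """Hand-marker samples of one trial, wheel-axis frame, millimetres."""

    points: np.ndarray
    subject_id: str = ""
    trial_id: str = ""
    area: AreaKind | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ConfigError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ConfigError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def _joint_box(chain: KinematicChain, area: AreaKind) -> dict[str, tuple[float, float]]:
    lims = chain.joint_limits
    rest = chain.rest_tilt()
    if area is AreaKind.AoC:
        return {"elbow": lims["elbow"]}
    if area is AreaKind.AoA:
        return {"shoulder": lims["shoulder"], "elbow": lims["elbow"]}
    if area is AreaKind.AoR:
        lo, hi = lims["hip"]
        return {
            "hip": (rest + lo, rest + hi),
            "shoulder": lims["shoulder"],
            "elbow": lims["elbow"],
        }
    raise ConfigError(f"area {area} has no quasi-static joint box (use simulate_propulsion)")


def _quasi_uniform_box(
    box: dict[str, tuple[float, float]], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Half regular grid (corners included), half uniform random."""
    names = list(box)
    d = len(names)
    m = max(2, int(math.floor((n / 2) ** (1.0 / d))))
    axes = [np.linspace(box[k][0], box[k][1], m) for k in names]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=-1)
    n_rand = n - len(grid)
    if n_rand < 0:
        grid = grid[:n]
        n_rand = 0
    rand = np.column_stack(
        [rng.uniform(box[k][0], box[k][1], size=n_rand) for k in names]
    )
    full = np.vstack([grid, rand]) if n_rand else grid
    return {k: full[:, i] for i, k in enumerate(names)}


def simulate_trial(
    subject: SubjectSpec,
    area: AreaKind | str,
    n_samples: int = 600,
    seed: int | None = None,
) -> PointCloud:
    """Simulate one quasi-static manipulation trial for one area.

    Mobilised joints are sampled quasi-uniformly over their limit box and
    mapped through forward kinematics; Gaussian noise of sd
    ``subject.noise_sd`` is added to both coordinates.  Deterministic for
    a fixed ``seed`` (defaults to ``subject.seed``).
    """
    area = AreaKind.coerce(area)
    if area is AreaKind.AoP:
        raise ConfigError("AoP is a propulsion trajectory; use simulate_propulsion")
    if n_samples < 50:
        raise ConfigError("n_samples must be >= 50")
    chain = subject.chain
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    box = _joint_box(chain, area)
    angles = _quasi_uniform_box(box, n_samples, rng)
    rest = chain.rest_tilt()
    tau = angles.get("hip", np.full(n_samples, rest))
    sig = angles.get("shoulder", np.zeros(n_samples))
    eps = angles["elbow"]
    pts = chain.hand_position(tau, sig, eps)
    if subject.noise_sd > 0:
        pts = pts + rng.normal(0.0, subject.noise_sd, size=pts.shape)
    return PointCloud(pts, subject_id=subject.subject_id, area=area)


def simulate_propulsion(
    subject: SubjectSpec,
    handrim_radius: float = 290.0,
    band_width: float = 35.0,
    n_cycles: int = 15,
    seed: int | None = None,
    arc_deg: tuple[float, float] = (-20.0, 75.0),
    points_per_cycle: int = 40,
) -> PointCloud:
    """Simulate hand positions over repeated push-recovery cycles.

    Points lie in the annular band ``handrim_radius ± band_width`` about
    the wheel axis, on the upper-forward arc typical of push propulsion.
    ``arc_deg`` measures from the top of the wheel, positive toward the
    front of the chair.
    """
    if handrim_radius <= 0 or band_width <= 0:
        raise ConfigError("handrim_radius and band_width must be > 0")
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    lo, hi = (math.radians(a) for a in arc_deg)
    clouds = []
    for _ in range(n_cycles):
        start = rng.uniform(lo, lo + 0.15 * (hi - lo))
        stop = rng.uniform(hi - 0.15 * (hi - lo), hi)
        phi = np.linspace(start, stop, points_per_cycle)
        # smooth radial wander confined to the band
        offs = band_width * np.clip(
            rng.uniform(-0.9, 0.9)
            + 0.3 * np.sin(phi * rng.uniform(1.0, 3.0) + rng.uniform(0, 2 * np.pi)),
            -1.0,
            1.0,
        )
        r = handrim_radius + offs
        clouds.append(np.column_stack([-r * np.sin(phi), r * np.cos(phi)]))
    pts = np.vstack(clouds)
    if subject.noise_sd > 0:
        noise = rng.normal(0.0, subject.noise_sd, size=pts.shape)
        pts = pts + noise
        # noise must not push samples out of the stated band contract
        rad = np.hypot(pts[:, 0], pts[:, 1])
        scale = np.clip(
            rad, handrim_radius - band_width, handrim_radius + band_width
        ) / np.where(rad > 0, rad, 1.0)
        pts = pts * scale[:, None]
    return PointCloud(pts, subject_id=subject.subject_id, area=AreaKind.AoP)


def default_chain() -> KinematicChain:
    """The 50th-percentile chain used as the cohort centre."""
    return KinematicChain()


def make_cohort(
    n_subjects: int = 10,
    trials_per_subject: int = 3,
    master_seed: int = 0,
    *,
    n_samples: int = 600,
    noise_sd: float = 5.0,
    length_cv: float = 0.02,
    base_chain: KinematicChain | None = None,
    areas: Iterable[AreaKind | str] = tuple(AreaKind),
) -> dict[AreaKind, list[PointCloud]]:
    """Generate a full cohort: one cloud per subject, trial and area.

    Subject segment lengths vary log-normally (coefficient of variation
    ``length_cv``) around the 50th-percentile targets; every trial gets
    its own seed derived from ``master_seed`` so reruns are byte-identical.
    The default 10 subjects x 3 trials yields 30 clouds per area.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ConfigError("n_subjects and trials_per_subject must be >= 1")
    base = base_chain if base_chain is not None else default_chain()
    areas = [AreaKind.coerce(a) for a in areas]
    root = np.random.SeedSequence(master_seed)
    subject_seqs = root.spawn(n_subjects)
    cohort: dict[AreaKind, list[PointCloud]] = {a: [] for a in areas}
    for s_idx, s_seq in enumerate(subject_seqs):
        srng = np.random.default_rng(s_seq)
        if length_cv > 0:
            f = np.exp(srng.normal(0.0, length_cv, size=3))
        else:
            f = np.ones(3)
        chain = dataclasses.replace(
            base,
            trunk_length=base.trunk_length * f[0],
            arm_length=base.arm_length * f[1],
            forearm_length=base.forearm_length * f[2],
            shoulder_offset=None,
        )
        trial_seqs = s_seq.spawn(trials_per_subject * len(areas))
        k = 0
        for t_idx in range(trials_per_subject):
            for area in areas:
                seed = int(trial_seqs[k].generate_state(1, np.uint32)[0] % (2**31))
                k += 1
                subject = SubjectSpec(
                    subject_id=f"S{s_idx:02d}",
                    chain=chain,
                    noise_sd=noise_sd,
                    seed=seed,
                )
                if area is AreaKind.AoP:
                    cloud = simulate_propulsion(subject)
                else:
                    cloud = simulate_trial(subject, area, n_samples=n_samples)
                cloud.trial_id = f"T{t_idx}"
                cohort[area].append(cloud)
    return cohort


def analytic_forward_extent(chain: KinematicChain, area: AreaKind | str) -> float:
    """Most negative reachable x (mm) for a quasi-static area, noise-free.

    For AoC the hand sweeps a circle of radius FA about the resting elbow;
    for AoA the straight arm+forearm sweeps about the shoulder; for AoR the
    shoulder is additionally carried forward by maximal hip flexion.
    Assumes joint limits allow a horizontal forward segment (true for the
    defaults), so the extent is pivot_x minus the mobilised chain length.
    """
    area = AreaKind.coerce(area)
    if area is AreaKind.AoC:
        return float(chain.elbow_rest_position()[0] - chain.forearm_length)
    reach = chain.arm_length + chain.forearm_length
    if area is AreaKind.AoA:
        return float(chain.shoulder_position(chain.rest_tilt())[0] - reach)
    if area is AreaKind.AoR:
        tilt = chain.rest_tilt() + chain.joint_limits["hip"][1]
        return float(chain.shoulder_position(tilt)[0] - reach)
    raise ConfigError("analytic extent is defined for AoC, AoA and AoR only")
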