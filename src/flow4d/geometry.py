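"""Parametric cerebrovascular flow-path geometries and their voxelization.

A geometry is one blood-vessel flow path: an ordered centerline with a
per-point radius, optional saccular aneurysm, and flat end caps cut normal
to the path.  Bifurcating paths carry extra branch paths with a volumetric
flux split.  The bank mixes idealized shapes, procedurally generated
tortuous "patient-like" vessels with aneurysm sacs, and systematic
modifications of the patient-like bases.

Conventions: world coordinates in millimetres, right-handed (x, y, z);
voxel arrays are indexed ``[z, y, x]`` with voxel centers at
``origin + (i + 0.5) * spacing`` and 0-based indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import GridTooLargeError, InvalidOperationError, InvalidParameterError

__all__ = [
    "Cap",
    "Aneurysm",
    "BranchPath",
    "VesselGeometry",
    "VoxelMask",
    "GeometryBankConfig",
    "make_idealized_geometry",
    "make_patientlike_geometry",
    "modify_geometry",
    "build_geometry_bank",
    "voxelize",
    "voxelize_sdf",
]

IDEALIZED_KINDS = ("straight", "bend", "helix", "taper", "bifurcation")
MODIFICATION_KINDS = ("inlet_angle", "diameter_scale", "aneurysm_size", "aneurysm_shape")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Cap:
    """Flat end plane of a flow path: a point on the plane and the outward unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise InvalidParameterError("cap normal must be nonzero")
        self.normal = self.normal / n


@dataclass
class Aneurysm:
    """Spherical sac blended onto the parent tube.

    ``attach_index`` indexes the centerline point the sac hangs off;
    ``offset`` (mm) is the vector from that point to the sac center.
    """

    attach_index: int
    sac_radius: float
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        if self.sac_radius <= 0:
            raise InvalidParameterError("sac radius must be positive")


@dataclass
class BranchPath:
    """Secondary flow path of a bifurcation.

    The branch centerline starts at ``attach_index`` on the parent path and
    carries ``flux_fraction`` of the inlet volumetric flow.
    """

    centerline: np.ndarray
    radius_profile: np.ndarray
    attach_index: int
    flux_fraction: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if np.any(self.radius_profile <= 0):
            raise InvalidParameterError("branch radii must be positive")
        if not 0 < self.flux_fraction < 1:
            raise InvalidParameterError("branch flux fraction must be in (0, 1)")


@dataclass
class VesselGeometry:
    """One vessel flow path (primary centerline plus optional branches/sac)."""

    centerline: np.ndarray          # (N, 3) mm
    radius_profile: np.ndarray      # (N,) mm
    aneurysm: Optional[Aneurysm]
    inlet_cap: Cap
    outlet_caps: list[Cap]
    label: str
    branches: list[BranchPath] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise InvalidParameterError("centerline needs at least two points")
        if self.centerline.shape[0] != self.radius_profile.shape[0]:
            raise InvalidParameterError("radius profile must match centerline length")
        if np.any(~np.isfinite(self.radius_profile)) or np.any(self.radius_profile <= 0):
            raise InvalidParameterError("all radii must be positive")
        diffs = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(diffs <= 0):
            raise InvalidParameterError("degenerate centerline (repeated points)")

    # -- derived helpers ----------------------------------------------------

    def tangents(self) -> np.ndarray:
        """Unit tangents at each centerline point (central differences)."""
        t = np.gradient(self.centerline, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def flux_fraction_profile(self) -> np.ndarray:
        """Fraction of inlet flow carried by the primary path at each point."""
        frac = np.ones(len(self.centerline))
        for b in self.branches:
            frac[b.attach_index + 1:] -= b.flux_fraction
        return frac

    def all_paths(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """All flow paths as (centerline, radii, per-point flux fraction)."""
        paths = [(self.centerline, self.radius_profile, self.flux_fraction_profile())]
        for b in self.branches:
            paths.append((b.centerline, b.radius_profile,
                          np.full(len(b.centerline), b.flux_fraction)))
        return paths

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = [self.centerline]
        margin = float(self.radius_profile.max())
        for b in self.branches:
            pts.append(b.centerline)
            margin = max(margin, float(b.radius_profile.max()))
        if self.aneurysm is not None:
            c = self.centerline[self.aneurysm.attach_index] + self.aneurysm.offset
            pts.append(c[None, :])
            margin = max(margin, float(np.linalg.norm(self.aneurysm.offset))
                         + self.aneurysm.sac_radius)
        pts = np.vstack(pts)
        return pts.min(axis=0) - margin, pts.max(axis=0) + margin

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "label": self.label,
            "centerline": self.centerline.tolist(),
            "radius_profile": self.radius_profile.tolist(),
            "aneurysm": None if self.aneurysm is None else {
                "attach_index": int(self.aneurysm.attach_index),
                "sac_radius": float(self.aneurysm.sac_radius),
                "offset": self.aneurysm.offset.tolist(),
            },
            "inlet_cap": {"point": self.inlet_cap.point.tolist(),
                          "normal": self.inlet_cap.normal.tolist()},
            "outlet_caps": [{"point": c.point.tolist(), "normal": c.normal.tolist()}
                            for c in self.outlet_caps],
            "branches": [{
                "centerline": b.centerline.tolist(),
                "radius_profile": b.radius_profile.tolist(),
                "attach_index": int(b.attach_index),
                "flux_fraction": float(b.flux_fraction),
            } for b in self.branches],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "VesselGeometry":
        d = json.loads(s)
        an = d["aneurysm"]
        return cls(
            centerline=np.array(d["centerline"]),
            radius_profile=np.array(d["radius_profile"]),
            aneurysm=None if an is None else Aneurysm(
                an["attach_index"], an["sac_radius"], np.array(an["offset"])),
            inlet_cap=Cap(np.array(d["inlet_cap"]["point"]),
                          np.array(d["inlet_cap"]["normal"])),
            outlet_caps=[Cap(np.array(c["point"]), np.array(c["normal"]))
                         for c in d["outlet_caps"]],
            label=d["label"],
            branches=[BranchPath(np.array(b["centerline"]),
                                 np.array(b["radius_profile"]),
                                 b["attach_index"], b["flux_fraction"])
                      for b in d["branches"]],
        )


@dataclass
class VoxelMask:
    """Voxelized vessel lumen with cut-cell style partial-volume fractions."""

    shape: tuple[int, int, int]          # (nz, ny, nx)
    spacing: float                       # mm, isotropic
    origin: np.ndarray                   # mm, corner of voxel (0,0,0)
    fraction: np.ndarray                 # [z,y,x] in [0,1]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        f = self.fraction
        if f.min() < 0 or f.max() > 1:
            raise InvalidParameterError("mask fractions must lie in [0, 1]")

    @property
    def binary(self) -> np.ndarray:
        return self.fraction >= 0.5

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World (x, y, z) mm of voxel centers for (z, y, x) index rows."""
        zyx = (np.asarray(indices, dtype=float) + 0.5) * self.spacing
        return zyx[:, ::-1] + self.origin


# ---------------------------------------------------------------------------
# idealized geometries
# ---------------------------------------------------------------------------

def _caps_from_path(centerline: np.ndarray) -> tuple[Cap, Cap]:
    t0 = centerline[1] - centerline[0]
    t1 = centerline[-1] - centerline[-2]
    return Cap(centerline[0], -t0), Cap(centerline[-1], t1)


def _check_diameter(d: float) -> None:
    if not np.isfinite(d) or d <= 0:
        raise InvalidParameterError(f"diameter must be positive, got {d}")
    if not 1.0 <= d <= 8.0:
        raise InvalidParameterError(f"diameter {d} mm outside the supported 1-8 mm range")


def make_idealized_geometry(kind: str, **params) -> VesselGeometry:
    """Construct one of the idealized (aneurysm-free) vessel shapes.

    Supported kinds: ``straight``, ``bend``, ``helix``, ``taper``,
    ``bifurcation``.  Diameters are in mm and must lie in 1-8 mm.
    """
    if kind not in IDEALIZED_KINDS:
        raise InvalidParameterError(f"unknown idealized kind {kind!r}")
    n = int(params.pop("n_points", 81))

    if kind == "straight":
        d = float(params.pop("diameter", 4.0))
        length = float(params.pop("length", 40.0))
        _check_diameter(d)
        if length <= 0:
            raise InvalidParameterError("length must be positive")
        s = np.linspace(0.0, length, n)
        cl = np.column_stack([s, np.zeros(n), np.zeros(n)])
        radii = np.full(n, d / 2.0)

    elif kind == "taper":
        d0 = float(params.pop("diameter_in", 4.0))
        d1 = float(params.pop("diameter_out", 2.0))
        length = float(params.pop("length", 40.0))
        _check_diameter(d0)
        _check_diameter(d1)
        s = np.linspace(0.0, length, n)
        cl = np.column_stack([s, np.zeros(n), np.zeros(n)])
        radii = np.linspace(d0 / 2.0, d1 / 2.0, n)

    elif kind == "bend":
        d = float(params.pop("diameter", 3.0))
        rc = float(params.pop("bend_radius", 12.0))
        angle = float(params.pop("angle_deg", 120.0))
        _check_diameter(d)
        lead = 8.0
        th = np.deg2rad(np.linspace(0.0, angle, n // 2))
        arc = np.column_stack([rc * np.sin(th), rc * (1 - np.cos(th)), np.zeros(len(th))])
        pre = np.column_stack([np.linspace(-lead, 0, n - len(th), endpoint=False),
                               np.zeros(n - len(th)), np.zeros(n - len(th))])
        tang_end = np.array([np.cos(th[-1]), np.sin(th[-1]), 0.0])
        post = arc[-1] + tang_end * np.linspace(0, lead, 12)[1:, None]
        cl = np.vstack([pre, arc, post])
        radii = np.full(len(cl), d / 2.0)

    elif kind == "helix":
        d = float(params.pop("diameter", 3.0))
        rh = float(params.pop("helix_radius", 6.0))
        pitch = float(params.pop("pitch", 12.0))
        turns = float(params.pop("turns", 1.5))
        _check_diameter(d)
        th = np.linspace(0.0, 2 * np.pi * turns, n)
        cl = np.column_stack([pitch * th / (2 * np.pi), rh * np.cos(th), rh * np.sin(th)])
        radii = np.full(n, d / 2.0)

    else:  # bifurcation
        d = float(params.pop("diameter", 4.0))
        db = float(params.pop("branch_diameter", 2.8))
        trunk_len = float(params.pop("trunk_length", 18.0))
        branch_len = float(params.pop("branch_length", 18.0))
        half_angle = np.deg2rad(float(params.pop("half_angle_deg", 32.0)))
        _check_diameter(d)
        _check_diameter(db)
        nt = n // 2
        trunk = np.column_stack([np.linspace(0, trunk_len, nt),
                                 np.zeros(nt), np.zeros(nt)])
        dir_a = np.array([np.cos(half_angle), np.sin(half_angle), 0.0])
        dir_b = np.array([np.cos(half_angle), -np.sin(half_angle), 0.0])
        sb = np.linspace(0, branch_len, n - nt + 1)[1:, None]
        bra = trunk[-1] + dir_a * sb
        brb = trunk[-1] + dir_b * sb
        cl = np.vstack([trunk, bra])
        radii = np.concatenate([np.full(nt, d / 2.0), np.full(len(bra), db / 2.0)])
        branch = BranchPath(
            centerline=np.vstack([trunk[-1][None, :], brb]),
            radius_profile=np.full(len(brb) + 1, db / 2.0),
            attach_index=nt - 1,
            flux_fraction=0.5,
        )
        inlet, outlet_a = _caps_from_path(cl)
        _, outlet_b = _caps_from_path(branch.centerline)
        return VesselGeometry(cl, radii, None, inlet, [outlet_a, outlet_b],
                              label=f"idealized:{kind}", branches=[branch])

    inlet, outlet = _caps_from_path(cl)
    return VesselGeometry(cl, radii, None, inlet, [outlet], label=f"idealized:{kind}")


# ---------------------------------------------------------------------------
# patient-like geometries
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    k = np.hanning(2 * width + 1)
    k /= k.sum()
    return np.apply_along_axis(lambda c: np.convolve(np.pad(c, width, mode="edge"), k,
                                                     mode="valid"), 0, x)


def _self_intersects(cl: np.ndarray, radii: np.ndarray, skip: int = 12) -> bool:
    # non-adjacent centerline points must stay farther apart than the sum of
    # the local radii, otherwise the swept tube folds onto itself
    n = len(cl)
    for i in range(n):
        j = np.arange(i + skip, n)
        if len(j) == 0:
            continue
        dist = np.linalg.norm(cl[j] - cl[i], axis=1)
        if np.any(dist <= radii[j] + radii[i]):
            return True
    return False


def make_patientlike_geometry(seed: int) -> VesselGeometry:
    """Procedural tortuous cerebral-vessel surrogate with one aneurysm sac.

    The centerline is a curvature-bounded smoothed random walk; a spherical
    sac is attached roughly mid-vessel, offset perpendicular to the local
    tangent.  Deterministic for a fixed seed.
    """
    for attempt in range(25):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        n = 64
        step = 0.75  # mm between points
        # random smooth turning: perturb the tangent direction gradually
        dtheta = _smooth(rng.normal(0, 1.0, (n, 2)), 6) * 0.35
        theta = np.cumsum(dtheta[:, 0])          # azimuth drift
        phi = np.cumsum(dtheta[:, 1]) * 0.6      # elevation drift
        tangents = np.column_stack([np.cos(theta) * np.cos(phi),
                                    np.sin(theta) * np.cos(phi),
                                    np.sin(phi)])
        cl = np.vstack([[0, 0, 0], np.cumsum(tangents * step, axis=0)])
        r0 = rng.uniform(1.15, 1.4)
        radii = r0 * (1 + 0.1 * np.sin(np.linspace(0, rng.uniform(2, 5), n + 1)
                                       + rng.uniform(0, 2 * np.pi)))
        if _self_intersects(cl, radii):
            continue
        idx = int(rng.integers(n // 3, 2 * n // 3))
        t = cl[idx + 1] - cl[idx - 1]
        t /= np.linalg.norm(t)
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        perp = np.cross(t, ref)
        perp /= np.linalg.norm(perp)
        ang = rng.uniform(0, 2 * np.pi)
        perp = perp * np.cos(ang) + np.cross(t, perp) * np.sin(ang)
        sac_radius = rng.uniform(1.8, 3.0)
        offset = perp * (radii[idx] + 0.55 * sac_radius)
        inlet, outlet = _caps_from_path(cl)
        return VesselGeometry(cl, radii, Aneurysm(idx, sac_radius, offset),
                              inlet, [outlet], label=f"patient_like:{seed}")
    raise InvalidParameterError(f"could not build a non-self-intersecting vessel for seed {seed}")


# ---------------------------------------------------------------------------
# modifications
# ---------------------------------------------------------------------------

def modify_geometry(base: VesselGeometry, modification: str, magnitude: float) -> VesselGeometry:
    """Return a copy of ``base`` altered in exactly one named attribute.

    ``inlet_angle`` tilts the inlet segment by ``magnitude`` degrees;
    ``diameter_scale`` multiplies all vessel radii; ``aneurysm_size`` scales
    the sac radius; ``aneurysm_shape`` scales the sac offset (stretching or
    sinking the blended sac).  The label records provenance.
    """
    if modification not in MODIFICATION_KINDS:
        raise InvalidParameterError(f"unknown modification {modification!r}")
    label = f"modified:{base.label}:{modification}:{magnitude:g}"

    if modification in ("aneurysm_size", "aneurysm_shape"):
        if base.aneurysm is None:
            raise InvalidOperationError(
                f"{modification} requires a geometry with an aneurysm sac")
        if magnitude <= 0:
            raise InvalidParameterError("magnitude must be positive")
        if modification == "aneurysm_size":
            an = Aneurysm(base.aneurysm.attach_index,
                          base.aneurysm.sac_radius * magnitude,
                          base.aneurysm.offset.copy())
        else:
            an = Aneurysm(base.aneurysm.attach_index,
                          base.aneurysm.sac_radius,
                          base.aneurysm.offset * magnitude)
        return replace(base, aneurysm=an, label=label)

    if modification == "diameter_scale":
        if magnitude <= 0:
            raise InvalidParameterError("magnitude must be positive")
        branches = [BranchPath(b.centerline.copy(), b.radius_profile * magnitude,
                               b.attach_index, b.flux_fraction) for b in base.branches]
        return replace(base, radius_profile=base.radius_profile * magnitude,
                       branches=branches, label=label)

    # inlet_angle: rotate the proximal quarter of the path about the hinge
    # point with a smooth ramp so the centerline stays C1
    angle = np.deg2rad(magnitude)
    cl = base.centerline.copy()
    k = max(2, len(cl) // 4)
    hinge = cl[k]
    t = cl[k + 1] - cl[k - 1]
    t /= np.linalg.norm(t)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    axis = np.cross(t, ref)
    axis /= np.linalg.norm(axis)
    ramp = np.linspace(1.0, 0.0, k)
    for i in range(k):
        a = angle * ramp[i]
        v = cl[i] - hinge
        cl[i] = hinge + (v * np.cos(a) + np.cross(axis, v) * np.sin(a)
                         + axis * np.dot(axis, v) * (1 - np.cos(a)))
    inlet = Cap(cl[0], cl[0] - cl[1])
    return replace(base, centerline=cl, inlet_cap=inlet, label=label)


# ---------------------------------------------------------------------------
# geometry bank
# ---------------------------------------------------------------------------

@dataclass
class GeometryBankConfig:
    """Counts and seeds for the default training-geometry bank.

    Defaults reproduce the study conditions: 5 idealized shapes, 5
    patient-like aneurysm vessels, and 4 modifications of each patient-like
    base (20 modified models), 30 geometries in total.
    """

    n_idealized: int = 5
    n_patientlike: int = 5
    modifications_per_base: int = 4
    seed: int = 2021


_DEFAULT_MODS: Sequence[tuple[str, float]] = (
    ("inlet_angle", 25.0),
    ("diameter_scale", 0.9),
    ("aneurysm_size", 1.4),
    ("aneurysm_shape", 1.3),
    ("diameter_scale", 1.1),
)


def build_geometry_bank(config: Optional[GeometryBankConfig] = None) -> list[VesselGeometry]:
    """Build the vessel-geometry bank (default: 30 geometries)."""
    cfg = config or GeometryBankConfig()
    bank: list[VesselGeometry] = []
    for kind in IDEALIZED_KINDS[:cfg.n_idealized]:
        bank.append(make_idealized_geometry(kind))
    bases = [make_patientlike_geometry(cfg.seed + i) for i in range(cfg.n_patientlike)]
    bank.extend(bases)
    for base in bases:
        for mod, mag in list(_DEFAULT_MODS)[:cfg.modifications_per_base]:
            bank.append(modify_geometry(base, mod, mag))
    labels = [g.label for g in bank]
    assert len(set(labels)) == len(labels), "bank labels must be unique"
    return bank


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _segment_distance_and_radius(points: np.ndarray, cl: np.ndarray,
                                 radii: np.ndarray) -> np.ndarray:
    """Signed distance of ``points`` to the tube swept along one polyline."""
    best = np.full(len(points), np.inf)
    a = cl[:-1]
    b = cl[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    for s in range(len(a)):
        ap = points - a[s]
        t = np.clip(ap @ ab[s] / ab2[s], 0.0, 1.0)
        closest = a[s] + t[:, None] * ab[s]
        d = np.linalg.norm(points - closest, axis=1)
        r = radii[s] + t * (radii[s + 1] - radii[s])
        np.minimum(best, d - r, out=best)
    return best


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float = 0.8) -> np.ndarray:
    # polynomial smooth-union of two distance fields (blend width k mm)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def geometry_sdf(geometry: VesselGeometry) -> Callable[[np.ndarray], np.ndarray]:
    """Approximate signed distance function (mm) of the vessel lumen."""
    caps = [geometry.inlet_cap] + list(geometry.outlet_caps)

    def sdf(points: np.ndarray) -> np.ndarray:
        d = _segment_distance_and_radius(points, geometry.centerline,
                                         geometry.radius_profile)
        for br in geometry.branches:
            db = _segment_distance_and_radius(points, br.centerline, br.radius_profile)
            d = np.minimum(d, db)
        if geometry.aneurysm is not None:
            an = geometry.aneurysm
            center = geometry.centerline[an.attach_index] + an.offset
            ds = np.linalg.norm(points - center, axis=1) - an.sac_radius
            d = _smooth_min(d, ds)
        for cap in caps:  # trim flat at the cut planes
            d = np.maximum(d, (points - cap.point) @ cap.normal)
        return d

    return sdf


def voxelize_sdf(sdf: Callable[[np.ndarray], np.ndarray], origin: np.ndarray,
                 shape: tuple[int, int, int], spacing: float,
                 supersample: int = 3) -> VoxelMask:
    """Voxelize any signed distance field into partial-volume fractions.

    Boundary voxels (|sdf| within half a voxel diagonal) are supersampled
    with a stratified jittered ``supersample**3`` sub-grid; interior voxels
    get fraction 1.  The jitter (deterministic per call) decorrelates the
    quadrature error between voxels, which would otherwise stay coherent
    along grid-aligned surfaces and stall volume convergence.
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    nz, ny, nx = shape
    origin = np.asarray(origin, dtype=float)
    zs = origin[2] + (np.arange(nz) + 0.5) * spacing
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    d = sdf(centers).reshape(shape)

    half_diag = spacing * np.sqrt(3) / 2
    fraction = np.where(d <= -half_diag, 1.0, 0.0)
    boundary = np.abs(d) < half_diag
    if boundary.any():
        idx = np.argwhere(boundary)
        base = np.column_stack([xs[idx[:, 2]], ys[idx[:, 1]], zs[idx[:, 0]]])
        cells = np.stack(np.meshgrid(*[np.arange(supersample)] * 3,
                                     indexing="ij"), axis=-1).reshape(-1, 3)
        rng = np.random.default_rng(0x766F78)
        n_sub = supersample ** 3
        frac = np.zeros(len(idx))
        jitter = rng.random((len(idx), n_sub, 3))
        sub = ((cells[None, :, :] + jitter) / supersample - 0.5) * spacing
        for k in range(n_sub):
            frac += (sdf(base + sub[:, k, :]) < 0)
        fraction[boundary.nonzero()] = frac / n_sub
    return VoxelMask(shape=tuple(shape), spacing=float(spacing),
                     origin=origin, fraction=fraction.astype(np.float32))


def voxelize(geometry: VesselGeometry, spacing: float, padding: int = 2,
             max_extent: int = 256, min_shape: Optional[int] = None) -> VoxelMask:
    """Voxelize a vessel geometry on an isotropic grid enclosing it.

    ``min_shape`` pads the grid symmetrically to at least that many voxels
    per axis (useful when downstream block operations need a minimum
    volume).  Raises ``GridTooLargeError`` if any grid dimension would
    exceed ``max_extent`` voxels.
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    lo, hi = geometry.bounding_box()
    origin = lo - padding * spacing
    extent = hi + padding * spacing - origin
    shape_xyz = np.ceil(extent / spacing).astype(int)
    if min_shape is not None:
        grow = np.maximum(min_shape - shape_xyz, 0)
        origin = origin - (grow // 2) * spacing
        shape_xyz = np.maximum(shape_xyz, min_shape)
    if np.any(shape_xyz > max_extent):
        raise GridTooLargeError(
            f"grid {tuple(shape_xyz)} exceeds max extent {max_extent}")
    shape = (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0]))
    return voxelize_sdf(geometry_sdf(geometry), origin, shape, spacing)


def fine_spacing(geometry: VesselGeometry, ratio: float = 0.05) -> float:
    """Grid spacing satisfying the cell-to-diameter refinement policy.

    Returns ``ratio`` times the smallest vessel diameter, the resolution at
    which tube flow profiles are effectively grid-independent.
    """
    dmin = 2.0 * float(geometry.radius_profile.min())
    for b in geometry.branches:
        dmin = min(dmin, 2.0 * float(b.radius_profile.min()))
    return ratio * dmin
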