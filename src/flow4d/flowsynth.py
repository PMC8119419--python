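"""Time-resolved, divergence-free ground-truth velocity fields.

This module stands in for a finite-volume CFD stage: it sweeps analytic
Womersley/Poiseuille tube profiles along each vessel flow path, scales them
to the instantaneous inlet flow rate, and then enforces numerical mass
conservation with an exact discrete divergence-free projection on the
masked voxel grid.  The result is a physically plausible, continuity-
satisfying pulsatile velocity field suitable as neural-network ground
truth; it is not a Navier-Stokes solution (no convective acceleration, no
secondary flow in bends).

Units: velocity cm/s, lengths mm, flow rate mL/s, time s.  Blood defaults
to density 1060 kg/m^3 and dynamic viscosity 0.004 Ns/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import jv

from .errors import InvalidParameterError
from .geometry import VesselGeometry, VoxelMask, voxelize

__all__ = [
    "BLOOD",
    "InflowProfile",
    "VelocityField",
    "UnstructuredField",
    "make_inflow_profiles",
    "solve_flow",
    "resample_to_cartesian",
    "compute_reynolds",
    "generate_dataset",
    "discrete_divergence",
    "DivergenceProjector",
]

#: Blood properties used throughout (SI units).
BLOOD = {"density": 1060.0, "viscosity": 0.004}

#: Export cadence of the flow solution, seconds.
FRAME_DT = 0.02


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class InflowProfile:
    """Pulsatile volumetric inlet waveform over exactly one period."""

    times: np.ndarray       # s, uniform grid with step FRAME_DT
    flow_rate: np.ndarray   # mL/s at each time point
    period: float           # s
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow_rate = np.asarray(self.flow_rate, dtype=float)
        if self.times.shape != self.flow_rate.shape:
            raise InvalidParameterError("times and flow_rate must align")
        if np.any(self.flow_rate <= 0):
            raise InvalidParameterError("inlet flow must stay positive (no reverse flow)")

    def fourier(self, n_harmonics: int) -> np.ndarray:
        """One-sided complex Fourier coefficients Q_k, k = 0..n_harmonics.

        Q(t) = Re( sum_k Q_k * exp(i * 2*pi*k*t / period) ) with Q_0 real.
        """
        m = len(self.flow_rate)
        c = np.fft.rfft(self.flow_rate) / m
        c[1:] *= 2.0
        out = np.zeros(n_harmonics + 1, dtype=complex)
        k = min(n_harmonics + 1, len(c))
        out[:k] = c[:k]
        return out


@dataclass
class UnstructuredField:
    """Cell-based velocity sample (e.g. an externally computed CFD export)."""

    centroids: np.ndarray   # (M, 3) mm, world (x, y, z)
    volumes: np.ndarray     # (M,) mm^3
    velocities: np.ndarray  # (M, 3) cm/s

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.volumes = np.atleast_1d(np.asarray(self.volumes, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        if len(self.centroids) == 0:
            raise InvalidParameterError("need at least one cell")
        if np.any(self.volumes <= 0):
            raise InvalidParameterError("cell volumes must be positive")


@dataclass
class VelocityField:
    """Cartesian time-resolved 3-component velocity volume.

    ``velocity`` is ``[t, 3, z, y, x]`` in cm/s with component order
    (vx, vy, vz); velocity is zero outside ``mask.binary``.
    """

    velocity: np.ndarray
    spacing: float                  # mm
    frame_dt: float                 # s
    mask: VoxelMask
    fluid: dict = field(default_factory=lambda: dict(BLOOD))
    label: str = ""
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float32)
        if self.velocity.ndim != 5 or self.velocity.shape[1] != 3:
            raise InvalidParameterError("velocity must be [t, 3, z, y, x]")
        if self.velocity.shape[2:] != tuple(self.mask.shape):
            raise InvalidParameterError("velocity and mask shapes differ")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[2:]

    def frame(self, t: int) -> np.ndarray:
        return self.velocity[t]


# ---------------------------------------------------------------------------
# inflow profiles
# ---------------------------------------------------------------------------

def make_inflow_profiles(n: int, seed: int, period: float = 1.0,
                         base_range: tuple[float, float] = (1.8, 2.6),
                         ) -> list[InflowProfile]:
    """Generate ``n`` distinct pulsatile cardiac-like inflow waveforms.

    Each waveform is a truncated Fourier series (3 harmonics) around a base
    flow drawn from ``base_range`` mL/s, with randomized systolic peak
    timing and amplitude.  Harmonic content is damped if needed so the flow
    stays positive and the peak factor stays below ~1.55, which keeps the
    Reynolds numbers of the default geometry bank in the physiological
    100-800 range.
    """
    if n < 1:
        raise InvalidParameterError("need n >= 1 profiles")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x666C6F]))
    times = np.arange(0.0, period - 1e-9, FRAME_DT)
    profiles = []
    for i in range(n):
        base = rng.uniform(*base_range)
        amps = np.array([rng.uniform(0.25, 0.42),
                         rng.uniform(0.10, 0.22),
                         rng.uniform(0.03, 0.10)])
        phases = rng.uniform(0, 2 * np.pi, 3)
        mod = np.zeros_like(times)
        for k in range(3):
            mod += amps[k] * np.cos(2 * np.pi * (k + 1) * times / period - phases[k])
        # damp harmonics so the waveform stays positive and the systolic
        # peak factor is bounded
        hi = mod.max()
        lo = mod.min()
        scale = min(1.0, 0.55 / max(hi, 1e-9), 0.8 / max(-lo, 1e-9))
        q = base * (1.0 + scale * mod)
        profiles.append(InflowProfile(times=times.copy(), flow_rate=q,
                                      period=period, label=f"inflow:{seed}:{i}"))
    return profiles


# ---------------------------------------------------------------------------
# discrete divergence and projection
# ---------------------------------------------------------------------------

def discrete_divergence(velocity: np.ndarray, spacing: float) -> np.ndarray:
    """Wide central-difference divergence, 1/s (velocity cm/s, spacing mm).

    Equivalent to net face flux per voxel with face values taken as the
    average of the two adjacent voxel values; field treated as zero outside
    the grid.
    """
    v = np.asarray(velocity, dtype=np.float64)
    div = np.zeros(v.shape[1:])
    for comp, axis in ((0, 2), (1, 1), (2, 0)):  # vx ~ x-axis (last), etc.
        plus = np.zeros_like(div)
        minus = np.zeros_like(div)
        src = v[comp]
        sl_fwd = [slice(None)] * 3
        sl_fwd[axis] = slice(1, None)
        sl_bwd = [slice(None)] * 3
        sl_bwd[axis] = slice(None, -1)
        plus[tuple(sl_bwd)] = src[tuple(sl_fwd)]
        minus[tuple(sl_fwd)] = src[tuple(sl_bwd)]
        div += (plus - minus) / (2.0 * spacing)
    return div * 10.0  # cm/s per mm -> 1/s


class DivergenceProjector:
    """Minimum-norm correction making a masked field discretely solenoidal.

    The divergence operator is the wide central difference (equivalently,
    two-point-average face fluxes).  Zero divergence is enforced at every
    voxel inside the vessel and in the one-voxel exterior shell, except
    within a buffer around the inlet/outlet cap planes where through-flow
    must enter and leave.  The correction has support only inside the
    vessel, so no-slip (zero exterior velocity) is preserved.  The
    minimum-L2-norm correction is obtained by a direct factorization of
    A A^T, reusable across frames.
    """

    def __init__(self, mask: VoxelMask, geometry: Optional[VesselGeometry] = None,
                 cap_buffer: float = 2.5):
        self.mask = mask
        self.spacing = mask.spacing
        binary = mask.binary
        shape = binary.shape

        # support voxels (columns): inside the vessel
        sup_idx = np.argwhere(binary)
        self._sup_idx = sup_idx
        col_of = -np.ones(shape, dtype=np.int64)
        col_of[tuple(sup_idx.T)] = np.arange(len(sup_idx))

        # enforcement voxels (rows): vessel + one-voxel shell, minus cap buffer
        shell = np.zeros(shape, dtype=bool)
        for axis in range(3):
            shell |= np.roll(binary, 1, axis) | np.roll(binary, -1, axis)
        enforce = shell | binary
        if geometry is not None:
            centers = mask.voxel_centers_mm(np.argwhere(enforce))
            keep = np.ones(len(centers), dtype=bool)
            for cap in [geometry.inlet_cap] + list(geometry.outlet_caps):
                d = (centers - cap.point) @ cap.normal
                keep &= d < -cap_buffer * self.spacing
            e = np.argwhere(enforce)[keep]
            enforce = np.zeros(shape, dtype=bool)
            enforce[tuple(e.T)] = True
        self._enforce = enforce
        row_idx = np.argwhere(enforce)
        self._row_idx = row_idx

        # assemble A: rows = enforcement voxels, cols = 3 * support voxels
        n_sup = len(sup_idx)
        rows, cols, vals = [], [], []
        h = self.spacing
        offsets = {0: np.array([0, 0, 1]), 1: np.array([0, 1, 0]), 2: np.array([1, 0, 0])}
        for comp in range(3):
            off = offsets[comp]
            for sign in (+1, -1):
                nb = row_idx + sign * off
                ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
                cidx = np.full(len(nb), -1, dtype=np.int64)
                cidx[ok] = col_of[tuple(nb[ok].T)]
                sel = cidx >= 0
                rows.append(np.nonzero(sel)[0])
                cols.append(cidx[sel] + comp * n_sup)
                vals.append(np.full(sel.sum(), sign / (2.0 * h)))
        A = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(len(row_idx), 3 * n_sup))
        # drop all-zero rows (enforcement voxels decoupled from the support)
        nz = np.diff(A.indptr) > 0
        A = A[nz]
        self._row_idx = row_idx[nz]
        self.A = A
        M = (A @ A.T).tocsc()
        eps = 1e-12 * M.diagonal().mean()
        self._lu = splu(M + eps * sp.eye(M.shape[0], format="csc"))

    def project(self, velocity: np.ndarray) -> np.ndarray:
        """Return the projected copy of one frame ``[3, z, y, x]``."""
        v = np.asarray(velocity, dtype=np.float64).copy()
        zyx = tuple(self._sup_idx.T)
        u = np.concatenate([v[c][zyx] for c in range(3)])
        r = self.A @ u
        du = np.zeros_like(u)
        for _ in range(2):  # direct solve + one refinement pass
            y = self._lu.solve(r)
            step = self.A.T @ y
            du -= step
            r = r - self.A @ step
        u = u + du
        n = len(self._sup_idx)
        for c in range(3):
            v[c][zyx] = u[c * n:(c + 1) * n]
        return v


# ---------------------------------------------------------------------------
# swept-profile tube flow
# ---------------------------------------------------------------------------

class _PathAssignment:
    """Per-voxel nearest flow path data: tangent, radial coord, radius, flux."""

    def __init__(self, geometry: VesselGeometry, mask: VoxelMask):
        idx = np.argwhere(mask.binary)
        pts = mask.voxel_centers_mm(idx)
        n = len(pts)
        best = np.full(n, np.inf)
        tangent = np.zeros((n, 3))
        radius = np.ones(n)
        rad_dist = np.full(n, np.inf)
        frac = np.zeros(n)
        for cl, radii, fr in geometry.all_paths():
            a, b = cl[:-1], cl[1:]
            ab = b - a
            ab2 = np.einsum("ij,ij->i", ab, ab)
            for s in range(len(a)):
                ap = pts - a[s]
                t = np.clip(ap @ ab[s] / ab2[s], 0.0, 1.0)
                closest = a[s] + t[:, None] * ab[s]
                d = np.linalg.norm(pts - closest, axis=1)
                r = radii[s] + t * (radii[s + 1] - radii[s])
                upd = d - r < best
                if upd.any():
                    best[upd] = (d - r)[upd]
                    tangent[upd] = ab[s] / np.sqrt(ab2[s])
                    radius[upd] = r[upd]
                    rad_dist[upd] = d[upd]
                    frac[upd] = fr[min(s, len(fr) - 1)]
        self.indices = idx
        self.tangent = tangent
        self.radius = radius
        self.y = np.clip(rad_dist / radius, 0.0, 1.0)   # normalized radial coord
        self.flux_fraction = frac
        self.inside_tube = rad_dist < radius            # sac voxels excluded


def _womersley_shapes(y: np.ndarray, radius_mm: np.ndarray, period: float,
                      fluid: dict, n_harmonics: int) -> np.ndarray:
    """Flux-normalized radial profile g_k(y) per harmonic, shape (K+1, n).

    g_0 is parabolic Poiseuille; for k >= 1 the rigid-tube Womersley
    solution is used, degrading to quasi-steady Poiseuille when the
    Womersley number alpha_k < 1.
    """
    nu = fluid["viscosity"] / fluid["density"]  # m^2/s
    omega = 2 * np.pi / period
    R = radius_mm * 1e-3
    out = np.empty((n_harmonics + 1, len(y)), dtype=complex)
    poiseuille = 2.0 * (1.0 - y ** 2)
    out[0] = poiseuille
    for k in range(1, n_harmonics + 1):
        alpha = R * np.sqrt(k * omega / nu)
        beta = alpha * np.exp(1j * 3 * np.pi / 4)  # i^{3/2} * alpha
        g = np.empty(len(y), dtype=complex)
        unsteady = alpha >= 1.0
        if unsteady.any():
            b = beta[unsteady]
            j0b = jv(0, b)
            flux = 1.0 - 2.0 * jv(1, b) / (b * j0b)
            g[unsteady] = (1.0 - jv(0, b * y[unsteady]) / j0b) / flux
        g[~unsteady] = poiseuille[~unsteady]
        out[k] = g
    return out


class FlowSolver:
    """Reusable per-(geometry, spacing) flow context.

    Voxelization, path assignment, Womersley radial shapes and the
    divergence projector are computed once and shared across inflow
    profiles and frames.
    """

    N_HARMONICS = 4

    def __init__(self, geometry: VesselGeometry, spacing: float,
                 max_extent: int = 256, project: bool = True,
                 fluid: Optional[dict] = None, min_shape: Optional[int] = None):
        self.geometry = geometry
        self.spacing = float(spacing)
        self.fluid = dict(fluid or BLOOD)
        self.mask = voxelize(geometry, spacing, max_extent=max_extent,
                             min_shape=min_shape)
        self.assign = _PathAssignment(geometry, self.mask)
        self.projector = DivergenceProjector(self.mask, geometry) if project else None
        self._shape_cache: dict[float, np.ndarray] = {}
        self._flux_plane = self._pick_flux_plane()

    # -- reference plane for flux rescaling ---------------------------------

    def _pick_flux_plane(self) -> tuple[int, int]:
        g = self.geometry
        direction = g.outlet_caps[0].point - g.inlet_cap.point
        axis_xyz = int(np.argmax(np.abs(direction)))            # 0=x,1=y,2=z
        axis = 2 - axis_xyz                                     # array axis
        ref = g.centerline[len(g.centerline) // 3]
        k = int((ref[axis_xyz] - self.mask.origin[axis_xyz]) / self.spacing - 0.5)
        k = int(np.clip(k, 1, self.mask.shape[axis] - 3))
        return axis, k

    def plane_flux(self, frame: np.ndarray) -> float:
        """Through-flow (mL/s) across the reference full-grid voxel plane."""
        axis, k = self._flux_plane
        comp = 2 - axis
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[axis] = k
        sl1[axis] = k + 1
        face = 0.5 * (frame[comp][tuple(sl0)] + frame[comp][tuple(sl1)])
        return float(face.sum()) * self.spacing ** 2 * 0.01  # cm/s*mm^2 -> mL/s

    # -- frame synthesis -----------------------------------------------------

    def _shapes(self, period: float) -> np.ndarray:
        if period not in self._shape_cache:
            self._shape_cache[period] = _womersley_shapes(
                self.assign.y, self.assign.radius, period, self.fluid,
                self.N_HARMONICS)
        return self._shape_cache[period]

    def solve(self, profile: InflowProfile, n_frames: Optional[int] = None,
              label: str = "") -> VelocityField:
        a = self.assign
        g = self._shapes(profile.period)
        qk = profile.fourier(self.N_HARMONICS)
        if n_frames is None or n_frames >= len(profile.times):
            t_idx = np.arange(len(profile.times))
        else:
            t_idx = np.linspace(0, len(profile.times) - 1, n_frames).astype(int)
        times = profile.times[t_idx]
        dt = times[1] - times[0] if len(times) > 1 else FRAME_DT

        area_cm2 = np.pi * (a.radius / 10.0) ** 2
        omega = 2 * np.pi / profile.period
        shape = self.mask.shape
        frames = np.zeros((len(t_idx), 3) + tuple(shape), dtype=np.float32)
        zyx = tuple(a.indices.T)
        for fi, t in enumerate(times):
            phase = np.exp(1j * omega * np.arange(self.N_HARMONICS + 1) * t)
            u_axial = np.real(np.einsum("k,kn->n", qk * phase, g))
            u_axial = u_axial * a.flux_fraction / area_cm2
            u_axial[~a.inside_tube] = 0.0
            vel = u_axial[:, None] * a.tangent   # cm/s, (vx,vy,vz)
            frame = np.zeros((3,) + tuple(shape))
            for c in range(3):
                frame[c][zyx] = vel[:, c]
            if self.projector is not None:
                frame = self.projector.project(frame)
            q_t = float(np.interp(t, profile.times, profile.flow_rate,
                                  period=profile.period))
            measured = self.plane_flux(frame)
            if abs(measured) > 1e-9 and abs(q_t) > 1e-9:
                frame *= q_t / measured
            frames[fi] = frame
        return VelocityField(velocity=frames, spacing=self.spacing,
                             frame_dt=float(dt), mask=self.mask,
                             fluid=dict(self.fluid), label=label,
                             times=times)


def solve_flow(geometry: VesselGeometry, profile: InflowProfile, spacing: float,
               n_frames: Optional[int] = None, project: bool = True,
               max_extent: int = 256, min_shape: Optional[int] = None) -> VelocityField:
    """Synthesize the pulsatile velocity field for one geometry and inflow.

    Inside the vessel the velocity follows the Womersley/Poiseuille profile
    aligned with the local centerline tangent, scaled so that the through-
    flow at a reference cross-section equals the instantaneous inlet flow
    rate; a discrete divergence-free projection then enforces continuity in
    the vessel interior (cap regions excluded).
    """
    solver = FlowSolver(geometry, spacing, max_extent=max_extent, project=project,
                        min_shape=min_shape)
    return solver.solve(profile, n_frames=n_frames,
                        label=f"{geometry.label}|{profile.label}")


# ---------------------------------------------------------------------------
# Cartesian resampling of unstructured cell data
# ---------------------------------------------------------------------------

def resample_to_cartesian(ufield: UnstructuredField, spacing: float,
                          shape: tuple[int, int, int],
                          origin: Sequence[float] = (0.0, 0.0, 0.0),
                          ) -> VelocityField:
    """Volume-weighted binning of cell velocities onto a Cartesian grid.

    Each voxel velocity is the cell-volume-weighted mean of the cells whose
    centroid falls in it; voxels receiving no cell are zero and excluded
    from the mask.
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    origin = np.asarray(origin, dtype=float)
    ijk = np.floor((ufield.centroids - origin) / spacing).astype(int)[:, ::-1]
    inside = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
    ijk = ijk[inside]
    w = ufield.volumes[inside]
    v = ufield.velocities[inside]
    wsum = np.zeros(shape)
    wv = np.zeros((3,) + tuple(shape))
    flat = np.ravel_multi_index(tuple(ijk.T), shape)
    np.add.at(wsum.ravel(), flat, w)
    for c in range(3):
        np.add.at(wv[c].ravel(), flat, w * v[:, c])
    occupied = wsum > 0
    out = np.zeros((1, 3) + tuple(shape), dtype=np.float32)
    for c in range(3):
        out[0, c][occupied] = wv[c][occupied] / wsum[occupied]
    mask = VoxelMask(shape=tuple(shape), spacing=float(spacing), origin=origin,
                     fraction=occupied.astype(np.float32))
    return VelocityField(velocity=out, spacing=float(spacing), frame_dt=FRAME_DT,
                         mask=mask, label="resampled")


# ---------------------------------------------------------------------------
# Reynolds numbers
# ---------------------------------------------------------------------------

def compute_reynolds(geometry: VesselGeometry, profile: InflowProfile,
                     fluid: Optional[dict] = None) -> dict:
    """Reynolds numbers Re = rho*U*D/mu along every flow path over the cycle.

    U is the instantaneous cross-section mean speed (flux / area) and D the
    local diameter.  Returns the peak over time and position plus the
    per-point maxima.
    """
    fl = dict(fluid or BLOOD)
    rho, mu = fl["density"], fl["viscosity"]
    q = profile.flow_rate  # mL/s == cm^3/s
    per_segment = []
    peak = 0.0
    for cl, radii, frac in geometry.all_paths():
        area_cm2 = np.pi * (radii / 10.0) ** 2
        u_cm_s = np.outer(q, frac / area_cm2)            # (T, N) cm/s
        d_m = 2.0 * radii * 1e-3
        re = rho * (u_cm_s / 100.0) * d_m[None, :] / mu
        seg_max = re.max(axis=0)
        per_segment.append(seg_max)
        peak = max(peak, float(seg_max.max()))
    return {"peak": peak, "per_segment": per_segment}


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(bank: Sequence[VesselGeometry],
                     profiles: Sequence[InflowProfile],
                     spacing: float,
                     seed: int = 0,
                     n_frames: Optional[int] = None,
                     project: bool = True,
                     max_extent: int = 256,
                     min_shape: Optional[int] = None,
                     out_dir: Optional[str] = None,
                     ) -> tuple[list[VelocityField], list[dict]]:
    """One velocity field per (geometry, profile) pair, with a manifest.

    The default bank (30 geometries) with 6 profiles yields 180 unique
    time-varying fields.  If ``out_dir`` is given, each field is written as
    an HDF5 bundle and dropped from memory (the returned list is empty).
    """
    manifest: list[dict] = []
    fields: list[VelocityField] = []
    if out_dir is not None:
        import os

        from .io import write_velocity_bundle
        os.makedirs(out_dir, exist_ok=True)
    for gi, geom in enumerate(bank):
        solver = FlowSolver(geom, spacing, max_extent=max_extent, project=project,
                            min_shape=min_shape)
        for pi, prof in enumerate(profiles):
            label = f"{geom.label}|{prof.label}"
            fld = solver.solve(prof, n_frames=n_frames, label=label)
            rec = {"label": label, "geometry": geom.label, "profile": prof.label,
                   "path": None}
            if out_dir is not None:
                import hashlib
                import os
                path = os.path.join(out_dir, f"field_{gi:03d}_{pi:02d}.h5")
                write_velocity_bundle(fld, path)
                with open(path, "rb") as fh:
                    rec["checksum"] = hashlib.sha256(fh.read()).hexdigest()
                rec["path"] = path
            else:
                fields.append(fld)
            manifest.append(rec)
    labels = [r["label"] for r in manifest]
    assert len(set(labels)) == len(labels), "manifest labels must be unique"
    return fields, manifest
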