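"""File formats, configuration, seed plumbing and fixture generation.

Canonical container: an HDF5 "velocity bundle" holding ``velocity``
``[t, 3, z, y, x]`` (float32, cm/s, C-order), the partial-volume mask, and
grid/fluid metadata as attributes.  NIfTI (via nibabel, with a JSON
sidecar for the non-spatial metadata) is supported for interchange.
Coordinates: millimetres, voxel centers at ``origin + (i + 0.5) * spacing``,
0-based indices, array axes ordered (z, y, x) with velocity components
(vx, vy, vz).

All stochastic stages derive their seed from one global seed plus a stage
name, so a single ``--seed`` reproduces a full pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import yaml

from .errors import FormatError
from .flowsynth import BLOOD, VelocityField
from .geometry import VoxelMask

__all__ = [
    "RunConfig",
    "DatasetManifest",
    "derive_seed",
    "rng_for",
    "write_velocity_bundle",
    "read_velocity_bundle",
    "write_nifti",
    "read_nifti",
    "make_fixtures",
    "sha256_of",
]


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2 ** 31))


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, stage))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One YAML-serializable configuration for the whole pipeline."""

    geometry: dict = field(default_factory=lambda: {
        "n_idealized": 5, "n_patientlike": 5, "modifications_per_base": 4,
        "bank_seed": 2021})
    flow: dict = field(default_factory=lambda: {
        "n_profiles": 6, "spacing": 0.6, "n_frames": 10, "min_shape": 32})
    acquisition: dict = field(default_factory=lambda: {
        "venc_fraction_range": [0.1, 0.9], "snr_range": [10.0, 10000.0],
        "crop_factor": 0.25, "background_ratio_range": [0.0, 2.0],
        "rotate": True})
    network: dict = field(default_factory=lambda: {
        "n_residual_blocks": 4, "channels": 16, "velocity_scale": 100.0,
        "residual_output": True})
    training: dict = field(default_factory=lambda: {
        "epochs": 20, "lr_max": 3e-3, "lr_min": 1e-4})
    metrics: dict = field(default_factory=lambda: {"probes": []})
    seed: int = 0
    output_dir: str = "flow4d_out"
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in data.items():
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(base, key, value)
        return base

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


@dataclass
class DatasetManifest:
    """Per-field records plus a snapshot of the generating configuration."""

    records: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r["label"] for r in self.records]
        if len(set(labels)) != len(labels):
            raise FormatError("manifest labels must be unique")

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"records": self.records, "config": self.config}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "DatasetManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(records=d["records"], config=d.get("config", {}))

    def verify_checksums(self) -> bool:
        for rec in self.records:
            if rec.get("path") and rec.get("checksum"):
                if sha256_of(rec["path"]) != rec["checksum"]:
                    return False
        return True


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# HDF5 bundles
# ---------------------------------------------------------------------------

def write_velocity_bundle(fld: VelocityField, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=fld.velocity.astype(np.float32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("mask_fraction", data=fld.mask.fraction.astype(np.float32),
                         compression="gzip", compression_opts=4)
        f.attrs["spacing"] = fld.spacing
        f.attrs["frame_dt"] = fld.frame_dt
        f.attrs["origin"] = fld.mask.origin
        f.attrs["label"] = fld.label
        f.attrs["density"] = fld.fluid["density"]
        f.attrs["viscosity"] = fld.fluid["viscosity"]
        if fld.times is not None:
            f.create_dataset("times", data=np.asarray(fld.times))


def _read_h5(path: str) -> VelocityField:
    with h5py.File(path, "r") as f:
        for key in ("velocity", "mask_fraction"):
            if key not in f:
                raise FormatError(f"bundle {path} missing dataset {key!r}")
        for key in ("spacing", "frame_dt"):
            if key not in f.attrs:
                raise FormatError(f"bundle {path} missing attribute {key!r}")
        vel = f["velocity"][...]
        frac = f["mask_fraction"][...]
        mask = VoxelMask(shape=frac.shape, spacing=float(f.attrs["spacing"]),
                         origin=np.asarray(f.attrs.get("origin", (0.0, 0.0, 0.0))),
                         fraction=frac)
        fluid = {"density": float(f.attrs.get("density", BLOOD["density"])),
                 "viscosity": float(f.attrs.get("viscosity", BLOOD["viscosity"]))}
        times = f["times"][...] if "times" in f else None
        return VelocityField(velocity=vel, spacing=mask.spacing,
                             frame_dt=float(f.attrs["frame_dt"]), mask=mask,
                             fluid=fluid, label=str(f.attrs.get("label", "")),
                             times=times)


# ---------------------------------------------------------------------------
# NIfTI interchange
# ---------------------------------------------------------------------------

def write_nifti(fld: VelocityField, prefix: str) -> dict:
    """Write velocity (x, y, z, t, component), mask and a JSON sidecar."""
    import nibabel as nib

    affine = np.diag([fld.spacing] * 3 + [1.0])
    affine[:3, 3] = fld.mask.origin + fld.spacing / 2.0
    vel = np.transpose(fld.velocity, (4, 3, 2, 0, 1))    # x, y, z, t, comp
    paths = {"velocity": prefix + "_vel.nii.gz", "mask": prefix + "_mask.nii.gz",
             "sidecar": prefix + ".json"}
    nib.save(nib.Nifti1Image(vel.astype(np.float32), affine), paths["velocity"])
    nib.save(nib.Nifti1Image(np.transpose(fld.mask.fraction, (2, 1, 0)).astype(np.float32),
                             affine), paths["mask"])
    sidecar = {"spacing": fld.spacing, "frame_dt": fld.frame_dt,
               "origin": fld.mask.origin.tolist(), "label": fld.label,
               "density": fld.fluid["density"], "viscosity": fld.fluid["viscosity"],
               "velocity_units": "cm/s"}
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return paths


def read_nifti(prefix: str) -> VelocityField:
    import nibabel as nib

    sidecar_path = prefix + ".json"
    if not os.path.exists(sidecar_path):
        raise FormatError(f"missing sidecar metadata file {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("spacing", "frame_dt"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing key {key!r}")
    vel = np.asanyarray(nib.load(prefix + "_vel.nii.gz").dataobj)
    frac = np.asanyarray(nib.load(prefix + "_mask.nii.gz").dataobj)
    vel = np.transpose(vel, (3, 4, 2, 1, 0))             # t, comp, z, y, x
    frac = np.transpose(frac, (2, 1, 0))
    mask = VoxelMask(shape=frac.shape, spacing=float(meta["spacing"]),
                     origin=np.asarray(meta.get("origin", (0.0, 0.0, 0.0))),
                     fraction=frac)
    return VelocityField(velocity=vel, spacing=mask.spacing,
                         frame_dt=float(meta["frame_dt"]), mask=mask,
                         fluid={"density": meta.get("density", BLOOD["density"]),
                                "viscosity": meta.get("viscosity", BLOOD["viscosity"])},
                         label=meta.get("label", ""))


def read_velocity_bundle(path: str) -> VelocityField:
    """Read a velocity field from HDF5 (or a NIfTI prefix with sidecar)."""
    if path.endswith((".h5", ".hdf5")):
        if not os.path.exists(path):
            raise FormatError(f"no such bundle: {path}")
        return _read_h5(path)
    # NIfTI: accept the sidecar path or the common prefix
    prefix = path[:-5] if path.endswith(".json") else path
    return read_nifti(prefix)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0, out_dir: Optional[str] = None):
    """Small deterministic dataset for tests and pipeline smoke runs.

    Two tiny geometries x two inflow profiles at coarse spacing, plus one
    pre-corrupted training pair.  Returns (fields, manifest, pair); when
    ``out_dir`` is given the bundles and manifest are also written there.
    """
    from .geometry import make_idealized_geometry
    from .flowsynth import generate_dataset, make_inflow_profiles
    from .mriforward import AcquisitionConfig, simulate_acquisition

    geoms = [
        make_idealized_geometry("straight", diameter=3.0, length=14.0, n_points=29),
        make_idealized_geometry("bend", diameter=3.0, bend_radius=8.0,
                                angle_deg=100.0, n_points=41),
    ]
    profiles = make_inflow_profiles(2, seed=derive_seed(seed, "fixtures/profiles"))
    fields, records = generate_dataset(geoms, profiles, spacing=0.5, n_frames=3,
                                       min_shape=36)
    acq = AcquisitionConfig(venc_fraction_range=(0.8, 0.8), snr_range=(50.0, 50.0),
                            crop_factor=0.25, background_ratio_range=(0.5, 0.5),
                            rotate=False)
    pair = simulate_acquisition(fields[0].velocity[0].astype(float),
                                fields[0].mask.fraction.astype(float), acq,
                                rng_for(seed, "fixtures/pair"),
                                spacing=fields[0].spacing,
                                pair_id=fields[0].label)
    manifest = DatasetManifest(records=records, config={"seed": seed})
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, fld in enumerate(fields):
            path = os.path.join(out_dir, f"fixture_{i}.h5")
            write_velocity_bundle(fld, path)
            manifest.records[i]["path"] = path
            manifest.records[i]["checksum"] = sha256_of(path)
        manifest.save(os.path.join(out_dir, "manifest.json"))
    return fields, manifest, pair
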