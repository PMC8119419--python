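"""Physics-based PC-MRI acquisition simulator.

Converts a clean high-resolution velocity frame into the corrupted,
low-resolution velocity + magnitude data a phase-contrast MRI scan would
measure: random 3D rotation, synthetic static-tissue background magnitude,
standard PC-MRI complex-signal encoding (reference + one encoding per
velocity axis, phase pi at Venc), additive complex white Gaussian k-space
noise, and central k-space cropping.  Corruptions are drawn fresh per call
so training sees a new realization every time a field is used.

Phase wrap for |v| > Venc is kept; aliasing correction is out of scope.
SNR is defined as (mean vessel signal magnitude) / (per-real-component
image-domain noise std), with the noise std referred to the full-resolution
image (before cropping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError

__all__ = [
    "AcquisitionConfig",
    "ComplexImage",
    "TrainingPair",
    "random_rotate",
    "synth_background",
    "compose_signal",
    "encode_pc",
    "corrupt",
    "decode_velocity",
    "simulate_acquisition",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionConfig:
    """Stochastic corruption parameters of the simulated acquisition.

    Venc is drawn as a fraction of the frame's peak speed, SNR
    log-uniformly, and the background-to-vessel magnitude ratio uniformly
    from their ranges.
    """

    venc_fraction_range: tuple[float, float] = (0.1, 0.9)
    snr_range: tuple[float, float] = (10.0, 10000.0)
    crop_factor: float = 0.25
    background_ratio_range: tuple[float, float] = (0.0, 2.0)
    rotate: bool = True
    #: fixed Venc in cm/s (scan-protocol style); overrides the peak-speed
    #: fraction draw when set
    venc_absolute: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.venc_fraction_range
        if not (0 < lo <= hi <= 1):
            raise InvalidParameterError("venc fractions must satisfy 0 < lo <= hi <= 1")
        if self.snr_range[0] < 1:
            raise InvalidParameterError("snr lower bound must be >= 1")
        if not (0 < self.crop_factor <= 1):
            raise InvalidParameterError("crop factor must be in (0, 1]")
        if self.background_ratio_range[0] < 0:
            raise InvalidParameterError("background ratio must be non-negative")

    def draw(self, rng: np.random.Generator) -> dict:
        lo, hi = self.snr_range
        return {
            "venc_fraction": float(rng.uniform(*self.venc_fraction_range)),
            "snr": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "background_ratio": float(rng.uniform(*self.background_ratio_range)),
        }


@dataclass
class ComplexImage:
    """4-point PC-MRI complex signal: reference plus one encoding per axis."""

    encodings: np.ndarray   # (4, z, y, x) complex; [0] is the reference
    venc: float             # cm/s
    spacing: float          # mm

    def __post_init__(self) -> None:
        if self.encodings.shape[0] != 4:
            raise InvalidParameterError("expected 4 encodings (reference + 3 axes)")
        if self.venc <= 0:
            raise InvalidParameterError("venc must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.encodings.shape[1:]


@dataclass
class TrainingPair:
    """Matched corrupted/clean volumes for supervised training.

    ``truth`` is the (possibly rotated) clean high-resolution velocity;
    ``corrupted_velocity`` is the decoded low-resolution velocity
    zero-filled back to the truth grid.
    """

    truth: np.ndarray               # (3, z, y, x) cm/s
    corrupted_velocity: np.ndarray  # (3, z, y, x) cm/s
    magnitude: np.ndarray           # (z, y, x) normalized
    mask_fraction: np.ndarray       # (z, y, x) in [0, 1]
    spacing: float
    config_draw: dict = field(default_factory=dict)
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.truth.shape != self.corrupted_velocity.shape:
            raise InvalidParameterError("truth and corrupted shapes differ")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def random_rotate(frame: np.ndarray, rng: np.random.Generator,
                  mask_fraction: Optional[np.ndarray] = None,
                  rotation: Optional[Rotation] = None,
                  ) -> tuple[np.ndarray, Optional[np.ndarray], Rotation]:
    """Rotate a velocity frame (and optionally its mask) in 3D space.

    The rotation is drawn uniformly on SO(3) unless given.  Scalar volumes
    are resampled about the volume center with cubic-spline interpolation
    (linear for the mask fraction); the three velocity components are then
    mixed by the same rotation matrix so the field rotates as a vector
    field.
    """
    if rotation is None:
        rotation = Rotation.random(rng=rng)
    R = rotation.as_matrix()                   # world (x, y, z)
    R_idx = R.T[::-1, ::-1]                    # inverse map in (z, y, x) index space
    center = (np.array(frame.shape[1:]) - 1) / 2.0
    offset = center - R_idx @ center

    rotated = np.empty_like(frame, dtype=float)
    for c in range(3):
        rotated[c] = affine_transform(frame[c].astype(float), R_idx, offset=offset,
                                      order=3, mode="constant", cval=0.0)
    rotated = np.einsum("ij,jzyx->izyx", R, rotated)

    rot_mask = None
    if mask_fraction is not None:
        rot_mask = affine_transform(mask_fraction.astype(float), R_idx, offset=offset,
                                    order=1, mode="constant", cval=0.0)
        rot_mask = np.clip(rot_mask, 0.0, 1.0)
    return rotated, rot_mask, rotation


def synth_background(shape: tuple[int, int, int], rng: np.random.Generator,
                     threshold_scale: float = 0.5) -> np.ndarray:
    """Synthetic static-tissue magnitude with sharp edges, max-normalized.

    A 5x5x5 complex standard-normal k-space block is embedded centrally in
    an otherwise empty k-space of the full shape, inverse-Fourier
    transformed, magnitude-detected, and soft-thresholded at
    ``threshold_scale`` times its median (creating flat exactly-zero
    regions bounded by high-resolution edges).
    """
    if any(s < 5 for s in shape):
        raise InvalidParameterError("background shape must be >= 5 per axis")
    k = np.zeros(shape, dtype=complex)
    block = rng.standard_normal((5, 5, 5)) + 1j * rng.standard_normal((5, 5, 5))
    c = [s // 2 for s in shape]
    k[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = block
    mag = np.abs(np.fft.ifftn(np.fft.ifftshift(k)))
    lam = threshold_scale * np.median(mag)
    mag = np.maximum(mag - lam, 0.0)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def compose_signal(mask_fraction: np.ndarray, background: np.ndarray,
                   ratio: float) -> np.ndarray:
    """Additively combine vessel mask and background magnitude, max 1."""
    if ratio < 0:
        raise InvalidParameterError("background ratio must be non-negative")
    mag = mask_fraction + ratio * background
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def encode_pc(frame: np.ndarray, magnitude: np.ndarray, venc: float,
              spacing: float = 1.0) -> ComplexImage:
    """Standard PC-MRI complex-signal model (simple 4-point encoding).

    Reference encoding has zero phase; the axis-k encoding has phase
    ``pi * v_k / venc``, which wraps naturally for |v_k| > venc.
    """
    if venc <= 0:
        raise InvalidParameterError("venc must be positive")
    enc = np.empty((4,) + frame.shape[1:], dtype=complex)
    enc[0] = magnitude.astype(float)
    for k in range(3):
        enc[k + 1] = magnitude * np.exp(1j * np.pi * frame[k] / venc)
    return ComplexImage(encodings=enc, venc=float(venc), spacing=float(spacing))


def _center_slices(n_full: tuple[int, ...], n_keep: tuple[int, ...]) -> tuple[slice, ...]:
    return tuple(slice(f // 2 - k // 2, f // 2 - k // 2 + k)
                 for f, k in zip(n_full, n_keep))


def corrupt(image: ComplexImage, snr: float, crop_factor: float,
            rng: np.random.Generator, vessel_mask: Optional[np.ndarray] = None,
            zero_fill: bool = False) -> ComplexImage:
    """Add k-space noise and crop to a fraction of the spatial resolution.

    Per encoding: forward FFT, additive complex white Gaussian noise
    calibrated so (mean vessel magnitude)/(full-res image noise std) equals
    ``snr``, retention of the central ``crop_factor`` of k-space per axis,
    inverse FFT.  With ``zero_fill`` the cropped spectrum is zero-padded
    back so the output grid matches the input.
    """
    if snr <= 0:
        raise InvalidParameterError("snr must be positive")
    if not (0 < crop_factor <= 1):
        raise InvalidParameterError("crop factor must be in (0, 1]")
    shape = image.shape
    keep = tuple(int(round(crop_factor * s)) for s in shape)
    if any(k < 4 for k in keep):
        raise InvalidParameterError(f"crop to {keep} leaves fewer than 4 samples per axis")

    ref_mag = np.abs(image.encodings[0])
    if vessel_mask is not None and vessel_mask.any():
        signal = float(ref_mag[vessel_mask].mean())
    else:
        signal = float(ref_mag.mean())
    sigma_img = signal / snr
    n_full = int(np.prod(shape))
    sigma_k = sigma_img * np.sqrt(n_full)

    out_shape = shape if zero_fill else keep
    out = np.empty((4,) + out_shape, dtype=complex)
    sl = _center_slices(shape, keep)
    for e in range(4):
        k = np.fft.fftshift(np.fft.fftn(image.encodings[e]))
        k = k + sigma_k * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
        kc = k[sl]
        if zero_fill:
            kz = np.zeros(shape, dtype=complex)
            kz[sl] = kc
            out[e] = np.fft.ifftn(np.fft.ifftshift(kz))
        else:
            scale = np.prod(keep) / n_full
            out[e] = np.fft.ifftn(np.fft.ifftshift(kc)) * scale
    spacing = image.spacing if zero_fill else image.spacing * shape[0] / keep[0]
    return ComplexImage(encodings=out, venc=image.venc, spacing=spacing)


def decode_velocity(image: ComplexImage) -> tuple[np.ndarray, np.ndarray]:
    """Phase-difference reconstruction: velocity (cm/s) and magnitude.

    The phase of a numerically vanishing signal is undefined; velocity is
    set to zero where the phase-difference product is below 1e-8 of the
    peak reference magnitude (squared).  Noise-level magnitudes sit far
    above this floor, so noisy voxels keep their physical random phase.
    """
    ref = image.encodings[0]
    floor = (1e-8 * np.abs(ref).max()) ** 2
    vel = np.empty((3,) + image.shape)
    for k in range(3):
        prod = image.encodings[k + 1] * np.conj(ref)
        vel[k] = image.venc / np.pi * np.angle(prod)
        vel[k][np.abs(prod) <= floor] = 0.0
    return vel, np.abs(ref)


def simulate_acquisition(frame: np.ndarray, mask_fraction: np.ndarray,
                         config: AcquisitionConfig, rng: np.random.Generator,
                         spacing: float = 1.0, pair_id: str = "") -> TrainingPair:
    """Full corruption pipeline producing one corrupted/clean training pair.

    rotate -> synthesize background -> compose magnitude -> PC encode at a
    randomly drawn Venc -> k-space noise + crop -> decode -> zero-fill to
    the truth grid.  The realized draws are recorded on the pair.
    """
    draw = config.draw(rng)
    if config.rotate:
        truth, frac, rot = random_rotate(frame, rng, mask_fraction)
        draw["rotation"] = rot.as_quat().tolist()
    else:
        truth, frac = frame.astype(float), mask_fraction.astype(float)
        draw["rotation"] = None
    binary = frac >= 0.5
    truth = truth * binary[None]

    peak = float(np.sqrt((truth ** 2).sum(axis=0)).max())
    if config.venc_absolute is not None:
        venc = float(config.venc_absolute)
    else:
        venc = draw["venc_fraction"] * peak if peak > 0 else 1.0
    draw["venc"] = venc

    background = synth_background(truth.shape[1:], rng)
    magnitude = compose_signal(frac, background, draw["background_ratio"])
    encoded = encode_pc(truth, magnitude, venc, spacing=spacing)
    corrupted = corrupt(encoded, draw["snr"], config.crop_factor, rng,
                        vessel_mask=binary, zero_fill=True)
    vel, mag = decode_velocity(corrupted)
    return TrainingPair(truth=truth.astype(np.float32),
                        corrupted_velocity=vel.astype(np.float32),
                        magnitude=mag.astype(np.float32),
                        mask_fraction=frac.astype(np.float32),
                        spacing=spacing, config_draw=draw, pair_id=pair_id)
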