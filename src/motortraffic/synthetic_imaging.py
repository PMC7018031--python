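"""Synthetic TIRF image stacks and kymographs from motor trajectories.

Renders trajectory sets (from :mod:`motortraffic.lattice_sim` or the
exclusion-free parametric generator below) into 16-bit image stacks that
emulate the experimental acquisition: 1000 frames at 200 ms exposure,
80 nm effective pixels, diffraction-limited Gaussian spots, Poisson shot
noise on signal plus background, and camera offset/gain digitization.
Within a run a motor is rendered at its mean velocity (bound motors move
ballistically between binding and unbinding), with motion blur approximated
by averaging sub-exposure positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .lattice_sim import TrajectorySet

__all__ = [
    "OpticsConfig",
    "ImageStack",
    "KymographData",
    "parametric_trajectories",
    "render_stack",
    "make_kymograph",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when trajectories or the microtubule axis leave the field of view."""


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition parameters of the emulated TIRF microscope.

    ``psf_sigma`` defaults to 130 nm, about the diffraction limit for GFP
    emission through an NA 1.49 objective.  ``photons_per_motor_per_frame``
    and ``background_photons_per_pixel`` default to a peak-pixel SNR of ~6
    for a single motor.  ``shot_noise=False`` disables the Poisson draw
    (expected-value images) for calibration tests.
    """

    pixel_size: float = 80.0  # nm
    psf_sigma: float = 130.0  # nm
    exposure: float = 0.2  # s
    n_frames: int = 1000
    photons_per_motor_per_frame: float = 800.0
    background_photons_per_pixel: float = 20.0
    bleach_rate: float = 0.0  # s^-1
    labeled_fraction: float = 1.0
    camera_offset: float = 100.0
    camera_gain: float = 1.0
    n_subsamples: int = 10
    shot_noise: bool = True
    margin_pixels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.psf_sigma, self.exposure) <= 0:
            raise ValueError("pixel_size, psf_sigma and exposure must be positive")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.n_frames < 1 or self.n_subsamples < 1:
            raise ValueError("n_frames and n_subsamples must be >= 1")
        if self.bleach_rate < 0 or self.photons_per_motor_per_frame < 0:
            raise ValueError("rates and photon yields must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size / 1000.0


@dataclass
class ImageStack:
    """Time series of images plus optics metadata and microtubule geometry.

    ``frames``: (n_frames, ny, nx); ``mt_axis``: 2x2 array of endpoint
    coordinates in continuous pixel units, (x, y) rows, pointing from the
    minus to the plus end.
    """

    frames: np.ndarray
    optics: OpticsConfig
    mt_axis: np.ndarray
    ground_truth: Optional[TrajectorySet] = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, y, x)")
        if self.frames.shape[0] != self.optics.n_frames:
            raise ValueError("frame count does not match optics.n_frames")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class KymographData:
    """Intensity along the microtubule axis for every frame, I(x, t).

    ``intensity`` has shape (n_x, n_t); x spacing is one pixel, t spacing is
    one exposure.  ``background_mean``/``background_std`` are per-frame
    statistics of a parallel off-axis band.
    """

    intensity: np.ndarray  # (n_x, n_t)
    x_um: np.ndarray
    t_s: np.ndarray
    background_mean: Optional[np.ndarray] = None
    background_std: Optional[np.ndarray] = None
    pixel_size_um: float = 0.08
    frame_interval_s: float = 0.2
    background_subtracted: bool = False

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    @property
    def segment_length_um(self) -> float:
        return float(self.x_um[-1] - self.x_um[0] + self.pixel_size_um)


def parametric_trajectories(
    v: float,
    omega_D: float,
    binding_rate_per_um: float,
    length: float,
    duration: float,
    seed: int = 0,
) -> TrajectorySet:
    """Exclusion-free trajectories: Poisson binding, constant speed, exponential lifetimes.

    Motors appear as a homogeneous Poisson process in space-time on
    [0, length] x [0, duration], move at exactly ``v`` (um/s) toward +x and
    unbind after an exponential lifetime of mean 1/omega_D, or leave the
    segment end (censored).  Useful as a ground-truth fixture for the image
    analyses, independent of the lattice simulator.
    """
    if min(v, omega_D, binding_rate_per_um, length, duration) < 0:
        raise ValueError("all parameters must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(binding_rate_per_um * length * duration)
    bind_t = np.sort(rng.uniform(0.0, duration, n))
    bind_x = rng.uniform(0.0, length, n)
    life = (
        rng.exponential(1.0 / omega_D, n) if omega_D > 0 else np.full(n, np.inf)
    )
    # censoring by segment exit or end of observation
    t_exit = (length - bind_x) / v if v > 0 else np.full(n, np.inf)
    t_end = duration - bind_t
    dwell = np.minimum.reduce([life, t_exit, t_end])
    censored = dwell < life  # ended by geometry/time, not detachment
    unbind_t = bind_t + dwell
    unbind_x = bind_x + v * dwell
    step_um = 0.008
    runs = pd.DataFrame(
        {
            "lane": np.zeros(n, dtype=int),
            "bind_time_s": bind_t,
            "unbind_time_s": unbind_t,
            "bind_site": np.round(bind_x / step_um).astype(int),
            "unbind_site": np.round(unbind_x / step_um).astype(int),
            "censored": censored,
            "bind_x_um": bind_x,
            "unbind_x_um": unbind_x,
        }
    )
    # rounding may invert site order for sub-step displacements
    runs["unbind_site"] = np.maximum(runs["unbind_site"], runs["bind_site"])
    meta = {
        "seed": int(seed),
        "generator": "parametric",
        "v_um_s": v,
        "omega_D": omega_D,
        "binding_rate_per_um": binding_rate_per_um,
        "length_um": length,
        "duration_s": duration,
    }
    return TrajectorySet(runs=runs, snapshots=pd.DataFrame(columns=["time_s", "lane", "site"]), meta=meta)


def _pixel_profile(centers: np.ndarray, n_pix: int, sigma_px: float) -> np.ndarray:
    """Pixel-integrated 1-D Gaussian profiles for a batch of centers."""
    edges = np.arange(n_pix + 1)
    z = (edges[None, :] - centers[:, None]) / (sigma_px * np.sqrt(2.0))
    c = special.erf(z)
    return 0.5 * (c[:, 1:] - c[:, :-1])


def render_stack(
    trajectories: TrajectorySet,
    optics: OpticsConfig,
    image_shape: Optional[tuple] = None,
) -> ImageStack:
    """Render a trajectory set into a 16-bit TIRF-like image stack.

    Each labeled, unbleached motor contributes a pixel-integrated isotropic
    Gaussian spot; motion blur is approximated by averaging
    ``optics.n_subsamples`` sub-exposure positions; per-pixel photon counts
    are Poisson (signal + background), then digitized with offset and gain.
    """
    rng = np.random.default_rng(optics.seed)
    runs = trajectories.runs
    ps = optics.pixel_size_um
    margin = optics.margin_pixels
    if len(runs):
        x_max = float(runs["unbind_x_um"].max())
        if runs["bind_x_um"].min() < 0:
            raise GeometryError("trajectory coordinates must be >= 0")
    else:
        x_max = 1.0
    if image_shape is None:
        nx = int(np.ceil(x_max / ps)) + 2 * margin
        ny = 2 * margin + 1
    else:
        ny, nx = image_shape
        if x_max / ps + margin > nx:
            raise GeometryError("trajectories overflow the requested field of view")
    y_c = ny / 2.0
    mt_axis = np.array([[margin, y_c], [nx - margin, y_c]], dtype=float)

    sigma_px = optics.psf_sigma / optics.pixel_size
    half = int(np.ceil(4 * sigma_px)) + 1

    labeled = rng.random(len(runs)) < optics.labeled_fraction
    if optics.bleach_rate > 0:
        label_life = rng.exponential(1.0 / optics.bleach_rate, len(runs))
    else:
        label_life = np.full(len(runs), np.inf)

    bt = runs["bind_time_s"].to_numpy()
    ut = runs["unbind_time_s"].to_numpy()
    bx = runs["bind_x_um"].to_numpy()
    ux = runs["unbind_x_um"].to_numpy()
    dur = np.where(ut > bt, ut - bt, np.inf)
    vel = (ux - bx) / dur  # per-run mean velocity

    n_sub = optics.n_subsamples
    photons_sub = optics.photons_per_motor_per_frame / n_sub
    frames = np.zeros((optics.n_frames, ny, nx), dtype=np.float64)
    sub_off = (np.arange(n_sub) + 0.5) / n_sub * optics.exposure

    y_center = y_c  # spot center in pixel units
    yprof_cache: dict = {}

    for f in range(optics.n_frames):
        t0 = f * optics.exposure
        active = np.nonzero(labeled & (bt < t0 + optics.exposure) & (ut > t0))[0]
        if active.size == 0:
            continue
        img = frames[f]
        for i in active:
            ts = t0 + sub_off
            vis = (ts >= bt[i]) & (ts < min(ut[i], bt[i] + label_life[i]))
            if not vis.any():
                continue
            xs = (bx[i] + vel[i] * (ts[vis] - bt[i])) / ps + margin  # pixel units
            ix0 = int(np.clip(np.floor(xs.mean()) - half, 0, nx - 1))
            ix1 = int(np.clip(np.floor(xs.mean()) + half + 1, 1, nx))
            px = _pixel_profile(xs - ix0, ix1 - ix0, sigma_px)  # (n_vis, w)
            key = (ny, round(y_center, 6))
            if key not in yprof_cache:
                yprof_cache[key] = _pixel_profile(np.array([y_center]), ny, sigma_px)[0]
            py = yprof_cache[key]
            img[:, ix0:ix1] += photons_sub * np.outer(py, px.sum(axis=0))

    frames += optics.background_photons_per_pixel
    if optics.shot_noise:
        frames = rng.poisson(frames).astype(np.float64)
    frames = optics.camera_offset + optics.camera_gain * frames
    if frames.max() > 65535:
        warnings.warn("rendered intensities exceed 16-bit range; clipping", stacklevel=2)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    return ImageStack(frames=frames, optics=optics, mt_axis=mt_axis, ground_truth=trajectories)


def make_kymograph(
    stack: ImageStack,
    width_pixels: int = 3,
    background_offset_pixels: int = 6,
) -> KymographData:
    """Sample intensity along the microtubule axis for every frame.

    Per frame the intensity is bilinearly interpolated at pixel-center
    spacing along ``stack.mt_axis`` and averaged over ``width_pixels``
    perpendicular offsets.  Background statistics come from two parallel
    bands offset by ``background_offset_pixels`` on either side.
    """
    if width_pixels < 1:
        raise ValueError("width_pixels must be >= 1")
    (x0, y0), (x1, y1) = stack.mt_axis
    n_t, ny, nx = stack.frames.shape
    if not (0 <= x0 <= nx and 0 <= x1 <= nx and 0 <= y0 <= ny and 0 <= y1 <= ny):
        raise GeometryError("microtubule axis lies outside the image")
    length_px = float(np.hypot(x1 - x0, y1 - y0))
    n_x = int(np.floor(length_px)) + 1
    tvec = np.array([x1 - x0, y1 - y0]) / length_px
    nvec = np.array([-tvec[1], tvec[0]])
    s = np.arange(n_x)
    base = np.array([x0, y0])[:, None] + tvec[:, None] * s[None, :]

    offs = np.arange(width_pixels) - (width_pixels - 1) / 2.0
    bg_offs = np.array([-background_offset_pixels, background_offset_pixels], dtype=float)

    def _sample(offsets: np.ndarray) -> np.ndarray:
        # coords in (row=y, col=x) order minus 0.5 pixel-center shift
        pts = base[:, None, :] + nvec[:, None, None] * offsets[None, :, None]
        coords = np.stack([pts[1] - 0.5, pts[0] - 0.5])  # (2, n_off, n_x)
        out = np.empty((n_t, offsets.size, n_x))
        for f in range(n_t):
            out[f] = ndimage.map_coordinates(
                stack.frames[f].astype(np.float64), coords, order=1, mode="nearest"
            )
        return out

    sig = _sample(offs).mean(axis=1)  # (n_t, n_x)
    bg = _sample(bg_offs)  # (n_t, 2, n_x)
    bg_flat = bg.reshape(n_t, -1)
    return KymographData(
        intensity=sig.T.copy(),
        x_um=s * stack.optics.pixel_size_um,
        t_s=(np.arange(n_t) + 0.5) * stack.optics.exposure,
        background_mean=bg_flat.mean(axis=1),
        background_std=bg_flat.std(axis=1, ddof=1),
        pixel_size_um=stack.optics.pixel_size_um,
        frame_interval_s=stack.optics.exposure,
        background_subtracted=False,
    )
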