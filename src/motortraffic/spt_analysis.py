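"""Single-particle tracking at low motor density.

Pipeline: local-maximum candidates refined by 2-D Gaussian fits, greedy
mutual-nearest-neighbour frame-to-frame linking (no gap closing — adequate
at single-molecule densities), then two ensemble estimators:

* mean displacement vs time lag, fitted by a weighted line through the
  origin, whose slope is the velocity;
* the cumulative distribution of net track lengths, fitted by a shifted
  exponential 1 - exp(-(x - x_min)/lambda); by memorylessness the mean
  lambda is unbiased for the true run length for any detection cutoff
  x_min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
import statsmodels.api as sm

from .synthetic_imaging import ImageStack

__all__ = [
    "Detection",
    "detect_spots",
    "link_detections",
    "detect_and_link",
    "track_summary",
    "mean_displacement_velocity",
    "runlength_cdf_fit",
    "SptError",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "x_along_um", "amplitude"]


class SptError(RuntimeError):
    """Raised when tracking preconditions or estimations fail."""


@dataclass(frozen=True)
class Detection:
    """A single sub-pixel localization."""

    frame: int
    x_um: float
    y_um: float
    amplitude: float
    background: float
    sigma_um: float
    r2: float


def _gauss2d(coords, a, x0, y0, sig, c):
    x, y = coords
    return a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sig**2)) + c


def _fit_spot(patch: np.ndarray, sigma0_px: float):
    """2-D Gaussian fit on a square patch; returns None on failure."""
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]
    z = patch.ravel().astype(float)
    c0 = float(np.percentile(z, 20))
    a0 = float(patch.max() - c0)
    if a0 <= 0:
        return None
    p0 = [a0, w / 2.0, h / 2.0, sigma0_px, c0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            z,
            p0=p0,
            bounds=([0, 0, 0, 0.4, -np.inf], [np.inf, w, h, max(w, h), np.inf]),
            maxfev=400,
        )
    except (RuntimeError, ValueError):
        return None
    pred = _gauss2d((xx.ravel(), yy.ravel()), *popt)
    ss = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - float(np.sum((z - pred) ** 2)) / ss if ss > 0 else 0.0
    return popt, r2


def detect_spots(
    stack: ImageStack,
    intensity_threshold: float,
    min_distance_px: int = 3,
    fit_halfwidth_px: int = 4,
) -> pd.DataFrame:
    """Detect and sub-pixel-localize fluorescent spots in every frame.

    ``intensity_threshold`` is in camera counts above the per-frame median
    background.  Returns a DataFrame with one row per accepted localization.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be positive")
    ps = stack.optics.pixel_size_um
    sigma0 = stack.optics.psf_sigma / stack.optics.pixel_size
    hw = fit_halfwidth_px
    rows = []
    n_sat = 0
    for f, frame in enumerate(stack.frames):
        if frame.max() >= 65535:
            n_sat += 1
        img = frame.astype(float)
        bg = float(np.median(img))
        peaks = peak_local_max(
            img,
            min_distance=min_distance_px,
            threshold_abs=bg + intensity_threshold,
            exclude_border=hw,
        )
        for py, px in peaks:
            patch = img[py - hw : py + hw + 1, px - hw : px + hw + 1]
            res = _fit_spot(patch, sigma0)
            if res is None:
                continue
            (a, x0, y0, sig, c), r2 = res
            if a <= 0.3 * intensity_threshold or not (0.3 * sigma0 < sig < 3 * sigma0 + 1):
                continue
            if not (0.5 < x0 < 2 * hw + 0.5 and 0.5 < y0 < 2 * hw + 0.5):
                continue
            rows.append(
                {
                    "frame": f,
                    "x_um": (px - hw + x0 + 0.5) * ps,
                    "y_um": (py - hw + y0 + 0.5) * ps,
                    "amplitude": a,
                    "background": c + bg,
                    "sigma_um": sig * ps,
                    "r2": r2,
                }
            )
    if n_sat:
        warnings.warn(f"{n_sat} saturated frames", stacklevel=2)
    cols = ["frame", "x_um", "y_um", "amplitude", "background", "sigma_um", "r2"]
    return pd.DataFrame(rows, columns=cols)


def link_detections(
    detections: pd.DataFrame,
    max_disp_per_frame: float,
    min_track_frames: int = 5,
) -> pd.DataFrame:
    """Greedy mutual-nearest-neighbour linking of consecutive frames.

    Pairs are accepted in order of increasing distance, each endpoint used
    once, within the gate ``max_disp_per_frame`` (um).  Tracks shorter than
    ``min_track_frames`` are discarded.  Returns the detections with a
    ``track_id`` column.
    """
    if max_disp_per_frame <= 0:
        raise ValueError("max_disp_per_frame must be positive")
    det = detections.sort_values(["frame"]).reset_index(drop=True)
    det["track_id"] = -1
    next_id = 0
    prev_idx: np.ndarray = np.array([], dtype=int)
    frames = sorted(det["frame"].unique())
    by_frame = {f: det.index[det["frame"] == f].to_numpy() for f in frames}
    for i, f in enumerate(frames):
        cur_idx = by_frame[f]
        linked_cur = set()
        if i > 0 and frames[i - 1] == f - 1 and len(prev_idx) and len(cur_idx):
            a = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            b = det.loc[cur_idx, ["x_um", "y_um"]].to_numpy()
            dist = cdist(a, b)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
            used_a: set = set()
            for ia, ib in order:
                if dist[ia, ib] > max_disp_per_frame:
                    break
                if ia in used_a or ib in linked_cur:
                    continue
                det.loc[cur_idx[ib], "track_id"] = det.loc[prev_idx[ia], "track_id"]
                used_a.add(ia)
                linked_cur.add(ib)
        for j, idx in enumerate(cur_idx):
            if j not in linked_cur:
                det.loc[idx, "track_id"] = next_id
                next_id += 1
        prev_idx = cur_idx
    sizes = det.groupby("track_id").size()
    keep = sizes.index[sizes >= min_track_frames]
    out = det[det["track_id"].isin(keep)].reset_index(drop=True)
    # renumber consecutively
    remap = {t: i for i, t in enumerate(sorted(out["track_id"].unique()))}
    out["track_id"] = out["track_id"].map(remap)
    return out


def _project_along_axis(tracks: pd.DataFrame, mt_axis: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    (x0, y0), (x1, y1) = mt_axis * pixel_size_um
    t = np.array([x1 - x0, y1 - y0])
    t = t / np.linalg.norm(t)
    tracks = tracks.copy()
    tracks["x_along_um"] = (tracks["x_um"] - x0) * t[0] + (tracks["y_um"] - y0) * t[1]
    return tracks


def detect_and_link(
    stack: ImageStack,
    intensity_threshold: float,
    max_disp_per_frame: float,
    min_track_frames: int = 5,
) -> pd.DataFrame:
    """Detection + linking + projection onto the microtubule axis.

    Returns a tracks DataFrame (one row per localization) with
    ``x_along_um``, the coordinate along the plus-end direction.  Zero
    detections yield an empty frame, not an error.
    """
    det = detect_spots(stack, intensity_threshold)
    if det.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    tracks = link_detections(det, max_disp_per_frame, min_track_frames)
    if tracks.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return _project_along_axis(tracks, stack.mt_axis, stack.optics.pixel_size_um)


def track_summary(tracks: pd.DataFrame, frame_interval_s: float) -> pd.DataFrame:
    """Per-track start/end frames, duration and net along-axis length (um)."""
    if tracks.empty:
        return pd.DataFrame(
            columns=["track_id", "start_frame", "end_frame", "n_frames", "duration_s", "length_um"]
        )
    g = tracks.sort_values("frame").groupby("track_id")
    out = pd.DataFrame(
        {
            "start_frame": g["frame"].first(),
            "end_frame": g["frame"].last(),
            "n_frames": g.size(),
            "length_um": g["x_along_um"].last() - g["x_along_um"].first(),
        }
    ).reset_index()
    out["duration_s"] = (out["end_frame"] - out["start_frame"]) * frame_interval_s
    return out


def mean_displacement_velocity(
    tracks: pd.DataFrame,
    frame_interval_s: float,
    max_lag_frames: int = 10,
    min_tracks: int = 20,
) -> tuple[float, float, pd.DataFrame]:
    """Velocity from the mean along-axis displacement vs time lag.

    For each lag the mean displacement is taken over all segments of all
    tracks; a weighted least-squares line through the origin gives the
    velocity and its standard error.  Returns (velocity, se, per-lag table).
    """
    n_tracks = tracks["track_id"].nunique() if not tracks.empty else 0
    if n_tracks < min_tracks:
        raise SptError(f"need >= {min_tracks} tracks, got {n_tracks}")
    rows = []
    grouped = [g.sort_values("frame")["x_along_um"].to_numpy() for _, g in tracks.groupby("track_id")]
    if all(len(x) < 2 for x in grouped):
        raise SptError("all tracks are single-frame; no displacements")
    for lag in range(1, max_lag_frames + 1):
        disps = np.concatenate([x[lag:] - x[:-lag] for x in grouped if len(x) > lag] or [np.array([])])
        if disps.size < 2:
            continue
        rows.append(
            {
                "lag_s": lag * frame_interval_s,
                "mean_disp_um": disps.mean(),
                "se": disps.std(ddof=1) / math.sqrt(disps.size),
                "n": disps.size,
            }
        )
    tab = pd.DataFrame(rows)
    if len(tab) < 2:
        raise SptError("not enough lags with displacement data")
    w = 1.0 / np.clip(tab["se"].to_numpy(), 1e-9, np.inf) ** 2
    x = tab["lag_s"].to_numpy()
    y = tab["mean_disp_um"].to_numpy()
    wls = sm.WLS(y, x[:, None], weights=w).fit()  # through origin
    return float(wls.params[0]), float(wls.bse[0]), tab


def runlength_cdf_fit(
    lengths: np.ndarray,
    min_observable: float = 0.0,
    n_bootstrap: int = 200,
    min_tracks: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean run length from the cumulative distribution of track lengths.

    Fits 1 - exp(-(x - min_observable)/lambda) to the empirical CDF of net
    track lengths >= ``min_observable`` by least squares; the standard error
    comes from ``n_bootstrap`` resamples.  Exponential memorylessness makes
    lambda insensitive to the choice of min_observable.
    """
    x = np.asarray(lengths, dtype=float)
    x = x[x >= min_observable]
    if x.size < min_tracks:
        raise SptError(f"need >= {min_tracks} track lengths >= min_observable, got {x.size}")
    if np.std(x) < 1e-12:
        raise SptError("degenerate length distribution (all values identical); exponential fit rejected")

    def _fit(sample: np.ndarray) -> float:
        xs = np.sort(sample)
        ecdf = (np.arange(xs.size) + 0.5) / xs.size
        lam0 = max(float(np.mean(xs) - min_observable), 1e-6)
        popt, _ = optimize.curve_fit(
            lambda t, lam: 1.0 - np.exp(-np.clip(t - min_observable, 0, None) / lam),
            xs,
            ecdf,
            p0=[lam0],
            bounds=(1e-9, np.inf),
            maxfev=1000,
        )
        return float(popt[0])

    lam = _fit(x)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        boots.append(_fit(rng.choice(x, x.size, replace=True)))
    return lam, float(np.std(boots, ddof=1))
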