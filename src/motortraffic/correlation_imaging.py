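"""Density, velocity and run length from intensity correlation of kymographs.

Three estimators act on a background-subtracted kymograph I(x, t):

* **FCS density** — the spatially summed intensity F(t) fluctuates as
  motors bind and unbind; for independent emitters the normalized temporal
  autocorrelation satisfies G(0+) = 1/N with N the mean number of labeled
  motors on the segment.  The shot-noise-free intercept is obtained by
  linear extrapolation of G over lags of 1-3 frames.
* **velocity** — the spatiotemporal correlation C(xi, tau) of intensity
  fluctuations has a peak that drifts at the ensemble velocity; Gaussian
  fits per time lag track the peak position x_p(tau), and a weighted linear
  fit yields v = dx_p/dtau.
* **run length** — the area A(tau) under the correlation peak decays with
  the motor detachment rate; an exponential fit gives omega_D and the run
  length v/omega_D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm

from .synthetic_imaging import KymographData

__all__ = [
    "TemporalACF",
    "CorrelationSurface",
    "MotilityEstimates",
    "FcsDensityResult",
    "background_subtract",
    "temporal_acf",
    "fcs_density",
    "spatiotemporal_correlation",
    "extract_velocity_runlength",
    "analyze_kymograph",
    "CorrelationError",
]


class CorrelationError(RuntimeError):
    """Raised when a correlation estimate cannot be formed."""


@dataclass
class TemporalACF:
    """Normalized autocorrelation of the spatially summed intensity."""

    lags_s: np.ndarray
    values: np.ndarray
    n_frames: int


@dataclass
class CorrelationSurface:
    """Spatiotemporal correlation C(xi, tau) with per-lag Gaussian fits.

    ``fits`` columns: tau_s, peak_um, peak_se, area, area_se, sigma_um, r2,
    ok (bool; lags with failed or poor fits are flagged, not fatal).
    """

    xi_um: np.ndarray
    tau_s: np.ndarray
    C: np.ndarray  # (n_xi, n_tau)
    fits: pd.DataFrame


@dataclass
class FcsDensityResult:
    """Mean labeled-motor number and derived densities from FCS."""

    n_labeled: float
    n_labeled_se: float
    labeled_density: float  # motors/um
    total_density: float  # motors/um (scaled by total/labeled concentration)
    total_density_se: float
    segment_length_um: float
    scaling: float


@dataclass
class MotilityEstimates:
    """Correlation-imaging observables for one microtubule segment."""

    velocity: float
    velocity_se: float
    run_length: float
    run_length_se: float
    detachment_rate: float
    detachment_rate_se: float
    density: Optional[float] = None
    density_se: Optional[float] = None
    segment_length_um: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def background_subtract(kymo: KymographData) -> KymographData:
    """Subtract the per-frame off-axis background mean from every row.

    Negative residuals are kept (not clipped) so fluctuation statistics stay
    unbiased.
    """
    if kymo.background_mean is None:
        raise CorrelationError("kymograph has no background-band statistics")
    out = replace(
        kymo,
        intensity=kymo.intensity - kymo.background_mean[None, :],
        background_subtracted=True,
    )
    return out


def temporal_acf(kymo: KymographData, max_lag_frames: int = 10) -> TemporalACF:
    """Normalized ACF G(tau) of F(t) = sum_x I(x, t)."""
    F = kymo.intensity.sum(axis=0)
    mean_f = F.mean()
    if abs(mean_f) < 1e-12 or abs(mean_f) < 1e-6 * np.abs(F).max():
        raise CorrelationError("mean intensity is ~0; cannot normalize ACF")
    dF = F - mean_f
    n = len(F)
    lags = np.arange(1, max_lag_frames + 1)
    vals = np.array([np.mean(dF[: n - L] * dF[L:]) for L in lags]) / mean_f**2
    return TemporalACF(lags_s=lags * kymo.frame_interval_s, values=vals, n_frames=n)


def fcs_density(
    kymo: KymographData,
    labeled_conc: float,
    total_conc: float,
) -> FcsDensityResult:
    """Motor density on the segment from intensity-fluctuation statistics.

    N = 1/G(0+), with G(0+) the zero-lag intercept of a straight line
    through G at lags of 1, 2 and 3 frames (the lag-0 point is skipped
    because uncorrelated shot noise inflates it).  The labeled density
    N/segment_length is scaled by total_conc/labeled_conc to the total
    motor density.  Concentrations may be in any common unit.
    """
    if not (total_conc >= labeled_conc > 0):
        raise ValueError("need total_conc >= labeled_conc > 0")
    if not kymo.background_subtracted:
        raise CorrelationError("fcs_density requires a background-subtracted kymograph")

    def _g0(intensity: np.ndarray) -> float:
        F = intensity.sum(axis=0)
        mean_f = F.mean()
        if abs(mean_f) < 1e-12:
            return np.nan
        dF = F - mean_f
        n = len(F)
        vals = np.array([np.mean(dF[: n - L] * dF[L:]) for L in (1, 2, 3)]) / mean_f**2
        fit = sm.OLS(vals, sm.add_constant(np.array([1.0, 2.0, 3.0]))).fit()
        return float(fit.params[0])

    g0 = _g0(kymo.intensity)
    # the short-lag extrapolation understates the record-to-record noise of
    # a correlated time series, so the SE comes from block subsampling
    n_blocks = 5
    edges = np.linspace(0, kymo.intensity.shape[1], n_blocks + 1).astype(int)
    blocks = [
        _g0(kymo.intensity[:, a:b]) for a, b in zip(edges[:-1], edges[1:]) if b - a > 10
    ]
    blocks = [b for b in blocks if np.isfinite(b)]
    if len(blocks) >= 3:
        g0_se = float(np.std(blocks, ddof=1) / math.sqrt(len(blocks)))
    else:
        g0_se = abs(g0)
    if g0 <= 0:
        raise CorrelationError(
            f"no fluctuation signal: extrapolated G(0+) = {g0:.3g} <= 0"
        )
    n_labeled = 1.0 / g0
    n_se = g0_se / g0**2
    seg = kymo.segment_length_um
    scaling = total_conc / labeled_conc
    labeled_density = n_labeled / seg
    return FcsDensityResult(
        n_labeled=n_labeled,
        n_labeled_se=n_se,
        labeled_density=labeled_density,
        total_density=labeled_density * scaling,
        total_density_se=n_se / seg * scaling,
        segment_length_um=seg,
        scaling=scaling,
    )


def _gauss_offset(x, a, mu, sig, c):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c


def _fit_gaussian_lag(xi, c, idx, window_px=10, r2_min=0.8):
    """Gaussian + offset fit in a window around ``idx``; one re-centered refit."""
    for _ in range(2):
        lo, hi = max(idx - window_px, 0), min(idx + window_px + 1, len(xi))
        xw, yw = xi[lo:hi], c[lo:hi]
        a0 = float(yw.max() - yw.min())
        p0 = [a0 if a0 > 0 else 1.0, xi[idx], 2.0 * (xi[1] - xi[0]), float(yw.min())]
        try:
            popt, pcov = optimize.curve_fit(
                _gauss_offset,
                xw,
                yw,
                p0=p0,
                bounds=(
                    [0.0, xw[0], 0.2 * (xi[1] - xi[0]), -np.inf],
                    [np.inf, xw[-1], (xw[-1] - xw[0]), np.inf],
                ),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            return None
        new_idx = int(np.argmin(np.abs(xi - popt[1])))
        if new_idx == idx:
            break
        idx = new_idx
    resid = yw - _gauss_offset(xw, *popt)
    ss_tot = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    a, mu, sig, _ = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    area = a * sig * math.sqrt(2.0 * math.pi)
    # area SE including amplitude-width covariance
    j = np.array([sig, 0.0, a, 0.0]) * math.sqrt(2.0 * math.pi)
    area_var = float(j @ pcov @ j)
    return {
        "peak_um": float(mu),
        "peak_se": float(perr[1]),
        "area": float(area),
        "area_se": math.sqrt(max(area_var, 0.0)),
        "sigma_um": float(sig),
        "r2": r2,
        "ok": r2 >= r2_min,
    }


def spatiotemporal_correlation(
    kymo: KymographData,
    max_lag: float = 10.0,
    window_px: int = 10,
    r2_min: float = 0.8,
) -> CorrelationSurface:
    """Correlate intensity fluctuations in space and time, pixel by pixel.

    C(xi, tau) = mean over valid (x, t) of dI(x, t) dI(x+xi, t+tau), with no
    wraparound and each (xi, tau) normalized by its overlap count; dI is the
    per-position temporal fluctuation.  A Gaussian + offset is fitted to
    every time-lag cross section.
    """
    n_x, n_t = kymo.intensity.shape
    if n_t < 100:
        raise CorrelationError("need at least 100 frames for the correlation surface")
    dt = kymo.frame_interval_s
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames > 0.2 * n_t:
        raise CorrelationError("max_lag exceeds 20% of the record length")
    dI = kymo.intensity - kymo.intensity.mean(axis=1, keepdims=True)

    nfft = int(2 ** np.ceil(np.log2(2 * n_x - 1)))
    taus = np.arange(0, max_lag_frames + 1)
    xi_px = np.arange(-(n_x - 1), n_x)
    C = np.empty((len(xi_px), len(taus)))
    counts_x = n_x - np.abs(xi_px)
    for j, L in enumerate(taus):
        A = dI[:, : n_t - L]
        B = dI[:, L:] if L > 0 else dI
        FA = np.fft.rfft(A, nfft, axis=0)
        FB = np.fft.rfft(B, nfft, axis=0)
        cc = np.fft.irfft((np.conj(FA) * FB).sum(axis=1), nfft)
        # cc[k] = sum_x A[x] B[x+k]; negative lags wrap to the tail
        full = np.concatenate([cc[nfft - (n_x - 1):], cc[:n_x]])
        C[:, j] = full / (counts_x * (n_t - L))

    px_um = kymo.pixel_size_um
    xi_um = xi_px * px_um
    rows = []
    # track the peak from xi = 0 outward: the physical correlation maximum
    # moves continuously with lag, so each lag's search window is centered
    # on the previous accepted peak (robust against spurious side maxima in
    # the low-overlap wings of the lag axis)
    prev_idx = n_x - 1  # xi = 0
    for j, L in enumerate(taus):
        lo = max(prev_idx - window_px, 0)
        hi = min(prev_idx + window_px + 1, len(xi_px))
        idx = lo + int(np.argmax(C[lo:hi, j]))
        res = _fit_gaussian_lag(xi_um, C[:, j], idx, window_px=window_px, r2_min=r2_min)
        if res is not None and res["ok"]:
            prev_idx = int(np.argmin(np.abs(xi_um - res["peak_um"])))
        if res is None:
            res = {
                "peak_um": np.nan,
                "peak_se": np.nan,
                "area": np.nan,
                "area_se": np.nan,
                "sigma_um": np.nan,
                "r2": np.nan,
                "ok": False,
            }
        res["tau_s"] = L * dt
        rows.append(res)
    fits = pd.DataFrame(rows)[
        ["tau_s", "peak_um", "peak_se", "area", "area_se", "sigma_um", "r2", "ok"]
    ]
    return CorrelationSurface(xi_um=xi_um, tau_s=taus * dt, C=C, fits=fits)


def extract_velocity_runlength(surface: CorrelationSurface) -> MotilityEstimates:
    """Velocity, detachment rate and run length from the per-lag fits.

    Velocity: weighted least-squares line through x_p(tau) over accepted
    lags tau > 0.  Detachment rate: nonlinear exponential fit of A(tau)
    (with a semi-log linear fit reported as a diagnostic).  Run length =
    velocity / detachment rate.  A non-decaying area curve flags the run
    length as undetermined (infinite) rather than negative.
    """
    f = surface.fits
    good = f[(f["ok"]) & (f["tau_s"] > 0)]
    if len(good) < 5:
        raise CorrelationError(
            f"only {len(good)} accepted Gaussian fits at tau > 0; need >= 5"
        )
    tau = good["tau_s"].to_numpy()
    peak = good["peak_um"].to_numpy()
    w = 1.0 / np.clip(good["peak_se"].to_numpy(), 1e-6, np.inf) ** 2
    X = sm.add_constant(tau)
    wls = sm.WLS(peak, X, weights=w).fit()
    v = float(wls.params[1])
    v_se = float(wls.bse[1])

    area = good["area"].to_numpy()
    area_se = np.clip(good["area_se"].to_numpy(), 1e-12, np.inf)
    pos = area > 0
    semilog_slope = np.nan
    if pos.sum() >= 3:
        semilog_slope = float(np.polyfit(tau[pos], np.log(area[pos]), 1)[0])
    k0 = -semilog_slope if np.isfinite(semilog_slope) and semilog_slope < 0 else 0.1
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, a0, k: a0 * np.exp(-k * t),
            tau,
            area,
            p0=[float(area[0]), k0],
            sigma=area_se,
            absolute_sigma=False,
            maxfev=5000,
        )
        k = float(popt[1])
        k_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    except (RuntimeError, ValueError):
        k, k_se = np.nan, np.nan

    diagnostics = {
        "velocity_r2": float(wls.rsquared),
        "semilog_decay_rate": -semilog_slope if np.isfinite(semilog_slope) else np.nan,
        "n_lags_used": int(len(good)),
        "n_lags_rejected": int((~f["ok"]).sum()),
    }
    # less than ~10% decay over the observed lags: the rate is not
    # constrained by the data, so report undetermined rather than a huge
    # spurious run length
    if not np.isfinite(k) or k <= 0 or k * float(tau.max()) < 0.1:
        warnings.warn("correlation area does not decay; run length undetermined", stacklevel=2)
        return MotilityEstimates(
            velocity=v,
            velocity_se=v_se,
            run_length=math.inf,
            run_length_se=math.nan,
            detachment_rate=max(k, 0.0) if np.isfinite(k) else math.nan,
            detachment_rate_se=k_se,
            diagnostics={**diagnostics, "run_length_undetermined": True},
        )
    rl = v / k
    rl_se = abs(rl) * math.sqrt((v_se / v) ** 2 + (k_se / k) ** 2) if v != 0 else math.nan
    return MotilityEstimates(
        velocity=v,
        velocity_se=v_se,
        run_length=rl,
        run_length_se=rl_se,
        detachment_rate=k,
        detachment_rate_se=k_se,
        diagnostics=diagnostics,
    )


def analyze_kymograph(
    kymo: KymographData,
    labeled_conc: Optional[float] = None,
    total_conc: Optional[float] = None,
    max_lag: float = 10.0,
) -> MotilityEstimates:
    """Full correlation-imaging pipeline on one kymograph.

    Background-subtracts (if not already done), runs the spatiotemporal
    correlation and, when concentrations are given, the FCS density.
    """
    if not kymo.background_subtracted:
        kymo = background_subtract(kymo)
    surface = spatiotemporal_correlation(kymo, max_lag=max_lag)
    est = extract_velocity_runlength(surface)
    if labeled_conc is not None and total_conc is not None:
        dens = fcs_density(kymo, labeled_conc, total_conc)
        est = replace(
            est,
            density=dens.total_density,
            density_se=dens.total_density_se,
            segment_length_um=dens.segment_length_um,
        )
    return est
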