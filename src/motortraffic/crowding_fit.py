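"""Staged inference of crowding parameters from concentration series.

Stage 1 uses the low-concentration linear regime, where density, velocity
and run length are linear in bulk concentration: the through-origin slope
of density vs concentration gives the volumetric affinity omega_A0 (via the
per-site attachment convention of :mod:`motortraffic.lattice_sim`), the
velocity and run-length plateaus give omega_D = v0/RL0, and the step
frequency is v0/motor_step.

Stage 2 grid-searches the crowding parameters — number of accessible lanes
(1-13), interaction range (0-20 motor sizes) and the constrained/free
detachment ratio omega_DC/omega_D (0-10) — by simulating a predicted
concentration series for every triple and scoring an SE-weighted squared
residual on log-transformed observables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice_sim import (
    EstimationError,
    KineticParams,
    LatticeConfig,
    nM_to_per_um3,
    simulate,
    summarize,
)

__all__ = [
    "SERIES_COLUMNS",
    "Stage1Rates",
    "FitResult",
    "validate_series",
    "fit_low_density",
    "predict_series",
    "grid_search_fit",
]

SERIES_COLUMNS = [
    "conc_nM",
    "density",
    "density_se",
    "velocity",
    "velocity_se",
    "runlength",
    "runlength_se",
]


@dataclass(frozen=True)
class Stage1Rates:
    """Low-density (linear-regime) kinetic rates with standard errors."""

    omega_A0: float  # um^3/s
    omega_A0_se: float
    omega_D: float  # s^-1
    omega_D_se: float
    step_rate: float  # s^-1
    step_rate_se: float
    v0: float  # um/s
    run_length0: float  # um


@dataclass
class FitResult:
    """Output of the staged fit: stage-1 rates plus the best grid triple."""

    stage1: Stage1Rates
    n_lanes: int
    interaction_range: int
    ratio: float  # omega_DC / omega_D
    loss: float
    loss_table: pd.DataFrame
    seed: int

    @property
    def params(self) -> KineticParams:
        return KineticParams(
            step_rate=self.stage1.step_rate,
            omega_A0=self.stage1.omega_A0,
            omega_D=self.stage1.omega_D,
            omega_DC=self.ratio * self.stage1.omega_D,
            n_lanes=self.n_lanes,
            interaction_range=self.interaction_range,
        )


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check the concentration-series schema and basic invariants."""
    missing = [c for c in SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"series is missing columns: {missing}")
    if (series["conc_nM"] <= 0).any():
        raise ValueError("concentrations must be > 0")
    if series["conc_nM"].nunique() < 3:
        raise ValueError("need at least 3 distinct concentrations")
    return series[SERIES_COLUMNS].sort_values("conc_nM").reset_index(drop=True)


def fit_low_density(
    series: pd.DataFrame,
    params_template: KineticParams,
    curvature_tol: float = 0.3,
) -> Stage1Rates:
    """Stage-1 rates from the low-concentration linear regime.

    Refuses (with the admissible concentration range named) if the density
    vs concentration relation shows relative curvature beyond
    ``curvature_tol`` at the highest concentration supplied.
    """
    s = validate_series(series)
    c_um3 = nM_to_per_um3(s["conc_nM"].to_numpy())
    dens = s["density"].to_numpy()
    w_d = 1.0 / np.clip(s["density_se"].to_numpy(), 1e-12, np.inf) ** 2
    if np.all(dens <= 0):
        raise EstimationError("zero-density series: nothing to fit")

    # curvature test: weighted fit of d = a*c + b*c^2; refuse only when the
    # quadratic term is both large (relative to the linear term at the top
    # of the range) and statistically significant given the supplied SEs
    X = np.column_stack([c_um3, c_um3**2])
    W = np.diag(w_d)
    xtwx = X.T @ W @ X
    beta, *_ = np.linalg.lstsq(xtwx, X.T @ W @ dens, rcond=None)
    a, b = beta
    try:
        b_se = math.sqrt(np.linalg.inv(xtwx)[1, 1])
    except np.linalg.LinAlgError:
        b_se = np.inf
    rel_curv = abs(b) * c_um3.max() / abs(a) if a != 0 else np.inf
    if rel_curv > curvature_tol and b < 0 and abs(b) > 2.0 * b_se:
        c_ok = curvature_tol * abs(a / b) if b != 0 else np.inf
        raise EstimationError(
            "density vs concentration is not linear over the supplied range "
            f"(relative curvature {rel_curv:.2f}); restrict to <= "
            f"{c_ok / nM_to_per_um3(1.0):.0f} nM"
        )

    # through-origin slope (um^2)
    slope = float(np.sum(w_d * c_um3 * dens) / np.sum(w_d * c_um3**2))
    slope_se = float(1.0 / math.sqrt(np.sum(w_d * c_um3**2)))

    w_v = 1.0 / np.clip(s["velocity_se"].to_numpy(), 1e-12, np.inf) ** 2
    v0 = float(np.average(s["velocity"], weights=w_v))
    v0_se = float(1.0 / math.sqrt(w_v.sum()))
    w_r = 1.0 / np.clip(s["runlength_se"].to_numpy(), 1e-12, np.inf) ** 2
    rl0 = float(np.average(s["runlength"], weights=w_r))
    rl0_se = float(1.0 / math.sqrt(w_r.sum()))
    if rl0 <= 0 or v0 <= 0:
        raise EstimationError("non-positive low-density velocity or run length")

    omega_d = v0 / rl0
    omega_d_se = omega_d * math.sqrt((v0_se / v0) ** 2 + (rl0_se / rl0) ** 2)
    step_um = params_template.motor_step_um
    step_rate = v0 / step_um
    step_rate_se = v0_se / step_um
    omega_a0 = slope * omega_d * step_um / params_template.n_lanes
    omega_a0_se = omega_a0 * math.sqrt(
        (slope_se / slope) ** 2 + (omega_d_se / omega_d) ** 2
    )
    return Stage1Rates(
        omega_A0=omega_a0,
        omega_A0_se=omega_a0_se,
        omega_D=omega_d,
        omega_D_se=omega_d_se,
        step_rate=step_rate,
        step_rate_se=step_rate_se,
        v0=v0,
        run_length0=rl0,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def predict_series(
    params: KineticParams,
    concentrations_nM: Sequence[float],
    reps: int = 3,
    seed: int = 0,
    lattice_length: float = 8.0,
    duration: float = 60.0,
    burn_in: Optional[float] = None,
) -> pd.DataFrame:
    """Model-predicted concentration series by direct simulation.

    Runs ``reps`` replicate simulations per concentration (common seed
    derivation, so repeated calls are reproducible) and averages the
    summarized observables.  Per-point failures are recorded as NaN and the
    sweep continues.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    concs = list(concentrations_nM)
    seeds = _child_seeds(seed, len(concs) * reps).reshape(len(concs), reps)
    rows = []
    for i, c_nm in enumerate(concs):
        vals = {"density": [], "velocity": [], "runlength": []}
        ses = {"density": [], "velocity": [], "runlength": []}
        for r in range(reps):
            cfg = LatticeConfig(
                lattice_length=lattice_length,
                duration=duration,
                concentration=nM_to_per_um3(c_nm),
                burn_in=burn_in,
                seed=int(seeds[i, r]),
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ts = simulate(params, cfg)
                    obs = summarize(ts, min_uncensored=10)
            except EstimationError as exc:
                if ts.n_runs == 0:
                    # nothing ever bound: density is exactly zero
                    vals["density"].append(0.0)
                    ses["density"].append(0.0)
                else:
                    warnings.warn(f"point {c_nm} nM rep {r} failed: {exc}", stacklevel=2)
                continue
            vals["density"].append(obs.density)
            vals["velocity"].append(obs.velocity)
            vals["runlength"].append(obs.run_length)
            ses["density"].append(obs.density_se)
            ses["velocity"].append(obs.velocity_se)
            ses["runlength"].append(obs.run_length_se)
        row = {"conc_nM": c_nm}
        for k in ("density", "velocity", "runlength"):
            if vals[k]:
                row[k] = float(np.mean(vals[k]))
                within = float(np.mean(ses[k])) / math.sqrt(len(vals[k]))
                between = (
                    float(np.std(vals[k], ddof=1)) / math.sqrt(len(vals[k]))
                    if len(vals[k]) > 1
                    else 0.0
                )
                row[f"{k}_se"] = max(within, between)
            else:
                row[k] = np.nan
                row[f"{k}_se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)[SERIES_COLUMNS]


def grid_search_fit(
    observed: pd.DataFrame,
    stage1: Stage1Rates,
    lanes_grid: Sequence[int] = tuple(range(1, 14)),
    range_grid: Sequence[int] = tuple(range(0, 21)),
    ratio_grid: Sequence[float] = tuple(range(0, 11)),
    reps: int = 3,
    seed: int = 0,
    lattice_length: float = 8.0,
    duration: float = 60.0,
    params_template: Optional[KineticParams] = None,
) -> FitResult:
    """Stage-2 grid search over (n_lanes, interaction_range, omega_DC/omega_D).

    For every triple a predicted series at the observed concentrations is
    simulated and scored with an SE-weighted squared residual on
    log-transformed observables (zeros offset by the smallest positive SE).
    Ties break toward smaller n_lanes, then range, then ratio; common seeds
    across triples reduce comparison noise.
    """
    obs = validate_series(observed)
    lanes_grid = sorted(set(int(x) for x in lanes_grid))
    range_grid = sorted(set(int(x) for x in range_grid))
    ratio_grid = sorted(set(float(x) for x in ratio_grid))
    if not lanes_grid or not range_grid or not ratio_grid:
        raise ValueError("empty parameter grid")
    if lanes_grid[0] < 1 or lanes_grid[-1] > 13:
        raise ValueError("n_lanes grid must lie in [1, 13]")
    if range_grid[0] < 0 or range_grid[-1] > 20:
        raise ValueError("interaction_range grid must lie in [0, 20]")
    if ratio_grid[0] < 0 or ratio_grid[-1] > 10:
        raise ValueError("omega_DC/omega_D grid must lie in [0, 10]")
    template = params_template or KineticParams()

    eps = {}
    for k in ("density", "velocity", "runlength"):
        se = obs[f"{k}_se"].to_numpy()
        pos = se[se > 0]
        eps[k] = float(pos.min()) if pos.size else 1e-6

    concs = obs["conc_nM"].tolist()
    rows = []
    best = None
    for lanes in lanes_grid:
        for rng in range_grid:
            for ratio in ratio_grid:
                with warnings.catch_warnings():
                    # ratio < 1 triples legitimately probe omega_DC < omega_D
                    warnings.simplefilter("ignore")
                    params = replace(
                        template,
                        step_rate=stage1.step_rate,
                        omega_A0=stage1.omega_A0,
                        omega_D=stage1.omega_D,
                        omega_DC=ratio * stage1.omega_D,
                        n_lanes=lanes,
                        interaction_range=rng,
                    )
                    pred = predict_series(
                        params,
                        concs,
                        reps=reps,
                        seed=seed,
                        lattice_length=lattice_length,
                        duration=duration,
                    )
                loss = 0.0
                for k in ("density", "velocity", "runlength"):
                    y = obs[k].to_numpy() + eps[k]
                    p = pred[k].to_numpy() + eps[k]
                    se = np.clip(obs[f"{k}_se"].to_numpy(), eps[k], np.inf)
                    ok = np.isfinite(p) & (p > 0) & (y > 0)
                    rel_se = se[ok] / y[ok]  # SE on the log scale
                    loss += float(np.sum(((np.log(y[ok]) - np.log(p[ok])) / rel_se) ** 2))
                    loss += 1e6 * int((~ok).sum())  # failed points penalize
                rows.append(
                    {"n_lanes": lanes, "interaction_range": rng, "ratio": ratio, "loss": loss}
                )
                if best is None or loss < best[0]:
                    best = (loss, lanes, rng, ratio)
    loss_table = pd.DataFrame(rows)
    assert best is not None
    return FitResult(
        stage1=stage1,
        n_lanes=best[1],
        interaction_range=best[2],
        ratio=best[3],
        loss=best[0],
        loss_table=loss_table,
        seed=seed,
    )
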