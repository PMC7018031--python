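"""Multi-lane TASEP-LK simulation of motor traffic on microtubules.

The model: each protofilament of a microtubule is an independent 1-D lattice
("lane") with a lattice constant equal to the motor step (8 nm).  A motor
occupies ``motor_size / motor_step`` consecutive sites, attaches anywhere a
full footprint is empty at rate ``omega_A0 * c`` per site (c the bulk motor
concentration), steps forward one site at the stepping rate provided the
target sites are empty and the gap to the motor ahead stays at least
``interaction_range`` motor sizes, and detaches at ``omega_D`` when free to
step or at the elevated rate ``omega_DC`` when its step is blocked
("constrained").  Motors never pass each other and never change lanes.

Time evolution is an exact continuous-time kinetic Monte Carlo
(Gillespie-type with rejection; see :mod:`motortraffic._kmc`), so there is
no time-discretization bias and a fixed seed reproduces the event sequence
bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kmc

__all__ = [
    "KineticParams",
    "LatticeConfig",
    "RunRecord",
    "TrajectorySet",
    "SimObservables",
    "LowDensityLimits",
    "simulate",
    "summarize",
    "analytic_low_density",
    "mean_field_velocity",
    "nM_to_per_um3",
    "per_um3_to_nM",
    "SimulationError",
    "EstimationError",
]

#: motors/um^3 per nM (Avogadro: 1 nmol/L = 0.6022 um^-3)
MOTORS_PER_UM3_PER_NM = 0.6022


class SimulationError(RuntimeError):
    """Raised for invalid simulation configurations or kernel failures."""


class EstimationError(RuntimeError):
    """Raised when observables cannot be estimated from a trajectory set."""


def nM_to_per_um3(conc_nM: float) -> float:
    """Convert a bulk concentration from nM to motors/um^3."""
    return conc_nM * MOTORS_PER_UM3_PER_NM


def per_um3_to_nM(conc: float) -> float:
    """Convert a bulk concentration from motors/um^3 to nM."""
    return conc / MOTORS_PER_UM3_PER_NM


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and geometric parameters of the lattice gas.

    Defaults are the kinesin-II parameter set in PEM12 buffer: 16 nm motor
    footprint, 8 nm steps at 37.5 s^-1 (0.3 um/s), volumetric affinity
    1.53e-4 um^3/s, detachment 0.25 s^-1 (0.75 s^-1 when blocked), 13
    accessible protofilaments and zero interaction range beyond the
    footprint.
    """

    motor_size: float = 16.0  # nm occupied on a protofilament
    motor_step: float = 8.0  # nm advanced per step
    step_rate: float = 37.5  # s^-1
    omega_A0: float = 1.53e-4  # um^3/s, attachment = omega_A0 * c per site
    omega_D: float = 0.25  # s^-1, unconstrained detachment
    omega_DC: float = 0.75  # s^-1, constrained (blocked) detachment
    n_lanes: int = 13
    interaction_range: int = 0  # in units of motor sizes

    def __post_init__(self) -> None:
        for name in ("step_rate", "omega_A0", "omega_D", "omega_DC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motor_size <= 0 or self.motor_step <= 0:
            raise ValueError("motor_size and motor_step must be positive")
        ratio = self.motor_size / self.motor_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("motor_size must be an integer multiple of motor_step")
        if not 1 <= self.n_lanes <= 13:
            raise ValueError("n_lanes must be in 1..13")
        if self.interaction_range < 0:
            raise ValueError("interaction_range must be >= 0")
        if self.omega_DC < self.omega_D:
            warnings.warn(
                "omega_DC < omega_D: constrained motors detach more slowly "
                "than free ones",
                stacklevel=2,
            )

    @property
    def footprint_sites(self) -> int:
        """Number of lattice sites covered by one motor."""
        return round(self.motor_size / self.motor_step)

    @property
    def motor_step_um(self) -> float:
        return self.motor_step / 1000.0


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, boundary condition and reservoir coupling of one run.

    ``concentration`` is in motors/um^3 (use :func:`nM_to_per_um3` at the
    boundary).  ``n_fixed_motors`` seeds that many motors per lane at t=0,
    evenly spaced; combined with ``boundary='ring'`` and
    ``langmuir_enabled=False`` this gives the closed fixed-N ensemble.
    ``burn_in=None`` resolves to max(5/omega_D, lattice_length/v0).
    """

    lattice_length: float  # um
    duration: float  # s
    concentration: float = 0.0  # motors/um^3
    boundary: str = "open"  # 'open' | 'ring'
    langmuir_enabled: bool = True
    burn_in: Optional[float] = None
    snapshot_interval: Optional[float] = None
    n_fixed_motors: int = 0  # per lane, placed at t=0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_length <= 0:
            raise SimulationError("lattice_length must be positive")
        if self.duration <= 0:
            raise SimulationError("duration must be positive")
        if self.boundary not in ("open", "ring"):
            raise SimulationError("boundary must be 'open' or 'ring'")
        if self.burn_in is not None and not 0 <= self.burn_in < self.duration:
            raise SimulationError("need duration > burn_in >= 0")
        if self.concentration < 0:
            raise SimulationError("concentration must be >= 0")
        if self.n_fixed_motors < 0:
            raise SimulationError("n_fixed_motors must be >= 0")
        if self.langmuir_enabled and self.n_fixed_motors > 0 and self.boundary == "ring":
            raise SimulationError(
                "ring boundary with Langmuir kinetics and a fixed particle "
                "number are mutually exclusive modes"
            )

    def resolved_burn_in(self, params: KineticParams) -> float:
        if self.burn_in is not None:
            return self.burn_in
        terms = [0.0]
        if params.omega_D > 0:
            terms.append(5.0 / params.omega_D)
        v0 = params.motor_step_um * params.step_rate
        if v0 > 0:
            terms.append(self.lattice_length / v0)
        b = max(terms)
        return min(b, 0.5 * self.duration)


@dataclass(frozen=True)
class RunRecord:
    """One binding-to-unbinding episode of a single motor."""

    lane: int
    bind_time: float
    unbind_time: float
    bind_site: int
    unbind_site: int
    censored: bool

    def __post_init__(self) -> None:
        if self.unbind_time < self.bind_time:
            raise ValueError("unbind_time must be >= bind_time")
        if self.unbind_site < self.bind_site:
            raise ValueError("motion is unidirectional: unbind_site >= bind_site")


RUN_COLUMNS = ["lane", "bind_time_s", "unbind_time_s", "bind_site", "unbind_site", "censored"]
SNAPSHOT_COLUMNS = ["time_s", "lane", "site"]


@dataclass
class TrajectorySet:
    """Simulated binding/stepping/unbinding histories plus snapshots.

    ``runs`` is a DataFrame with columns ``lane, bind_time_s, unbind_time_s,
    bind_site, unbind_site, censored`` plus derived ``bind_x_um`` /
    ``unbind_x_um`` coordinates (front of the motor footprint).  ``snapshots``
    is long-format ``time_s, lane, site`` with one row per bound motor
    (front site) per snapshot time.
    """

    runs: pd.DataFrame
    snapshots: pd.DataFrame
    params: Optional[KineticParams] = None
    config: Optional[LatticeConfig] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def iter_runs(self):
        for r in self.runs.itertuples(index=False):
            yield RunRecord(
                int(r.lane),
                float(r.bind_time_s),
                float(r.unbind_time_s),
                int(r.bind_site),
                int(r.unbind_site),
                bool(r.censored),
            )

    def occupancy(self, snapshot_time: float) -> np.ndarray:
        """Boolean lane x site occupancy (full footprints) at one snapshot."""
        if self.params is None or self.config is None:
            raise ValueError("occupancy requires simulation params/config")
        foot = self.params.footprint_sites
        n_sites = _n_sites(self.params, self.config)
        occ = np.zeros((self.params.n_lanes, n_sites), dtype=bool)
        sel = self.snapshots[np.isclose(self.snapshots["time_s"], snapshot_time)]
        ring = self.config.boundary == "ring"
        for r in sel.itertuples(index=False):
            for j in range(foot):
                s = int(r.site) - j
                if ring:
                    s %= n_sites
                if 0 <= s < n_sites:
                    if occ[int(r.lane), s]:
                        raise AssertionError("overlapping footprints in snapshot")
                    occ[int(r.lane), s] = True
        return occ

    def mean_bound_count(self, t0: float = 0.0, t1: Optional[float] = None) -> float:
        """Time-averaged number of simultaneously bound motors on [t0, t1]."""
        if t1 is None:
            t1 = float(self.runs["unbind_time_s"].max()) if self.n_runs else 0.0
        if t1 <= t0:
            return 0.0
        lo = np.maximum(self.runs["bind_time_s"].to_numpy(), t0)
        hi = np.minimum(self.runs["unbind_time_s"].to_numpy(), t1)
        return float(np.clip(hi - lo, 0.0, None).sum() / (t1 - t0))


@dataclass(frozen=True)
class SimObservables:
    """Ensemble observables with standard errors.

    density: motors/um summed over lanes; velocity: um/s
    (displacement-weighted ensemble mean, Sum d / Sum t over runs);
    run_length: um (exponential MLE with censored runs as survival terms).
    """

    density: float
    density_se: float
    velocity: float
    velocity_se: float
    run_length: float
    run_length_se: float
    n_runs: int
    n_uncensored: int
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "density_per_um": self.density,
            "density_se": self.density_se,
            "velocity_um_s": self.velocity,
            "velocity_se": self.velocity_se,
            "run_length_um": self.run_length,
            "run_length_se": self.run_length_se,
            "n_runs": self.n_runs,
            "n_uncensored": self.n_uncensored,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LowDensityLimits:
    """Analytic dilute-limit observables."""

    v0: float  # um/s
    run_length: float  # um (inf if omega_D == 0)
    capacity_per_um_per_lane: int  # motors/um on one protofilament
    run_length_infinite: bool


def analytic_low_density(params: KineticParams) -> LowDensityLimits:
    """Dilute-limit velocity, run length and per-lane packing capacity.

    v0 = motor_step * step_rate; run length = v0 / omega_D; capacity =
    floor(1000 nm / motor_size) motors per micron of protofilament.
    """
    v0 = params.motor_step_um * params.step_rate
    if params.omega_D > 0:
        rl = v0 / params.omega_D
        inf_flag = False
    else:
        rl = math.inf
        inf_flag = True
    if params.step_rate == 0:
        rl, inf_flag = 0.0, False
    capacity = math.floor(1000.0 / params.motor_size)
    return LowDensityLimits(v0, rl, capacity, inf_flag)


def mean_field_velocity(params: KineticParams, covered_fraction: float) -> float:
    """Velocity if site occupation were uncorrelated: v0 * (1 - rho).

    ``covered_fraction`` is the fraction of lattice length covered by motor
    footprints on a lane.  At half occupancy this predicts a 50% drop; the
    simulated exclusion process with blocked-motor detachment decorrelates
    the occupancy and drops less.
    """
    if not 0 <= covered_fraction <= 1:
        raise ValueError("covered_fraction must be in [0, 1]")
    return analytic_low_density(params).v0 * (1.0 - covered_fraction)


def _n_sites(params: KineticParams, config: LatticeConfig) -> int:
    return max(int(round(config.lattice_length * 1000.0 / params.motor_step)), 1)


def simulate(params: KineticParams, config: LatticeConfig) -> TrajectorySet:
    """Run the exact event-driven simulation.

    Returns a :class:`TrajectorySet` with every binding-to-unbinding run
    (censored when the motor exits an open end or survives to the end of the
    observation window) and periodic occupancy snapshots.
    """
    n_sites = _n_sites(params, config)
    foot = params.footprint_sites
    ring = config.boundary == "ring"
    if config.n_fixed_motors * foot > n_sites:
        raise SimulationError("n_fixed_motors do not fit on the lattice")
    v0 = params.motor_step_um * params.step_rate
    if (
        config.boundary == "open"
        and params.omega_D > 0
        and v0 > 0
        and config.lattice_length < 5.0 * (params.step_rate / params.omega_D) * params.motor_step_um
    ):
        warnings.warn(
            "open lattice shorter than 5 mean run lengths: end-censoring "
            "will not be rare",
            stacklevel=2,
        )

    ka_site = params.omega_A0 * config.concentration
    duration = float(config.duration)
    snap_dt = config.snapshot_interval or duration / 25.0
    snap_times = np.arange(snap_dt, duration + 0.5 * snap_dt, snap_dt)
    snap_times = snap_times[snap_times <= duration]

    langmuir = bool(config.langmuir_enabled)
    r_att = ka_site * params.n_lanes * n_sites if langmuir else 0.0
    mean_attempts = r_att * duration
    max_m = (params.n_lanes * n_sites) // foot + 1
    run_cap = int(mean_attempts + 6.0 * math.sqrt(mean_attempts + 1.0)) + max_m + 64
    snap_cap = (len(snap_times) + 1) * max_m + 64

    run_lane = np.empty(run_cap, np.int64)
    run_bt = np.empty(run_cap, np.float64)
    run_ut = np.empty(run_cap, np.float64)
    run_bs = np.empty(run_cap, np.int64)
    run_us = np.empty(run_cap, np.int64)
    run_cens = np.empty(run_cap, np.uint8)
    snap_idx = np.empty(snap_cap, np.int64)
    snap_lane = np.empty(snap_cap, np.int64)
    snap_site = np.empty(snap_cap, np.int64)

    seed = int(config.seed) % (2**31)
    n_runs, n_snap, status = _kmc.run_kmc(
        seed,
        params.n_lanes,
        n_sites,
        foot,
        params.interaction_range * foot,
        float(params.step_rate),
        float(params.omega_D),
        float(params.omega_DC),
        float(ka_site),
        duration,
        ring,
        langmuir,
        int(config.n_fixed_motors),
        snap_times,
        run_lane,
        run_bt,
        run_ut,
        run_bs,
        run_us,
        run_cens,
        snap_idx,
        snap_lane,
        snap_site,
    )
    if status != _kmc.OK:
        raise SimulationError(f"kernel buffer overflow (status={status})")

    step_um = params.motor_step_um
    runs = pd.DataFrame(
        {
            "lane": run_lane[:n_runs],
            "bind_time_s": run_bt[:n_runs],
            "unbind_time_s": run_ut[:n_runs],
            "bind_site": run_bs[:n_runs],
            "unbind_site": run_us[:n_runs],
            "censored": run_cens[:n_runs].astype(bool),
        }
    )
    runs["bind_x_um"] = runs["bind_site"] * step_um
    runs["unbind_x_um"] = runs["unbind_site"] * step_um
    snapshots = pd.DataFrame(
        {
            "time_s": snap_times[snap_idx[:n_snap]],
            "lane": snap_lane[:n_snap],
            "site": snap_site[:n_snap],
        }
    )
    meta = {
        "seed": seed,
        "n_sites": n_sites,
        "footprint_sites": foot,
        "ka_per_site": ka_site,
        "burn_in_s": config.resolved_burn_in(params),
        "attachment_convention": "per 8-nm lattice site, full footprint must be empty",
        "snapshot_times": snap_times,
    }
    return TrajectorySet(runs=runs, snapshots=snapshots, params=params, config=config, meta=meta)


def summarize(trajectories: TrajectorySet, min_uncensored: int = 100) -> SimObservables:
    """Reduce a trajectory set to density, velocity and run length.

    Only runs that start after the burn-in enter the velocity and run-length
    estimates; density is the time average of the bound-motor count per
    micron (all lanes) over the post-burn-in window.  The run length is the
    maximum-likelihood mean of an exponential in which censored runs
    contribute survival terms: lambda = (sum of all lengths) / (number of
    uncensored runs).
    """
    params, config = trajectories.params, trajectories.config
    if params is None or config is None:
        raise EstimationError("summarize requires params/config on the TrajectorySet")
    burn = config.resolved_burn_in(params)
    duration = config.duration
    runs = trajectories.runs
    post = runs[runs["bind_time_s"] >= burn]
    n_unc = int((~post["censored"]).sum())
    if n_unc == 0:
        frac = float(post["censored"].mean()) if len(post) else float("nan")
        raise EstimationError(
            f"no uncensored runs after burn-in (censoring fraction {frac:.3f})"
        )
    if n_unc < min_uncensored:
        warnings.warn(
            f"only {n_unc} uncensored runs after burn-in; estimates will be noisy",
            stacklevel=2,
        )

    # velocity: displacement-weighted ensemble mean over all post-burn-in runs
    d = (post["unbind_x_um"] - post["bind_x_um"]).to_numpy()
    tt = (post["unbind_time_s"] - post["bind_time_s"]).to_numpy()
    tot_t = tt.sum()
    if tot_t <= 0:
        raise EstimationError("zero total attached time after burn-in")
    v = d.sum() / tot_t
    v_se = math.sqrt(np.sum((d - v * tt) ** 2)) / tot_t  # ratio-estimator SE

    # run length: exponential MLE with right censoring
    lam = d.sum() / n_unc
    lam_se = lam / math.sqrt(n_unc)

    # density: exact time average of bound count from run intervals,
    # SE from 10 batch means
    lo = np.maximum(runs["bind_time_s"].to_numpy(), burn)
    hi = np.minimum(runs["unbind_time_s"].to_numpy(), duration)
    window = duration - burn
    dens = np.clip(hi - lo, 0.0, None).sum() / window / config.lattice_length
    edges = np.linspace(burn, duration, 11)
    batch = []
    for a, b in zip(edges[:-1], edges[1:]):
        l_ = np.maximum(runs["bind_time_s"].to_numpy(), a)
        h_ = np.minimum(runs["unbind_time_s"].to_numpy(), b)
        batch.append(np.clip(h_ - l_, 0.0, None).sum() / (b - a) / config.lattice_length)
    dens_se = float(np.std(batch, ddof=1) / math.sqrt(len(batch)))

    return SimObservables(
        density=float(dens),
        density_se=dens_se,
        velocity=float(v),
        velocity_se=float(v_se),
        run_length=float(lam),
        run_length_se=float(lam_se),
        n_runs=len(post),
        n_uncensored=n_unc,
        seed=trajectories.meta.get("seed", config.seed),
    )
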