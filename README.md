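# motortraffic

Collective dynamics of motor proteins walking on microtubules, studied the
way the experiments are done: simulate crowded motor traffic, render it
into realistic TIRF image stacks, and recover motility parameters from the
images with correlation-based and single-particle analyses.

The package targets the crowding behaviour of heterodimeric kinesin-II
(the slow kinesin-2 that drives intraflagellar transport in *C. elegans*
cilia), but every stage is parameterized and reusable for other processive
motors.

## The model and the analyses

**Traffic model (TASEP-LK).** Each of up to 13 microtubule protofilaments
is an independent 1-D lattice with 8 nm sites. A motor occupies 16 nm
(2 sites), attaches wherever its footprint is empty at rate ω_A0·c per
site (c = bulk concentration), steps +8 nm at rate p = 37.5 s⁻¹ when the
site ahead is free, and detaches at ω_D = 0.25 s⁻¹ — or at the elevated
rate ω_DC = 3ω_D when its step is blocked by the motor in front
("constrained"). No passing, no lane changes. Time evolution is an exact
continuous-time kinetic Monte Carlo (numba-compiled), so a seed fixes the
event sequence bit for bit. Dilute-limit observables follow in closed
form: v₀ = 8 nm × 37.5 s⁻¹ = 0.3 μm/s, run length v₀/ω_D = 1.2 μm,
packing capacity ⌊1000/16⌋ = 62 motors/μm per protofilament.

**Synthetic imaging.** Trajectories (simulated, or from an exclusion-free
parametric generator) are rendered as diffraction-limited Gaussian spots
(σ = 130 nm) on 80 nm pixels, 200 ms exposures, with Poisson shot noise,
background, camera offset/gain, optional photobleaching and partial
labeling — emulating the experimental acquisition (1000-frame 16-bit TIFF
stacks).

**Correlation imaging** works on the kymograph I(x,t) of a microtubule
segment: the motor density comes from intensity-fluctuation statistics
(FCS: N = 1/G(0⁺)); the velocity from tracking the drifting peak of the
spatiotemporal correlation C(ξ,τ) with per-lag Gaussian fits (v = dx_p/dτ);
the run length from the exponential decay of the correlation-peak area
A(τ), run length = v / decay rate.

**Single-particle tracking** (for dilute data): 2-D Gaussian localization,
mutual-nearest-neighbour linking, mean-displacement-vs-lag velocity and a
cumulative run-length distribution fit.

**Staged fitting**: the low-concentration linear regime yields ω_A0, ω_D
and the step frequency; a grid search over (lanes 1–13, interaction range
0–20 motor sizes, ω_DC/ω_D 0–10) then matches simulated concentration
series to observed density/velocity/run-length curves.

## Worked example

```python
from motortraffic import (KineticParams, LatticeConfig, analytic_low_density,
                          simulate, summarize)

params = KineticParams()            # kinesin-II parameter set
lim = analytic_low_density(params)
print(f"dilute limits: v0 = {lim.v0} um/s, run length = {lim.run_length} um, "
      f"capacity = {lim.capacity_per_um_per_lane} motors/um/protofilament")

cfg = LatticeConfig(lattice_length=20.0, duration=600.0,
                    concentration=0.2,  # motors/um^3 (~0.33 nM)
                    seed=7)
obs = summarize(simulate(params, cfg))
print(f"simulated: density = {obs.density:.2f} motors/um, "
      f"velocity = {obs.velocity:.3f} +/- {obs.velocity_se:.3f} um/s, "
      f"run length = {obs.run_length:.2f} +/- {obs.run_length_se:.2f} um "
      f"({obs.n_uncensored} complete runs)")
```

prints

```
dilute limits: v0 = 0.3 um/s, run length = 1.2 um, capacity = 62 motors/um/protofilament
simulated: density = 0.18 motors/um, velocity = 0.300 +/- 0.001 um/s, run length = 1.20 +/- 0.05 um (485 complete runs)
```

i.e. at vanishing density the simulation reproduces the analytic dilute
limits; at high concentration the same pipeline produces the crowding
curves (density saturation, velocity and run-length decline).

A command-line pipeline wraps the stages
(`motortraffic simulate | render | kymo | analyze-corr | analyze-spt |
fit | series | demo`); every output directory carries a `manifest.json`
with the full configuration and seeds.

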