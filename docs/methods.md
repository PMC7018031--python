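# Methods

## Lattice model

The simulator implements a multi-lane totally asymmetric simple exclusion
process with Langmuir kinetics (TASEP-LK) and state-dependent detachment.
Geometry and rates (kinesin-II defaults in parentheses):

| parameter | meaning | default |
| --- | --- | --- |
| `motor_size` | length excluded on a protofilament | 16 nm |
| `motor_step` | lattice constant and step length | 8 nm |
| `step_rate` | forward hopping rate p | 37.5 s⁻¹ |
| `omega_A0` | volumetric affinity; attachment = ω_A0·c per site | 1.53×10⁻⁴ μm³/s |
| `omega_D` | detachment of unconstrained motors | 0.25 s⁻¹ |
| `omega_DC` | detachment of constrained (blocked) motors | 0.75 s⁻¹ |
| `n_lanes` | independent protofilaments | 13 |
| `interaction_range` | extra empty gap required ahead, in motor sizes | 0 |

Choices where the physical description leaves freedom:

* **Lattice mapping.** The lattice constant is the motor step (8 nm); a
  motor occupies `motor_size/motor_step` = 2 consecutive sites and steps by
  one site. This keeps the step length and the packing capacity
  (⌊1000/16⌋ = 62 motors/μm per protofilament) simultaneously correct.
* **Attachment convention.** Candidate binding positions are every 8-nm
  site on every lane; an attempt at rate ω_A0·c per position succeeds only
  if the whole footprint is empty. This convention fixes the calibration
  between ω_A0 and the dilute density slope, density/μm = ω_A0·c·n_lanes /
  (ω_D·motor_step), and is echoed in the output metadata.
* **Constrained = cannot step now.** A motor whose target sites (one step
  plus the interaction-range gap) are not all empty detaches at ω_DC
  *instead of* ω_D; the rates are not additive. `interaction_range = 0`
  reduces to plain hard-core exclusion.
* **Time evolution.** Exact continuous-time kinetic Monte Carlo with
  rejection: the total rate is bounded by attachment attempts everywhere
  plus (p + max(ω_D, ω_DC)) per bound motor; disallowed attempts are null
  events, which leaves the sampled process statistically exact while the
  bookkeeping stays O(1) per event. A fixed seed reproduces the event
  sequence bit for bit.
* **Boundaries.** Open lattices remove motors whose front passes the last
  site; such runs are censored and enter the run-length likelihood as
  survival terms only. Ring lattices (optionally with a fixed motor number
  and Langmuir kinetics off) exist for exact-oracle tests: the stationary
  measure of the closed footprint-1 ring process is uniform, giving
  velocity p(L−N)/(L−1), verified against brute-force enumeration.
* **Burn-in.** Default max(5/ω_D, lattice_length/v₀), capped at half the
  duration; discarded before all averaging.

Observables from a run set: density = time-averaged bound-motor count per
μm (batch-means SE); velocity = Σ displacements / Σ attached times over
runs (a displacement-weighted ensemble mean — the quantity image
correlation measures; ratio-estimator SE); run length = maximum-likelihood
mean of an exponential with right-censored runs as survival terms,
λ̂ = (Σ all lengths)/(number of uncensored runs), SE λ̂/√n.

Two dilute-limit values are in tension in the source parameter table: the
stated rates give v₀/ω_D = 0.3/0.25 = 1.2 μm, while the table also prints
a dilute run length of 1.14 μm that does not follow from the stated rules.
This package uses 1.2 μm (the value the imaging analyses report) as the
dilute-limit reference.

## Synthetic imaging

The renderer emulates the acquisition: 80 nm pixels, 200 ms exposures,
1000 frames, 16-bit digitization. Per frame each labeled, unbleached motor
contributes a pixel-integrated 2-D Gaussian (σ = 130 nm, an effective
diffraction limit for GFP emission at NA 1.49; the true PSF shape is not
modeled). Motion blur uses 10 sub-exposure positions; within a run motors
move at their run-mean velocity. Photon counts are Poisson per pixel
(signal + background), then offset/gain digitized; EMCCD excess noise is
not modeled. Defaults (800 photons/motor/frame over ~20 background
photons/pixel) give a peak-pixel SNR ≈ 6 for a single motor. The
microtubule is a straight segment; kymographs sample along it by bilinear
interpolation averaged over a configurable perpendicular width, with
background statistics from parallel off-axis bands.

The parametric trajectory generator (Poisson binding in space-time,
constant speed, exponential lifetimes, no exclusion) provides ground truth
that is independent of the lattice simulator, so each analysis stage is
testable in isolation.

What the synthetic data deliberately omits: microtubule curvature and
drift, TIRF evanescent-depth intensity profiles, sCMOS/EMCCD noise maps,
aggregates and inactive motors. Passing tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
every experimental artifact.

## Correlation imaging

All estimators act on background-subtracted kymographs I(x,t) (per-frame
off-axis mean subtracted; negative residuals kept).

* **Density (FCS).** F(t) = Σ_x I(x,t); G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩². The
  mean labeled-motor number is N = 1/G(0⁺), where G(0⁺) is the zero-lag
  intercept of a straight line through lags 1–3 frames — the lag-0 point
  is excluded because uncorrelated shot noise inflates it. The SE comes
  from block subsampling (5 blocks), because the 3-point extrapolation
  understates the record-to-record variance of a correlated series; a
  single 600-frame record still carries ~20–25% noise on N. Labeled
  density N/segment-length is scaled by total/labeled concentration.
* **Velocity.** C(ξ,τ) is the overlap-normalized correlation of δI (per-x
  temporal mean removed), computed by FFT over space, no wraparound. Per
  time lag a Gaussian + offset is fitted in a ±10 px window; the window is
  centred by *tracking* the peak from ξ=0 outward (each lag searches
  around the previous accepted peak), which rejects spurious side maxima
  in the low-overlap wings. Lags with R² < 0.8 are excluded. Velocity is
  the slope of a weighted least-squares line through x_p(τ), τ > 0;
  default maximum lag 10 s.
* **Run length.** The peak area A(τ) = amplitude·σ·√(2π) decays with the
  detachment rate; a nonlinear exponential fit (semi-log linear fit kept
  as a diagnostic) yields ω and run length = v/ω. If the fitted decay over
  the observed lag range is below 10%, the rate is unconstrained and the
  run length is flagged undetermined (∞) rather than reported as a huge or
  negative number. Photobleaching adds to the fitted decay (ω_eff ≈ ω_D +
  bleach rate); no automatic correction is applied — bleaching is simply
  off in the validation fixtures, matching experiments designed to
  minimize it. Motors drifting off the segment end add ~v/L to the decay
  (≈ 6% of ω_D on a 20 μm segment), a known small bias of the method.

## Single-particle tracking

Detection: per-frame local maxima above a threshold over the median
background, refined by 2-D Gaussian fits in 9×9 px windows with sanity
gates on amplitude, width and position. Linking: greedy
mutual-nearest-neighbour between consecutive frames within a gate
(default 0.4 μm/frame); no gap closing, merging or splitting — at
single-molecule densities these are rare, and this simplification is
deliberate. Tracks shorter than 5 frames (1 s) are discarded to keep noise
tracks out of the statistics.

Velocity: mean along-axis displacement per time lag over all track
segments, weighted line through the origin. Run length: net along-axis
track length fitted by the shifted exponential CDF
1 − exp(−(x − x_min)/λ) for x ≥ x_min (least squares on the empirical CDF,
bootstrap SE). Memorylessness of the exponential makes λ insensitive to
the observability cutoff x_min, which absorbs the minimum-track-length
bias; tracks touching the first/last frame or the segment end should be
excluded by the caller as censored.

## Staged fitting

Stage 1 (linear regime): ω_D = v₀/RL₀ from the velocity and run-length
plateaus; step frequency = v₀/motor_step; ω_A0 from the through-origin
density-vs-concentration slope via the attachment convention above. A
weighted quadratic curvature test refuses series that bend significantly
(relative curvature > 0.3 at the top concentration and quadratic term
> 2 SE), naming the admissible range. On finite open lattices the density
profile builds over ~one run length from the minus end, so ω_A0 recovered
from simulated series is biased low by roughly run-length/lattice-length
(~15% at 8 μm); ω_D and the step frequency are unaffected.

Stage 2 (grid search): over lanes 1–13, interaction range 0–20 motor
sizes, ω_DC/ω_D 0–10 (integer grids), each triple is scored by simulating
the concentration series (common seeds across triples, so comparisons use
common random numbers) and summing SE-weighted squared residuals of
log-transformed density, velocity and run length; zeros are offset by the
smallest positive SE, failed points carry a large penalty, and ties break
toward the smallest (lanes, range, ratio). Defaults for the embedded
simulations: 8 μm lattice (≈ 6.7 dilute run lengths, keeping
end-censoring modest), 60 s observation after an automatic burn-in,
2–3 replicates per point — sizes chosen so a full coarse grid runs in
minutes on one core while each point's SE stays a few percent.

## Crowding phenotype of the kinesin-II parameter set

With the default parameters the simulated blocked fraction f(ρ) follows
the footprint-2 exclusion relation v/v₀ = (1−2ρ̂)/(1−ρ̂) (ρ̂ = motors per
site), and because constrained motors detach at 3ω_D the effective
detachment is ω_D(1 + 2f): the relative run-length decline is ~3× the
velocity decline at any density. Measured on the predicted curves:
velocity −6% and run length −18% at ~110 motors/μm; velocity −14% and run
length −31% at ~210 motors/μm; at ~50% site coverage (≈400 motors/μm,
extrapolated) the velocity drop approaches one third — half of what
uncorrelated occupancy (v = v₀(1−ρ), the `mean_field_velocity` helper)
would predict. Consequently "both observables flat to within 10% up to
~200 motors/μm" is not a property this model can produce for the run
length; the acceptance test that encodes that band documents the
discrepancy by failing its run-length clause, and the qualitative
ordering (run length declining faster than velocity, both declining
beyond ~200 motors/μm) holds.

## Known limitations

* Lane changes (sidestepping), force dependence, torque and microtubule
  dynamics are out of scope by design.
* The FCS density estimator needs long records; on 1000-frame stacks a
  single segment carries ~20% noise, so replicate segments should be
  averaged (the acceptance script averages six).
* The correlation run length inherits small biases from segment-end exits
  and, if present, photobleaching.
* The greedy linker degrades above ~1 motor/μm; use correlation imaging
  there — that division of labour is the point of the package.
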