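# Methods

## Observation model

A confocal beam with a 3D Gaussian profile
`W(r) = exp(−2(x² + y²)/w0² − 2z²/wz²)` is rastered along a line of
`n_pixels` positions spaced `pixel_size` apart; the photon count at line
`l`, pixel `p` is Poisson with mean
`background + brightness · Σᵢ W(rᵢ − beam(l, p))`, summed over molecules.
Defaults mirror a fast commercial line scanner: 32 pixels of 100 nm,
6.3 µs pixel dwell, 0.473 ms line period (the difference is retrace dead
time), w0 = 0.25 µm, and an axial aspect κ = wz/w0 = 5, a typical
confocal value (only the radial waist is usually calibrated; κ is
configurable).  `brightness = 0.5` counts per molecule per dwell at the
beam center (≈ 80 kHz peak molecular brightness, a bright but realistic
GFP) and `background = 0.05` counts per dwell.  Molecule density defaults
to ~1 per focal volume `π^{3/2} w0² wz`.

## Brownian dynamics

Positions advance by isotropic Gaussian increments of standard deviation
√(2 D Δt) per axis — one step per pixel dwell while the beam is active
and one lumped step over the retrace.  This resolves intra-line
correlations at the µs scale without paying for finer integration; the
increments themselves are exact draws from the free propagator, so the
step size carries no discretization error in the diffusion law (verified
by the MSD = 2Dt property test).  Outer box walls reflect; periodic
wrapping would teleport molecules across the barrier.  Compartment
diffusivities `d_left` / `d_right` change at the barrier plane.

### The semi-permeable barrier

The nuclear-envelope analog is an infinitesimally thin plane.  A step
whose x-path crosses it is accepted with probability
`p_cross · σ_ref/σ_step`, else reflected.  The `1/σ_step` factor is
required for detailed balance: crossing *attempts* arrive at a rate
proportional to the step size on the attempting side, so a bare
per-attempt probability would pump molecules from the fast-D side into
the slow-D side (and make the dwell and retrace phases inequivalent).
With the scaling, equal concentrations give equal fluxes for any
`d_left/d_right`; the passive steady state is Keq = 1, as verified by
simulation.

Because per-attempt transmission still depends on the step schedule, the
physical permeability is imposed empirically: `mean_crossing_time` is a
brute-force first-passage oracle that walks 1-D trajectories with the
*same* step schedule as the scanner (censored walkers are reported, never
averaged in), and `calibrate_permeability` bisects log p_cross against it
until a target mean crossing time (e.g. 250 ms from 0.5 µm) is met within
10%.  A calibrated p_cross therefore transfers to the full simulation
exactly.  The workflow calibration runs in a standardized release
geometry (the scan-sized, 0.75 µm-pad box): first-passage times include
the time spent wandering the compartment, so in a deep reservoir free
diffusion alone would reach the target and the fitted barrier would be
transparent.  Standardizing the calibration box makes the target a
property of the barrier, and the transmission probability carries over
unchanged to the production geometry.

### Directional active transport

Carrier-mediated import is modeled minimally as a capture-and-release
channel: a molecule whose passive transmission failed and that sits on
the channel's source side is captured with probability `p_active`, held
for an exponentially distributed translocation dwell (default mean 5 ms),
and released just across the plane.  This produces the two experimental
signatures — a fast directional transit component and an asymmetric
steady state (Keq > 1 toward the destination side) — without claiming
any mechanistic pore model.  Disabling the channel is the energy-depletion
analog and restores symmetric, slow, passive-only exchange.

### The gap (impenetrable boundary) control

The gap between two adjacent cells is a fluorophore-free void: a slab of
configurable width whose faces reflect and transmit nothing.  Its width
also keeps each population outside the other's detection volume, which
matters — see "optical cross-talk" below.

### Box geometry for barrier experiments

Single-compartment carpets use a shallow box (0.75 µm beyond the scan
ends).  Two-compartment transit experiments deepen the box to 5 µm on
each side.  The reason is physical: a molecule that needs hundreds of
milliseconds to cross must still be *locally* enriched near the envelope
on arrival for a transit hump to exist.  In a shallow closed box the
crossing time exceeds the compartment mixing time, the arrival density
never overshoots its equilibrium value, and the hump cancels against the
closed-box occupancy anti-correlation (below).  A deep box restores the
reservoir-like geometry of a real cell.

## Correlation estimation

The estimator is `G(τ) = ⟨δF_a δF_b(τ)⟩ / (⟨F_a⟩_head ⟨F_b⟩_tail)` with
symmetric normalization (each segment normalized by its own mean), which
halves drift-induced bias on ~30 s segments.  Lags live on a multi-tau
grid in line-period units: 16 linear lags at full resolution, then 8 per
octave with factor-2 co-binning of both series, up to a quarter of the
record by default.  The `direct` scheme evaluates the identical estimator
(same grid, same binning) by single-pass binning and compensated (fsum)
summation and serves as the implementation oracle; on photon-count input
the two agree to < 1e-12.  The constant intra-line sampling offset
between columns (δ · pixel_dwell, well under a line period) is added to
reported lag values rather than resolved as extra grid points.  Negative
values are preserved — the short-lag anti-correlation dip is the
single-molecule signature of the method.

Stationarity QC cuts the record into windows and flags columns whose
windowed means span more than 20% of the grand mean (threshold
configurable; the default rejects bleaching-like drifts while passing
Poisson noise at realistic means, validated by Monte-Carlo).  Detrending
by moving-average division exists but is off by default; selecting
stationary segments is preferred.

## Fitting

Free 3D diffusion through the Gaussian volume gives
`G(τ) = (γ/N)(1 + 4Dτ/w0²)^{-1}(1 + 4Dτ/wz²)^{-1/2}`, and the two-focus
(pair) model multiplies this by `exp(−δr²/(w0² + 4Dτ))`.  The shape
factor is fixed at γ = 1: the paper-level readouts (D and peak delays)
are γ-independent and the amplitude is absorbed into the apparent N.
Fits are weighted least squares (inverse variance across contributing
columns when the curve is an average, else uniform), optimized in log
space for positivity, initialized from the first-lag amplitude and the
half-decay lag, converged to 1e-8 or flagged.  A two-component model is
available but never auto-selected.

Two corrections matter for *simulated* (closed-box) data and are applied
by the workflow fits:

* **Fixed-N baseline.**  A closed reservoir holding exactly N molecules
  adds a constant −1/N to every correlation (occupancy fluctuations are
  anti-correlated under the constraint Σnᵢ = N).  An optional additive
  baseline parameter absorbs it.  For cell data the reservoir is vast and
  the option stays off.
* **Decay-limited fit window.**  The window ends where the averaged curve
  first falls below 5% of its initial amplitude; beyond that the tail
  constrains only the baseline, and reflecting-wall effects distort lags
  where diffusion spans the box.

With both, D recovery on carpets at the reference conditions is unbiased
within the few-percent seed-to-seed scatter.

## Transit-delay readout and classification

The delay readout is never a model fit.  For sharp humps (intracompartment
diffusion, fast translocation) it is the position of the maximum of the
smoothed curve.  Barrier-crossing humps are different: the transit-time
distribution spans more than a decade, the hump top is flat, and its argmax
wanders between statistically equivalent bins — so cross-barrier delays are
read as the average position (in time) of the hump: the correlation-weighted
mean log-lag over the bins whose smoothed value exceeds its own standard
error (the gate keeps positive *noise* mass at the high-variance early lags
from dragging the centroid off the hump).  Smoothing is
Gaussian along the log-lag axis (σ = 2 bins), precision-weighted when the
curve carries per-lag standard errors, and the search starts at twice the
first lag to exclude the shot-noise/anti-correlation region.  Two entry
points separate two questions:

* `peak_delay` — unconditional readout (the hump position, however weak);
* `detect_peak` — the same readout gated by a significance threshold
  (peak amplitude over the standard error at the peak, or over a
  MAD-based noise scale from the earliest bins for single curves);
  significance < 3 means "no communication".  The 3σ default rejects
  ≥95% of pure-noise curves in the null Monte-Carlo.

Transit maps classify each origin column as `intra`,
`barrier_delayed` (peak delay more than 10× the median intra delay — a
threshold safely between intra scatter and the 40–100× ratios a tight
barrier produces), `no_communication`, or `unstable` (failed QC).  All
thresholds are recorded in the map.  The barrier index is the median
barrier-delayed over median intra delay; it is None (never a fake 1.0)
when either group is empty.

### Optical cross-talk at the barrier

Columns within ~1.5 beam waists of the barrier see molecules on the
*other* side through the PSF tail, producing fast correlations that have
nothing to do with crossing.  Cross-barrier delay readouts therefore drop
pairs whose origin or target lies within 0.4 µm of the barrier (the leak
amplitude falls as exp(−2d²/w0²), below a percent of G(0) at that
distance).  This is why the default cross-barrier separation is 14 pixels
on the 32-pixel scan: it leaves six usable origin columns outside the
margins on each side.

## Problem sizes and the multi-cell protocol

Default experiment sizes were chosen so each simulated record resembles
a single-cell acquisition while keeping a full pipeline run to minutes:
60 000 lines (~28 s) for compartment-D recovery, 200 000 point-scan
samples for the dye calibration, 100–400 first-passage replicates for
permeability calibration.  Cross-barrier delay experiments simulate
three independent ~30 s records (64 000 lines each) and average all
spanning curves across records before the single peak readout — the way
delays are read off multi-cell acquisitions.  Pooling independent
records is statistically equivalent to one record of the combined
length but keeps one atypical record (the cross-barrier hump carries
only a few hundred crossing events per record, so its shape fluctuates
strongly from record to record) from dictating the delay.

## Known limitations

* The barrier is a uniform permeable plane: there are no discrete pores,
  so the pore-distance dispersion of peak delays seen in cells is not
  modeled, and "single-pore" readouts are out of scope.
* No anomalous diffusion, no triplet/blinking photophysics, no bleaching
  (bleaching exists only as a QC failure mode, not a simulated process).
* The closed box makes the anti-correlation dip (−1/N) much stronger
  than in a cell, where N is enormous; tests of the dip exploit this
  rather than suffer from it, but absolute short-lag amplitudes should
  not be compared to cell data.
* The active channel is phenomenological; its translocation-dwell scale,
  not its mechanism, is the meaningful parameter.  At the default photon
  budget its fast pair-correlation component is at the edge of
  detectability: the channel itself depletes the cytoplasm ~9-fold, so the
  source columns are dim and the forward hump reaches only ~1 standard
  error even after pooling records.  The channel's direction and strength
  are unambiguous in the simulator's ground truth (crossing events and the
  realized concentration ratio), which is what the property tests assert.
* The 2D-limit peak-time formula (δr² − w0²)/4D is exact only for
  wz → ∞; the 3D peak sits slightly earlier (the numeric maximizer is
  authoritative).
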