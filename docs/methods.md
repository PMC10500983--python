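# Methods

`mugrid` models how the design of a surface-EMG electrode grid — its area
and its interelectrode distance (IED) — limits how many motor units can be
identified from the recording, and provides the full simulation and
decomposition pipeline needed to study that question on synthetic data with
ground truth.

## Anatomical model

The muscle is a cylinder of parallel fibers (radius 25.4 mm by default)
under 5 mm of subcutaneous fat and 1 mm of skin; electrodes sit on the skin
surface, whose transverse coordinate is arc length around the limb.  A pool
of 200 motor units is generated as follows.

* **Territory centers** are spread over the muscle cross-section with
  greedy farthest-point sampling over a seeded uniform candidate set (50
  candidates per unit, first center drawn uniformly): each new center
  maximizes its minimum distance to all previous ones, giving an even but
  randomized layout.
* **Innervation numbers** follow a deterministic exponential ladder from 15
  to 1500 fibers: unit *i* of *M* innervates
  `round(15 * 100**((i-1)/(M-1)))` fibers, so the printed range is met
  exactly and the pre-rounding ratio between consecutive units is constant.
* **Territory radius** derives from the fiber count at 20 fibers/mm²
  (`r = sqrt(n / 20π)`, clipped to 0.2–9.8 mm).  Fibers are placed uniformly
  in the territory disc intersected with the muscle disc.
* **Territory fitting.** Centers of units whose territory would overhang
  the muscle boundary are pulled radially inward until the territory fits
  (`fit_territories=True`).  Territories are anatomical sub-regions of the
  muscle; allowing the largest units to overhang the boundary would bias
  the pool-depth distribution shallow and truncate exactly the units that
  carry most of the surface signal.  The overhang convention remains
  available as `fit_territories=False`.
* **Innervation zones** sit at the fiber midpoint with a uniform ±5 mm
  axial scatter per fiber; fibers are 100 mm long.  Unit **depth** is the
  distance from the territory center to the skin surface
  (`outer radius − radial distance`).

## Volume conductor

Published cylindrical-layer conductor models for this problem are not
reproducible from their descriptions alone, so the forward model here is an
analytic line-source model chosen to preserve the geometry-dependent
waveform differences that the discriminability statistic measures:

* The transmembrane potential has the classical Rosenfalck form
  `psi(z) = 96 z³ e^(−z) − 90` mV (z in mm); a discharge launches two
  depolarization zones from the innervation zone toward both fiber ends at
  the unit's conduction velocity, where they extinguish.  The current
  source density is the second spatial difference of the membrane potential
  on a 1-mm axial grid; replicated-edge (Neumann) differencing keeps the
  total source zero at every instant and produces the non-propagating
  end-of-fiber component.
* The electrode potential is the source density weighted by
  `1 / (k·rho² + dz² + s²)^(p/2)` with transverse source–electrode distance
  `rho` (through fat and skin), axial offset `dz`, anisotropy penalty `k`
  (default 1: the effective medium metric is isotropic), smoothing constant
  `s = 1 mm` (finite contact), and falloff exponent `p = 3`.  The cubic
  falloff approximates the steeper-than-monopole decay of potentials in a
  finite cylindrical conductor with an insulating boundary; because the
  kernel widens linearly with distance, deep and far sources are both
  attenuated and temporally low-pass filtered — the physical effect that
  makes deep units hard to tell apart.
* Conduction velocity increases with unit size, linear in log fiber count
  from 3.5 m/s (15 fibers) to 4.5 m/s (1500 fibers); an optional per-unit
  random scatter (`cv_scatter`, default off) is available for sensitivity
  analyses.
* 1-mm circular electrodes are treated as points (IED ≥ 2 mm ≫ contact
  radius); a 5-point disc stencil is available as a check and changes
  waveforms by <0.1% in correlation.
* The overall gain is set so large superficial units produce a few hundred
  µV peak-to-peak on a 4-mm grid.  Per-unit MUAPs may be computed from a
  seeded fiber subsample (≤100 fibers, rescaled by `n/subsample`), which
  changes identifiability decisions for only a few units per pool while
  bounding runtime.

These conductor defaults are the package's model choice; the identifiable
percentages they produce land inside the published ranges for large grids
(see the acceptance criteria), but the model is deliberately simple and its
parameters are all exposed on `TissueElectrical`.

## Theoretical identifiability

Two units are *discriminable* when, after aligning their multichannel MUAPs
in time by one global lag (chosen to maximize the magnitude of the summed
cross-correlation; per-channel alignment would erase the inter-electrode
propagation delays that distinguish units), the normalized mean-square
difference is at least 5%.  The NMSD of a pair is
`(E_a + E_b − 2·C(lag*)) / max(E_a, E_b)`: dividing by the larger energy is
the conservative choice — a pair only counts as discriminable when the
difference is substantial relative to the stronger waveform; the symmetric
mean-energy normalization is available as `normalization="mean"`.  A unit
is *identifiable* when it is discriminable from every other unit; a
single-unit pool is identifiable by convention (the pairwise condition is
vacuous).  The statistic is independent of any decomposition algorithm and
upper-bounds the yield of all of them.

The sweep evaluates 84 configurations: 7 grid lengths (4–10 cm at 3.6-cm
width, areas 14.4–36 cm²) × 12 IEDs (2–36 mm, all even).  Because every
IED is a multiple of 2 mm, all configurations are sublattices of one 2-mm
master grid; `sweep_shared_master` computes the MUAPs once on the master
and evaluates each configuration as a centered crop plus centered-phase
decimation, which is ~20× faster than independent per-configuration grids
and statistically equivalent.  The literal per-configuration path is kept
in `sweep_configs`.

The all-pairs NMSD matrix is computed in one FFT batch (cross-spectra
summed over channels, one complex matrix product per retained frequency)
and verified against the pairwise reference implementation.

## Synthetic EMG with ground truth

* **Recruitment** follows the tibialis-anterior threshold distribution
  `Fth(j) = 0.50(58.12 j + 120 j^1.83)` %MVC over the normalized pool index
  `j ∈ [0, 1]` (strictly increasing, `Fth(1) = 89.06` %MVC); its inverse is
  computed by bisection.  The exponent is read as `j**1.83`; with that
  reading the top threshold is physiologically plausible.
* **Force profiles** are trapezoids: ramps at 5 %MVC/s and a plateau
  (20 s at 30% and 15 s at 50% MVC reproduce the 32-s and 35-s task
  durations).
* **Rate coding**: discharge rate is `8 + 0.3·(F − Fth)` spikes/s capped at
  35/s (all below the 50/s physiological ceiling for submaximal isometric
  contractions); inter-spike intervals carry Gaussian jitter with CoV 0.15
  (truncated at 3 SD).  These constants are typical for tibialis anterior
  and are all configurable.
* **Mixing**: each channel is the sum over units of the discharge train
  convolved with that unit's MUAP, plus Gaussian noise band-limited to
  20–500 Hz and scaled to a prescribed overall SNR (default 20 dB).  All
  discharge times, thresholds, and early/late labels are retained as ground
  truth.

What the generator does *not* emulate: force production and twitch
dynamics, fatigue, common synaptic input (short-term synchronization),
electrode-skin impedance variations, movement artifacts, and line
interference.  Passing tests therefore demonstrate algorithmic correctness
under a clean, stationary mixing model — not robustness to every
experimental nuisance.

### The decomposition benchmark recording

`validation_recording` builds the standard 15-unit decomposition benchmark:
a full 200-unit pool is generated, and the 15 units with the largest
surface RMS on the 64-electrode montage form the mixture (trapezoid to 50%
MVC, 10-s plateau, ≈30 s, 20 dB).  A 15-unit pool spread over the whole
cylinder would place most units on the far side of the limb, 60+ dB below
the strongest unit at the skin — unrecoverable by construction for any
surface method.  Selecting the surface-visible sample makes the benchmark a
test of the separation algorithm rather than of far-field attenuation.

## Decomposition

The convolutive blind-source-separation pipeline:

1. **Preprocessing**: zero-phase 2nd-order Butterworth band-pass
   (20–500 Hz); channels whose RMS deviates from the montage median by >3
   robust z-scores (median/MAD) are rejected — an automated stand-in for
   visual channel screening; at least 8 channels must survive.
2. **Extension**: each channel is augmented with delayed copies (factor
   `ceil(1000/m)`, e.g. 16 for 64 channels → 1024 extended channels),
   converting the convolutive mixture into an instantaneous one.
3. **Whitening** by eigen-decomposition of the extended covariance.  The
   covariance is accumulated in float64 — the informative tail eigenvalues
   sit far below float32 matmul precision — and eigenvalues below
   `1e-12 × max` are dropped, making the output covariance the identity on
   the retained subspace.  The first and last `R + 0.05 s` samples are
   trimmed afterwards: extension zero-padding and filter transients
   otherwise dominate the activity used to initialize extraction.
4. **Fixed-point extraction** with the log-cosh contrast (g′ = tanh):
   vectors initialize at maxima of the summed squared whitened signal not
   yet explained, are deflated against all previously returned vectors, and
   iterate until the sparsity measure (mean log-cosh of the source) changes
   by <1e-4.  Deflation uses an orthonormalized (QR) basis: plain
   Gram-Schmidt against correlated prior vectors is not a projection.
   After a train is accepted, its spike-triggered whitened templates at all
   extension delays are added to the deflation basis — otherwise the
   extraction re-finds the same unit indefinitely as delayed replicas of
   itself.
5. **Spike extraction**: peaks of the square-rectified source (minimum
   10-ms separation) are split by exact two-class 1-D K-means on peak
   amplitude; the high class is the discharge set.
6. **Refinement**: the motor-unit filter is re-estimated as the mean
   whitened observation at the current spikes, reprojected, and spikes
   re-extracted; the iterate with the lowest inter-spike-interval CoV is
   kept (≤20 passes, stopping when CoV stops decreasing or when the
   re-detected spikes no longer overlap the previous set after lag
   alignment — a guard against the filter drifting to a different unit).
   This automated pass replaces interactive manual editing.
7. **Quality gates**: pulse-to-noise ratio
   `PNR = 10·log10(mean(pt² at spikes) / mean(pt² elsewhere))` computed on
   the square-rectified pulse train, accepted above 28 dB; physiological
   gates reject trains with mean rate >50/s, <2 s of activity, <8 spikes,
   or CoV-ISI >0.5 (isometric discharge is regular; a higher CoV indicates
   a merged or fragmented source).
8. **Duplicate removal**: binary trains are aligned by their
   cross-correlation lag (±50 ms); discharges within 0.5 ms are common, and
   trains sharing ≥30% of the smaller train's discharges form a duplicate
   group, of which the member with the lowest CoV-ISI survives.

`decompose(..., mode="quadrants")` splits a composite 256-electrode montage
into its four 64-electrode sub-grids, decomposes each independently, and
removes duplicates across sub-grids — the strategy that maximizes
identified units on such montages.

The pipeline is deterministic: every stochastic-looking step (K-means,
initialization) is an exact deterministic computation, so identical inputs
give identical results.

## Post-decomposition metrics

* **Early/late classification**: with the task target `F`, the active pool
  is `[0, j*]` where `Fth(j*) = F`; units whose measured threshold (force
  at their first up-ramp discharge) is ≤ `Fth(j*/2)` are early-recruited.
  At 30% MVC the boundary is ≈11.5 %MVC.  The per-condition percentage is
  averaged per subject first, and suppressed when ≤5 units were found for
  ≥3 subjects.
* **Spike-triggered averaging** over a 50-ms window (edge-clipped segments
  dropped) recovers MUAP waveforms from recordings.
* **Adjacent-electrode correlation**: the waveform correlation between the
  peak-to-peak-maximal electrode and its (up to four) lattice neighbors at
  distance `d`, averaged — the redundancy measure that saturates as grids
  become ultradense.
* **Count normalization**: per subject, identified-unit counts are
  expressed as a percentage of that subject's best condition.
* **Trend fits**: weighted least squares of `y = a + b·ln(x)` (statsmodels
  WLS), with r² and the slope t-test p-value.  The natural log is the
  convention under which the published density-trend coefficients evaluate
  to the 100% normalization anchor at the densest montage.
* **Rate of agreement**: after the constant lag (±25 ms) maximizing
  one-to-one matches within 0.5 ms, `RoA = common / (common + only_found +
  only_truth)`.  The generous lag bound reflects that a decomposed source
  is a delayed replica of its unit (extension delays plus the discharge
  peak's position inside the MUAP).

## Numerical choices and problem sizes

Forward modelling uses a 1-mm axial source grid, 30-ms MUAP windows at
2048 Hz (long enough for full end-of-fiber extinction), float32 waveform
storage, and chunked BLAS contractions.  The acceptance analyses use
5 pool seeds × 200 units with ≤100 subsampled fibers per unit; the test
suite's benchmark decomposition uses one ~30-s, 64-channel recording.
Degenerate inputs (empty pools or grids, zero-energy waveform pairs,
zero-baseline PNR, all-zero subjects) raise errors or are flagged rather
than silently propagated.

## Known limitations

* The conductor is an analytic stand-in, not a layered finite-element
  model; absolute identifiable percentages carry model error even though
  the qualitative size/density trends are robust.  In particular the depth
  profile of *non*-identifiable units differs from published values: here
  the hardest-to-discriminate units are deep or on the far side of the
  limb, so the mean depth of identifiable units stays near the pool mean
  (~14 mm) for all configurations rather than rising with grid size.
* Identified-unit counts from real experiments (dozens of units per
  participant) are not reproducible from simulation alone and are out of
  scope; the decomposition is validated on synthetic ground truth instead.
* No pennation, fiber curvature, bone, or inhomogeneous conductivities;
  no fatigue or common-drive correlation in the firing model.
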