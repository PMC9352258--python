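# Methods

## The problem

Resistive-pulse (nanopore) sensing reads out single molecules as
transient reductions of the ionic current through a pore held under a
potential. For peptides and small proteins the residence time is
micro- to milliseconds while the blockade depth is picoamperes, so the
signal sits close to the amplifier noise floor and is always low-pass
filtered — by the analog anti-alias filter, by the pore's RC charging,
and by any digital preprocessing. When the filter's response time
approaches the event duration, the pulse is *dilated*: the observed
depth shrinks and the observed duration stretches, while the area is
conserved. Reading amplitude and dwell time off such a trace directly
is biased in a way that depends on the filter, not on the molecule.

## The event model

Each blockade is modelled with five parameters,

    I(t) = I_O + dI_B * exp(-(|t - mu| / sigma) ** beta),

where `I_O` is the open-pore current (pA), `dI_B` the signed current
difference of the blockade plateau (negative for blockades), `mu` the
localization (s), `sigma` the scale (s) and `beta` the dimensionless
shape exponent. The kernel is the generalized normal (exponential
power) family: Gaussian at `beta = 2`, Laplace at `beta = 1`, and in
the limit `beta -> inf` a rectangle of half-width `sigma` with
Heaviside edges. Everything else the package reports is a closed form
on this family:

* PDF `beta / (2 sigma Gamma(1/beta)) * exp(-(|x-mu|/sigma)**beta)`,
  CDF and quantile via the regularized lower incomplete gamma function
  `P(1/beta, ((x-mu)/sigma)**beta)` and its inverse,
* full width at half maximum `2 sigma (ln 2)**(1/beta)`,
* back-mapped dwell time (below), excluded current
  `I_ex = |dI_B| / |I_O|` and residual current `I_res = 1 - I_ex`.

`beta` is restricted to `[1, 500]`: below 1 the kernel is cusped,
which no band-limited pulse can produce; above 500 the profile is
numerically indistinguishable from a rectangle, and fits pinned at the
bound are flagged. At large `beta` the incomplete-gamma argument
under- or overflows double precision long before the probabilities
become negligible, so the CDF and quantile switch to log-space series
(`P ~ z**(1/beta) / Gamma(1 + 1/beta)` for small `z`) below
`z = 1e-20`, keeping the quantile/CDF round-trip at machine precision
across the whole shape domain.

## Back-mapped dwell time

The physical translocation is treated as an ideal rectangular pulse of
height `dI_B` and unknown width that the acquisition chain has dilated
into the observed profile. Because linear filters with unit DC gain
conserve area, the pulse width is recovered by equating areas:

    dt = area / |dI_B| = 2 sigma Gamma(1 + 1/beta).

At `beta = 2` this gives `sqrt(pi) * sigma`; as `beta -> inf` it tends
to `2 sigma`, a rectangle recovering its own width. The closed form is
verified against numerical integration to better than 1e-6 relative
error over 1000 random parameter draws in both the test suite and the
acceptance script.

The fwhm is sometimes used as a dwell-time surrogate. Its relative
deviation from the back-mapped dwell time is ~6.1% at `beta = 2`,
dips below 1% for `beta` in roughly [3, 4.5], rises again to ~1.5%
near `beta = 6`, and then decays to zero — i.e. it is a <2% surrogate
for any `beta >= 3` but a biased one for Gaussian-dilated events. The
test suite freezes this curve as a regression fixture.

## Validity checks

Two flags qualify every fitted event:

* **Localization containment** — the detection window must contain the
  fitted `mu` (inclusive at both edge samples). A localization outside
  its own window indicates the fit wandered to a neighbouring feature.
* **Plateau (overlap) validation** — the back-mapped pulse of width
  `dt` centered on `mu` must contain the central quantile interval
  `[Q(p), Q(1-p)]` of the fitted profile for an acceptably small
  probability `p`. The smallest admissible `p*` solves
  `mu - Q(p) = dt/2`, a transcendental equation resolved by bisection
  to 1e-6 (its closed-form value, `CDF(mu - dt/2)`, serves as an
  independent oracle in the tests). The event validates when
  `p* <= p_max`.

  The default `p_max = 0.05` is a significance convention: the pulse
  must explain at least 90% of the event's probability mass. It was
  calibrated on noiseless geometry alone: a Gaussian-dilated profile
  (`beta = 2`, which never reaches its plateau) has `p* = 0.105` at
  any scale, marginally resolved pulses (filtered exactly at the
  cutoff where the peak first reaches 99% of the depth) have
  `p* ~ 0.05-0.09`, and well-resolved ones fall between 0.002 and
  0.05. Events that fail the check should have their depth and dwell
  treated as lower/upper bounds respectively.

## Per-event required sampling frequency

`F_s,event` quantifies how fast the acquisition must be for an event of
the *fitted shape* to reach its plateau. It is a property of the shape
only, not of the dwell time. Two readings are implemented:

* `mode="cdf"` (default): `1 / (Q(1/2 + p) - Q(1/2 - p))` — the
  reciprocal of the time the curve spends within CDF distance `p` of
  the localization, with `p = 0.001` by default.
* `mode="amplitude"`: the reciprocal rise time between kernel levels
  `p` and `1 - p`,
  `1 / (sigma ((-ln p)**(1/beta) - (-ln(1-p))**(1/beta)))`.

The two readings are not equivalent and the source descriptions of the
quantity support both; the CDF reading is the default. Both are
undefined at the rectangular limit and the package reports `F_s,event`
as absent for `beta >= 500`. Characteristic behavior of the CDF
reading (reproduced end-to-end in the tests): computed on an
under-filtered event it reads far above the filter frequency, and it
stabilizes once the filter is fast enough for the event to reach its
plateau.

For simulated rectangles the package also provides the closed-form
ground truth `required_cutoff(width, level=0.99)` — the Gaussian -3 dB
cutoff at which the filtered peak first reaches `level` of the true
depth, `sqrt(2 ln 2) erfinv(level) / (pi width)` — used to score the
filter recommendation.

## RC correction

The pore/membrane RC circuit charges with time constant `tau`, so the
residual current observed at time `t` after onset is
`I_res(t) = I_res + (1 - I_res) exp(-t/tau)`. `rc_correct` inverts
this for the asymptotic `I_res`; it is the identity at `tau = 0` (the
default — the correction only matters when `tau` is comparable to the
event duration) and warns, without clamping, when the inversion lands
outside [0, 1].

## Pipeline

1. **Localization** on a heavily filtered copy (5 kHz zero-phase
   Gaussian by default): robust baseline from a rolling median (10,000
   samples), noise SD as 1.4826 x MAD of the residual, windows opened
   at `baseline - 5 sd` excursions and closed on re-entry within 1 sd,
   merged across gaps under 10 samples. Localization only provides
   windows; no amplitude from this stage is ever reused.
2. **Characterization**: each window plus 5x padding (so the open-pore
   level is constrained by true baseline) is fitted by bounded
   trust-region least squares over `(I_O, dI_B, mu, ln sigma,
   ln beta)`; log-space scale/shape for conditioning, `mu` bounded to
   the padded segment, `beta` to [1, 500]. The start point is
   moment-based (median baseline, extremum depth and position, half
   the above-half-depth width, `beta = 2`). Fits are deterministic;
   non-convergence is recorded, not raised; a fitted depth below 3x
   the baseline noise SD is flagged as a non-event. Windows showing no
   excursion above the noise floor are still fitted (null-input
   contract) and come out flagged.
3. **Features** per event: dwell time, excluded/residual current,
   `F_s,event`, both validity flags, and the plateau probability
   threshold; persisted in an SQLite store with separate `detections`,
   `fits` and `features` tables (a detection survives a failed fit) and
   a `meta` table holding the configuration snapshot. Re-running a
   trace replaces rows keyed by `(trace_id, t_start)`.

## Filters

* **Digital Gaussian** (preprocessing/characterization): zero-phase
  convolution, kernel SD `sqrt(ln 2) / (2 pi cutoff)` so the -3 dB
  point sits exactly at the cutoff, unit DC gain, reflective edges.
  The -3 dB convention for the Gaussian cutoff is assumed, matching
  the patch-clamp convention used for the Bessel stage.
* **4-pole Bessel** (acquisition emulation): the analog transfer
  function, magnitude-normalized to -3 dB at the cutoff (amplifier
  datasheet convention), simulated as a continuous-time linear system
  on the trace's own grid and applied causally, preserving the phase
  delay of the hardware filter. Requires sampling at >= 20x the
  cutoff; a bilinear-transform digital variant is available behind the
  same interface for speed and agrees with the analog simulation to
  ~2% of the pulse height.

## Synthetic traces

The simulator composes, in acquisition order: constant open-pore
baseline, non-overlapping ideal rectangular pulses, optional single-pole
RC charging, optional acquisition filter (Bessel or Gaussian), additive
white Gaussian noise from a single integer seed, and optional plain
subsampling to the recorded rate (with an anti-alias warning when no
filter precedes it). It returns the exact per-pulse ground truth
(onset, width, depth, dwell, excluded current, area).

Default study conditions mirror a typical peptide recording: 100 pA
open pore, 30 pA blockades (`I_ex = 0.3`), SNR 10 (3 pA white noise),
pulse widths 5-100 us; acquisition at 500 kHz with 100 kHz bandwidth
is the experimental regime, while pulse-dilation fixtures use a 100 MHz
virtual rate so the analog Bessel simulation is exact. What the
generator does *not* emulate: 1/f and dielectric noise (noise power
growing with bandwidth), baseline drift and gating, multi-level events,
and capture-rate statistics. Consequences: passing tests demonstrate
correctness of the characterization given the model, not robustness to
colored noise — in particular the *under*-filtering artifact (amplitude
corruption at needlessly high bandwidth) does not occur under white
noise with a full-model least-squares fit, because unfiltered white
noise data is statistically optimal for such a fit. That artifact
requires bandwidth-dependent instrument noise, which is out of scope
here. Over-filtering artifacts (depth loss, dwell elongation) are fully
reproduced.

## Filter recommendation

`recommend_filter` localizes once, characterizes at every requested
cutoff, and reports per cutoff the median `F_s,event`, dwell, excluded
current, fitted depth and plateau-validation fraction (cutoffs with
fewer than 5 valid events are flagged unreliable and excluded). The
recommended lower bound is the smallest cutoff whose median `F_s,event`
differs by less than 10% from the next cutoff up (stability); the upper
bound is the cutoff maximizing the median fitted depth — an
operationalization of where baseline noise would start eating into the
fits; under purely white noise it typically sits at the highest
reliable cutoff. On synthetic 10 us pulses the lower bound lands within
a factor of two of the closed-form required cutoff (measured ratio
0.73 at the default study conditions).

## Problem sizes and numerical defaults

Test and acceptance workloads are sized to settle the medians they
assert: 1000 random draws for area conservation; 200 events (widths
log-uniform 5-100 us, SNR 10, one event per 3 ms trace at 4 MHz) for
recovery and over-filtering bias; 20 events x 7 cutoffs at 2 MHz for
the sweep; 50 seeds for the Monte Carlo depth-error check. Bisection
tolerance on the plateau threshold is 1e-6 in `p`; the fitter stops
after 500 residual evaluations (typical fits use well under 100);
baseline estimation uses a 10,000-sample rolling median. All
randomness flows from explicit integer seeds; identical input and
configuration reproduce bit-identical stores.

## Known limitations

* Single-level events only: one pulse per window, no sub-states, no
  overlapping-event decomposition.
* The blockade direction is a configuration choice (decreases in
  |current| by default), not inferred per event.
* ABF reading requires the optional `pyabf` dependency; without it the
  reader raises a clear error.
* The amplitude-mode `F_s,event` and the CDF-mode default can differ by
  orders of magnitude for sharp events; comparisons across datasets
  must fix the mode and `p`.
* White-noise-only simulation, as discussed above.
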