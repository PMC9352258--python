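# gndfit

Unbiased characterization of fast nanopore translocation events with a
generalized normal distribution function (gNDF).

Single-molecule nanopore electrophysiology reads analytes — peptides,
proteins, nucleic acids — as transient current blockades. For fast,
unassisted translocations (micro- to milliseconds, picoampere depths)
every blockade is dilated by the acquisition chain's low-pass filtering:
the observed depth shrinks and the duration stretches while the area is
conserved, so reading amplitudes and dwell times off the trace directly
is filter-biased. `gndfit` is for experimentalists and analysts doing
nanopore spectrometry / peptide fingerprinting who need per-event
quantities that are comparable across setups and filter settings.

Each blockade is fitted with five parameters plus noise,

    I(t) = I_O + dI_B * exp(-(|t - mu| / sigma) ** beta),

with open-pore current `I_O`, blockade current difference `dI_B`,
localization `mu`, scale `sigma` and shape `beta` (Gaussian profile at
`beta = 2`, Heaviside-edged rectangle as `beta -> inf`). From the fit,
the package derives:

* the **back-mapped dwell time** `dt = 2 sigma Gamma(1 + 1/beta)` — the
  width of the ideal rectangular pulse of height `dI_B` with the same
  area, undoing pulse dilation,
* the **excluded / residual current** `I_ex = |dI_B| / |I_O|`,
  `I_res = 1 - I_ex`,
* two **validity flags**: the detection window must contain `mu`, and
  the back-mapped pulse must contain the central quantile interval of
  the fit (i.e. the event demonstrably reached its plateau),
* the **minimal required sampling frequency**
  `F_s,event = 1 / (Q(1/2 + p) - Q(1/2 - p))` (quantile function `Q`,
  `p = 0.001`), undefined at the rectangular limit,
* an optional **RC correction** inverting the pore capacitance's
  charging of the residual current.

A synthetic-trace simulator (baseline + ideal pulses + RC charging +
4-pole Bessel / Gaussian filtering + white noise, with exact ground
truth), a robust threshold localizer, an SQLite event store and a
filter-range recommender round out the pipeline.

## Worked example

`examples/03_characterize_trace.py` simulates ten 20 us, 30 pA
blockades on a 100 pA open pore at SNR 10, localizes them on a
5 kHz-filtered copy and characterizes them at 100 kHz:

```
event  dI_B (pA)    beta   I_ex  dwell (us) overlap_valid
    0     -31.21    8.53  0.312       19.59          True
    1     -30.58    8.49  0.306       19.58          True
    2     -30.89    7.64  0.309       19.72          True
    ...
Ground truth: dI_B = -30.0, I_ex = 0.30, dwell = 20 us for every event.
```

The fitted depths and back-mapped dwell times recover the ground truth
to about 1-2%, and `overlap_valid=True` certifies that each event
reached its full depth. `examples/02_pulse_dilation.py` shows why the
correction matters — after a 10 kHz 4-pole Bessel filter, a 10 us
full-height pulse and a 20 us half-height pulse differ by only 1.6% of
the pulse height (their areas are equal), so only the area, not the
apparent amplitude, survives heavy filtering.

The other examples cover the gNDF shape family
(`01_event_shapes.py`) and data-driven filter selection
(`04_filter_recommendation.py`, which brackets the usable filter range
of a synthetic 10 us-pulse trace at 50-100 kHz against a closed-form
required cutoff of 68 kHz).

There is also a thin CLI:

```sh
gndfit simulate --config sim.toml -o trace.npy
gndfit fit trace.npy -o events.sqlite --filter gaussian:1e5
gndfit export events.sqlite -o events.csv
gndfit recommend-filter trace.npy --cutoffs 1e3,5e3,25e3,1e5
```

Units are seconds, Hz and pA throughout.

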