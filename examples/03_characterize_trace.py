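"""Full pipeline on a synthetic trace: localize, fit, featurize.

Builds a noisy trace with ten 20 us blockades (depth 30 pA on a 100 pA
open pore, SNR 10), localizes events on a 5 kHz-filtered copy,
characterizes them on a 100 kHz-filtered copy, and prints the fitted
parameters and derived features per event.  With adequate filtering the
excluded current comes back near the true 0.30 and the back-mapped dwell
time near the true 20 us; overlap_valid reports whether each event can
be trusted to have reached its full depth.
"""

import gndfit as g

WIDTH, DEPTH = 20e-6, 30.0

cfg = g.SimConfig(
    fs=2e6,
    duration=0.021,
    i_open=100.0,
    noise_sd=3.0,
    pulses=[g.Pulse(1e-3 + i * 2e-3, WIDTH, DEPTH) for i in range(10)],
    seed=23,
)
trace, truth = g.synthesize(cfg)
records = g.characterize_trace(
    trace, characterization_filter=g.FilterSpec("gaussian", 100e3)
)

print(f"{'event':>5} {'dI_B (pA)':>10} {'beta':>7} {'I_ex':>6} "
      f"{'dwell (us)':>11} {'overlap_valid':>13}")
for i, rec in enumerate(records):
    p, f = rec.fit.params, rec.features
    print(
        f"{i:5d} {p.di_b:10.2f} {p.beta:7.2f} {f.i_ex:6.3f} "
        f"{f.dwell_time * 1e6:11.2f} {str(f.overlap_valid):>13}"
    )

print(
    f"\nGround truth: dI_B = -{DEPTH}, I_ex = {DEPTH / 100:.2f}, "
    f"dwell = {WIDTH * 1e6:.0f} us for every event."
)
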