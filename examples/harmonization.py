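"""Harmonising caller outputs onto one absolute copy-number scale.

Shows the three harmonisation paths: frequency-peak bias correction of
absolute copy numbers, median-centred log2-ratio conversion, and the
equaliser that undoes the exponential distortion of ratios taken against
a zero-coverage null alignment.
"""

import numpy as np

from cnvmeta import (
    CallerRole,
    CallerTrack,
    IntervalCall,
    ValueScale,
    equalize_null_ratio,
    estimate_bias,
    invert_equalizer,
    log2_to_absolute,
    normalize_cn,
)

# -- bias correction: a coverage caller whose diploid peak sits at 1.9 ----
calls = [IntervalCall("1", i * 450, (i + 1) * 450, v)
         for i, v in enumerate([1.9] * 40 + [2.9] * 6 + [0.9] * 4)]
track = CallerTrack(CallerRole.COVERAGE, ValueScale.ABSOLUTE_CN, calls)
est = estimate_bias(track, ploidy=2)
print(f"frequency peak at CN {est.peak_cn:.2f} -> bias {est.bias:+.2f}")
for cn in (0.9, 1.9, 2.9):
    print(f"  CN {cn:.1f} -> normalised {normalize_cn(cn, est.bias):.3f}")

# -- log2 ratios vs a matched sample ---------------------------------------
log2 = [0.3, 0.3, 1.3, 0.3, -0.7]     # constant offset 0.3 plus one gain, one loss
cn_abs = log2_to_absolute(log2, ploidy=2)
print("\nlog2 ratios", log2, "->", np.round(cn_abs, 3))
print("(the genome-wide median offset is removed before 2**x scaling)")

# -- null-ratio equalisation ------------------------------------------------
print("\nratios against a zero-coverage null alignment:")
for y in (0.0, 2.0, 4.0, 8.0):
    print(f"  reported {y:.1f} -> equalised CN {equalize_null_ratio(y):.6f}")
print(f"a true CN of 4.499456 is reported as {invert_equalizer(4.499456):.6f} "
      "(the distortion grows with the amplification)")
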