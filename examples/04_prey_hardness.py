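"""Prey hardness: fit exoskeleton failure force against crab carapace width
and ask whether a predator's bite force exceeds the predicted hardness of
the largest adult crabs (6 cm carapace).

The margin report answers the ecological question directly: a ratio above 1
means the predator can crack the shell.
"""

import jawstatics as js

records = js.make_hardness_dataset(slope=42.5, intercept=0.0, sd=8.0, n=30, seed=7)
fit = js.fit_hardness_vs_size(records)
print(f"hardness fit over {fit.n} crabs: "
      f"F_fail = {fit.intercept:+.1f} + {fit.slope:.1f} x width_cm  (r^2 = {fit.r2:.3f})")

for width in (4.5, 6.0):
    hardness = fit.predict(width)
    margin = js.exceeds_hardness(256.0, hardness)  # a 256 N biter
    verdict = "exceeds" if margin.exceeds else "does NOT exceed"
    print(f"crab {width} cm: predicted failure {hardness:6.1f} N -> "
          f"256 N bite {verdict} it (margin {margin.difference:+.1f} N, "
          f"ratio {margin.ratio:.2f})")
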