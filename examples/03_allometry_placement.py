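"""Comparative allometry: fit the log-log bite-force-head-width line on a
synthetic 332-specimen / 44-species dataset and place a model-estimated
focal species on it.

A species whose estimated force matches its head width has a residual near
zero ("on" the line); a residual of +0.3 log10 means it bites twice as hard
as an average skink of its size.
"""

import jawstatics as js

records = js.make_comparative_dataset(js.SyntheticComparativeParams(seed=1))
fit = js.fit_loglog(records)  # specimen-level, as plotted
fit_sp = js.fit_loglog(records, per_species=True)  # species means, for inference

print(f"{len(records)} specimens, {fit_sp.n} species")
print(f"specimen-level fit: log10 F = {fit.intercept:+.3f} + {fit.slope:.3f} log10 HW"
      f"  (r^2 = {fit.r2:.3f})")
print(f"species-mean fit:   slope {fit_sp.slope:.3f} +- {fit_sp.slope_se:.3f} SE")

# place a focal species: head width 30 mm, model-estimated jaw-tip force
head_width = 30.0
for force, note in [(90.0, "average biter"), (180.0, "hard biter")]:
    r = js.residual_position(fit, head_width, force)
    verdict = js.placement_verdict(fit, r)
    print(f"HW {head_width} mm, force {force:5.1f} N -> residual {r:+.3f} log10 "
          f"({verdict} the line; predicted {fit.predict(head_width):.1f} N)")
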