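"""Simulate a dialysis release assay and recover the kinetics.

A nanoparticle batch carrying 2 mg of drug sits in a 14 mL buffer bath; at
each sample time a 1 mL aliquot is withdrawn for HPLC and replaced with
blank buffer.  We simulate the assay with measurement noise, rebuild the
withdrawal-corrected cumulative-release curve, and fit the biexponential
burst/sustained model back to it.
"""

from imequant.release import cumulative_release, fit_biexponential
from imequant.synth.chem import ReleaseTruth, gen_release

truth = ReleaseTruth(measurement_cv=0.03, seed=1)
sim = gen_release(truth)
curve = cumulative_release(
    truth.sample_times, sim.table["conc_ug_per_ml"], truth.loaded_mass,
    truth.bath_volume, truth.aliquot_volume,
)

print("t (d)   aliquot (ug/mL)   cumulative release")
for t, c, f in zip(curve.times, curve.aliquot_conc, curve.cumulative_fraction):
    print(f"{t:5.2f}   {c:15.2f}   {100 * f:17.1f}%")

fit = fit_biexponential(curve.times, curve.cumulative_fraction)
print(f"\nfitted: f_burst={fit.f_burst:.3f}  k_burst={fit.k_burst:.2f}/d  "
      f"k_sustained={fit.k_sustained:.4f}/d")
print(f"truth : f_burst={truth.f_burst:.3f}  k_burst={truth.k_burst:.2f}/d  "
      f"k_sustained={truth.k_sustained:.4f}/d")
print("\nThe cumulative column shows the burst (~65% inside day 1) flattening")
print("toward ~98% by day 24; the fit recovers the generating rate constants.")
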