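"""Chemical degradation degree from 1H NMR peak integrals.

Builds synthetic spectra with a monomer peak at 4.20 ppm and a polymer peak
at 5.20 ppm, integrates both over their default windows, and reports the
degradation degree 100 * monomer / (monomer + polymer).  Also follows a
half-hourly alkali-digestion time course and recovers its linear trend.
"""

import numpy as np

from phbdeg import (
    MONOMER_REGION,
    POLYMER_REGION,
    SpectrumParams,
    degradation_degree,
    degradation_kinetic,
    integrate_peak,
    simulate_spectrum,
    simulate_spectrum_series,
)

print("single spectra at known degradation fractions:")
for d in (0.230, 0.500, 0.737):
    sim = simulate_spectrum(SpectrumParams(degradation_fraction=d, noise_sd=0.0))
    mono = integrate_peak(sim.spectrum, MONOMER_REGION)
    poly = integrate_peak(sim.spectrum, POLYMER_REGION)
    degree = degradation_degree(mono, poly)
    print(
        f"  true fraction {d:.3f} -> monomer integral {mono:.4f}, "
        f"polymer integral {poly:.4f}, degradation degree {degree:5.1f} %"
    )
print("the recovered degree equals 100 x the generating fraction: the ratio")
print("cancels the identical tail and baseline losses of the two peaks.\n")

# a 9.5 h digestion sampled every 30 min, degradation growing linearly
times = np.linspace(0.0, 9.5, 20)
spectra = simulate_spectrum_series(times, times / times[-1], seed=4)
curve = degradation_kinetic(spectra)
slope = np.polyfit(curve.times, curve.values, 1)[0]
print("digestion time course (every 30 min):")
print("  t_h:", np.array2string(curve.times[:5], precision=1), "...")
print("  deg%:", np.array2string(curve.values[:5], precision=1), "...")
print(f"  fitted slope {slope:.2f} %/h vs true {100.0 / times[-1]:.2f} %/h")
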