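# phbdeg

Computational monitoring of poly(3-hydroxybutyrate) (PHB) blend
degradation, for lab groups following polymer biodegradation by time-lapse
well photography and by ¹H NMR.

PHB is a bacterial polyester; blending it with a plasticizer changes how
fast fungi and chemical agents break it down. This package quantifies that
breakdown from two kinds of raw data:

* **Image kinetics.** A well containing bright polymer grains on dark agar
  is photographed over days. Every frame of one series is binarized with
  the *same* closed grey-level interval `[low, high]`, chosen so grains are
  white while agar and the (white-ish) fungal mycelium stay black. With
  `WP_t` the white-pixel count at time `t`, the remaining polymer fraction
  is

  ```
  remaining(t) = 100 · WP_t / WP_t0        (%)
  ```

  The curve is fitted by ordinary least-squares polynomial regression; the
  degree is chosen by an F-test significance screen followed by adjusted-R²
  maximization, and **t50** — the time at which the fit first crosses 50% —
  summarizes each replicate. A curve that never reaches 50% inside the
  observed window is reported censored (`> t_max`), never extrapolated.

* **NMR degradation degree.** Hydrolysis converts the polymer's methine
  resonance (≈ 5.20 ppm) into the free β-hydroxybutyric-acid monomer signal
  (≈ 4.20 ppm). After trapezoidal integration with endpoint-baseline
  subtraction,

  ```
  degree(t) = 100 · I_monomer / (I_monomer + I_polymer)   (%)
  ```

* **Group comparison.** Replicate t50 values are compared across blends by
  one-way ANOVA and Tukey HSD (α = 0.05), summarized as a compact letter
  display: blends sharing no letter differ significantly.

A synthetic-data generator renders well image series with exact
ground-truth grain areas (plus mycelium growth, illumination gradients and
noise) and two-peak NMR spectra with analytic integrals, so the whole
pipeline is testable without any wet-lab input.

## Worked example

```bash
python examples/image_kinetics.py
```

```
threshold range applied to the whole series: [0.723, 1.0]

 time_h   white_px   remaining_%
      0       6714        100.0
     28       6618         98.6
    ...
    140       3865         57.6
    168       2463         36.7
    ...
    336         28          0.4

selected polynomial degree 6 (adj R^2 = 0.9994, F-test p = 3.39e-10)
estimated t50 = 149.4 h (true value used by the generator: 150.0 h)
```

The generator consumed the grains along a logistic trajectory with a true
half-life of 150 h; the pipeline recovers 149.4 h from the rendered,
noisy images. `examples/nmr_degradation.py` shows the NMR round trip
(fraction 0.737 → 73.7%), and `examples/blend_comparison.py` runs the full
four-blend study:

```
mean t50 by blend (3 replicates each):
  BDF00:  298.5 h  (letters: a)
  BDF05:  218.7 h  (letters: b)
  BDF20:  143.7 h  (letters: c)
  BDF40:   98.4 h  (letters: d)

one-way ANOVA: F = 341.1, p = 8.88e-09
```

## Command line

The same stages are available as subcommands for file-based runs:

```bash
phbdeg all --seed 1 --out out/            # full synthetic study
phbdeg simulate --out out/                # frames + manifest + truth tables
phbdeg binarize --manifest out/manifest.csv --out out/
phbdeg t50 --kinetics-csv out/kinetics.csv --out out/
phbdeg compare --t50-csv out/t50.csv --out out/
phbdeg nmr --demo --out out/
```

All parameters (threshold range or `auto`, polynomial `max_degree`, `alpha`,
integration windows, scene settings) live in a YAML or `key = value` config
file overridable by flags; every run writes a `run.json` recording the
resolved configuration, thresholds and seeds.

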