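# fbgpalp

Computational pipeline for an endoscopic palpation probe built from four
fiber Bragg gratings (FBGs) embedded in an elastic silicone dome. During
minimally invasive surgery the surgeon loses tactile feedback; such a probe
restores it by pressing the dome against tissue and reading how much the
four Bragg reflection peaks move. This package implements the full signal
chain — sub-resolution Bragg-peak localization, per-channel wavelength-shift
tracking, a relative-stiffness statistic, and stiffness heat-map
reconstruction — together with a forward simulator of palpation sessions
over tissue phantoms with rigid inclusions, so the method can be developed
and tested without hardware.

## Method

The interrogator samples the combined reflection spectrum on a uniform
wavelength grid with a 2 pm hardware step. The spectrum is divided into
four windows (boundaries at midpoints between the nominal Bragg
wavelengths) and a Gaussian plus constant baseline is fitted in each; the
fitted center is the Bragg wavelength λ_B of that channel, localized far
below the grid step. For each palpation point two frames are acquired —
light contact (reference) and after a ~2 mm press — and each channel's
shift is

    Δλ_B(ch) = λ_B,pressed(ch) − λ_B,contact(ch)    [pm]

(negative = blue-shift = compression, positive = red-shift = tension). The
per-point relative-stiffness statistic is the non-vectorial sum

    S = Σ_ch |Δλ_B(ch)|    [pm]

min–max normalized within one session so the stiffest point maps to 1 and
the softest to 0. The normalized scores at the press coordinates are
interpolated (piecewise-linear on the Delaunay triangulation, so the [0,1]
band is never overshot) into a 2D heat map that localizes hard inclusions
under soft tissue. Linear calibration fits (mean shift vs. indentation
depth, and vs. Shore A target hardness) are included.

## Worked example

Simulate a 5×5-point palpation session over a 40 mm × 40 mm phantom with a
needle-like rigid inclusion through the center, then run the full pipeline:

```
fbgpalp simulate --seed 7 --out-dir sess
fbgpalp run sess/manifest.json --out-dir out
fbgpalp map out/stiffness_table.csv --out-dir out --roi 40 40 --threshold 0.5
```

The stiffness table (top rows by score):

```
point_id  x_rel  y_rel       d1_pm       d2_pm       d3_pm       d4_pm        S_pm   s_norm
    p013     20     20 -299.916556 -299.886291 -299.798053 -299.959167 1199.560068 1.000000
    p012     12     20   29.835887  -29.989555  -30.073935  -30.076522  119.975899 0.069288
    p014     28     20  -30.076263  -29.897479   29.967357  -29.809021  119.750120 0.069093
    p022     12     36  -10.300730  -10.129706   -9.647758  -10.223452   40.301646 0.000600
```

Point p013 presses directly on the inclusion: all four channels blue-shift
by ~300 pm and it scores s_norm = 1. Its lateral neighbours p012/p014 feel
the inclusion from the side: the summed response is 10× weaker and the
grating facing the inclusion red-shifts (+30 pm) while the others
blue-shift — the sign split that distinguishes side contact from direct
contact. Background points sum to ~40 pm (four ~10 pm shifts from soft
tissue alone). Region detection then reports

```
stiff region: centroid=(20.0, 20.0) mm, area=2.4%
```

recovering the inclusion centroid, and `out/stiffness_map.png` shows the
red-high / blue-low heat map.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the Monte-Carlo sub-resolution localization
study: 1000 single-Gaussian spectra (FWHM 60 pm, unit amplitude) sampled at
the 2 pm hardware grid with 1% additive white noise and random off-grid
true centers, fitted by the package's Gaussian estimator; it reports the
95th percentile of the absolute center error in pm.
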