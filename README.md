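# mersense

Analysis pipeline for **whole-cell mercury biosensors**: engineered
*E. coli* whose MerR-regulated reporter output (red fluorescence or a blue
chromoprotein) reports the concentration of ionic mercury (Hg²⁺) in a
water sample.  The package takes raw plate-reader time series and pellet
photographs all the way to a dose–response calibration, a limit of
detection, and censored concentration estimates for unknown environmental
samples.  A seeded forward simulator generates every input the pipeline
consumes, so the whole inferential loop is testable without wet-lab data.

It is written for people characterizing biosensor circuits: synthetic
biologists profiling dose–response curves, and environmental-monitoring
groups who need defensible "x nM" or "< x nM" calls from living-cell
assays.

## The model

**Kinetics.**  Per well, with blank-corrected fluorescence and OD600 on a
shared time grid, the promoter activity is the per-density protein
synthesis rate, estimated by forward differences:

    f(t_n) = (1 / OD_n) * (Fluo_{n+1} - Fluo_n) / (t_{n+1} - t_n)

Growth phases (lag / exponential / stationary) are called from the
specific growth rate d ln(OD)/dt, and each well is summarized by
**Fmax**, the maximum of f(t) over the exponential phase.

**Colorimetry.**  For the chromoprotein variant, the pellet's colour score
is the RGB Euclidean distance against a white reference pellet of
non-transformed cells, averaged over a nine-pixel region:

    E = sqrt((R_s - R_r)^2 + (G_s - G_r)^2 + (B_s - B_r)^2)

**Calibration.**  The dose–response of either signal S (Fmax or E) versus
inducer I is fitted two ways:

* Hill curve  `S = psi_min + psi_max * I^h / (I^h + K^h)`  by nonlinear
  least squares (positivity-constrained, multistart over h);
* log-log line  `ln S = m * ln I + y0`  by OLS over the linear range
  (chosen automatically as the widest contiguous dose window with
  R² ≥ 0.98, or pinned manually), with residual SD `sigma0`.

The limit of detection follows the 3.3-sigma convention applied on the
log scale: `LOD = exp(3.3 * sigma0 / m)`, in nM.

**Quantification.**  An unknown sample's signal inverts through the line,
`I = exp((ln S - y0) / m)`, is multiplied by the sample's dilution factor,
and is censored to "< LOD × dilution" when the culture-level estimate
falls below the LOD.

## Worked example

Simulate a fluorescent-variant dose series (8 doses × 3 wells + blanks,
16 h at 15-min sampling), characterize it, calibrate, and quantify two
unknown signals prepared at 2× dilution:

```sh
mersense simulate --seed 11 --out demo --no-pellets
mersense characterize demo/plate.csv demo/plate_map.csv --out demo/chr
mersense calibrate demo/chr/dose_table.tsv --out demo/cal.json
printf 'sample_id\tsignal\tdilution_factor\npond_1\t170\t2.0\nbucket\t3000\t2.0\n' > demo/signals.tsv
mersense quantify demo/signals.tsv demo/cal.json --out demo/results.tsv
```

which prints

```
dose table: demo/chr/dose_table.tsv (24 wells)
K=286.1 nM  h=1.591  m=0.8641  LOD=1.8 nM  range=10-500 nM
pond_1  19.2 nM
bucket  533.2 nM
```

Reading: the refitted Hill constant (286 nM) recovers the generating
half-maximal dose (305 nM) to ~6% under 5% measurement noise; the log-log
slope 0.86 and LOD 1.8 nM define the usable quantitation window; the two
unknown signals invert to 19.2 and 533.2 nM after dilution correction
(both above the LOD, so neither is censored — a below-LOD sample would be
reported as e.g. `<3.6`).  The same `calibrate`/`quantify` commands accept
colour scores E from `mersense pellets` for the colorimetric variant.

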