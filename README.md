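# loopx

Quantitative analysis of SMC-driven DNA loop extrusion and its
biochemical regulation, built around three assays used to characterise
condensin I activation:

* **Single-molecule loop extrusion** — surface-tethered 48.5-kbp lambda
  DNA imaged by TIRF; a growing fluorescent punctum marks an extruding
  loop.  `loopx` builds kymographs (median filter radius 2, 11-pixel
  band sum along the DNA axis), tracks the loop punctum (per-line peak
  detection + nearest-neighbour linking), partitions each time line into
  *Up / Loop / Down* regions (9-pixel loop window) and converts
  intensity fractions into DNA amounts:
  `region_kbp = 48.5 * I_region / I_total`.  The extrusion rate *k*
  (kbp/s) is a linear fit *f(t) = k·t + c* to the first 5 s of monotone
  loop growth (Savitzky–Golay 2/50 smoothing locates the window; the fit
  uses raw data).  Looping activity is the fraction of tethers with at
  least one loop, compared across conditions by Wilcoxon rank-sum
  (exact for small n); rates are compared with Welch's *t*-test.
* **Fluorescence polarisation binding** — the exact ligand-depletion
  (quadratic) model
  `FP = (FPmax/2[Pep])(([C]+[Pep]+Kd) − √(([C]+[Pep]+Kd)² − 4[C][Pep]))`
  fitted for (K_d, FP_max) by weighted least squares, plus
  background-subtracted competition analysis with pairwise *t*-tests.
* **ATPase activity** — steady-state slopes of phosphate-sensor time
  courses, enzyme-normalised rates, and DNA fold-stimulation
  (rate at each DNA concentration ÷ rate without DNA).

Every stage ships with a ground-truthed synthetic-data generator
(`loopx.simulate`), so the full chain is testable by parameter recovery
without any external data.  See `docs/methods.md` for models,
parameters, defaults and known accuracy limits.

## Worked example

```python
import numpy as np
from loopx import (TetherSimConfig, LoopEvent, simulate_tether_movie,
                   PipelineConfig, analyze_movie, simulate_fp_plate, fit_kd)

# one tether, one loop event: 1 kbp/s from t = 5 s, plateau at 30 kbp
cfg = TetherSimConfig(
    n_frames=60,
    loop_events=(LoopEvent(t_start=5.0, rate=1.0, anchor_pos=0.5, max_loop=30.0),),
    seed=7,
)
series, truth = simulate_tether_movie(cfg)
result = analyze_movie(series, PipelineConfig())
print(f"looped: {result.looped}")
print(f"track: {len(result.track)} frames, "
      f"loop at frame 40: {result.dna.loop_kbp[result.dna.frames == 40][0]:.1f} kbp "
      f"(truth {truth.loop_kbp[40]:.1f} kbp)")
print(f"rate: k = {result.rate.k:.2f} kbp/s over t = {result.rate.window} s "
      f"(r^2 = {result.rate.r_squared:.3f})")

# FP titration at Kd = 5.9 uM, 100 nM probe, 2 mP replicate noise
plate = simulate_fp_plate(kd=5.9, fp_max=60.0, probe_conc=0.1,
                          receptor_concs=np.logspace(-1, 2, 12),
                          noise_sd=2.0, n_replicates=3, seed=1)
fit = fit_kd(plate)
print(f"Kd = {fit.kd:.1f} +/- {fit.kd_se:.1f} uM, FPmax = {fit.fp_max:.1f} mP")
```

prints

```
looped: True
track: 37 frames, loop at frame 40: 28.3 kbp (truth 30.0 kbp)
rate: k = 0.89 kbp/s over t = (23.0, 28.0) s (r^2 = 0.970)
Kd = 6.2 +/- 0.3 uM, FPmax = 60.9 mP
```

The loop is detected once its punctum clears the 5%-prominence
threshold, its size tracks the programmed ground truth to a few percent
(the intensity-ratio method carries a small, documented deficit), and
the fitted rate and K_d recover the programmed values.

The same chain is available from the shell:

```sh
loopx simulate sim.json movie.tif        # render a configured tether movie
loopx kymo movie.tif kymo.tif            # median filter + 11-px band sum
loopx quantify movie.tif partitions.csv  # Up/Loop/Down kbp per frame
loopx rates partitions.csv rate.json     # 5-s window linear fit
loopx compare 0.2,0.3,0.25 0.9,1.0,0.92  # rank-sum test of looped fractions
loopx fp fit plate.csv fit.json --probe-conc 0.1
loopx atpase traces.csv rates.csv --fold-json fold.json
```

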