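# Methods

`loopx` implements the quantitative analysis stack of a single-molecule
condensin study: kymograph-based DNA loop-extrusion detection and rate
measurement, fluorescence-polarisation (FP) equilibrium binding and
competition analysis, and ATPase rate / DNA fold-stimulation analysis.
Because raw imaging and plate data of the kind this pipeline consumes
are rarely deposited, every stage is paired with a synthetic-data
generator so that the whole chain is verifiable by parameter recovery.

## Loop-extrusion analysis

### Kymograph construction (`loopx.kymo`)

A tether ROI movie (one doubly-tethered 48.5-kbp lambda DNA per ROI) is
median filtered with a radius-2 disc (discrete Euclidean ball, boundary
ties included; radius 0 is the identity), and each frame is collapsed
into one kymograph column by summing an 11-pixel band centred on the
DNA-axis column.  The axis column is fixed per ROI (no per-frame
re-centring) and defaults to the column of maximal summed intensity.  A
radius-10 white top-hat (input minus grey opening) is available for
display snapshots and as an optional background-subtraction step before
quantification (`quantify_on_tophat`); by default DNA ratios are
computed on median-filtered, non-top-hat data.  Pixel coordinates are
0-based, row 0 is the top tether anchor.

### Loop detection, linking, partitioning (`loopx.tracking`)

Per kymograph line, local maxima with prominence above 5% of the line's
total intensity are peak candidates; the most intense candidate is the
loop centre.  Centres are linked across frames by minimum-displacement
assignment (scipy's Hungarian solver) with a 10-px search range and a
3-frame gap memory; tracks shorter than 10 frames are discarded.  The
gap memory and the per-track QC flags stand in for the interactive
supervision a human tracker would provide; no claim of equivalence is
made.  Each tracked line is split into **Loop** (9 pixels centred on the
peak), **Up** (rows above) and **Down** (rows below); windows truncated
by the kymograph edge are flagged `edge` and excluded from rate fitting,
as are lines with non-positive total intensity.  DNA amounts are the
region intensity fractions multiplied by 48.5 kbp, so
Up + Loop + Down = 48.5 kbp identically on every valid frame.

### Rate fitting (`loopx.rates`)

The loop growth curve (loop kbp vs time, valid frames only) is smoothed
with a second-order Savitzky-Golay filter, 50-point window (shrunk to
the largest odd length with a warning on shorter series).  Smoothing is
used *only* to locate the fitting window; the rate always comes from
ordinary least squares on the raw curve.  The window is the earliest
5-s span after loop initiation (first sustained excursion of the
smoothed curve above 1 kbp) in which the smoothed curve is monotone
within a 0.5-kbp decrement tolerance *and* shows at least 1 kbp of net
growth — the net-growth requirement keeps plateau or stalled phases out
of the fit, which a purely non-decreasing rule would accept.  Events
with no qualifying window are excluded.  Two behaviours are available
when the first candidate window fails monotonicity: `reselect` (default)
scans later start points; `exclude` drops the event, matching the
stricter reading in which early slip-back disqualifies an event
altogether.  Neither is claimed canonical.

Per-experiment activity is the fraction of tethers with at least one
accepted track during the acquisition.  Fractions are compared across
conditions with the two-sided Wilcoxon rank-sum test — enumerated
exactly over all C(n, n1) group assignments (mid-ranks on ties) for
combined n <= 10, tie-corrected normal approximation otherwise — and
rates with Welch's unequal-variance two-tailed t-test
(Welch-Satterthwaite degrees of freedom).  Two groups of zero variance
with different means raise an error rather than silently inflating the
variance; equal-mean constant groups return (t=0, p=1).

## FP binding and competition (`loopx.fp`)

Peptide probe concentrations (0.1 uM) are not negligible against the
measured dissociation constants (2.8-17.7 uM), so the binding model is
the exact ligand-depletion solution of 1:1 mass action,

    FP = (FPmax / 2[Pep]) ((C + Pep + Kd) - sqrt((C + Pep + Kd)^2 - 4 C Pep)),

whose bracketed term is exactly the bound-probe concentration.  The
discriminant is clamped at zero against round-off.  `fit_kd` runs
bounded least squares over (Kd, FPmax) on per-concentration replicate
means with inverse-variance (SEM) weights; an unweighted and a
raw-readings fit are available by flag.  Initialisation: Kd at the
geometric-mean titration concentration, FPmax at the maximum observed
mean; Kd bounded to (1e-4, 1e4) uM.  Standard errors are asymptotic
(scaled fit covariance); whether the original analyses report
fit-covariance or across-replicate errors is not documented, and this
choice is recorded here, not attributed.  Non-convergence returns a
flagged result.  Competition plates are background-subtracted
replicate-wise (matched probe+peptide-buffer readings) and compared with
unpaired two-tailed Student's t-tests (the competition figure legend
specifies plain t-tests; Welch's correction is reserved for the rate and
ATPase comparisons that specify it).

## ATPase analysis (`loopx.atpase`)

Phosphate-sensor time courses (uM phosphate vs seconds; an
absorbance-to-phosphate calibration factor is applied upstream by the
user) are fitted by OLS over a steady-state window.  With no explicit
window, start points are scanned from the trace beginning and the
longest suffix reaching r^2 >= 0.99 is taken, then trimmed further while
r^2 still improves — this sheds an initial lag phase automatically.  If
no window qualifies the full-trace fit is returned flagged.  Slopes are
reported both as uM/min and normalised by enzyme concentration as
ATP.condensin^-1.min^-1.  Fold-stimulation divides the rate at each DNA
concentration by the DNA-free rate (baseline fold is exactly 1);
relative uncertainties propagate in quadrature.  No saturation model is
fitted to the DNA titration.

## Synthetic data (`loopx.simulate`)

### Tether movies

The generator emulates a flow-stretched, doubly-tethered, intercalator-
stained lambda DNA imaged by TIRF: a vertical fluorescent line of
100 px (0.485 kbp/px) inside a 120 x 33 px ROI, margin 10 px.  A loop
event (start time, rate in kbp/s, anchor position, plateau size,
optional slippage) condenses the extruded DNA into a compact blob, drawn
as loop kbp spread uniformly over 7 rows at the anchor position.  The
non-looped DNA always spans the full distance from each attachment point
to the blob edge; its linear density falls as the loop grows.  The ideal
image is blurred with a sigma = 0.8 px Gaussian PSF (diffraction-limited
spot at ~110 nm pixels), scaled to 300 photons/kbp/frame, and degraded
with Poisson shot noise plus sigma = 2 counts Gaussian read noise.
Frames model offset- and background-corrected camera counts and keep
negative read-noise excursions — clipping at zero would rectify the
noise into a spurious background pedestal that biases every intensity
ratio (the 16-bit TIFF writer therefore adds a declared 100-count
baseline, removed again on read).  Stray-light background is available
via `background_mean` (default 0); because the published estimator
ratios *unsubtracted* median-filtered intensities, constant background
attenuates DNA amounts by b.n_px/total-photons, and the `quantify_on_tophat`
switch exists for such data.  All randomness flows from one integer
seed through a single generator instance; identical configurations are
bit-reproducible.

The blob geometry was chosen deliberately: a point-like punctum loses
substantially more of its band intensity to the radius-2 disc median
filter than the extended line does (~0.87 vs ~0.95 mass retention),
which would make the intensity-ratio estimator inconsistent by 6-9%
even without noise.  An axially extended blob with the line's PSF
cross-section attenuates like the line, the factor cancels in the
ratio, and the 9-px loop window captures ~99% of the blob.  One loop
per tether is simulated (the tracker follows a single most-intense
peak); events may not overlap in time.

**What the generator does not emulate:** polymer dynamics and thermal
wiggling of the tether, flow-stretching hydrodynamics, photobleaching,
intercalator binding kinetics, neighbouring tethers, drift, or camera
fixed-pattern noise.  Passing recovery tests therefore demonstrates the
correctness and calibration of the analysis chain on ideal-geometry
data, not robustness to every artefact of real movies.

**Known accuracy limits of the published estimator (measured on
noise-free synthetic data):** mature loops (>= 20 kbp) recover within
2%; younger tracked loops carry up to ~+3% because slack-DNA intensity
bleeds into the fixed 9-px window.  Because that bleed shrinks as the
loop grows and the median filter erodes the blob slightly more with
increasing size — and, under noise, the median filter drifts toward
mean-filter behaviour, spilling blob mass past the window — fitted
rates carry a systematic deficit of roughly 8%.  Across 50 events at
1.0 kbp/s and default SNR the median relative rate error is ~9%, inside
the 10% recovery tolerance but with little margin; surveys over blob
extent (3-9 px), PSF (0.5-2 px) and blob edge profiles did not reduce
the deficit below ~6% without breaking the noise-free 2% accuracy, so
the simple rectangular blob was kept.  Detection by the 5% prominence
threshold requires a loop of roughly 16 kbp, so tracks begin mid-growth;
this does not bias the rate fit, which only needs a growing window.

### FP plates and phosphate traces

FP plates draw replicate readings from the exact model plus i.i.d.
Gaussian noise (defaults: 2 mP noise, 3 replicates, 12 receptor
concentrations 0.1-100 uM, 100 nM probe, FPmax 60 mP — matching the
titration design and replicate structure of the assays emulated).
Phosphate traces are linear in time with Gaussian noise (defaults 50 nM
enzyme, 30-s sampling, 20 min, 0.05 uM noise).

## Problem sizes

Synthetic studies are scaled for quick turnaround: movies of 50-80
frames at 1 s/frame rather than full 1000-s acquisitions, 12 tethers
per simulated experiment, 50-tether detection studies, 100-seed
Monte-Carlo recoveries for Kd and ATPase slopes, 50-seed studies for
rates and fold-stimulation.  These sizes keep every recovery estimate
well-determined while the full test suite runs in well under a minute
of compute per study.

## Pipeline plumbing (`loopx.pipeline`, `loopx.cli`)

`PipelineConfig` (pydantic, unknown keys rejected, lossless JSON/YAML
round trip) carries every stage parameter; defaults mirror the
published analysis: median radius 2, top-hat radius 10, 11-px band,
9-px loop window, Savitzky-Golay 2/50, 5-s fit window, 1000-s
acquisition span, 48.5-kbp substrate.  `run_pipeline` is deterministic
given the seed and writes per-event rates CSV, per-tether partition
CSV, a summary JSON and a run manifest (package version, seed, config
hash); outputs are validated by re-parsing through their pydantic
models, whose JSON schemas ship under `loopx/schemas/`.  The `loopx`
command line exposes the chain as thin verbs
(`simulate kymo track quantify rates summarize compare fp atpase`).

## Known limitations

* Single-loop model; no Z-loops, multi-loop bookkeeping or two-colour
  analysis.
* The fixed axis column assumes a drift-free, vertical tether.
* The ~8% systematic rate deficit described above is inherent to the
  fixed-window intensity-ratio method at this SNR and window size.
* The rank-sum exact path enumerates up to C(10,5) assignments; larger
  designs use the tie-corrected normal approximation.
* Absorbance-to-phosphate calibration and enzyme-coupling kinetics of
  the phosphate sensor are out of scope.
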