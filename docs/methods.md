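# Methods

This note documents the quantitative procedures implemented in
`hypometrics`, their assumptions, parameter defaults, numerical choices,
and the scope of what the synthetic generators establish.

## Movement index (video_activity)

For a grayscale stack `I_0..I_{T-1}` with dynamic range `(lo, hi)`:

    index_t = mean_pixels |I_t − I_{t−1}| / (hi − lo),   t = 1..T−1

The normalization by the *fixed* dynamic range (rather than a per-video
maximum) guarantees the [0, 1] bounds and keeps indices comparable across
videos; the trade-off is that absolute values depend on how much of the
frame the animals occupy, so treated/vehicle *ratios* and within-video
trends are the comparable quantities. The index is symmetric under time
reversal and zero exactly when consecutive frames are identical. Optional
Gaussian pre-blur (off by default) suppresses sensor noise before
differencing. Binning tiles `[0, duration)` half-open; a trailing partial
bin is kept and flagged rather than dropped.

## Beat counting (cardiac)

The ROI mean-intensity trace is detrended by subtracting a moving average
over one slowest-expected-beat period (window = 60/min_rate s). Peaks are
detected with a minimum separation of 60/max_rate s and prominence ≥
k·σ̂ (default k = 3, configurable). The noise scale σ̂ is the MAD-based SD
of the lag residual x_t − x_{t−P}, where P is the dominant
autocorrelation lag: for a periodic pulse train this residual cancels the
beat component even when a beat spans only ~3 samples, which defeats
sample-scale estimators (a median-filter residual misreads the beat as
noise at 180 bpm / 10 fps). Noise-free traces have near-zero residual, so
a floor of 10⁻³ of the detrended swing keeps genuine peaks detectable. A
secondary amplitude gate rejects peaks below half the 75th-percentile peak
height; on ECGs this suppresses T and P waves, which otherwise double the
rate. The rate estimator

    bpm = 60 · (n_peaks − 1) / (t_last − t_first)

is unbiased with respect to window/beat phase alignment, unlike
n_peaks/duration. A perfectly flat trace returns 0 beats (asystole is a
result, not an error). The whole chain is invariant under affine intensity
transforms a·x + b, a > 0.

## ECG metrics (cardiac)

Computed over a 30 s window: isoelectric baseline = median of PR segments
(100–40 ms before each R peak); mean amplitude = mean R height above that
baseline; QRS interval = mean width at 10 % of the R amplitude (threshold
crossings walked outward from each peak); ST height = mean signal 40–80 ms
after the QRS end minus baseline; pulse rate from mean R-R. The QRS/ST
definitions are declared and configurable because the original
measurements in this domain are usually delegated to commercial analyzers
whose algorithms are opaque; here they are tested against the generator's
parametric truth. Rate classification uses the porcine normal range
70–120 beats/min as a closed interval: 70 and 120 are "normal", anything
strictly outside is brady-/tachycardia. Windows with R-R coefficient of
variation above 0.2 (configurable) are flagged `irregular` and their rate
should be interpreted cautiously.

## Respirometry (respirometry)

OCR is −slope of an ordinary-least-squares line through the O2 trace; the
fit window is a required, recorded parameter (default: full trace after a
configurable equilibration skip), since a sub-window choice changes the
estimate and must be auditable. QC before fitting: a leak is any rolling
window of ≥ 5 min (default) whose fitted slope exceeds +0.5 units/min
(default); a bubble is a single-step change larger than 8× the robust
noise SD of the first differences. Either flag excludes the trace with a
reason; excluded traces are refused by `fit_ocr` and never enter group
summaries — data are flagged, not silently dropped. Rates are reported per
chamber (a vial holds several organisms; cumulative consumption is the
measured quantity); per-organism division is available but off by default.
Group fold change = mean(treated)/mean(vehicle) with a seeded 1000-resample
bootstrap percentile interval; the hypothesis-testing layer is out of
scope. Units are carried per trace and never mixed within a comparison.

## Perfusion MVO2 (perfusion)

    [O2]  = 1.34 · Hb · SO2 + K(T) · pO2        [mL O2/dL]
    MVO2  = (([O2]a − [O2]v)/100 · Q / weight) · 100   [mL O2/min/100 g]

SO2 comes from a co-oximeter measurement when present; otherwise from the
Severinghaus closed form SO2 = 1/(23400/(pO2³ + 150·pO2) + 1), the
standard human-blood empirical curve (half-saturation ≈ 26.9 mmHg). For
hemoglobin-based oxygen-carrier perfusates whose P50 differs, an optional
`p50` override rescales pO2 before the curve; the default is the human
curve. K(T) is interpolated piecewise-linearly over a bundled
physiological solubility table (0.00415 mL O2/dL/mmHg at 4 °C falling to
0.0030 at 37 °C); the table is swappable and the K actually used is logged
into every result row, because the absolute MVO2 level shifts slightly
with the K-table/saturation-curve variant. Negative MVO2 (venous content
above arterial) is returned with a warning flag, not clipped — it signals
a measurement anomaly the analyst must see. Arterial/venous temperature
mismatch beyond 0.5 °C (configurable) is likewise flagged.

The synthetic perfusion generator fixes the arterial sample, computes the
venous content the Fick formula requires for the requested true MVO2, and
inverts the content function to a Severinghaus-consistent venous pO2. The
content function is strictly increasing in pO2 but has no tidy closed-form
inverse (cubic saturation term plus linear dissolved term), so the
inversion uses Brent root-finding at 10⁻¹⁴ tolerance — five orders below
the 10⁻⁹ round-trip requirement, and effectively exact.

## Ratiometric ATP/ADP quantification (ratiometric)

Pipeline per image: (1) nuclei from the RFP marker — Otsu threshold,
8-connected components, [min_area, max_area] size filter (Otsu is the
default because the original GUI pipeline's threshold method is
unspecified; the method is pluggable); (2) each cell = its nucleus
expanded by 4 pixels of Euclidean distance, with contested pixels assigned
to the nearest nucleus so masks are disjoint by construction and each
nucleus is a subset of its cell; (3) per-cell ratio = mean YFP / mean CFP
(ratio of means, not mean of per-pixel ratios — low-intensity pixels would
otherwise dominate the variance); a zero CFP mean flags the cell
`undefined` instead of raising; (4–6) per-image summary = mean of
non-flagged per-cell ratios reported *together with* the cell count.
Dividing the mean again by the count would yield a non-ratio quantity, so
the mean + n reading is the default; (5) tracking links cells to the
nearest previous-timepoint centroid within 2× the median nucleus radius
(default), starting new tracks for unmatched cells, and per-timepoint
summaries are emitted regardless of linkage success. Per-pixel ratio
images use `yfp / max(cfp, ε)` to stay finite. Per-cell ratios are
invariant under any common scaling of both channels.

## Assays (assays)

- TEER: tissue impedance = Z(100 Hz) − Z(100 kHz), exactly linear;
  negative values flagged anomalous, never dropped.
- Comparative CT: ΔCT = CT_target − CT_housekeeping per sample; group mean
  ΔCTs are differenced (treated − control) *before* exponentiation
  (fold = 2^−ΔΔCT); averaging before exponentiation is the documented
  default since the alternative order is also seen in practice. CT values
  outside (0, 40] are rejected.
- Binding: constrained four-parameter logistic
  B(c) = bottom + (top − bottom)/(1 + (c/IC50)^h), fitted on
  log-concentration for conditioning, asymptotes fixed at 0/100 on the
  percent-specific-binding scale by default. Series whose observed span is
  under 20 % of the asymptote span carry no inflection information and are
  flagged non-converged; a fitted IC50 below the lowest tested
  concentration is reported as the bounded estimate "IC50 < c_min",
  matching how very-high-affinity ligands are conventionally reported.

A precision note: for the standard 8-point threefold ladder from 10 µM
with additive noise of SD 3 (percent scale), the Fisher information bound
gives σ(log₁₀ IC50) ≈ 0.033 even with the Hill slope known, i.e. a median
relative IC50 error of about 5 % for *any* unbiased estimator. The
nonlinear-least-squares fit here sits at that floor (Monte-Carlo medians
4.8–5.6 % depending on where the IC50 falls in the ladder); materially
tighter recovery requires replicates or more concentrations, not a better
fitter.

## Synthetic generators (synthio)

Each generator returns data plus a truth record of its generating
parameters and is bitwise deterministic given (params, seed); every call
owns its RNG stream. Defaults mirror the experimental designs the package
targets: heart videos at 1 frame/100 ms; O2 vials logged once per minute
for 60 min with five organisms per chamber; RFP/YFP/CFP images every
20 min for 180 min; 8-concentration threefold binding ladders from 10 µM;
respirometry group sizes 9 treated vs 7 vehicle at one-third suppression;
perfusion records at the treated/vehicle consumption levels typical of
cold-perfused grafts (2.39 / 4.28 mL O2/min/100 g). Where the underlying
studies specify no value (swim kinematics, dish illumination, noise
levels) the defaults are plain choices a microscopist would call
unremarkable: Gaussian random-walk blobs with step SD = activity_level ×
6 px on a bright dish, 16-bit dynamic range, Gaussian sensor noise.

What the generators deliberately do not emulate: optics (PSF, shading,
photobleaching), organism morphology and behavior beyond net
displacement, hemodynamic waveform realism beyond a schematic P-QRS-T,
chamber thermodynamics, or cell division/death during time courses. A
green recovery test therefore establishes that the estimator is correct
*for its stated signal model* and robust at the stated noise levels — not
that it is robust to every artifact of real recordings; the QC stages
(leak/bubble flags, irregularity flags, undefined-value flags) are the
designed escape hatches for real-data pathologies.

Cell images are float32 so that YFP = ratio × CFP holds exactly in the
noise-free limit; integer quantization would otherwise corrupt the truth
ratios at the fourth decimal.

## Pipeline and provenance (pipeline, cli)

A run is a YAML-serializable config validated against a schema that
rejects unknown keys by path. Every stochastic stage derives its seed from
the config seed via SHA-256 of a stage tag, so stage results are
independent but fully determined; two runs of one config are
byte-identical in all tables (asserted in tests). Every GroupTable row
carries provenance (generator or source file plus parameters) and a QC
flag; excluded rows never enter summaries. Summaries use the sample
standard deviation (n−1); single-value cells report an undefined SD
rather than 0. Exit codes: 0 success, 2 config error, 3 input error,
4 fatal QC exclusion.

## Known limitations

- The movement index's absolute scale depends on animal size/count in
  frame; only ratios and trends are comparable across setups.
- The beat counter assumes a dominant periodic component; highly irregular
  rhythms are flagged, not parsed into arrhythmia classes.
- MVO2 absolute values shift slightly with the solubility-table and
  saturation-curve variant; both are logged and swappable.
- Tracking is nearest-centroid only — adequate for adherent cells on a
  20-min grid, not for confluent motile populations.
- The ΔΔCT implementation assumes one housekeeping gene and no PCR
  efficiency correction.
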