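# Methods

This note records the models, defaults and design decisions behind
`voltkit`, and what the synthetic-data experiments do and do not show.

## Signal model

A measured voltammogram is treated as

    y(V) = background(V) + peaks(V) + noise,

where the background is the non-Faradaic (capacitive) current plus
drift, the peaks are the Faradaic responses of electroactive species,
and the noise is broadband measurement noise. The analytical quantity
is the response `d = c − b` at each peak: the current at the sampled
peak extremum minus the estimated background at the same index. `c` is
read from the series the baseline was fitted to, so `d` equals the
background-corrected signal at the peak — an identity the tests rely
on. Zero response resolves to anodic polarity by the `d ≥ 0`
convention.

## Processing chains

**DPV**: drop the opening `floor(f·n)` samples (default `f = 0.05`) to
discard the charging transient; Savitzky–Golay smooth the current
(window 11, order 3); fit the ALS baseline; detect prominence-filtered
local extrema on the corrected signal; keep the peak with the largest
`|d|` (ties to the lower potential); classify `d` against the
threshold. A trace with no surviving peak yields an explicit
non-detection finding, not a failure.

**CV**: locate the sweep reversal at the global potential extremum
(robust to readback jitter; a monotone potential yields an empty
reverse sweep plus a warning); optionally smooth (off by default — CV
peaks are broad relative to the grid and smoothing buys little);
fit the per-sweep linear baseline; search anodic peaks on the forward
sweep and cathodic on the reverse. With repeated scans, the scan whose
mean absolute current difference from its following scan is smallest is
selected ("stable electrode conditions"); that criterion is this
package's choice of rule for a stated goal.

## Baseline estimators

*Polynomial* (default degree 2): least squares with the abscissa mapped
to [−1, 1] for conditioning; fitted values agree with the raw normal
equations to 1e−8 relative (tested). *Segmented linear* is the default
CV quantification baseline: within each sweep a line is fitted to the
opening `edge_fraction` (default 0.2) of the sweep — the pre-peak
region — and extrapolated. The global quadratic is retained as an
alternative and drift diagnostic because a single polynomial smooths
across the sweep reversal, where the capacitive offset changes sign.

*ALS*: minimise `Σ wᵢ(yᵢ−zᵢ)² + λ‖D₂z‖²` with `D₂` the (n−2)-row
interior second-difference matrix (standard Whittaker construction;
boundary values constrained by the data term only). Weights start
uniform — so round one is the symmetric Whittaker smoother — and
re-assign to `p` above / `1−p` below the current baseline; iteration
stops at a weight fixed point, when the weight-change norm reaches
`tol` (default 0), or at `max_iter = 50`. The solver is a sparse LU on
the pentadiagonal system; it matches a dense direct solve to 1e−8
relative at every iteration (tested). The penalty assumes a
near-uniform potential grid, the usual case for instrument exports.

**Choice of λ.** The Whittaker penalty acts as a smoother whose
half-width grows like `λ^(1/4)` samples. The baseline must stay stiff
across the full support of a Faradaic peak, or it bends upward into the
peak and `d` is underestimated: at λ = 1e5 (half-width ≈ 18 samples)
the noise-free bias against a peak of σ ≈ 10 grid steps is about 13%.
The default is λ = 1e7 (half-width ≈ 56 samples), which brings the
noise-free bias near 2% while still tracking linear and gently curved
backgrounds; softer backgrounds can drop to 1e5–1e6. Asymmetry default
`p = 0.01`.

The reconstruction invariant `y == baseline + corrected` is kept exact
in floating point by computing `corrected = y − fitted` and re-deriving
`baseline = y − corrected`.

## Peak detection

Strict local maxima (anodic) and minima (cathodic) with plateaus
resolved to their leftmost index; prominence is the height above the
higher of the two flanking valleys. Candidates below `min_prominence`
are dropped, then a minimum index separation is enforced greedily in
order of descending prominence. The separation filter operates within
each polarity — an adjacent anodic/cathodic pair is a legitimate redox
couple. The default prominence floor is data-driven: 3× a robust noise
sigma, `1.4826 · MAD(Δy)/√2` (differencing cancels the smooth signal
and doubles the noise variance). Sub-sample (parabolic) peak
interpolation is deliberately absent: the reported extremum is a
sampled point.

## Synthetic study conditions

The generators emulate trace morphology, not electrode kinetics.
DPV default: 0→0.6 V in 121 points (5 mV step, the typical DPV step
increment), Gaussian peak at 0.30 V with amplitude 5 µA and σ = 0.05 V,
background `1 + 2V` µA plus a 3 µA transient decaying at 30 V⁻¹,
Gaussian noise 0.1 µA (signal-to-noise 50). CV default: −0.2→0.8→−0.2 V
at 201 points per sweep, anodic peak 5 µA/σ 0.08 V at 0.30 V, cathodic
mirror at 0.20 V, ±1 µA capacitive offset, 2 µA/V drift, 0.1 µA noise.
Gaussian peak shapes give closed-form ground truth but lack the
asymmetric diffusion tailing of real voltammetric peaks, and the
generator has no scan-rate dependence, electrode fouling or pulse
artefacts; passing recovery tests therefore demonstrates correctness of
the signal-processing chain under the stated morphology, not
performance on every real electrode.

Under these conditions (100 seeds) the DPV chain recovers the peak
potential within one grid step in ≥ 95% of runs and the response with
≈ 2% median relative error; the CV chain recovers the anodic response
with ≈ 3% median relative error. These batteries run in seconds and are
recomputed by `scripts/acceptance.py`.

**A bias subtlety.** At exactly zero noise the median amplitude error
equals the small downward ALS smoothing bias (≈ 0.10 µA at defaults).
At the default noise level the upward selection bias of reading a
sampled maximum partially cancels it, so the median error is *smaller*
with a little noise than with none. Noise degradation of recovery is
therefore monotone from the default level upward, which is how the
stochastic-monotonicity test is framed.

## Numerical and interface choices

- CSV dialect: comma-separated, first column potential (V), second
  current (µA), optional single header line auto-detected (a numeric
  first row is never consumed as a header — property-tested); extra
  columns ignored; decimal commas unsupported; units taken as-is.
  Writing uses nine-decimal fixed point, so a write/read round trip is
  identity to 1e−9 absolute.
- Savitzky–Golay edges: the polynomial is re-fitted over the truncated
  one-sided window, so polynomial inputs of degree ≤ order are
  reproduced exactly everywhere; with fewer points than coefficients
  the minimum-norm fit interpolates and the edge value is the sample
  itself.
- Turning-point detection uses the global potential extremum rather
  than local sign changes; sweep ranges always partition the trace.
- The classification threshold is a required user input; the reference
  trace in a DPV comparison is processed symmetrically and does not set
  the threshold.
- Reports embed the full effective parameter set and no timestamps;
  identical inputs give byte-identical reports.
- Config files are JSON; CLI flags override file values which override
  defaults.

## Known limitations

No resampling onto a uniform grid (near-uniform grids assumed); no
peak-area integration or overlapping-peak deconvolution; no
concentration calibration; mixed Whittaker penalty orders other than 2
are out of scope. The CV multi-peak case reports every surviving peak
per sweep without ranking beyond prominence.
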