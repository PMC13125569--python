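# Methods

This note documents the models, conventions and numerical choices behind
`microtension`, what the synthetic-data generators do and do not emulate,
and the known limitations of each component.

## Force readout model

The platform measures one scalar per well and timepoint: the distance
between the two bead centroids. Three conventions turn it into a force:

* **Scale.** The µm/px scale is self-calibrated per well: the first frame's
  pixel gap is mapped to the physically measured initial inter-post distance
  (≈4 mm). This absorbs objective/magnification differences but assumes the
  first frame is at rest; any pre-imaging contraction biases all deflections
  by a constant.
* **Symmetric pair.** Tension in a two-post tether loads both posts equally,
  so gap closure is twice the per-post deflection and `F = k·Δd/2`
  (`mode="symmetric_pair"`, the default). `mode="per_post"` (`F = k·δ`) is
  exposed for sensitivity analysis; on half the closure it is exactly
  equivalent.
* **Per-cell normalization** divides by the *initially seeded* cell count
  (volume × density, default 90 µl × 10⁶ /ml = 9×10⁴ cells); proliferation
  or death during culture is deliberately not modelled.

Active/residual splitting assumes the post-stimulation force relaxes to a
plateau; the residual is the mean over a user-chosen window, and the window
should start ≥3 relaxation time constants after the drug for the ~2%
accuracy quoted in the tests.

## Bead segmentation and sub-pixel centroids

Frames are polarity-normalised (beads bright), Gaussian-blurred
(σ = 2 px default), thresholded by Otsu, and connected components are
filtered by area and circularity before keeping the two largest (area ties
broken by left-most centroid — deterministic). Centroids are intensity
first moments computed over the component's bounding box padded by
`3σ_blur + 3` px with the window-border median as local background: using
the full blurred skirt rather than the hard mask removes the sub-pixel bias
a threshold boundary introduces at fractional bead positions (measured
residual ≲ 0.005 px on ideal discs, < 0.3 px at SNR 10). Coordinates are
(row, col), 0-based, pixel centres at integers. A Hough-circle backend was
considered and rejected: moments are parameter-light and deterministic.

## Beam-on-foundation spring-constant model

The post is an Euler–Bernoulli beam (`I = πd⁴/64`); the PDMS mat is a
Winkler foundation with modulus per unit length `k_w = E_pdms·d/(1 − ν²)` —
a first-order elastic-foundation mapping scaled by the contact width. The
embedded segment is treated as semi-infinite; its end compliance under shear
`F` and moment `F·a` is the Hetényi matrix `[[2λ/k_w, 2λ²/k_w], [2λ²/k_w,
4λ³/k_w]]`, giving total tip compliance `a³/3EI + (2λ + 4λ²a + 4λ³a²)/k_w`.
The lever arm `a` is the active length plus the bead radius by default
(`load_at_bead_center=True`); the rigid-clamp formula `k = 3EI/L³` uses the
bare active length by default so the two functions agree with their textbook
forms. The components are reported separately and sum to `1/k` to machine
precision.

Properties worth knowing:

* With soft (kPa-range) PDMS and ~1 mm steel posts, `λa ≪ 1`: compliance is
  dominated by *foundation translation*, so `k ∝ d^(7/4)` along a diameter
  sweep, and the rigid-clamp limit is approached only as `k_w^(−1/4)` — the
  bending term becomes dominant only for astronomically stiff foundations.
  The tests therefore check the rigid limit deep in the converged regime and
  the supercubic (`≥ d³`) growth only where foundation rotation dominates.
* For default geometry (10 mm embedment, 5 kPa PDMS), `embedded_length·λ < 3`
  and the semi-infinite assumption is formally violated; the model warns and
  proceeds. Predictions there are order-of-magnitude (0.85 µN/µm predicted
  vs ~1.3 µN/µm measured for compliant posts) — the model's purpose is
  parametric trends, not absolute calibration, which is why measured spring
  constants are always explicit inputs downstream.
* Oracle equivalence (≤2%) against a finite-difference minimisation of the
  beam + foundation energy is established on grids where the semi-infinite
  regime holds, with the oracle's foundation domain extended to ~12/λ.

The bead's modulus and density are stored but unused: in statics a rigid
load-application point is an excellent approximation for a ceramic bead on
kPa PDMS.

## Calibration

`fit_spring_constant` is OLS with a free intercept — the probe contacts the
bead with an unknown force offset, and only the slope is physical. Samples
above the sensor ceiling (400 µN compliant / 4000 µN rigid, by condition)
are truncated before fitting. Fitted non-positive slopes are flagged
invalid, excluded from condition summaries, and counted.

## Fascicle tensile analysis

Records are grip-to-grip; `gauge_length_mm` is required metadata since it
cannot be inferred from a force–displacement file. Preconditioning cycles
are stripped by taking the final monotone segment (reversal-tagged). The
strain origin is the first upward crossing of the 0.015 N preload (linear
interpolation). Nominal stress divides by the initial circular CSA from the
measured diameter; specimens under 90 µm are rejected (boundary inclusive).
The tangent modulus is the OLS slope inside the 0.5–1% strain window
(measured from the preload origin), stiffness the force–displacement slope
over the same window, and failure is the *global* force maximum — the
simplest deterministic reading of a ramp-to-failure record; a record whose
maximum is its final sample is flagged "no failure detected" rather than
rejected.

## DSC endotherms

A straight baseline is fitted over two flanking windows (each ≥5 samples)
and subtracted. The signal is lightly smoothed (cubic Savitzky–Golay,
window ≈ n/80 samples) before feature extraction so the metrics tolerate a
few percent of instrument noise. T_peak is the vertex of a quadratic fitted
over the top 20% of the peak (falling back to the grid argmax for narrow
caps); FWHM comes from linearly interpolated half-height crossings; the
onset is ISO-style — the tangent at the maximum-slope point of the leading
edge intersected with the baseline, which for a Gaussian peak lands at
µ − 2σ exactly. Curves from endo-down instruments are sign-normalised by the
`endo_down` flag. Peaks below 3× the baseline-fit residual SD are treated
as "no transition". Enthalpy integration and multi-peak deconvolution are
out of scope.

## Morphometrics

* **Orientation.** Hann-windowed 2-D FFT power, angular sum inside a radial
  band of 0.1–0.8 Nyquist (DC and highest frequencies excluded), spectral
  angle rotated 90° so the reported angle is the structure direction,
  folded to [0, 180) and measured counterclockwise from the horizontal
  image axis. The principal angle is the circular mean of the doubled-angle
  distribution and the alignment index its resultant length — isotropic
  noise scores < 0.1 at the 99th percentile over 500 seeds.
* **Circularity.** `4πA/P²` per labeled object (area ≥ 20 px), clipped to
  [0, 1]. The perimeter is the length of the marching-squares iso-contour
  after a 3-point moving average along the polygon. This was chosen over a
  Crofton estimator after measuring both: the smoothed contour is the only
  estimator tested that simultaneously scores rasterized circles ≈1
  (r = 50 → 0.984), squares near π/4 (0.809), 2:1 ellipses near the
  Ramanujan value 0.8412 (0.828), and is stable (< 0.01) when the same
  shape is rasterized at doubled resolution; the 4-direction Crofton
  over-scores squares by ~0.10 and is unstable across resolutions.
* **Intensity.** Background defaults to the histogram mode of the raw image
  (exact binning for integer dtypes), robust when the foreground is sparse;
  group means of background-subtracted per-image means are expressed as
  fold versus a reference group. Nuclei segmentation from raw fluorescence
  is out of scope — masks are inputs.

## Estimation statistics

Cohen's d uses the (n−1)-weighted pooled SD; degenerate zero-spread input
raises rather than returning ±∞. The permutation test uses the two-sided
mean difference: when the number of label arrangements `C(n, n_a)` is at
most 20 000 all splits are enumerated and `p = count/total`; otherwise
`n_perm` seeded relabelings are drawn and `p = (1 + count)/(1 + n_perm)`,
never exactly zero. A `≥` comparison with a 1e−12 slack keeps ties stable
under floating-point noise. Reference genes in 2^−ΔCt are combined by the
arithmetic mean of Ct (geometric mean of linear quantities).

## Synthetic data: what it emulates, what it does not

Generators are deterministic given (seed, parameters) — byte-identical
outputs, hash-checked in tests — and every artifact ships a truth table
sufficient to compute each downstream metric.

* **Bead frames** are area-coverage rendered discs (4× supersampling), so
  sub-pixel centroid truth is exact by construction; noise is additive
  Gaussian. Not emulated: illumination gradients, defocus, debris, tissue
  shadowing over the beads, or stage drift — so passing round-trip tests
  demonstrates the pipeline's numerical fidelity, not robustness to real
  brightfield artifacts.
* **Calibration sweeps** are exactly linear plus Gaussian force noise (no
  probe slip or contact nonlinearity).
* **Tensile records** follow a toe-exponential `σ = A(e^{Bε} − 1)` joined
  C¹-continuously to a linear limb at the toe strain (default 0.4%,
  B = 200), then a steep linear drop past the failure strain; force noise
  is multiplicative (default 1%), sampling matches a 1 mm/s ramp at 200 Hz.
  Cohort generation adds mean-preserving lognormal modulus dispersion
  between specimens. Not emulated: viscoelasticity, grip slippage, partial
  fiber pull-out plateaus.
* **Endotherms** are a single Gaussian on a linear baseline over a
  20–100 °C grid; real collagen endotherms are asymmetric, which mainly
  biases the onset construction — a limitation shared with any
  tangent-method analysis.
* **Textures/nuclei** are cosine gratings with angle jitter (coherence dial)
  and non-overlapping rasterized ellipses on a jittered grid with analytic
  (Ramanujan) circularity truth.
* **Timecourses** are logistic rises `F(t) = plateau/(1 + e^{−rate(t−t₅₀)})`
  with additive noise. Note a logistic is nonzero at t = 0; recovery tests
  compare against closure *relative to the first frame*, mirroring what the
  tracking pipeline can observe.

## Problem sizes in tests and the acceptance script

Simulation sizes were chosen as the smallest that make each statistical
check sharp: 100 sweeps for calibration recovery (mean SE ≈ 0.03% of k),
200 seeds × 6-per-group cohorts for the tensile group-difference check
(seed-mean SE ≈ 0.05 pp), 2000 null simulations at n = 10 + 10 with 499
permutations for type-I error (binomial SE ≈ 0.5 pp), 500 replicates for
centroid noise robustness. The acceptance script runs in a few seconds; the
full test suite in well under a minute.

## Known limitations

* The beam model is linear-elastic with a Winkler foundation: no PDMS
  hyperelasticity, no 3D continuum effects, no dynamics; absolute k
  predictions for soft mats are indicative only.
* Per-batch calibration varies (different reported batches differ by ~6%),
  so every downstream conversion requires an explicit measured k — nothing
  is hard-coded.
* Whether published force values use `Δd` or `Δd/2` is convention-dependent;
  this package states its convention (`symmetric_pair`) and keeps the
  alternative one switch away.
* The orientation analysis reports a single principal direction; bimodal
  fiber populations are visible in the returned distribution but not
  summarised.
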