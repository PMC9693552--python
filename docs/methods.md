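# Methods

This note documents the models implemented in `saxsfibril`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the known limitations.

## Geometry and conventions

A pixel at radial offset `r` (mm) from the beam centre scatters at
`2θ = arctan(r/L)`, giving `q = (4π/λ)·sin θ` in nm⁻¹.  The exact formula is
used rather than the small-angle approximation `q ≈ 2πr/(λL)`; at the
reference geometry (λ = 0.2 nm, L = 982.8 mm) the two agree to better than
0.1% across the detector, but the exact form costs nothing.

The azimuth χ is zero along the displayed-image "up" axis (row index
decreasing) and increases counter-clockwise, stored in [0, 2π).  The
experiment itself fixes no reference axis, so the convention is declared
once and shared by the reduction code and the simulator.  Internal units are
nm and nm⁻¹ everywhere; configs may give the wavelength in Å (converted on
load).  The default pixel pitch, 0.172 mm, is that of Pilatus-class hybrid
photon-counting detectors; it is always overridable.

## Reduction

Pixels are assigned whole to (q, χ) bins — no pixel splitting — which keeps
the binning exactly reproducible by a per-pixel reference loop (this
equivalence is asserted in the tests).  Bins that receive no usable pixels
propagate as missing values, never as zeros.

`H(χ) = ∫ I(q_r, χ) dq_r` over a configurable band (default 0.3–2.0 nm⁻¹)
is evaluated per χ bin by splitting the band into 64 radial sub-bins,
averaging the pixels of each sub-bin, and integrating the sub-bin means with
the trapezoidal rule (constant extension to the band edges, so a flat frame
integrates exactly to `c·(qmax − qmin)`).  Integrating means rather than
summing raw pixels makes H independent of how many pixels each annulus
happens to contain.

**Effective azimuth nodes.**  On a coarse detector, a narrow wedge near a
principal axis contains only whole pixel columns, so the pixels of a χ bin
cluster away from the bin's nominal centre.  Where the azimuthal profile is
steep (the flank of a streak) this produces a deterministic ±40%
bin-to-bin jitter if H values are attributed to bin centres.  Each bin
therefore records the contribution-weighted mean azimuth of its own pixels,
and all downstream evaluation (folding, the inversion operator) uses these
effective nodes.  With 0.5° bins on the 512×512 synthetic detector this
removes the jitter's first-order effect entirely; the recovered RMS angle
is stable to ±0.01° across noise realizations.

χ binning defaults to 720 bins over the full circle (0.5°/bin).  Resolving
an orientation spread of ~3° demands sub-degree azimuthal resolution: at
2°/bin, fold alignment is quantized to ±1° and bin averaging adds ~w²/12 of
spurious angular variance, which together inflate a 3.3° RMS to ≈3.45°.

Folding exploits the centrosymmetry of the pattern: the profile is aligned
so the circular argmax sits at zero, mapped by
χ → min(χ mod π, π − (χ mod π)) onto [0, π/2], and averaged over
contributing bins (effective nodes averaged alongside).

The anisotropy score `(max H − min H)/mean H` is 0 for a constant profile
and ~25 for the reference streak pattern; the default classification
threshold is 0.5.  At very low photon budgets the score's Poisson noise
floor rises toward the threshold, so classification is only meaningful with
a few times 10⁶ counts or more at this binning.

## Power-law fit

The lamellar diagnostic is an ordinary least-squares line in log–log space;
the exponent is the negative slope.  For oriented patterns the profile is
averaged over two centrosymmetric wedges of half-width 15° about the streak
axis, and two corrections are applied before fitting:

* **Coverage filter.**  A q bin whose pixel count inside the sector falls
  below 98% of the unmasked reference is dropped: a detector gap crossing
  the streak removes an unrepresentative (brightest) part of the azimuth
  range and can halve the annulus mean.
* **Isotropic floor subtraction.**  The mean intensity of wedges
  perpendicular to the streak is subtracted per q bin, so the fit sees only
  the oriented component; an additive flat background otherwise flattens
  the high-q end and biases the exponent low by ~0.03.

The default fit window, 0.4–1.8 nm⁻¹, is the region where intraparticle
interference dominates on the synthetic patterns: above the beamstop
vicinity and below the range where the streak signal approaches the floor.
On ground truth q^−2.03 the pipeline recovers 2.017 ± 0.002 — the small
residual bias is the second-order remnant of the discrete azimuthal
sampling of the steep streak profile within the wedge.

## Broad-peak fit

The isotropic branch fits
`I(q) = c·q^−b + d + A·exp(−(q − q₀)²/(2σ²))` by bounded nonlinear least
squares.  The peak position is initialized at the maximum of a
moving-median-smoothed residual from a background-only fit; five jittered
restarts (fixed sub-seeds, deterministic) guard against local minima and the
best-SSE convergent fit wins.  A peak is reported (`found = True`) only if
the amplitude exceeds three times its standard error *and* 10⁻³ of the data
maximum — the second guard matters on featureless frames, where the
background model fits exactly, its covariance collapses, and an arbitrarily
tiny bump would otherwise be "significant".  Non-convergence yields
`found = False` with a diagnostic, never an exception.  The characteristic
period is `d = 2π/q_peak`, exact by construction.

## Orientation transform and inversion

For fibrils at angle μ to the alignment axis with density f(μ) on
[0, π/2], the streak profile is

    H(χ) = 4 ∫_χ^{π/2} f(μ) sin μ / √(cos²χ − cos²μ) dμ .

The substitution u = cos μ converts this to the Abel-type form
`H = 4 ∫_0^{cos χ} g(u)/√(cos²χ − u²) du` with `g(u) = f(arccos u)`.  The
density is modelled as piecewise linear on its μ grid (constant-extended to
the interval ends), and each cell integral of `(a + bu)/√(c² − u²)` is taken
in closed form (`a·arcsin(u/c) − b·√(c² − u²)`), which handles the
inverse-square-root endpoint singularity exactly.  The forward operator is
verified in the tests against 4096-point smooth quadrature (after
u = c·sin θ) to <0.1% and against the closed-form limit: a uniform density
f = 2/π gives H ≡ 4.

Inversion solves `min ‖Mf − H‖² + λ²‖D₂f‖²` subject to f ≥ 0, with D₂ the
second-difference operator and λ = 10⁻³·‖M‖₂ (fixed, no automatic tuning; a
pathologically ill-conditioned operator raises a warning and a tenfold
stronger penalty).  Non-negative least squares is preferred over the
classical series inversion of the Schlömilch equation because the latter
differentiates H and is fragile under noise; the series formula is kept as
an independent cross-check in the test suite.  The recovered density is
reported on a grid extended to μ = 0 and π/2 (matching the operator's
constant-extension convention — a bin-centre grid starting at w/2 would
silently drop ~6% of the mass of a 3°-wide distribution) and renormalized
to unit integral, `∫ f dμ = 1`, treating f as a probability density over the
angle itself rather than a sin μ-weighted measure.

Before inversion the folded profile has its isotropic floor removed — the
5th percentile of H over χ — and values driven negative are deliberately
*kept*: clipping would rectify tail noise into a positive bias that the
μ²-weighted RMS statistic amplifies, whereas the non-negative model simply
pulls negative bins toward zero.

The summary statistic is the RMS angle about the alignment axis,
`√(∫ μ² f dμ / ∫ f dμ)` in degrees (closed-form checks: a spike at zero
gives 0°, the uniform density 90/√3 ≈ 51.96°).  It is computed about μ = 0,
not about the mean, because folding has already placed the alignment axis
at zero.

## Synthetic data generator

The generator emulates the two regimes observed for bacterial cellulose
envelopes, with ground truth known exactly:

* **streaked** — noiseless intensity `A·q^−α·H_true(χ_folded)` with
  `H_true` the forward transform of a truncated-Gaussian f(μ) of requested
  RMS (default 3.3°) and α = 2.03 by default.  The simulator deliberately
  shares the forward transform with the analyzer so recovery tests are true
  round trips; the independent quadrature oracle protects against a shared
  bug.
* **isotropic** — `q^−α` baseline (α = 1 by default) plus a Gaussian ridge
  at `peak_q` (default 0.85 nm⁻¹, σ = 0.3 nm⁻¹, amplitude 1.5× the baseline
  at the peak); a variant preset is parameterized directly by the real-space
  period (7.5 nm → peak_q = 2π/7.5 ≈ 0.8378 nm⁻¹).

Noise is pure Poisson — hybrid photon-counting detectors contribute
essentially no read noise — drawn from a single generator seeded per spec.
A fraction of the photon budget (default 5%) is spread as a flat isotropic
background; the expected total over usable pixels equals the budget.  The
mask contains a beamstop disk and two horizontal detector-gap bands placed
centro-symmetrically, so the noiseless intensity keeps its point symmetry.

The default detector is 512×512 pixels of 0.4 mm at L = 982.8 mm and
λ = 0.2 nm: a desk-scale stand-in that covers the central ~205 mm of a
Pilatus-class detector at reduced resolution, reaching q ≈ 3.3 nm⁻¹ at the
edge — enough to span both the power-law window and the broad-peak region.
Larger frames are available by passing a bigger shape.  The default photon
budget of 10⁷ gives comfortable counting statistics at 0.5° azimuthal
binning; it is a statistics choice, not an emulation of any particular
beamline flux.

What the generator does **not** emulate: form factors of cellulose
crystallites, instrument smearing and beam divergence, detector
flat-field/polarization/solid-angle effects, multi-population fibril
mixtures, or sample-to-sample heterogeneity.  Passing recovery tests
therefore demonstrates the correctness and stability of the reduction and
inversion chain under counting noise and masking — not robustness to every
systematic a real beamline adds.

## Problem sizes and determinism

Reference computations run on the 512×512 synthetic frames with 720 χ bins,
64 radial sub-bins, 160 q bins, and a ~180-point inversion grid; a full
streaked-frame analysis takes on the order of a second.  All randomness —
photon noise, fit-restart jitter — flows from explicit integer seeds, and
identical inputs produce identical reports (timestamps aside).

## Known limitations

* The inversion assumes a single fibril population symmetric about one
  alignment axis; pole-figure (3D) reconstruction is out of scope.
* The RMS statistic is sensitive to spurious density at large μ; the fixed
  regularization handles the reference conditions well, but very noisy or
  very broad distributions may need a stronger penalty.
* The effective-node correction removes the first-order azimuthal
  quantization error; a second-order remnant persists where the profile's
  curvature is large within a bin (visible as the ~0.01 residual bias in
  the recovered power-law exponent).
* `beam centre` is a required input; no auto-calibration is attempted.
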