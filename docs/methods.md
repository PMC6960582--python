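# Methods

## The reconstruction problem

Single-shot T1 mapping with an inversion-recovery Look-Locker (IR-LL)
sequence samples the longitudinal recovery continuously after one inversion
pulse: every repetition (TR ≈ 6 ms) acquires one radial spoke of k-space at
its own inversion time, with spoke angles following the golden-angle
ordering (increments of 180°/φ ≈ 111.246°).  A full scan of ~6 s therefore
yields hundreds of projections, but each *time frame* contains exactly one
spoke — the per-frame k-space is drastically undersampled, and no frame can
be reconstructed on its own.

Model-based iterative reconstruction resolves this by exploiting that every
pixel's signal through time follows the three-parameter driven recovery

    M(t) = M0* − (M0 + M0*) · exp(−t / T1*),

where T1* and M0* are the *apparent* relaxation time and steady-state
magnetisation under the repeated small-angle excitations, and the true
relaxation time follows from

    T1 = T1* · M0 / M0* = T1* · k,      k = M0 / M0*.

The loop alternates between (a) a parametric image-series model evaluated at
every inversion time and coil, and (b) a data-consistency step in k-space
that overwrites the model with the measured spoke samples at their acquired
grid nodes.  At convergence the model agrees with the data wherever data
exist and interpolates everywhere else, and the parameter maps *are* the
reconstruction.

## Pipeline

1. **Gridding.**  Spoke samples are deposited on the Cartesian grid by
   nearest-neighbour snapping; samples colliding on one node are averaged
   (deterministically).  A coil-calibrated operator (GRAPPA operator
   gridding) could replace this backend without touching the loop; the
   phantom's `direct` sampling mode synthesises data exactly on the snapped
   nodes so that gridding error is zero when testing the iteration itself.
2. **Initial model** (one of three):
   * *OFM* — zero-filled inverse FFT of each projection alone (needs many
     iterations; supported but not recommended);
   * *IFM* — linear interpolation of every covered k-space node through
     time (real and imaginary parts separately; nearest-end constant
     extrapolation outside the sampled range, hence constant for
     single-sample nodes);
   * *MFM* — node-wise mean over the projections that cover each node,
     inverse transformed to a per-coil image treated as M0*, with the fixed
     simplified recovery M(t) = M0*(1 − 2 e^{−t/T1*}), T1* = 1000 ms.
3. **Phase maps.**  Per-coil background phase φ_c(j) is estimated once from
   a composite image of the last 200 projections (late recovery, positive
   signal), so the phase of the composite is the coil's own phase.  This
   presumes the scan is long enough that the composite window lies past the
   zero crossing t₀ = T1*·ln((M0+M0*)/M0*) of every tissue of interest
   (~1.3 s for CSF-like tissue here); a window reaching into the negative
   part of the recovery flips φ by π and with it the combined polarity.
   `ReconConfig.phase_last_n` controls the window.
4. **Iteration.**  FFT the model; record the termination metric
   Σ |measured − model| over sampled nodes; reinsert the measured values;
   optionally zero everything outside the disk of radius n_read/2 (the
   region the spokes actually reach — applied after reinsertion so measured
   samples are never altered); inverse FFT; combine coils.
5. **Coil combination** preserves the inversion polarity:
   θ(j,t) = Σ_c sign(Re{M_c e^{−iφ_c}}) · |Re{M_c e^{−iφ_c}}|², and the
   combined value is sign(θ)·√|θ| — a signed root-sum-of-squares.  (The
   no-root variant, θ itself, is available for sensitivity checks.)
6. **Two-step fit.**  Step 1 fits (M0, M0*, T1*) per pixel to the combined
   curve; step 2 fixes k and T1* and re-fits only a complex amplitude per
   coil against the basis b(t) = 1 − (k+1) e^{−t/T1*}, the closed form
   M0*_c = Σ_t d(t) b(t) / Σ_t b(t)².  The model rebuilt from
   (M0*_c, k, T1*) starts the next iteration.
7. **Termination** on relative change of the metric (default 10⁻⁴) or at a
   fixed iteration cap (150 for MFM/OFM, 30 for IFM — the interpolated
   start converges in far fewer iterations).

Projection reduction keeps every n-th projection, with its original
inversion time, independently for the initial model (`nth_init`) and for the
iteration loop (`nth_iter`); with 999 projections and stride 6, 167
projections enter each iteration.

## Numerical choices

* **Step-1 fitting** is a damped Gauss–Newton (Levenberg–Marquardt)
  iteration vectorised over pixels: every pixel carries its own damping
  factor, and the 3×3 normal equations are assembled from moment sums of
  the exponential (Σe, Σe², Σte, Σte², Σt²e²), so one LM step for a whole
  slice is a handful of array reductions.  The analytic Jacobian of the
  recovery model is used throughout.  Convergence is declared when the
  accepted relative step falls below 10⁻¹⁰ (10⁻⁹ inside the reconstruction
  loop, where fits are warm-started from the previous iteration and capped
  at 30 LM steps).  Bounds: T1* ∈ [0.01, 10⁴] ms, M0* > 0, enforced by
  projection after each step.
* **Initialisation**: M0*₀ = max of the curve, M0₀ = −min of the curve (the
  recovery starts near −M0 and saturates at M0*), T1*₀ = 1000 ms; later
  iterations warm-start from the previous parameters.
* **Degenerate fits.**  A pixel whose fit collapses onto the M0* floor or
  the T1* lower bound has effectively zero steady state, and a non-positive
  fitted M0 implies T1 ≤ 0; in both cases T1 is undefined at that pixel and
  the map carries NaN (excluded from ROI statistics).  Warm starts from
  such parameters are re-initialised by the extremum rule so the pixel can
  recover in later iterations.
* **Background skip.**  Pixels whose combined-curve peak magnitude stays
  below 1% of the image-wide peak carry no tissue signal and are skipped
  (switchable off; fitting them changes no tissue value).
* **Fourier convention**: centered, unitary 2-D FFTs; DC at (N/2, N/2).
* **Precision.**  The per-iteration (n_proj, n_coil, N, N) arrays default
  to complex64 (`ReconConfig.single_precision`); all parameter fitting is
  float64.  Float32 rounding (~10⁻⁷ relative) is orders of magnitude below
  the reconstruction's intrinsic accuracy.
* **Ties and degenerate inputs**: collision averaging is order-independent;
  sign(0) = 0 so a zero θ combines to 0; all-zero curves are flagged
  non-fittable; an empty ROI yields a NaN row; zero-std ROI reports an
  infinite mean/std ratio (sample std, n−1 denominator).

## The synthetic phantom

The phantom emulates exactly the scanner data layout (projections × coils ×
readout points).  Tissue is a set of ellipses with true T1 and proton
density; the default brain-like object uses T1 = 700 / 1400 / 4000 ms for
WM-, GM- and CSF-like regions (typical reference values at 3 T) with a
readout train of TR = 6 ms, TE = 2.5 ms, flip angle 7°, 600 projections at
matrix 64 — a deliberate scale-down of a 999-projection, 256-matrix scan
that preserves the undersampling character (one spoke per frame) while
keeping a full reconstruction in the minutes range on one CPU.

Apparent parameters follow the driven-equilibrium relations
1/T1* = 1/T1 − ln(cos α)/TR and M0* = M0 · T1*/T1, which make
T1 = T1*·M0/M0* exact by construction — the phantom is therefore a true
oracle for the fitting chain.  Coil sensitivities are smooth complex
Gaussian fields with distinct constant and linear phases per coil,
RSS-normalised at the grid center.  Complex Gaussian noise of configurable
σ can be added per k-space sample (seeded, bit-reproducible).

What the phantom does **not** model: off-resonance, motion, slice profile,
inter-coil noise correlation, trajectory errors, and — in `direct` mode —
gridding error.  Passing tests on this phantom therefore validate the
algorithmic chain (gridding bookkeeping, consistency, combination, both
fits, reduction logic), not robustness to scanner non-idealities;
`continuous` mode adds realistic gridding error for sensitivity studies.

## Known limitations

* Nearest-neighbour gridding leaves isolated unsampled nodes at larger
  k-space radii where a coil-calibrated gridding would fill them (measured
  on 200 consecutive golden-angle spokes at matrix 256: full coverage to
  radius 24, 99.6% at 32, 93.1% at 64).  The composite phase maps and the
  MFM mean are insensitive to these holes; absolute image quality would
  improve with a better gridding backend.
* The sparsity-conditioned reinsertion option implements a declared
  interpretation (keep sampled nodes whose magnitude exceeds a fraction of
  a reference composite's magnitude at that node) and is off by default.
* ROI statistics are within-mask; pooling across subjects or phantoms is
  left to the caller.
* No regularisation beyond the signal model itself; no multi-slice
  acquisition (projection reduction only emulates the time budget one).
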