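# Methods

## Problem and model

A multiplex-CARS (MCARS) microscope records, at every pixel of an
`X x Y` scan, a broadband coherent anti-Stokes Raman spectrum over `N`
wavenumber channels (by convention here 2,500-3,200 cm^-1, the C-H/O-H
stretch region of cells).  The raw spectrum at a pixel is a mixture of
the spectra of the chemical constituents present there — water, protein,
lipid, nucleic acid — each distorted by the coherent non-resonant
background (NRB) into dispersive line shapes.

The package linearizes the cube into a data matrix `D` (`M = X*Y` pixel
spectra as rows) and fits the bilinear model of multivariate curve
resolution (MCR),

```
D = C S^T + E,
```

where `C` (`M x K`) holds per-pixel component concentrations, `S^T`
(`K x N`) the component spectra, and `E` the residual.  The factors are
found by alternating least squares (ALS) under three constraints:

1. non-negativity of `C` (per-pixel NNLS given `S^T`);
2. unit row sums of `C` (each pixel's concentrations are proportions;
   all-zero rows stay zero);
3. non-negativity of `S^T` (per-channel NNLS given `C`).

Fit quality is the lack-of-fit

```
LOF = sqrt( sum(E_ij^2) / sum(D_ij^2) ),
```

stored as a fraction and displayed as percent.  A `plain` variant
without the square root is selectable (`lof_definition`); the square
root is the standard chemometric definition and the default.

The spatially constrained variant (`mcr_s`) inserts a segmentation step
into every ALS iteration: (1) `C` by NNLS, (2) refold `C` into `K`
component images, (3) Chan-Sandberg-Vese (CSV) level-set segmentation of
each image and combination of the per-component cell-phase masks into a
single mask, (4) zero `C` outside the mask, (5) unfold, (6) row
normalization, (7) `S^T` by NNLS.  The reported LOF always uses the full
unmasked `D` in numerator and denominator, so discarding the
extracellular milieu deliberately *raises* the LOF — the rise measures
how much of the data the mask removed, not a loss of quality inside the
cell.

## Initialization and determinism

The initial `S^T` comes from SIMPLISMA purest-variable selection, so
every run is deterministic (no randomness anywhere in the solver;
identical inputs give bit-identical results).  Two orientations exist:

* `init="pixels"` (default): SIMPLISMA on the transposed matrix selects
  the `K` purest *pixels* and seeds `S^T` with their raw spectra.
  Hyperspectral cell images contain near-pure pixels (extracellular
  milieu, nucleoli, lipid bodies), which makes this start
  well-conditioned.
* `init="channels"`: the classic orientation, selecting the `K` purest
  wavenumber channels and deriving `S^T` by one NNLS pass.  Because the
  NRB gives every component intensity in every channel, no channel is
  pure, and on phantoms this start can converge to a rotated stationary
  point (matched spectral cosine ~0.95 instead of ~1.0).  It is kept for
  data whose channel structure is sparser.

Purity ties break toward the lowest index.  The SIMPLISMA noise offset
is `alpha = 0.05`, the common literature default for moderate-noise
data.

ALS stops when the relative LOF change falls below `tol = 1e-6`, when
the LOF is numerically zero (< 1e-12), or after `max_iter = 50`
iterations — conventional MCR-ALS practice.  The LOF is evaluated after
the `S` update of each cycle.

## Rank selection

`scan_k` runs a full decomposition per candidate `K`; `aggregate_lof`
averages the curves over datasets.  `elbow_region` locates the
curvature break of the mean-LOF curve with the distance-to-chord
statistic: each point's distance to the straight line joining the first
and last points.  The region is grown outward from the global maximum
while the distance decays monotonically and stays within 90% of the
maximum.  Both conditions matter: the 90% band alone can reach across a
*separate* local maximum of the distance profile (a competing knee
earlier in the curve), which belongs to a different break, not to the
plateau around the elbow; the monotone-decay condition ends the region
there.  An exactly linear curve has no elbow and raises `NoElbowError`.
Small upticks of the aggregated curve (up to 5% of its range) are
tolerated as cross-dataset noise.

## Chan-Sandberg-Vese segmentation

`csv_segment` minimizes the two-phase piecewise-constant fitting energy

```
F(c1, c2, C) = mu * Length(C) + nu * Area(inside)
             + lambda1 * int_inside |I - c1|^2
             + lambda2 * int_outside |I - c2|^2
```

by evolving a level-set function `phi` with a semi-implicit scheme: the
curvature term is discretized with one-sided neighbor coefficients and
treated implicitly in the center pixel (a fully explicit step
oscillates at `dt = 0.5`).  Implementation choices:

* images are min-max scaled to [0, 1] first, so `mu` has the same
  meaning for every component image regardless of intensity scale;
* `phi` starts from the standard checkerboard pattern
  `sin(pi x/5) sin(pi y/5)`; there is no reinitialization;
* region means `c1`, `c2` are computed from the sharp partition
  (`phi > 0`), not the smoothed Heaviside — with the smoothed version
  the means never separate from a checkerboard start;
* the Dirac factor uses the arctan-regularized form with width
  `epsilon = 1` pixel;
* stopping: fewer than `tol = 0.1%` of pixels change phase for five
  consecutive iterations, checked only after a 100-iteration burn-in,
  cap 500.  The burn-in exists because the partition can freeze for a
  stretch while `phi` amplitude still drains toward a later contour
  rearrangement (the "checkerboard melt"); stopping inside that lull
  returns a half-converged mask.  Passing `tol=0` disables early
  stopping entirely, which the convergence-sensitive tests use.

The monitored energy (discrete perimeter plus sharp-region fit terms)
is non-increasing up to single-step discretization noise; the test
suite asserts no sustained (5-step) increase beyond 1%.

Defaults `mu = 0.35`, `nu = 0`, `lambda1 = lambda2 = 1`, `dt = 0.5` are
the working values for MCARS cell images: `mu` large enough to bridge
noise-induced boundary detail, no area prior (cell size unknown a
priori), and symmetric fit weights.

`select_cell_phase` resolves which phase is the cell: cells sit in the
frame interior while the milieu touches the border, so the phase
occupying the minority of the border wins (water-dominated component
images have the cell as the *dark* phase, where the raw inside must be
inverted).  An exact tie keeps the `phi > 0` phase and warns.

`combine_masks` merges the `K` per-component cell-phase masks; the
default is a strict pixelwise majority vote, with `union` and
`intersection` selectable.  During `mcr_s` the mask is recomputed every
iteration (a `recompute_mask=False` switch freezes it after its first
computation, and `warmup=N` delays the constraint by `N` unconstrained
iterations).  A component whose refolded image is constant cannot be
segmented and contributes an all-false vote instead of aborting the run.

## MEM phase retrieval (validation path)

The raw CARS spectrum is, up to scale, `|chi3|^2` with
`chi3 = chi_NR + sum_j A_j / (Omega_j - delta - i Gamma_j)`.  The
validation path recovers the Raman-like `Im{chi3}`:

1. dark-background subtraction (floored at zero, floored channels
   counted in a warning) from both the spectrum and the solvent
   reference;
2. division by the solvent (NRB reference) spectrum;
3. maximum-entropy phase retrieval: autocorrelation coefficients are
   Fourier moments of the power spectrum; the all-pole (AR) model
   coefficients solve the Hermitian-Toeplitz normal equations via
   Levinson recursion; the model phase, minus a slowly varying error
   phase, gives `Im{chi3} = sqrt(S) sin(phase)`.

The order of steps 1-3 is fixed by the config schema; there is no
reordering switch because swapping dark subtraction and NRB division
changes the result.

Numerical choices: AR order `N//2` by default (resolution vs ringing);
before the Fourier moments the measured window is closed with a cosine
bridge from its right edge back to its left edge (the moments treat the
spectrum as periodic, and the raw wrap-around step otherwise biases
broad lines by several cm^-1); the error phase is a degree-8 polynomial
fitted over non-peak channels, where peaks are flagged by a 1.5x-MAD
threshold on the phase derivative and the flagged runs are dilated by
4% of the window so Lorentzian phase wings stay out of the baseline
fit.  If the left and right baselines sit more than pi/2 apart the
spectrum carries a genuine pi step (a resonance with vanishing NRB) and
detrending is skipped rather than allowed to absorb resonant phase.
On the single-line forward model this pipeline recovers peak positions
within 2 cm^-1 and FWHM within 25% of `2*Gamma` for
`Gamma` in [5, 30] cm^-1 and resonant/NRB ratios in [0.1, 2].

`dispersive_shift` quantifies the NRB-induced offset between each
retrieved `Im{chi3}` peak and the nearest extremum of the raw spectrum.
A prominence floor on the `sqrt(mean power)` scale keeps pure-noise
wiggles from counting as resonances.  Below a resonant/NRB ratio of
about 4 the retrieval is clean; at ratios above ~10 the MEM model rings
and spurious peaks appear, which is the regime limit of the validation
path.

## Synthetic phantoms

The generator exists so that every stage has ground truth without any
external data.  A phantom is a set of geometric compartments
(background, cytoplasm, nucleus, nucleoli, membrane annulus), each with
a fixed weight vector over the `K` components; the clean cube is
exactly `C_true S_true^T`.  Component spectra use the CARS line-shape
model above with bands at the cell-relevant positions (2,845 and
3,005 cm^-1 lipid, 2,930 and 3,056 cm^-1 protein, ~2,970 cm^-1
nucleic-acid CH3, broad O-H water) on a 2,500-3,200 cm^-1 axis with 300
channels by default.

Conditions chosen once, for realism:

* resonance amplitudes give peak resonant/non-resonant ratios of about
  1-4, the contrast of raw C-H-region CARS spectra of cells;
* every cell compartment carries a small floor weight of every
  component — in a real cell no constituent vanishes exactly anywhere;
* noise is shot-like: Gaussian with variance proportional to the
  signal, scaled so `gaussian_frac` is the overall relative RMS level
  (plus optional additive read noise), applied after mixing and clipped
  at zero.  "2% noise" therefore also predicts the LOF floor of a
  correct decomposition;
* presets: `single-cell` (interphase-like, five components),
  `mitotic`, `cluster-N` (N = 2..8 cells), and `three-compartment`
  (a minimal rank-3 phantom with pure regions per component, used by
  the factorization tests).  A `jitter` parameter perturbs cell
  position and size from the seed so a suite of phantoms varies in
  geometry, not only in noise realization.

What the phantoms do *not* emulate: optical point-spread blur, axial
sectioning, detector nonlinearity, spatially structured NRB, and
sub-resolution texture.  Passing the phantom suite therefore shows the
algorithm chain is correct and stable under realistic contrast and
noise, not that the defaults are optimal for any particular microscope.

## Known limitations

* On multi-cell cluster phantoms the default majority vote can erode
  the mask over iterations: masking concentrates `S^T` on the brightest
  cell interior, which dims the other cells' component images, which
  shrinks the next mask.  `combine="union"` is stable on clusters but
  can over-include rogue background components on other data; neither
  strategy dominates, so the default follows the single-cell behavior
  and cluster runs should be inspected (or run with
  `recompute_mask=False`).  The cluster tests accordingly check island
  count/area rather than Dice.
* The spatial constraint assumes the cell does not touch the frame
  border (`select_cell_phase`); fields of view clipped by a cell are
  mis-phased.
* MCR concentration maps from raw CARS intensity are not quantitative:
  the CARS signal is nonlinear in concentration, so maps rank and
  localize constituents rather than measure them.
* Component order is arbitrary (MCR permutation ambiguity); a display
  option sorts by descending mean concentration, nothing more.

## Problem sizes used by the test and acceptance suites

Factorization and noise tests use 32x32x200 rank-3 phantoms;
segmentation-quality suites use 48x48x300 five-component phantoms (ten
jittered single-cell/mitotic geometries at 2% noise); the MEM grid uses
512-channel single-line spectra; the small-instance optimizer
cross-check uses 6x5 rank-2 matrices.  These sizes were chosen so each
phantom is large enough to contain the full compartment geometry while
a complete suite run stays interactive on one CPU core.
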