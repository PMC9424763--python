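# mc2s — unsupervised unmixing and segmentation of multiplex-CARS cell images

Multiplex coherent anti-Stokes Raman scattering (MCARS) microscopy
records a full vibrational spectrum at every pixel of a cell image,
label-free.  Turning such a hypercube into chemical maps usually
requires a heavy spectrum-by-spectrum phase-retrieval step to strip the
coherent non-resonant background (NRB).  `mc2s` takes the alternative
route: it unmixes the **raw** hypercube directly by multivariate curve
resolution with alternating least squares (MCR-ALS),

```
D = C S^T + E,        C >= 0,  S >= 0,  each row of C sums to 1,
```

where `D` is the linearized cube (`M` pixel spectra x `N` Raman
shifts), `C` the per-pixel concentration maps of `K` components and
`S^T` their spectra.  Fit quality is the lack-of-fit
`LOF = sqrt(sum E^2 / sum D^2)`; the number of components is chosen
from the elbow of the mean LOF-versus-K curve.

On top of the classical constraints the package implements a spatial
**segmentation constraint**: inside every ALS iteration the `K`
concentration images are segmented by the Chan–Sandberg–Vese (CSV)
level-set method, the per-component cell masks are combined by majority
vote, and concentrations outside the combined mask are zeroed before the
spectra update.  The decomposition and a cell segmentation mask are thus
produced jointly, in one unsupervised pass (`MC^2` without, `MC^2,S`
with the constraint).  Mask quality is scored against ground truth with
the Dice coefficient `2|A∩B|/(|A|+|B|)`.

For spectroscopic validation a maximum-entropy (MEM) phase-retrieval
path converts raw CARS spectra into Raman-like `Im{chi3}` spectra
(dark-background subtraction, solvent/NRB normalization,
Toeplitz–Levinson all-pole model, error-phase removal), and a phantom
generator renders ground-truthed synthetic cells so the whole pipeline
is testable without any external data.

Intended users: coherent-Raman microscopists and image-analysis people
who want chemical maps and cell masks from MCARS stacks without
training data or phase retrieval.

## Worked example

```sh
mc2s simulate --preset single-cell --shape 48 48 --seed 7 --noise 0.02 --out phantom/
mc2s decompose --input phantom/phantom.h5 --k 5 --out mc2/
mc2s decompose --input phantom/phantom.h5 --k 5 --segment --mu 0.35 --out mc2s/
mc2s dice mc2s/mask.png phantom/truth_mask.png
```

which prints

```
phantom written to phantom
final LOF 1.929% (50 iterations)
final LOF 91.424% (2 iterations)
0.996222
```

Reading the numbers: the phantom is a five-component interphase-like
cell in an aqueous milieu with 2% shot-like noise.  The unconstrained
decomposition (`mc2/`) reaches a LOF of 1.9% — the injected noise
floor, i.e. the model explains everything but noise.  With the
segmentation constraint (`mc2s/`) the LOF measured against the *full*
data jumps to 91%: the masked model no longer represents the
extracellular milieu, which dominates this frame, and the jump is the
fraction of data the mask removed — not a loss of quality inside the
cell.  The final mask overlaps the true cell mask with Dice 0.996.
Each output directory also contains `spectra.csv` (wavenumber + K
component spectra), one 32-bit float TIFF concentration map per
component, `lof_history.csv` and a JSON run manifest (parameters, input
hashes, package version) for reproducibility.

The same functionality is available as a library:

```python
from mc2s import McrConfig, CsvParams, mcr_s, unfold
from mc2s.synthetic import make_preset

cube, truth = make_preset("single-cell", shape=(48, 48), seed=7,
                          gaussian_frac=0.02)
res = mcr_s(unfold(cube), McrConfig(K=5), CsvParams(mu=0.35))
res.lof_final, res.mask          # decomposition + cell mask
```

## Layout

```
src/mc2s/io_hypercube.py     containers, unfold/refold, HDF5/TIFF/CSV/PNG I/O
src/mc2s/mcr_core.py         MCR-ALS, SIMPLISMA, LOF, rank scan, elbow, projection
src/mc2s/segmentation.py     Chan-Vese level set, phase selection, mask algebra, Dice
src/mc2s/mcr_s.py            the segmentation-constrained decomposition
src/mc2s/spectral_preproc.py dark/NRB preprocessing and MEM phase retrieval
src/mc2s/synthetic.py        ground-truthed MCARS cell phantoms
src/mc2s/cli.py              the `mc2s` command line
docs/methods.md              model, numerical choices, limitations
```
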