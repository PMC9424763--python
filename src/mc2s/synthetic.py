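"""Ground-truthed MCARS cell phantoms for end-to-end testing.

A phantom is built from geometric compartments (background, cytoplasm,
nucleus, nucleoli, membrane annulus, ...) each carrying a fixed weight
vector over K chemical components.  Component spectra follow the standard
CARS line-shape model

    S_k(delta) = | chi_NR + sum_j A_j / (Omega_j - delta - i Gamma_j) |^2

on a 2,500-3,200 cm^-1 axis (300 channels by default), so a nonzero
non-resonant background chi_NR produces the dispersive profiles seen in
real raw CARS data.  The clean cube is exactly the bilinear product
``D = C_true @ S_true^T``; shot-like noise (Gaussian with variance
proportional to the signal) plus additive read noise is applied after
mixing.  Everything is determined by the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_hypercube import DataMatrix, Hypercube, Mask, WavenumberAxis, unfold


@dataclass(frozen=True)
class ResonanceLine:
    """One vibrational resonance: center (cm^-1), half-width, amplitude."""

    omega: float
    gamma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class Compartment:
    """A geometric region carrying one component-weight vector.

    ``geometry`` is ``("ellipse", cx, cy, rx, ry)`` or
    ``("annulus", cx, cy, rx, ry, thickness)`` in pixel units (fractions
    of the frame in [0, 1] are also accepted).  Later compartments
    overwrite earlier ones where they overlap (z-order).
    """

    geometry: tuple
    weights: tuple[float, ...]
    is_cell: bool = True


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (64, 64)
    axis: WavenumberAxis = field(
        default_factory=lambda: WavenumberAxis(np.linspace(2500.0, 3200.0, 300))
    )
    compartments: list[Compartment] = field(default_factory=list)
    component_lines: list[list[ResonanceLine]] = field(default_factory=list)
    chi_nr: list[float] = field(default_factory=list)
    gaussian_frac: float = 0.0
    read_noise_frac: float = 0.0
    poisson: bool = False
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.component_lines)


@dataclass
class PhantomTruth:
    C_true: np.ndarray
    S_true: np.ndarray
    cell_mask: Mask
    compartment_labels: np.ndarray


def cars_spectrum(lines: list[ResonanceLine], chi_nr: float,
                  axis: WavenumberAxis) -> np.ndarray:
    """Raw CARS intensity |chi_NR + sum A/(Omega - delta - i Gamma)|^2."""
    delta = axis.values
    chi = np.full(delta.shape, complex(chi_nr))
    for ln in lines:
        chi = chi + ln.amplitude / (ln.omega - delta - 1j * ln.gamma)
    return np.abs(chi) ** 2


def _rasterize(spec: PhantomSpec) -> np.ndarray:
    """Compartment label per pixel (0 = first compartment, later wins)."""
    x_dim, y_dim = spec.shape
    xs, ys = np.meshgrid(np.arange(x_dim), np.arange(y_dim), indexing="ij")
    labels = np.zeros(spec.shape, dtype=int)

    def scale(v: float, dim: int) -> float:
        return v * dim if 0 < v <= 1 else v

    for idx, comp in enumerate(spec.compartments):
        kind = comp.geometry[0]
        if kind == "full":
            region = np.ones(spec.shape, dtype=bool)
        elif kind == "ellipse":
            _, cx, cy, rx, ry = comp.geometry
            cx, rx = scale(cx, x_dim), scale(rx, x_dim)
            cy, ry = scale(cy, y_dim), scale(ry, y_dim)
            region = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
        elif kind == "annulus":
            _, cx, cy, rx, ry, th = comp.geometry
            cx, rx = scale(cx, x_dim), scale(rx, x_dim)
            cy, ry = scale(cy, y_dim), scale(ry, y_dim)
            r_out = ((xs - cx) / (rx + th)) ** 2 + ((ys - cy) / (ry + th)) ** 2 <= 1.0
            r_in = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
            region = r_out & ~r_in
        else:
            raise ValueError(f"unknown geometry {kind!r}")
        labels[region] = idx
    return labels


def make_phantom(spec: PhantomSpec) -> tuple[Hypercube, PhantomTruth]:
    """Render a phantom cube and its exact ground truth.

    The clean unfolded cube equals ``C_true @ S_true^T`` exactly; noise
    (if any) is added afterwards and the result clipped at zero.
    """
    if not spec.compartments:
        raise ValueError("phantom needs at least one compartment")
    K = spec.n_components
    if len(spec.chi_nr) != K:
        raise ValueError("chi_nr must have one value per component")
    for comp in spec.compartments:
        if len(comp.weights) != K:
            raise ValueError("each compartment needs one weight per component")
        if any(w < 0 for w in comp.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(comp.weights) - 1.0) > 1e-9:
            raise ValueError("compartment weights must sum to 1")

    labels = _rasterize(spec)
    x_dim, y_dim = spec.shape

    S_true = np.stack([
        cars_spectrum(lines, nr, spec.axis)
        for lines, nr in zip(spec.component_lines, spec.chi_nr)
    ])
    weight_table = np.array([c.weights for c in spec.compartments], dtype=float)
    labels_flat = labels.T.reshape(-1)  # raster order i = y*X + x
    C_true = weight_table[labels_flat]

    D_clean = C_true @ S_true
    rng = np.random.default_rng(spec.seed)
    D = D_clean
    if spec.gaussian_frac > 0:
        mean = D_clean.mean()
        sigma = spec.gaussian_frac * np.sqrt(np.maximum(D_clean, 0.0) * mean)
        D = D + sigma * rng.standard_normal(D_clean.shape)
    if spec.read_noise_frac > 0:
        D = D + spec.read_noise_frac * D_clean.mean() * rng.standard_normal(D_clean.shape)
    if spec.poisson:
        D = rng.poisson(np.maximum(D, 0.0)).astype(float)
    D = np.clip(D, 0.0, None)

    cube = Hypercube(D.reshape(y_dim, x_dim, -1).transpose(1, 0, 2), spec.axis)
    cell_flags = np.array([c.is_cell for c in spec.compartments])
    cell_mask = Mask(cell_flags[labels])
    truth = PhantomTruth(C_true=C_true, S_true=S_true, cell_mask=cell_mask,
                         compartment_labels=labels)
    return cube, truth


# ---------------------------------------------------------------------------
# presets


# resonance strengths chosen so peak resonant amplitude |A|/Gamma is 1-4x
# the non-resonant chi_NR, as in raw C-H-region CARS spectra of cells
_LIPID = [ResonanceLine(2845.0, 15.0, 60.0), ResonanceLine(3005.0, 18.0, 25.0)]
_PROTEIN = [ResonanceLine(2930.0, 18.0, 60.0), ResonanceLine(3056.0, 20.0, 25.0)]
_WATER = [ResonanceLine(3150.0, 80.0, 150.0)]
_DNA = [ResonanceLine(2970.0, 14.0, 40.0)]


def _single_cell_compartments(cx: float = 0.5, cy: float = 0.5,
                              r: float = 0.30) -> list[Compartment]:
    """Nucleus + two nucleoli + cytoplasm + membrane annulus + milieu."""
    # every cell compartment carries a floor of every component: in real
    # cells no constituent vanishes exactly anywhere inside the cell
    return [
        # aqueous background: water-rich, slight protein
        Compartment(("full",), (0.85, 0.0, 0.0, 0.15, 0.0), is_cell=False),
        # membrane annulus (lipid-rich)
        Compartment(("annulus", cx, cy, r, 0.92 * r, 2.0),
                    (0.05, 0.15, 0.60, 0.15, 0.05)),
        # cytoplasm: protein + water + lipid mix
        Compartment(("ellipse", cx, cy, r, 0.92 * r),
                    (0.20, 0.30, 0.20, 0.25, 0.05)),
        # nucleus: protein-dominated with DNA signature
        Compartment(("ellipse", cx, cy, 0.55 * r, 0.5 * r),
                    (0.10, 0.45, 0.05, 0.15, 0.25)),
        # nucleoli: dense protein
        Compartment(("ellipse", cx - 0.18 * r, cy - 0.1 * r, 0.13 * r, 0.13 * r),
                    (0.05, 0.65, 0.05, 0.10, 0.15)),
        Compartment(("ellipse", cx + 0.2 * r, cy + 0.12 * r, 0.11 * r, 0.11 * r),
                    (0.05, 0.65, 0.05, 0.10, 0.15)),
    ]


_FIVE_COMPONENTS = dict(
    component_lines=[
        _WATER,                                   # 0 extracellular water
        _PROTEIN,                                 # 1 protein (nucleus/nucleoli)
        _LIPID,                                   # 2 lipid (membranes)
        [ResonanceLine(3150.0, 80.0, 100.0),      # 3 water + lipid mix
         ResonanceLine(2845.0, 15.0, 25.0)],
        _DNA,                                     # 4 DNA/RNA signature
    ],
    chi_nr=[3.0, 2.0, 2.0, 2.5, 2.0],
)


def preset_spec(name: str, shape: tuple[int, int] = (64, 64), seed: int = 0,
                gaussian_frac: float = 0.0, read_noise_frac: float = 0.0,
                axis: WavenumberAxis | None = None,
                jitter: float = 0.0) -> PhantomSpec:
    """Named phantom presets.

    ``single-cell``: one interphase-like cell (nucleus, two nucleoli,
    cytoplasm, membrane annulus) in an aqueous milieu, five components.
    ``mitotic``: rounded cell without nucleoli, condensed protein core.
    ``cluster-N``: N touching/near cells (N in 2..8).
    ``three-compartment``: minimal rank-3 phantom (background, disc,
    annulus) with pure regions per component, for factorization tests.

    ``jitter`` perturbs cell position and size by up to that fraction of
    the frame (seed-driven), so a suite of phantoms varies in geometry
    and not only in its noise realization.
    """
    axis = axis or WavenumberAxis(np.linspace(2500.0, 3200.0, 300))
    common = dict(shape=shape, axis=axis, seed=seed,
                  gaussian_frac=gaussian_frac, read_noise_frac=read_noise_frac)
    jrng = np.random.default_rng(seed + 131)
    cx, cy = 0.5 + jitter * jrng.uniform(-0.5, 0.5, 2)
    r_scale = 1.0 + jitter * jrng.uniform(-0.6, 0.6)
    if name == "single-cell":
        comps = _single_cell_compartments(cx, cy, 0.30 * r_scale)
        return PhantomSpec(compartments=comps, **_FIVE_COMPONENTS, **common)
    if name == "mitotic":
        r = 0.26 * r_scale
        comps = [
            Compartment(("full",), (0.85, 0.0, 0.0, 0.15, 0.0), is_cell=False),
            Compartment(("annulus", cx, cy, r, r, 2.0),
                        (0.05, 0.20, 0.55, 0.15, 0.05)),
            Compartment(("ellipse", cx, cy, r, r),
                        (0.15, 0.35, 0.20, 0.25, 0.05)),
            Compartment(("ellipse", cx, cy, 0.58 * r, 0.5 * r),
                        (0.05, 0.50, 0.05, 0.05, 0.35)),
        ]
        return PhantomSpec(compartments=comps, **_FIVE_COMPONENTS, **common)
    if name.startswith("cluster-"):
        n = int(name.split("-", 1)[1])
        if not 2 <= n <= 8:
            raise ValueError("cluster size must be in 2..8")
        rng = np.random.default_rng(seed + 7919)
        comps = [Compartment(("full",), (0.85, 0.0, 0.0, 0.15, 0.0),
                             is_cell=False)]
        angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        angles = angles + rng.uniform(-0.15, 0.15, n)
        radius = 0.15 if n <= 4 else 0.12
        ring = 0.22 if n <= 4 else 0.26
        for a in angles:
            cx = 0.5 + ring * np.cos(a)
            cy = 0.5 + ring * np.sin(a)
            r = radius * rng.uniform(0.85, 1.15)
            comps.append(Compartment(("ellipse", cx, cy, r, 0.95 * r),
                                     (0.2, 0.30, 0.2, 0.25, 0.05)))
            comps.append(Compartment(("ellipse", cx, cy, 0.5 * r, 0.45 * r),
                                     (0.05, 0.55, 0.05, 0.1, 0.25)))
        return PhantomSpec(compartments=comps, **_FIVE_COMPONENTS, **common)
    if name == "three-compartment":
        comps = [
            Compartment(("full",), (1.0, 0.0, 0.0), is_cell=False),
            Compartment(("annulus", 0.5, 0.5, 0.22, 0.22, 3.0),
                        (0.0, 0.0, 1.0)),
            Compartment(("ellipse", 0.5, 0.5, 0.22, 0.22),
                        (0.1, 0.6, 0.3)),
            Compartment(("ellipse", 0.5, 0.5, 0.10, 0.10),
                        (0.0, 1.0, 0.0)),
        ]
        lines = [_WATER, _PROTEIN, _LIPID]
        return PhantomSpec(compartments=comps, component_lines=lines,
                           chi_nr=[3.0, 2.0, 2.0], **common)
    raise ValueError(f"unknown preset {name!r}")


def make_preset(name: str, **kwargs) -> tuple[Hypercube, PhantomTruth]:
    """Convenience: :func:`preset_spec` followed by :func:`make_phantom`."""
    return make_phantom(preset_spec(name, **kwargs))


def unfolded(cube: Hypercube) -> DataMatrix:
    """Shorthand re-export so pipeline code can stay in one namespace."""
    return unfold(cube)
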