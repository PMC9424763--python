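"""CARS spectral preprocessing and maximum-entropy phase retrieval.

Raw multiplex-CARS spectra measure (up to scale) the modulus squared of
the third-order susceptibility, ``S ~ |chi3|^2``, where
``chi3 = chi_NR + sum_j A_j / (Omega_j - delta - i Gamma_j)`` mixes the
resonant Raman response with a non-resonant background (NRB) that turns
each Lorentzian line into a dispersive profile and shifts its apparent
peak.  The validation path here is:

1. subtract the spectrometer dark background from both the spectrum and
   the solvent (NRB reference) spectrum;
2. divide by the solvent spectrum (NRB normalization);
3. maximum-entropy (MEM) phase retrieval: model the power spectrum with an
   autoregressive (all-pole) filter obtained from the Toeplitz/Levinson
   normal equations, take the model phase, remove the slowly varying
   error phase by polynomial detrending over non-peak regions, and return
   the Raman-like imaginary part ``Im{chi3} = sqrt(S) * sin(phase)``.

The order of the three steps is fixed (dark -> NRB -> MEM); the config
dataclass encodes it and offers no reordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.ndimage import binary_dilation
from scipy.signal import find_peaks

from .io_hypercube import WavenumberAxis


class NoPeaksError(ValueError):
    """No vibrational peaks found in the spectrum."""


@dataclass
class PreprocConfig:
    """Dark background and NRB (solvent) reference spectra.

    ``dark`` is the spectrometer dark/background count vector; the NRB
    reference is the raw CARS spectrum of the solvent.  Dark subtraction
    is applied to both before the ratio is taken; after subtraction the
    NRB reference must be strictly positive.
    """

    dark: np.ndarray | None = None
    nrb_reference: np.ndarray | None = None

    def apply(self, spectrum: np.ndarray) -> np.ndarray:
        s = np.asarray(spectrum, dtype=float)
        nrb = self.nrb_reference
        if self.dark is not None:
            s = background_subtract(s, self.dark)
            if nrb is not None:
                nrb = np.asarray(nrb, dtype=float) - np.asarray(self.dark, dtype=float)
        if nrb is not None:
            s = nrb_normalize(s, nrb)
        return s


@dataclass
class RamanLikeSpectrum:
    """Raman-like spectrum retrieved from a raw CARS spectrum."""

    axis: WavenumberAxis
    im_chi3: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if len(self.im_chi3) != len(self.axis) or len(self.phase) != len(self.axis):
            raise ValueError("spectrum length does not match axis")


def background_subtract(spectrum: np.ndarray, dark: np.ndarray,
                        warn: bool = True) -> np.ndarray:
    """Elementwise dark subtraction, floored at zero."""
    s = np.asarray(spectrum, dtype=float)
    d = np.asarray(dark, dtype=float)
    if s.shape != d.shape:
        raise ValueError("spectrum and dark have different lengths")
    out = s - d
    n_floor = int(np.sum(out < 0))
    if n_floor and warn:
        warnings.warn(f"floored {n_floor} channels below the dark level")
    return np.clip(out, 0.0, None)


def nrb_normalize(spectrum: np.ndarray, nrb: np.ndarray) -> np.ndarray:
    """Divide by the solvent (NRB reference) spectrum."""
    s = np.asarray(spectrum, dtype=float)
    r = np.asarray(nrb, dtype=float)
    if s.shape != r.shape:
        raise ValueError("spectrum and NRB reference have different lengths")
    if np.any(r <= 0):
        raise ValueError("NRB reference must be strictly positive everywhere")
    return s / r


# ---------------------------------------------------------------------------
# maximum entropy phase retrieval


def _mem_phase(power: np.ndarray, order: int, pad_frac: float = 1.0) -> np.ndarray:
    """Phase of the all-pole MEM model of a power spectrum.

    Autocorrelation coefficients are Fourier moments of the measured power
    spectrum; the AR coefficients solve the Hermitian-Toeplitz normal
    equations (Levinson recursion via ``solve_toeplitz``).  The Fourier
    moments treat the spectrum as periodic, so before transforming, the
    measured window is closed with a smooth cosine bridge from its right
    edge back to its left edge — without it the wrap-around step leaks
    into the phase of broad lines.
    """
    n = power.size
    npad = max(int(pad_frac * n), 2)
    t = np.linspace(0.0, np.pi, 2 * npad)
    bridge = power[-1] + (power[0] - power[-1]) * (1.0 - np.cos(t)) / 2.0
    ext = np.concatenate([power, bridge])
    N = ext.size
    m = np.arange(order + 1)
    # R_m = (1/N) sum_k power_k exp(2 pi i m k / N)
    R = (ext[None, :] * np.exp(2j * np.pi * m[:, None] * np.arange(N)[None, :] / N)
         ).sum(axis=1) / N
    a = solve_toeplitz((R[:order], np.conj(R[:order])), -R[1:order + 1])
    k = np.arange(1, order + 1)
    A = 1.0 + (a[None, :] * np.exp(-2j * np.pi * k[None, :] * np.arange(N)[:, None] / N)
               ).sum(axis=1)
    return -np.unwrap(np.angle(A))[:n]


def _error_phase(phase: np.ndarray, degree: int, mad_factor: float = 1.5
                 ) -> np.ndarray:
    """Slowly varying error phase: polynomial fit over non-peak channels.

    Peaks are masked where the phase derivative deviates from its median
    by more than ``mad_factor`` times the median absolute deviation; the
    masked runs are dilated by ~4% of the window so the Lorentzian phase
    wings do not leak into the baseline fit.
    """
    n = phase.size
    dphi = np.gradient(phase)
    med = np.median(dphi)
    mad = np.median(np.abs(dphi - med))
    if mad == 0:
        keep = np.ones(n, dtype=bool)
    else:
        peaked = np.abs(dphi - med) > mad_factor * mad
        peaked = binary_dilation(peaked, iterations=max(3, round(0.04 * n)))
        keep = ~peaked
    # a resonance with vanishing NRB carries a genuine pi phase step: the
    # baseline then sits at different levels left and right of the line,
    # and a polynomial through both would absorb resonant phase — leave
    # such spectra undetrended
    left = keep & (np.arange(n) < n // 2)
    right = keep & (np.arange(n) >= n // 2)
    if left.any() and right.any():
        step = abs(np.median(phase[right]) - np.median(phase[left]))
        if step > np.pi / 2:
            return np.zeros(n)
    deg = min(degree, max(int(keep.sum()) - 1, 0))
    if keep.sum() < degree + 1:
        keep = np.ones(n, dtype=bool)
        deg = min(degree, n - 1)
    x = np.linspace(-1.0, 1.0, n)
    coeffs = np.polynomial.polynomial.polyfit(x[keep], phase[keep], deg)
    return np.polynomial.polynomial.polyval(x, coeffs)


def mem_retrieve(spectrum: np.ndarray, axis: WavenumberAxis,
                 order: int | None = None, detrend_degree: int = 8
                 ) -> RamanLikeSpectrum:
    """Retrieve the Raman-like Im{chi3} spectrum from a raw CARS spectrum.

    ``spectrum`` must be strictly positive (it is a power spectrum up to
    scale).  ``order`` is the autoregressive model order (default N//2,
    balancing spectral resolution against ringing).  The retrieved phase
    has its slowly varying error component removed by a polynomial fit of
    ``detrend_degree`` over non-peak channels.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1 or s.size != len(axis):
        raise ValueError("spectrum must be 1-D and match the axis")
    if np.any(s <= 0):
        raise ValueError("MEM needs strictly positive input channels")
    n = s.size
    order = n // 2 if order is None else int(order)
    if not 0 < order < n:
        raise ValueError("MEM order must be in (0, N)")

    phase = _mem_phase(s, order)
    phase = phase - _error_phase(phase, detrend_degree)
    im = np.sqrt(s) * np.sin(phase)
    # sign convention: vibrational resonances have positive Im{chi3}
    if np.abs(im.min()) > np.abs(im.max()):
        im = -im
        phase = -phase
    return RamanLikeSpectrum(axis=axis, im_chi3=im, phase=phase)


def dispersive_shift(raw_spectrum: np.ndarray, mem_spectrum: RamanLikeSpectrum,
                     prominence_frac: float = 0.05) -> list[tuple[float, float]]:
    """Per-peak offset between MEM-retrieved and raw CARS peak positions.

    The NRB turns each Raman line into a dispersive profile whose apparent
    extremum sits below the true vibrational frequency; this measures that
    shift.  For each peak of ``Im{chi3}`` the signed offset (in cm^-1) to
    the nearest local extremum of the raw spectrum is returned as a list
    of ``(peak_position_cm1, shift_cm1)`` pairs, where
    ``shift = raw_extremum_position - mem_peak_position``.
    """
    raw = np.asarray(raw_spectrum, dtype=float)
    wn = mem_spectrum.axis.values
    if raw.size != wn.size:
        raise ValueError("raw spectrum does not match the MEM axis")
    im = mem_spectrum.im_chi3
    # prominence floor on the sqrt-intensity scale keeps pure-noise
    # wiggles (|Im| << sqrt(mean power)) from counting as resonances
    prom = prominence_frac * max(im.max() - im.min(),
                                 float(np.sqrt(raw.mean())))
    mem_peaks, _ = find_peaks(im, prominence=prom)
    if mem_peaks.size == 0:
        raise NoPeaksError("no peaks found in the MEM spectrum")

    span = raw.max() - raw.min()
    raw_max, _ = find_peaks(raw, prominence=prominence_frac * span)
    raw_min, _ = find_peaks(-raw, prominence=prominence_frac * span)
    raw_ext = np.sort(np.concatenate([raw_max, raw_min]))
    if raw_ext.size == 0:
        raise NoPeaksError("no extrema found in the raw spectrum")

    out = []
    for p in mem_peaks:
        nearest = raw_ext[np.argmin(np.abs(wn[raw_ext] - wn[p]))]
        out.append((float(wn[p]), float(wn[nearest] - wn[p])))
    return out
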