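"""MCR-ALS curve resolution under non-negativity and row-normalization.

The bilinear model is ``D = C @ S_T + E`` where ``D`` is the linearized
hypercube (M pixel spectra x N Raman shifts), ``C`` the M x K concentration
matrix, ``S_T`` the K x N matrix of component spectra and ``E`` the
residual.  The alternating least-squares cycle is

1. ``C`` by non-negative least squares (NNLS) given ``S_T``;
2. row-normalization of ``C`` (each pixel's concentrations sum to one);
3. ``S_T`` by NNLS given ``C``;

repeated until the relative change of the lack-of-fit (LOF) drops below a
tolerance.  The initial ``S_T`` comes from SIMPLISMA purest-variable
selection, so the whole procedure is deterministic.

Fit quality is the lack-of-fit ``LOF = sqrt(sum(E**2) / sum(D**2))``
(stored as a fraction; a ``plain`` variant without the square root is
selectable).  Rank selection scans K, aggregates LOF curves over datasets
and locates the elbow of the mean-LOF curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .io_hypercube import DataMatrix


class NoElbowError(ValueError):
    """The LOF curve has no curvature break (e.g. exactly linear decay)."""


@dataclass
class McrConfig:
    """Settings for one MCR-ALS run.

    Attributes
    ----------
    K : number of components (default 5, the working value for MCARS cells).
    max_iter : ALS iteration cap.
    tol : relative LOF-change stopping threshold.
    simplisma_offset : SIMPLISMA noise-offset fraction alpha in [0, 1].
    normalize_rows : enforce unit row sums on C after the C update.
    nonneg_C / nonneg_S : non-negativity of the two factors.
    lof_definition : "sqrt" (standard) or "plain" (squared ratio).
    init : "pixels" applies SIMPLISMA to the transposed matrix so the
        purest *pixels* seed S_T with their spectra (hyperspectral images
        contain near-pure pixels — extracellular milieu, nucleoli, lipid
        bodies — making this the better-conditioned start); "channels"
        selects purest wavenumber channels instead.
    """

    K: int = 5
    max_iter: int = 50
    tol: float = 1e-6
    simplisma_offset: float = 0.05
    normalize_rows: bool = True
    nonneg_C: bool = True
    nonneg_S: bool = True
    lof_definition: str = "sqrt"
    init: str = "pixels"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if not 0.0 <= self.simplisma_offset <= 1.0:
            raise ValueError("simplisma_offset must be in [0, 1]")
        if self.lof_definition not in ("sqrt", "plain"):
            raise ValueError("lof_definition must be 'sqrt' or 'plain'")
        if self.init not in ("pixels", "channels"):
            raise ValueError("init must be 'pixels' or 'channels'")


@dataclass
class Decomposition:
    """Result of an MCR-ALS run."""

    C: np.ndarray
    S_T: np.ndarray
    lof_history: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def K(self) -> int:
        return self.C.shape[1]

    def residual(self, D: np.ndarray) -> np.ndarray:
        return np.asarray(D) - self.C @ self.S_T

    @property
    def lof(self) -> float:
        return self.lof_history[-1]


@dataclass
class LofCurve:
    """LOF as a function of K for one dataset (fractions, not %)."""

    ks: list[int]
    lof: list[float]

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.lof):
            raise ValueError("ks and lof must have the same length")


# ---------------------------------------------------------------------------
# primitives


def compute_lof(D, C, S_T, definition: str = "sqrt") -> float:
    """Lack-of-fit of the factorization C @ S_T against D.

    ``sqrt``: sqrt(sum(e_ij^2) / sum(d_ij^2)); ``plain`` omits the root.
    Returned as a fraction (display as % by multiplying by 100).
    """
    D = np.asarray(D, dtype=float)
    denom = float(np.sum(D * D))
    if denom == 0.0:
        raise ValueError("LOF undefined for an all-zero data matrix")
    E = D - np.asarray(C) @ np.asarray(S_T)
    ratio = float(np.sum(E * E)) / denom
    if definition == "sqrt":
        return float(np.sqrt(ratio))
    if definition == "plain":
        return ratio
    raise ValueError("definition must be 'sqrt' or 'plain'")


def nnls_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise non-negative least squares: X >= 0 minimizing ||A X - B||.

    A is (m, n); B is (m,) or (m, p); returns (n,) or (n, p).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be 2-D")
    if not np.any(A):
        raise ValueError("A is all-zero: NNLS is ill-posed")
    B = np.asarray(B, dtype=float)
    single = B.ndim == 1
    if single:
        B = B[:, None]
    if B.shape[0] != A.shape[0]:
        raise ValueError("A and B have incompatible shapes")
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j] = _scipy_nnls(A, B[:, j])[0]
    return X[:, 0] if single else X


def normalize_rows(C: np.ndarray) -> np.ndarray:
    """Scale each nonzero row of C to unit sum; zero rows stay zero."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("normalize_rows expects non-negative input")
    sums = C.sum(axis=-1, keepdims=True)
    out = np.divide(C, sums, out=np.zeros_like(C, dtype=float), where=sums > 0)
    return out


def simplisma_init(D, K: int, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Initial spectra estimate from SIMPLISMA purest-variable selection.

    The K purest spectral channels (columns of D) are chosen by the
    purity/determinant recursion: the purity of column j is
    ``sigma_j / (mu_j + alpha * max(mu))`` weighted, from the second pick
    onward, by the determinant of the correlation-around-the-origin
    submatrix of already-selected channels — which drives selection toward
    channels independent of those picked before.  The channel intensities
    serve as a first concentration estimate, from which an initial K x N
    spectra matrix is obtained by one NNLS pass.

    Returns ``(S0, pure_variable_indices)``.  Deterministic; purity ties
    break toward the lowest column index.
    """
    D = _as_values(D)
    M, N = D.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError("K cannot exceed the number of spectral channels")
    if np.any(D < 0):
        raise ValueError("SIMPLISMA expects non-negative data")
    if not np.any(D):
        raise ValueError("SIMPLISMA undefined for an all-zero matrix")

    mu = D.mean(axis=0)
    sigma = D.std(axis=0)
    if not np.any(sigma > 0):
        raise ValueError("all columns are constant: no pure variables")
    offset = alpha * mu.max()
    purity1 = sigma / (mu + offset)

    # correlation around the origin of noise-corrected, length-scaled columns
    lam = np.sqrt(mu**2 + (sigma + offset) ** 2)
    Dl = D / lam[None, :]
    COO = (Dl.T @ Dl) / M

    selected: list[int] = []
    for _ in range(K):
        if not selected:
            weights = np.ones(N)
        else:
            weights = np.empty(N)
            sub = COO[np.ix_(selected, selected)]
            for j in range(N):
                m = np.empty((len(selected) + 1,) * 2)
                m[0, 0] = COO[j, j]
                m[0, 1:] = COO[j, selected]
                m[1:, 0] = COO[selected, j]
                m[1:, 1:] = sub
                weights[j] = np.linalg.det(m)
        p = weights * purity1
        p[selected] = -np.inf
        j_star = int(np.argmax(p))  # argmax takes the lowest index on ties
        if not np.isfinite(p[j_star]) or p[j_star] <= 0:
            raise ValueError(
                f"only {len(selected)} non-degenerate pure variables found"
            )
        selected.append(j_star)

    idx = np.array(selected)
    C0 = D[:, idx]
    S0 = nnls_solve(C0, D)
    return S0, idx


# ---------------------------------------------------------------------------
# alternating least squares


def _as_values(D) -> np.ndarray:
    if isinstance(D, DataMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def _als_half_steps(D: np.ndarray, S_T: np.ndarray, cfg: McrConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One C-update (+ normalization) followed by one S-update."""
    C = _update_C(D, S_T, cfg)
    if cfg.normalize_rows:
        C = normalize_rows(C) if cfg.nonneg_C else C / C.sum(1, keepdims=True)
    S_T = _update_S(D, C, cfg)
    return C, S_T


def _update_C(D: np.ndarray, S_T: np.ndarray, cfg: McrConfig) -> np.ndarray:
    if cfg.nonneg_C:
        return nnls_solve(S_T.T, D.T).T
    return np.linalg.lstsq(S_T.T, D.T, rcond=None)[0].T


def _update_S(D: np.ndarray, C: np.ndarray, cfg: McrConfig) -> np.ndarray:
    if not np.any(C):
        raise ValueError("concentration matrix collapsed to zero")
    if cfg.nonneg_S:
        return nnls_solve(C, D)
    return np.linalg.lstsq(C, D, rcond=None)[0]


def mcr_als(D, config: McrConfig | None = None, S0: np.ndarray | None = None
            ) -> Decomposition:
    """MCR-ALS decomposition of D under the configured constraints.

    Starts from ``S0`` (default: SIMPLISMA estimate), alternates
    C-update / row normalization / S-update, and stops when the relative
    LOF change falls below ``config.tol`` or ``config.max_iter`` is hit.
    """
    cfg = config or McrConfig()
    D = _as_values(D)
    if not np.all(np.isfinite(D)):
        raise ValueError("D must be finite")
    M, N = D.shape
    if cfg.K > min(M, N):
        raise ValueError(f"K={cfg.K} exceeds min(M, N)={min(M, N)}")
    if S0 is None:
        S0 = initial_spectra(D, cfg)
    S_T = np.asarray(S0, dtype=float)
    if S_T.shape != (cfg.K, N):
        raise ValueError(f"S0 must be ({cfg.K}, {N})")

    lof_history: list[float] = []
    converged = False
    C = None
    for _ in range(cfg.max_iter):
        C, S_T = _als_half_steps(D, S_T, cfg)
        if cfg.nonneg_C:
            assert np.all(C >= 0)
        if cfg.nonneg_S:
            assert np.all(S_T >= 0)
        lof_history.append(compute_lof(D, C, S_T, cfg.lof_definition))
        if _lof_converged(lof_history, cfg.tol):
            converged = True
            break
    return Decomposition(C=C, S_T=S_T, lof_history=lof_history,
                         converged=converged)


def initial_spectra(D, cfg: McrConfig) -> np.ndarray:
    """SIMPLISMA initial S_T per the configured orientation."""
    D = _as_values(D)
    if cfg.init == "pixels":
        _, idx = simplisma_init(D.T, cfg.K, cfg.simplisma_offset)
        return D[idx, :].copy()
    S0, _ = simplisma_init(D, cfg.K, cfg.simplisma_offset)
    return S0


def _lof_converged(history: list[float], tol: float) -> bool:
    if history and history[-1] < 1e-12:  # numerically perfect fit
        return True
    if len(history) < 2:
        return False
    prev, cur = history[-2], history[-1]
    return prev == 0 or abs(cur - prev) / prev < tol


# ---------------------------------------------------------------------------
# rank selection


def scan_k(D, k_range, config: McrConfig | None = None) -> LofCurve:
    """Run a full MCR-ALS per K with identical settings; collect final LOFs."""
    base = config or McrConfig()
    ks, lofs = [], []
    for k in k_range:
        cfg = McrConfig(K=int(k), max_iter=base.max_iter, tol=base.tol,
                        simplisma_offset=base.simplisma_offset,
                        normalize_rows=base.normalize_rows,
                        nonneg_C=base.nonneg_C, nonneg_S=base.nonneg_S,
                        lof_definition=base.lof_definition)
        ks.append(int(k))
        lofs.append(mcr_als(D, cfg).lof)
    return LofCurve(ks=ks, lof=lofs)


def aggregate_lof(curves: list[LofCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-K mean and standard deviation of LOF across datasets.

    Returns ``(ks, mu_lof, sigma_lof)``; all curves must share the K grid.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    ks = np.asarray(curves[0].ks)
    for c in curves[1:]:
        if not np.array_equal(np.asarray(c.ks), ks):
            raise ValueError("curves have mismatching K grids")
    arr = np.array([c.lof for c in curves], dtype=float)
    return ks, arr.mean(axis=0), arr.std(axis=0)


def elbow_region(ks, mean_lof, rel_threshold: float = 0.9
                 ) -> tuple[int, int]:
    """Contiguous K-range bracketing the elbow of a mean-LOF curve.

    The elbow statistic is the distance of each point to the chord joining
    the first and last points of the curve.  The region is grown outward
    from the global maximum while the distance decays monotonically and
    stays above ``rel_threshold`` of the maximum; a re-increase of the
    distance marks a distinct competing knee and ends the region.  Returns
    ``(k_low, k_high)``.

    Raises :class:`NoElbowError` when the curve is (numerically) linear.
    """
    ks = np.asarray(list(ks))
    y = np.asarray(list(mean_lof), dtype=float)
    if ks.size != y.size:
        raise ValueError("ks and mean_lof must have the same length")
    if ks.size < 4:
        raise ValueError("need at least 4 points to locate an elbow")
    # small upticks (noise across aggregated datasets) are tolerated
    if np.any(np.diff(y) > 0.05 * max(np.ptp(y), 1e-300)):
        raise ValueError("mean LOF must be non-increasing (up to tolerance)")

    chord = y[0] + (y[-1] - y[0]) * (ks - ks[0]) / (ks[-1] - ks[0])
    dist = chord - y  # below-chord distance; scaling-invariant ratios
    scale = max(np.ptp(y), abs(y[0]), 1e-300)
    if dist.max() <= 1e-9 * scale:
        raise NoElbowError("curve is linear: no elbow")

    i_star = int(np.argmax(dist))
    cutoff = rel_threshold * dist[i_star]
    lo = i_star
    while lo > 0 and dist[lo - 1] >= cutoff and dist[lo - 1] <= dist[lo]:
        lo -= 1
    hi = i_star
    while hi < ks.size - 1 and dist[hi + 1] >= cutoff and dist[hi + 1] <= dist[hi]:
        hi += 1
    return int(ks[lo]), int(ks[hi])


# ---------------------------------------------------------------------------
# projection onto reference spectra


def project_reference(D_new, S_ref: np.ndarray) -> np.ndarray:
    """Project new pixel spectra onto a fixed basis of reference spectra.

    Per-pixel NNLS of each spectrum onto the rows of ``S_ref`` followed by
    row normalization; ``S_ref`` is left untouched.  Used to compare cells
    under different conditions in one common component basis.
    """
    D = _as_values(D_new)
    S_ref = np.asarray(S_ref, dtype=float)
    if np.any(S_ref < 0):
        raise ValueError("reference spectra must be non-negative")
    if D.shape[1] != S_ref.shape[1]:
        raise ValueError(
            f"channel mismatch: D has {D.shape[1]}, S_ref has {S_ref.shape[1]}"
        )
    C = nnls_solve(S_ref.T, D.T).T
    return normalize_rows(C)
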