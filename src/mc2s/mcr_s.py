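"""MCR-ALS with an in-loop Chan-Vese segmentation constraint (MCR^S).

Every alternating-least-squares iteration executes:

1. compute ``C`` by NNLS;
2. refold ``C`` into K component images;
3. Chan-Vese segment each image and combine the per-component cell-phase
   masks into one segmentation mask;
4. zero the concentrations outside the mask;
5. unfold back to matrix layout;
6. row-normalize ``C``;
7. compute ``S_T`` by NNLS.

The spatial constraint removes the extracellular milieu from the model, so
the final lack-of-fit — always evaluated against the FULL, unmasked data
matrix — rises compared with the unconstrained decomposition: the rise
quantifies how much of the data the segmentation discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_hypercube import DataMatrix, Mask, refold
from .mcr_core import (
    McrConfig,
    Decomposition,
    compute_lof,
    initial_spectra,
    normalize_rows,
    _lof_converged,
    _update_C,
    _update_S,
    _as_values,
)
from .segmentation import (
    CsvParams,
    DegenerateImageError,
    apply_mask,
    combine_masks,
    csv_segment,
    select_cell_phase,
)


class EmptySegmentationError(RuntimeError):
    """The combined mask is empty: everything was segmented away."""


@dataclass
class McrSResult:
    decomposition: Decomposition
    mask: Mask
    mask_history: list[Mask] | None = None

    @property
    def lof_final(self) -> float:
        """LOF against the full original D (fraction)."""
        return self.decomposition.lof


def _segment_components(images: np.ndarray, csv_params: CsvParams,
                        combine: str) -> Mask:
    """CSV-segment each refolded component image; vote a combined mask."""
    votes: list[Mask] = []
    for k in range(images.shape[2]):
        img = images[:, :, k]
        try:
            inside = csv_segment(img, csv_params)
            votes.append(select_cell_phase(inside, img))
        except DegenerateImageError:
            # constant component image cannot vote for any cell region
            votes.append(Mask(np.zeros(img.shape[:2], dtype=bool)))
    return combine_masks(votes, combine)


def mcr_s_iteration(D: DataMatrix, S_prev: np.ndarray,
                    mcr_cfg: McrConfig, csv_params: CsvParams,
                    combine: str = "majority",
                    forced_mask: Mask | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, Mask]:
    """One spatially constrained ALS cycle; returns ``(C, S_T, mask)``."""
    Dv = D.values
    C = _update_C(Dv, S_prev, mcr_cfg)
    if forced_mask is not None:
        mask = forced_mask
    else:
        images = refold(D, C)
        mask = _segment_components(images, csv_params, combine)
        if mask.area == 0:
            raise EmptySegmentationError(
                "segmentation removed every pixel; decrease mu to keep more "
                "boundary detail or check the component images"
            )
    C = apply_mask(C, mask)
    if not np.any(C):
        raise EmptySegmentationError(
            "all concentrations are zero after masking; decrease mu or "
            "check the component images"
        )
    if mcr_cfg.normalize_rows:
        C = normalize_rows(C)
    S_T = _update_S(Dv, C, mcr_cfg)
    return C, S_T, mask


def mcr_s(D: DataMatrix, mcr_cfg: McrConfig | None = None,
          csv_params: CsvParams | None = None, *,
          combine: str = "majority", warmup: int = 0,
          recompute_mask: bool = True, forced_mask: Mask | None = None,
          keep_mask_history: bool = False) -> McrSResult:
    """Segmentation-constrained curve resolution of a hypercube matrix.

    Runs :func:`mcr_s_iteration` from the SIMPLISMA initialization until
    the relative LOF change drops below ``mcr_cfg.tol`` or ``max_iter``.
    The reported LOF uses the full unmasked ``D`` in both numerator and
    denominator.

    Parameters
    ----------
    combine : mask combination strategy across components.
    warmup : number of initial unconstrained iterations before the
        segmentation constraint is switched on (default 0: constrained
        from the first iteration).
    recompute_mask : recompute the mask every iteration (default) or
        freeze it after its first computation.
    forced_mask : bypass segmentation entirely and impose this mask
        (an all-true mask makes the run identical to plain MCR-ALS).
    """
    cfg = mcr_cfg or McrConfig()
    csv_p = csv_params or CsvParams()
    Dv = _as_values(D)
    if not isinstance(D, DataMatrix):
        raise TypeError("mcr_s needs a DataMatrix (spatial layout required)")
    if cfg.K > min(Dv.shape):
        raise ValueError(f"K={cfg.K} exceeds min(M, N)")

    S_T = initial_spectra(Dv, cfg)
    lof_history: list[float] = []
    mask_history: list[Mask] = []
    mask: Mask | None = forced_mask
    frozen: Mask | None = forced_mask
    C = None
    converged = False
    for it in range(cfg.max_iter):
        if it < warmup and forced_mask is None:
            use_mask: Mask | None = Mask(np.ones(D.shape_xy, dtype=bool))
        elif frozen is not None:
            use_mask = frozen
        else:
            use_mask = None  # recompute inside the iteration
        C, S_T, mask = mcr_s_iteration(D, S_T, cfg, csv_p, combine,
                                       forced_mask=use_mask)
        if not recompute_mask and frozen is None and it >= warmup:
            frozen = mask
        if keep_mask_history:
            mask_history.append(mask)
        lof_history.append(compute_lof(Dv, C, S_T, cfg.lof_definition))
        if _lof_converged(lof_history, cfg.tol):
            converged = True
            break

    dec = Decomposition(C=C, S_T=S_T, lof_history=lof_history,
                        converged=converged)
    return McrSResult(decomposition=dec, mask=mask,
                      mask_history=mask_history if keep_mask_history else None)
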