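"""Exhaustive conformer-pair fitting of difference scattering.

Every (Pfr, Pr) conformer pair is scored against an experimental difference
curve by the scale-optimized sum of squared errors

.. math::

    \\mathrm{SSE}(pfr, pr) = \\min_k \\sum_q
        \\left(\\Delta S(q) - k\\,(S_{pfr} - S_{pr})\\right)^2 ,

summed over grid points inside a q window (default 0.5–2.5 nm⁻¹, the region
reporting on large-scale domain motion). The minimizing scale has the closed
form ``k = Σ ΔS·D / Σ D²`` with ``D = S_pfr − S_pr``; ``k`` is unconstrained
in sign. The sum is unweighted by default; per-point 1/σ² weighting is
available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import DifferenceCurve, Ensemble, require_same_grid
from .scatter import debye_scattering

__all__ = [
    "DEFAULT_WINDOW",
    "PairScore",
    "optimal_scale",
    "pairwise_scan",
    "top_fraction",
    "ensure_curves",
    "scores_to_frame",
]

logger = logging.getLogger(__name__)

#: Default scoring window in nm⁻¹.
DEFAULT_WINDOW = (0.5, 2.5)


@dataclass(frozen=True)
class PairScore:
    """One row of the exhaustive scan: indices, optimal scale, residual."""

    pr_index: int
    pfr_index: int
    k: float
    sse: float


def _window_mask(q: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (q >= lo) & (q <= hi)  # endpoints inclusive
    return mask


def optimal_scale(
    delta_exp: DifferenceCurve,
    delta_calc: DifferenceCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    sigma_weighted: bool = False,
) -> tuple[float, float]:
    """Closed-form least-squares scale and residual over a q window.

    Returns ``(k, sse)``. If the calculated difference vanishes identically
    over the window, ``k = 0`` and ``sse = Σ ΔS²``.
    """
    require_same_grid(delta_exp.q, delta_calc.q)
    mask = _window_mask(delta_exp.q, window)
    if mask.sum() < 2:
        raise ValueError(
            f"window {window} intersects the q grid in fewer than 2 points"
        )
    y = delta_exp.delta[mask]
    d = delta_calc.delta[mask]
    if sigma_weighted:
        if delta_exp.sigma is None:
            raise ValueError("sigma_weighted requires delta_exp.sigma")
        w = 1.0 / delta_exp.sigma[mask] ** 2
    else:
        w = np.ones_like(y)
    den = float(np.dot(w * d, d))
    if den == 0.0:
        return 0.0, float(np.dot(w * y, y))
    k = float(np.dot(w * y, d)) / den
    resid = y - k * d
    return k, float(np.dot(w * resid, resid))


def ensure_curves(ensemble: Ensemble, q: np.ndarray) -> np.ndarray:
    """Return an (n_members, n_q) intensity matrix on grid ``q``.

    Uses pre-computed curves when present (grids must match exactly),
    computing Debye curves otherwise.
    """
    if ensemble.curves is not None:
        require_same_grid(ensemble.curves[0].q, q, "pre-computed curves and data")
        return np.stack([c.intensity for c in ensemble.curves])
    return np.stack(
        [debye_scattering(m, q).intensity for m in ensemble.members]
    )


def pairwise_scan(
    pr_ensemble: Ensemble,
    pfr_ensemble: Ensemble,
    delta_exp: DifferenceCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    max_pairs: Optional[int] = None,
) -> list[PairScore]:
    """Score all |Pr| × |Pfr| conformer pairs; return scores sorted by SSE.

    The scan is vectorized: with curve matrices ``P`` (Pr) and ``F`` (Pfr) on
    the window grid, the per-pair projection ``Σ ΔS·D`` and norm ``Σ D²`` are
    assembled from matrix products rather than per-pair loops. Ties in SSE are
    broken by (pr_index, pfr_index) ascending. ``max_pairs`` keeps only the
    first members of each ensemble such that the pair count stays below the
    cap (a desk-demo subsample, not a ranking shortcut).
    """
    mask = _window_mask(delta_exp.q, window)
    if mask.sum() < 2:
        raise ValueError(
            f"window {window} intersects the q grid in fewer than 2 points"
        )
    P = ensure_curves(pr_ensemble, delta_exp.q)[:, mask]
    F = ensure_curves(pfr_ensemble, delta_exp.q)[:, mask]
    if max_pairs is not None and len(P) * len(F) > max_pairs:
        n_keep = max(1, int(math.sqrt(max_pairs)))
        logger.warning(
            "subsampling scan to first %d×%d members (max_pairs=%d)",
            n_keep, n_keep, max_pairs,
        )
        P, F = P[:n_keep], F[:n_keep]
    y = delta_exp.delta[mask]
    yy = float(np.dot(y, y))

    # D[i, j] = F[j] - P[i];  num[i, j] = y·D;  den[i, j] = D·D
    f_y = F @ y          # (n_pfr,)
    p_y = P @ y          # (n_pr,)
    f_sq = np.einsum("ij,ij->i", F, F)
    p_sq = np.einsum("ij,ij->i", P, P)
    cross = P @ F.T      # (n_pr, n_pfr)
    num = f_y[None, :] - p_y[:, None]
    den = f_sq[None, :] + p_sq[:, None] - 2.0 * cross
    # den is a squared norm; clip tiny negative round-off
    den = np.maximum(den, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(den > 0.0, num / np.where(den > 0, den, 1.0), 0.0)
    # residuals are evaluated explicitly (row by row to bound memory): the
    # expanded form yy - k*num cancels catastrophically near sse = 0
    sse = np.empty_like(k)
    for i in range(k.shape[0]):
        resid = y[None, :] - k[i][:, None] * (F - P[i])
        sse[i] = np.einsum("ij,ij->i", resid, resid)
    sse = np.where(den > 0.0, sse, yy)

    n_pr, n_pfr = k.shape
    pr_idx, pfr_idx = np.divmod(np.arange(n_pr * n_pfr), n_pfr)
    order = np.lexsort((pfr_idx, pr_idx, sse.ravel()))
    flat_k = k.ravel()
    flat_sse = sse.ravel()
    return [
        PairScore(int(pr_idx[o]), int(pfr_idx[o]),
                  float(flat_k[o]), float(flat_sse[o]))
        for o in order
    ]


def top_fraction(
    scores: Sequence[PairScore],
    fraction: Optional[float] = None,
    count: Optional[int] = None,
) -> list[PairScore]:
    """First ceil(fraction·N) entries of an SSE-sorted score list.

    An absolute ``count`` may be given instead; a count above N is clamped
    with a logged warning.
    """
    sse = [s.sse for s in scores]
    if any(a > b for a, b in zip(sse, sse[1:])):
        raise ValueError("scores must be sorted ascending by sse")
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    n = len(scores)
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        n_keep = math.ceil(fraction * n)
    else:
        if count < 1:
            raise ValueError("count must be >= 1")
        if count > n:
            logger.warning("requested %d scores but only %d exist", count, n)
        n_keep = min(count, n)
    return list(scores[:n_keep])


def scores_to_frame(scores: Sequence[PairScore]):
    """Scores as a pandas DataFrame (pr_id, pfr_id, k, sse, rank)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pr_id": [s.pr_index for s in scores],
            "pfr_id": [s.pfr_index for s in scores],
            "k": [s.k for s in scores],
            "sse": [s.sse for s in scores],
            "rank": np.arange(1, len(scores) + 1),
        }
    )
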