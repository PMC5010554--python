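"""Solution X-ray scattering prediction with the Debye equation.

For a set of point scatterers with weights :math:`f_i` at positions
:math:`r_i`, the orientation-averaged intensity is

.. math::

    I(q) = \\sum_i \\sum_j f_i f_j \\frac{\\sin(q r_{ij})}{q r_{ij}},

with the :math:`r_{ij} = 0` (and :math:`q = 0`) terms taken at the sinc limit
of 1. This is exact for in-vacuo point-scatterer models; no excluded-volume or
hydration-layer correction is applied — difference scattering between
conformers of the same protein largely cancels the solvent terms, and the
pair-fitting stage allows a free scale factor.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .models import (
    DifferenceCurve,
    ScatteringCurve,
    StructureModel,
    as_qgrid,
    require_same_grid,
)

__all__ = [
    "debye_scattering",
    "debye_scattering_binned",
    "difference_curve",
]


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the limit 1 at x = 0 (np.sinc is normalized by π)."""
    return np.sinc(x / np.pi)


def debye_scattering(model: StructureModel, q) -> ScatteringCurve:
    """Exact Debye sum, vectorized over unique pairs.

    Memory scales as ``N(N-1)/2 × len(q)``; for models beyond a few thousand
    beads use :func:`debye_scattering_binned`.
    """
    q = as_qgrid(q)
    f = model.weights
    r = pdist(model.coords)  # unique pairs i<j; empty for a single atom
    ij = np.triu_indices(model.n_atoms, k=1)
    fw = f[ij[0]] * f[ij[1]]
    # I(q) = Σ f_i² + 2 Σ_{i<j} f_i f_j sinc(q r_ij)
    cross = 2.0 * (fw[None, :] * _sinc(np.outer(q, r))).sum(axis=1)
    intensity = np.dot(f, f) + cross
    return ScatteringCurve(q=q, intensity=intensity,
                           provenance=f"debye:{model.model_id}")


def debye_scattering_binned(
    model: StructureModel, q, bin_width: float = 0.01
) -> ScatteringCurve:
    """Debye sum accelerated through a pair-distance histogram.

    All pair distances are accumulated into bins of ``bin_width`` (nm) with
    their weight products, and the sinc kernel is evaluated once per bin
    center. The relative error shrinks with ``bin_width``; 0.01 nm keeps it
    below ~1e-3 for q ≤ 5 nm⁻¹.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    q = as_qgrid(q)
    f = model.weights
    r = pdist(model.coords)
    if r.size == 0:  # single atom: no pairs, flat curve
        return ScatteringCurve(q=q, intensity=np.full(q.size, np.dot(f, f)),
                               provenance=f"debye-binned:{model.model_id}")
    d_max = r.max()
    if bin_width > d_max:
        raise ValueError(
            f"bin_width {bin_width} nm exceeds the model diameter {d_max:.4g} nm"
        )
    ij = np.triu_indices(model.n_atoms, k=1)
    fw = f[ij[0]] * f[ij[1]]
    n_bins = int(np.ceil(d_max / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(r, bins=edges, weights=fw)
    moment, _ = np.histogram(r, bins=edges, weights=fw * r)
    occupied = hist != 0
    # evaluate the kernel at the weighted mean distance of each bin, which
    # cancels the first-order binning error
    r_mean = moment[occupied] / hist[occupied]
    cross = 2.0 * (hist[occupied][None, :]
                   * _sinc(np.outer(q, r_mean))).sum(axis=1)
    intensity = np.dot(f, f) + cross
    return ScatteringCurve(q=q, intensity=intensity,
                           provenance=f"debye-binned:{model.model_id}")


def difference_curve(
    s_pfr: ScatteringCurve, s_pr: ScatteringCurve
) -> DifferenceCurve:
    """Pointwise difference ΔS = S_pfr − S_pr on a shared grid."""
    require_same_grid(s_pfr.q, s_pr.q)
    return DifferenceCurve(
        q=s_pfr.q.copy(),
        delta=s_pfr.intensity - s_pr.intensity,
        provenance=f"({s_pfr.provenance})-({s_pr.provenance})",
    )
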