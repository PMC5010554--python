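"""Bend and twist conformational coordinates and the residual landscape.

The domain motion is quantified by two scalar coordinates measured on marker
residues (Cα atoms):

* the **bend angle** — the interior angle at a hinge residue between the start
  of the long scaffolding helix and the center of the moving domain (default
  markers: residues 300, 317, 439 of chain A);
* the **dihedral (twist) angle** — the signed torsion about the 300→317 axis
  between a reference plane (288, 300, 317) and a variable plane
  (300, 317, 439), IUPAC sign convention, in (−180°, 180°].

Pairs from the scattering scan are binned by their (Δbend, Δdihedral) change,
pfr minus pr, and each bin is summarized by the mean SSE of its lowest 10%;
the landscape minimum localizes the structural change explaining the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import Ensemble, StructureModel
from .pairfit import PairScore

__all__ = [
    "AtomSelector",
    "AngleSpec",
    "DEFAULT_ANGLE_SPEC",
    "PairAngles",
    "Landscape",
    "bend_angle",
    "plane_dihedral",
    "pair_angle_table",
    "build_landscape",
    "wrap_degrees",
]


@dataclass(frozen=True)
class AtomSelector:
    """(chain, residue index, atom name) — must resolve to exactly one atom."""

    chain: str = "A"
    res_id: int = 0
    atom_name: str = "CA"

    def resolve(self, model: StructureModel) -> np.ndarray:
        hits = np.where(
            (model.chain_ids == self.chain)
            & (model.residue_ids == self.res_id)
            & (model.atom_names == self.atom_name)
        )[0]
        if hits.size != 1:
            raise ValueError(
                f"selector {self.chain}:{self.res_id}:{self.atom_name} resolves "
                f"to {hits.size} atoms in model {model.model_id!r}"
            )
        return model.coords[hits[0]]


@dataclass(frozen=True)
class AngleSpec:
    """Marker definitions for the bend triplet and dihedral quadruplet."""

    bend: tuple[AtomSelector, AtomSelector, AtomSelector] = (
        AtomSelector("A", 300),
        AtomSelector("A", 317),
        AtomSelector("A", 439),
    )
    dihedral: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector] = (
        AtomSelector("A", 288),
        AtomSelector("A", 300),
        AtomSelector("A", 317),
        AtomSelector("A", 439),
    )

    def __post_init__(self) -> None:
        if len(set(self.bend)) != 3 or len(set(self.dihedral)) != 4:
            raise ValueError("angle selectors must be distinct")


DEFAULT_ANGLE_SPEC = AngleSpec()


def _angle_from_points(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident points in bend-angle triplet")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def bend_angle(model: StructureModel, spec: AngleSpec = DEFAULT_ANGLE_SPEC) -> float:
    """Interior angle (degrees, in [0, 180]) at the middle bend marker."""
    a, b, c = (sel.resolve(model) for sel in spec.bend)
    return _angle_from_points(a, b, c)


def _torsion_from_points(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)  # reference-plane normal
    n2 = np.cross(b2, b3)  # variable-plane normal
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise ValueError("collinear triple in dihedral quadruplet")
    # atan2 form: numerically stable and gives the IUPAC sign about p2->p3
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return wrap_degrees(ang)


def plane_dihedral(model: StructureModel, spec: AngleSpec = DEFAULT_ANGLE_SPEC) -> float:
    """Signed torsion (degrees, in (−180, 180]) about the p2→p3 axis."""
    p1, p2, p3, p4 = (sel.resolve(model) for sel in spec.dihedral)
    return _torsion_from_points(p1, p2, p3, p4)


def wrap_degrees(angle: float) -> float:
    """Wrap an angle to (−180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class PairAngles:
    """Angle changes (pfr − pr, degrees) of one scored pair."""

    pr_index: int
    pfr_index: int
    d_bend: float
    d_dihedral: float  # wrapped to (−180, 180]
    sse: float


def pair_angle_table(
    scores: Sequence[PairScore],
    pr_ensemble: Ensemble,
    pfr_ensemble: Ensemble,
    spec: AngleSpec = DEFAULT_ANGLE_SPEC,
) -> list[PairAngles]:
    """Per-pair (Δbend, Δdihedral) with the SSE carried from the scan.

    Angles are measured once per distinct conformer, not once per pair.
    """
    bend_pr = {}
    bend_pfr = {}
    tors_pr = {}
    tors_pfr = {}
    for s in scores:
        if s.pr_index not in bend_pr:
            m = pr_ensemble.members[s.pr_index]
            bend_pr[s.pr_index] = bend_angle(m, spec)
            tors_pr[s.pr_index] = plane_dihedral(m, spec)
        if s.pfr_index not in bend_pfr:
            m = pfr_ensemble.members[s.pfr_index]
            bend_pfr[s.pfr_index] = bend_angle(m, spec)
            tors_pfr[s.pfr_index] = plane_dihedral(m, spec)
    return [
        PairAngles(
            pr_index=s.pr_index,
            pfr_index=s.pfr_index,
            d_bend=bend_pfr[s.pfr_index] - bend_pr[s.pr_index],
            d_dihedral=wrap_degrees(tors_pfr[s.pfr_index] - tors_pr[s.pr_index]),
            sse=s.sse,
        )
        for s in scores
    ]


@dataclass
class Landscape:
    """Best-fraction mean residual on a 2-D (Δbend, Δdihedral) grid.

    ``statistic`` is NaN in empty bins; ``counts`` holds bin occupancies.
    """

    bend_edges: np.ndarray
    dihedral_edges: np.ndarray
    statistic: np.ndarray  # (n_bend_bins, n_dihedral_bins)
    counts: np.ndarray
    fraction: float

    def minimum(self) -> tuple[float, float]:
        """(Δbend, Δdihedral) bin center with the smallest statistic."""
        if np.all(np.isnan(self.statistic)):
            raise ValueError("landscape has no occupied bins")
        i, j = np.unravel_index(np.nanargmin(self.statistic),
                               self.statistic.shape)
        bc = 0.5 * (self.bend_edges[i] + self.bend_edges[i + 1])
        dc = 0.5 * (self.dihedral_edges[j] + self.dihedral_edges[j + 1])
        return float(bc), float(dc)

    def to_frame(self):
        """Long-format DataFrame (bend_center, dihedral_center, statistic, count)."""
        import pandas as pd

        bc = 0.5 * (self.bend_edges[:-1] + self.bend_edges[1:])
        dc = 0.5 * (self.dihedral_edges[:-1] + self.dihedral_edges[1:])
        bb, dd = np.meshgrid(bc, dc, indexing="ij")
        return pd.DataFrame(
            {
                "bend_center_deg": bb.ravel(),
                "dihedral_center_deg": dd.ravel(),
                "statistic": self.statistic.ravel(),
                "count": self.counts.ravel(),
            }
        )


def default_edges(values: np.ndarray, width: float = 2.0) -> np.ndarray:
    """Bin edges of a given width (degrees) covering the observed range."""
    lo = math.floor(values.min() / width) * width
    hi = math.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def build_landscape(
    table: Sequence[PairAngles],
    bend_edges: Optional[np.ndarray] = None,
    dihedral_edges: Optional[np.ndarray] = None,
    fraction: float = 0.10,
    bin_width: float = 2.0,
) -> Landscape:
    """Bin pairs by (Δbend, Δdihedral); per bin, mean SSE of the lowest fraction.

    Default bins are ``bin_width``-degree (2°) squares covering the observed
    range. The per-bin statistic averages the ceil(fraction·n) smallest SSE
    values, so a single member bin reports its own SSE.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not table:
        raise ValueError("empty pair-angle table")
    d_bend = np.array([p.d_bend for p in table])
    d_tors = np.array([p.d_dihedral for p in table])
    sse = np.array([p.sse for p in table])
    if bend_edges is None:
        bend_edges = default_edges(d_bend, bin_width)
    if dihedral_edges is None:
        dihedral_edges = default_edges(d_tors, bin_width)
    bend_edges = np.asarray(bend_edges, dtype=float)
    dihedral_edges = np.asarray(dihedral_edges, dtype=float)
    for edges in (bend_edges, dihedral_edges):
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, length >= 2")

    nb = bend_edges.size - 1
    nd = dihedral_edges.size - 1
    # right-inclusive top edge so boundary pairs are kept
    bi = np.clip(np.digitize(d_bend, bend_edges) - 1, 0, nb - 1)
    di = np.clip(np.digitize(d_tors, dihedral_edges) - 1, 0, nd - 1)
    inside = (
        (d_bend >= bend_edges[0]) & (d_bend <= bend_edges[-1])
        & (d_tors >= dihedral_edges[0]) & (d_tors <= dihedral_edges[-1])
    )
    stat = np.full((nb, nd), np.nan)
    counts = np.zeros((nb, nd), dtype=int)
    flat = bi * nd + di
    for bin_id in np.unique(flat[inside]):
        sel = inside & (flat == bin_id)
        n = int(sel.sum())
        i, j = divmod(int(bin_id), nd)
        counts[i, j] = n
        n_keep = math.ceil(fraction * n)
        vals = np.sort(sse[sel])[:n_keep]
        stat[i, j] = vals.mean()
    if counts.sum() == 0:
        raise ValueError("all pairs fall outside the landscape bins")
    return Landscape(
        bend_edges=bend_edges,
        dihedral_edges=dihedral_edges,
        statistic=stat,
        counts=counts,
        fraction=fraction,
    )
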