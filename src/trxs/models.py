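"""Core data containers for the scattering analysis pipeline.

Conventions used throughout the package:

* coordinates are stored in **nm** (PDB ångström are divided by 10 on ingest);
* the scattering-vector modulus ``q`` is in **nm⁻¹** with the
  ``q = 4π sin(θ) / λ`` convention;
* scattering weights ``f_i`` are dimensionless effective electron counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class StateLabel(str, Enum):
    """Photochemical state a conformer is assigned to."""

    PR = "PR"
    PFR = "PFR"
    UNLABELLED = "UNLABELLED"


def as_qgrid(q: Sequence[float] | np.ndarray) -> np.ndarray:
    """Validate and return a q grid: strictly increasing, non-negative, 1-D."""
    arr = np.asarray(q, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("q grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("q grid contains non-finite values")
    if arr[0] < 0:
        raise ValueError("q must be non-negative")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError("q grid must be strictly increasing")
    return arr


@dataclass
class StructureModel:
    """Labelled point-scatterer model: positions (nm) plus per-atom weights.

    This is the unit the Debye sum consumes; an all-atom structure and a
    one-bead-per-residue coarse model are both represented this way.
    """

    coords: np.ndarray  # (N, 3) in nm
    weights: np.ndarray  # (N,) effective electron counts, all > 0
    residue_ids: np.ndarray  # (N,) int
    chain_ids: np.ndarray  # (N,) str
    atom_names: np.ndarray  # (N,) str
    state: StateLabel = StateLabel.UNLABELLED
    model_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if n < 1:
            raise ValueError("a structure model needs at least 1 atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for name, arr in (
            ("weights", self.weights),
            ("residue_ids", self.residue_ids),
            ("chain_ids", self.chain_ids),
            ("atom_names", self.atom_names),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if not np.all(self.weights > 0):
            raise ValueError("all scattering weights must be positive")
        # residue indices must be non-decreasing within each chain
        for chain in np.unique(self.chain_ids):
            res = self.residue_ids[self.chain_ids == chain]
            if np.any(np.diff(res) < 0):
                raise ValueError(
                    f"residue indices decrease within chain {chain!r}"
                )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (coords @ Rᵀ + t)."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return StructureModel(
            coords=self.coords @ rot.T + t,
            weights=self.weights.copy(),
            residue_ids=self.residue_ids.copy(),
            chain_ids=self.chain_ids.copy(),
            atom_names=self.atom_names.copy(),
            state=self.state,
            model_id=self.model_id,
        )


@dataclass
class ScatteringCurve:
    """Scattering intensity I(q) on a q grid, with optional uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.q = as_qgrid(self.q)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity and q must have the same length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have the same length")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")


@dataclass
class DifferenceCurve:
    """Signed difference scattering ΔS(q), optionally time-stamped (seconds)."""

    q: np.ndarray
    delta: np.ndarray
    sigma: Optional[np.ndarray] = None
    time_s: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.q = as_qgrid(self.q)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != self.q.shape:
            raise ValueError("delta and q must have the same length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have the same length")


@dataclass
class Ensemble:
    """Ordered pool of conformers sharing a state label.

    ``curves`` may hold one pre-computed :class:`ScatteringCurve` per member,
    all on one common grid; the pairwise scan fills it lazily otherwise.
    """

    members: list[StructureModel] = field(default_factory=list)
    curves: Optional[list[ScatteringCurve]] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must be non-empty")
        if self.curves is not None:
            if len(self.curves) != len(self.members):
                raise ValueError("one curve per member required")
            q0 = self.curves[0].q
            for c in self.curves[1:]:
                if not np.array_equal(c.q, q0):
                    raise ValueError("pre-computed curves must share one grid")

    def __len__(self) -> int:
        return len(self.members)


def same_grid(a: np.ndarray, b: np.ndarray, rtol: float = 0.0, atol: float = 1e-12) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=rtol, atol=atol)


def require_same_grid(a: np.ndarray, b: np.ndarray, what: str = "curves") -> None:
    if not same_grid(a, b):
        raise ValueError(f"{what} are not on the same q grid (no silent interpolation)")
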