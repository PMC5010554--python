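"""Reading and writing coordinate files and scattering curves.

PDB coordinates are parsed with biotite; positions are converted from Å to nm
on ingest. Scattering curves use the plain-text "DAT" dialect: whitespace- or
comma-delimited columns ``q  I  [sigma]``, ``#`` comments, and at most one
non-numeric header line.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .models import DifferenceCurve, ScatteringCurve, StateLabel, StructureModel

__all__ = [
    "ELECTRON_COUNTS",
    "load_structure",
    "load_ensemble",
    "write_ensemble_pdb",
    "read_curve",
    "write_curve",
    "read_difference_curve",
    "write_difference_curve",
]

# Electron counts (atomic numbers) for elements that occur in protein PDB
# files; deliberately not exhaustive — an unknown element is an error under
# the `electrons` scheme rather than a silent guess.
ELECTRON_COUNTS = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

WEIGHT_SCHEMES = ("electrons", "calpha", "uniform")


def _parse_pdb(source) -> list[struc.AtomArray]:
    """Parse a PDB file into one AtomArray per MODEL, with line diagnostics."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        name = str(source)
    else:
        text = source.read()
        name = "<stream>"
    try:
        pdb = PDBFile.read(_stdio.StringIO(text))
        stack = pdb.get_structure()  # AtomArrayStack, one entry per model
    except Exception as exc:
        # locate the first malformed coordinate record for the error message
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(
                        f"{name}: unparseable PDB record at line {lineno}: {line!r}"
                    ) from exc
        raise ValueError(f"{name}: unparseable PDB file: {exc}") from exc
    models = [stack[i] for i in range(stack.stack_depth())]
    if not models or models[0].array_length() == 0:
        raise ValueError(f"{name}: no ATOM/HETATM records found")
    return models


def _element_weight(element: str, atom_name: str) -> float:
    key = element.strip().upper()
    if not key:  # fall back to the first letter of the atom name
        key = atom_name.strip().upper()[:1]
    if key not in ELECTRON_COUNTS:
        raise ValueError(
            f"unknown element {element!r} for atom {atom_name!r} "
            "under the 'electrons' weight scheme"
        )
    return float(ELECTRON_COUNTS[key])


def _atoms_to_model(
    atoms: struc.AtomArray,
    weight_scheme: str,
    state: StateLabel,
    model_id: str,
) -> StructureModel:
    if weight_scheme not in WEIGHT_SCHEMES:
        raise ValueError(
            f"unknown weight scheme {weight_scheme!r}; choose from {WEIGHT_SCHEMES}"
        )
    coords_nm = np.asarray(atoms.coord, dtype=float) / 10.0  # Å → nm

    if weight_scheme == "uniform":
        weights = np.ones(atoms.array_length())
        return StructureModel(
            coords=coords_nm,
            weights=weights,
            residue_ids=atoms.res_id,
            chain_ids=atoms.chain_id,
            atom_names=atoms.atom_name,
            state=state,
            model_id=model_id,
        )

    elem_w = np.array(
        [_element_weight(e, n) for e, n in zip(atoms.element, atoms.atom_name)]
    )
    if weight_scheme == "electrons":
        return StructureModel(
            coords=coords_nm,
            weights=elem_w,
            residue_ids=atoms.res_id,
            chain_ids=atoms.chain_id,
            atom_names=atoms.atom_name,
            state=state,
            model_id=model_id,
        )

    # calpha: one bead per residue at the Cα position, weight = total residue
    # electron count. Residues without a CA atom cannot be represented.
    bead_pos, bead_w, bead_res, bead_chain = [], [], [], []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        sel = slice(s, e)
        ca = np.where(atoms.atom_name[sel] == "CA")[0]
        if ca.size != 1:
            raise ValueError(
                f"residue {atoms.chain_id[s]}:{atoms.res_id[s]} has "
                f"{ca.size} CA atoms; 'calpha' scheme requires exactly one"
            )
        bead_pos.append(coords_nm[sel][ca[0]])
        bead_w.append(elem_w[sel].sum())
        bead_res.append(int(atoms.res_id[s]))
        bead_chain.append(str(atoms.chain_id[s]))
    return StructureModel(
        coords=np.array(bead_pos),
        weights=np.array(bead_w),
        residue_ids=np.array(bead_res),
        chain_ids=np.array(bead_chain),
        atom_names=np.array(["CA"] * len(bead_pos)),
        state=state,
        model_id=model_id,
    )


def load_structure(
    source,
    weight_scheme: str = "calpha",
    state: StateLabel = StateLabel.UNLABELLED,
    model_id: Optional[str] = None,
) -> StructureModel:
    """Load the first MODEL of a PDB file as a :class:`StructureModel`."""
    models = _parse_pdb(source)
    mid = model_id if model_id is not None else _default_id(source, 0)
    return _atoms_to_model(models[0], weight_scheme, state, mid)


def load_ensemble(
    source,
    weight_scheme: str = "calpha",
    state: StateLabel = StateLabel.UNLABELLED,
) -> list[StructureModel]:
    """Load all MODELs of a multi-model PDB file as a conformer list."""
    models = _parse_pdb(source)
    return [
        _atoms_to_model(m, weight_scheme, state, _default_id(source, i))
        for i, m in enumerate(models)
    ]


def _default_id(source, index: int) -> str:
    stem = Path(source).stem if isinstance(source, (str, Path)) else "model"
    return f"{stem}:{index}"


def write_ensemble_pdb(path, members: Iterable[StructureModel]) -> None:
    """Write conformers as a multi-model PDB (coordinates nm → Å).

    Occupancy and B-factor columns are written as 1.00 / 0.00.
    """
    members = list(members)
    arrays = []
    for m in members:
        atoms = struc.AtomArray(m.n_atoms)
        atoms.coord = m.coords * 10.0
        atoms.chain_id = m.chain_ids
        atoms.res_id = m.residue_ids
        atoms.res_name = np.array(["ALA"] * m.n_atoms)
        atoms.atom_name = m.atom_names
        atoms.element = np.array(
            [n.strip()[:1] if n.strip() else "C" for n in m.atom_names]
        )
        atoms.set_annotation("occupancy", np.ones(m.n_atoms))
        atoms.set_annotation("b_factor", np.zeros(m.n_atoms))
        arrays.append(atoms)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_columns(source) -> np.ndarray:
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = source.read().splitlines()
    rows = []
    header_seen = False
    for line in lines:
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if header_seen or rows:
                raise ValueError(f"cannot parse curve line: {line!r}")
            header_seen = True  # one header line tolerated
    if not rows:
        raise ValueError("curve file contains no data rows")
    ncol = len(rows[0])
    if ncol not in (2, 3) or any(len(r) != ncol for r in rows):
        raise ValueError("curve file must have 2 or 3 numeric columns")
    return np.array(rows)


def read_curve(source, provenance: str = "") -> ScatteringCurve:
    data = _read_columns(source)
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return ScatteringCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma,
                           provenance=provenance)


def read_difference_curve(source, time_s: Optional[float] = None,
                          provenance: str = "") -> DifferenceCurve:
    data = _read_columns(source)
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return DifferenceCurve(q=data[:, 0], delta=data[:, 1], sigma=sigma,
                           time_s=time_s, provenance=provenance)


def _write_columns(path, q, y, sigma, header: str) -> None:
    cols = [q, y] if sigma is None else [q, y, sigma]
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.10e")


def write_curve(path, curve: ScatteringCurve) -> None:
    _write_columns(path, curve.q, curve.intensity, curve.sigma,
                   "q_nm^-1  I  [sigma]")


def write_difference_curve(path, curve: DifferenceCurve) -> None:
    _write_columns(path, curve.q, curve.delta, curve.sigma,
                   "q_nm^-1  dS  [sigma]")
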