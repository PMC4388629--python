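"""Readers and writers for the toolkit's on-disk formats.

XYZ (single and multi-frame trajectories with ``key=value`` metadata on the
comment line), PDB input via biotite (atom and residue names retained for
name-based collective-variable selection), TSV maps, CSV profiles and
plain-text Hessians.  All text, all round-trippable.
"""

from __future__ import annotations

import io
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .structures import Structure
from .tsopt import HessianMatrix
from .units import HARTREE_TO_KCAL_PER_MOL


class FileFormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _parse_comment(comment: str) -> dict:
    meta = {}
    for tok in comment.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            try:
                meta[k] = int(v) if v.lstrip("+-").isdigit() else float(v)
            except ValueError:
                meta[k] = v
    return meta


def _format_comment(meta: dict) -> str:
    parts = []
    for k, v in meta.items():
        if isinstance(v, float):
            parts.append(f"{k}={v:.12g}")
        else:
            parts.append(f"{k}={v}")
    return " ".join(parts)


def read_xyz_frames(path) -> list[Structure]:
    """Read one or more XYZ frames; comment metadata lands in ``meta``."""
    frames = []
    lines = FsPath(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FileFormatError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise FileFormatError(f"{path}:{i + 1}: truncated frame")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        labels, coords = [], []
        for k in range(n):
            ln = i + 2 + k
            toks = lines[ln].split()
            if len(toks) < 4:
                raise FileFormatError(f"{path}:{ln + 1}: malformed atom record")
            labels.append(toks[0])
            try:
                coords.append([float(t) for t in toks[1:4]])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{ln + 1}: bad coordinate") from exc
        frames.append(
            Structure(labels=labels, coords=np.array(coords),
                      meta=_parse_comment(comment))
        )
        i += 2 + n
    if not frames:
        raise FileFormatError(f"{path}: no frames found")
    return frames


def read_xyz(path) -> Structure:
    """Read a single-frame XYZ file (first frame if several)."""
    return read_xyz_frames(path)[0]


def write_xyz(structure: Structure, path, meta: dict | None = None) -> None:
    write_trajectory([structure], path, [meta or structure.meta])


def write_trajectory(
    structures: list[Structure], path, metadata: list[dict] | None = None
) -> None:
    """Write a multi-frame XYZ; per-frame comment carries index/energy/etc."""
    if not structures:
        raise ValueError("no structures to write")
    n = structures[0].n_atoms
    if any(s.n_atoms != n for s in structures):
        raise ValueError("inconsistent atom counts across frames")
    if metadata is None:
        metadata = [dict(s.meta, index=i) for i, s in enumerate(structures)]
    buf = io.StringIO()
    for s, meta in zip(structures, metadata):
        buf.write(f"{s.n_atoms}\n{_format_comment(meta)}\n")
        for el, (x, y, z) in zip(s.labels, s.coords):
            buf.write(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
    FsPath(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# PDB (read-only, via biotite)
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read ATOM/HETATM coordinates from a PDB file.

    Atom and residue names are retained (``names`` holds atom names;
    ``meta['residues']`` the residue names) so collective variables can be
    selected by name.  Only the first altLoc conformer is kept.  1-based PDB
    serials map to 0-based indices in file order.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    labels = [el.capitalize() if len(el) > 1 else el
              for el in atoms.element]
    return Structure(
        labels=list(labels),
        coords=np.asarray(atoms.coord, dtype=float),
        names=list(atoms.atom_name),
        meta={"residues": list(atoms.res_name), "source": str(path)},
    )


def read_structure(path) -> Structure:
    """Read a structure, format chosen from the file extension."""
    suffix = FsPath(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path)
    if suffix in (".pdb", ".ent"):
        return read_pdb(path)
    raise FileFormatError(f"unsupported structure format: {suffix!r}")


# ---------------------------------------------------------------------------
# Maps, profiles, Hessians
# ---------------------------------------------------------------------------

def pesmap_to_frame(pesmap) -> pd.DataFrame:
    """Flatten a PES map to a tidy table (one row per grid point)."""
    rows = []
    v1, v2 = pesmap.axis1.values, pesmap.axis2.values
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            row = {
                "axis1_value": a,
                "axis2_value": b,
                "energy_kcal": pesmap.energies[i, j],
                "energy_hartree": pesmap.energies[i, j] / HARTREE_TO_KCAL_PER_MOL
                + pesmap.reference_energy,
                "converged": bool(pesmap.converged[i, j]),
                "outlier": bool(pesmap.outlier[i, j]),
            }
            for name, grid in pesmap.monitors.items():
                row[f"monitor_{name}"] = grid[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def write_pesmap(pesmap, path, meta: dict | None = None) -> None:
    """Serialize a PES map as TSV with a commented header."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        pesmap_to_frame(pesmap).to_csv(fh, sep="\t", index=False)


def write_hessian(hessian: HessianMatrix, path, meta: dict | None = None) -> None:
    """Plain-text symmetric matrix with a header line."""
    header = {"step": hessian.step, "mass_weighted": hessian.mass_weighted,
              **(meta or {})}
    with open(path, "w") as fh:
        fh.write("# " + _format_comment(header) + "\n")
        np.savetxt(fh, hessian.matrix, fmt="%.12e")


def read_hessian(path) -> HessianMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FileFormatError(f"{path}:1: missing Hessian header")
        meta = _parse_comment(header[1:])
        matrix = np.loadtxt(fh)
    return HessianMatrix(
        matrix=np.atleast_2d(matrix),
        step=float(meta.get("step", np.nan)),
        mass_weighted=str(meta.get("mass_weighted", "False")) == "True",
    )
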