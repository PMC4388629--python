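"""Molecular structures: element labels, Cartesian coordinates and mobility roles.

A :class:`Structure` is the common currency of the toolkit.  Each atom carries
one of three mobility roles:

``mobile``
    optimized by the outer geometry driver (the analogue of a QM region whose
    Cartesian coordinates span the optimization space),
``env``
    a relaxed-environment atom, re-minimized to its own tolerance before every
    outer gradient evaluation (the analogue of a fully-relaxed MM region),
``frozen``
    never moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLES = ("mobile", "env", "frozen")

#: Standard atomic masses (amu) for the elements the toolkit encounters.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026,
    "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Zn": 65.38,
    "X": 1.0,  # abstract / surface pseudo-atom
}


@dataclass
class Structure:
    """Element labels plus Cartesian coordinates in Å.

    Parameters
    ----------
    labels
        Element symbols, one per atom.
    coords
        Array of shape ``(n_atoms, 3)``, Å.
    masses
        Atomic masses in amu; defaulted from ``labels`` when omitted.
    roles
        Per-atom mobility role, one of ``mobile``/``env``/``frozen``.
        Defaults to all-mobile.
    names
        Optional per-atom names (e.g. PDB atom names) for name-based
        selection of collective-variable atoms.
    """

    labels: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    roles: np.ndarray | None = None
    names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if len(self.labels) != n:
            raise ValueError("labels and coords disagree on atom count")
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_MASSES[el] for el in self.labels])
            except KeyError as exc:
                raise ValueError(f"no default mass for element {exc}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.roles is None:
            self.roles = np.full(n, "mobile", dtype=object)
        else:
            self.roles = np.asarray(self.roles, dtype=object)
            bad = set(self.roles) - set(ROLES)
            if bad:
                raise ValueError(f"unknown roles: {bad}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def mobile_mask(self) -> np.ndarray:
        return self.roles == "mobile"

    @property
    def env_mask(self) -> np.ndarray:
        return self.roles == "env"

    def copy(self) -> "Structure":
        return Structure(
            labels=list(self.labels),
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            roles=self.roles.copy(),
            names=list(self.names) if self.names is not None else None,
            meta=dict(self.meta),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(self.coords.shape)
        return out

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))
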