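"""Declarative run configuration (YAML) with upfront validation.

A run configuration picks the energy model by name, defines collective
variables by atom index (or PDB atom name when a named structure is
loaded), and carries per-stage settings in the units the stages quote
(restraint constants in Hartree Å⁻², NEB springs in eV Å⁻¹, convergence in
Hartree Å⁻¹).  Everything random flows from the single ``seed``; the
configuration hash is embedded in outputs for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace

import yaml

from .colvars import CV, DistanceCV, DistanceDifferenceCV
from .models import EnergyModel, MullerBrown
from .structures import Structure
from .toysni import PRESETS, ToySNiModel, ToySNiParams, build_toy_sni


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


@dataclass
class RunConfig:
    model: str = "toy-sni"
    structure: str | None = None          # optional input structure file
    cvs: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    neb: dict = field(default_factory=dict)
    ts: dict = field(default_factory=dict)
    ring: list = field(default_factory=list)
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- resolution ---------------------------------------------------------

    def build_model(self) -> tuple[EnergyModel, Structure | None, Structure | None]:
        """Instantiate the model and, for built-in fixtures, its endpoints."""
        if self.model in PRESETS:
            model, reactant, product = build_toy_sni(PRESETS[self.model], seed=self.seed)
            return model, reactant, product
        if self.model == "muller-brown":
            return MullerBrown(), None, None
        raise ConfigError(
            f"unknown model {self.model!r}; choose from "
            f"{sorted(PRESETS) + ['muller-brown']}"
        )

    def resolve_cv(self, name_or_spec, structure: Structure | None = None) -> CV:
        """Resolve a CV by config name or inline specification."""
        if isinstance(name_or_spec, str):
            if name_or_spec not in self.cvs:
                raise ConfigError(f"undefined CV {name_or_spec!r}")
            spec = self.cvs[name_or_spec]
            name = name_or_spec
        else:
            spec, name = name_or_spec, name_or_spec.get("name", "")
        kind = spec.get("type", "distance")
        atoms = [self._atom_index(a, structure) for a in spec.get("atoms", [])]
        if kind == "distance":
            if len(atoms) != 2:
                raise ConfigError(f"CV {name!r}: distance needs 2 atoms")
            return DistanceCV(*atoms, name=name)
        if kind == "distance_difference":
            if len(atoms) != 4:
                raise ConfigError(f"CV {name!r}: distance_difference needs 4 atoms")
            return DistanceDifferenceCV(*atoms, name=name)
        raise ConfigError(f"CV {name!r}: unknown type {kind!r}")

    def _atom_index(self, ref, structure: Structure | None) -> int:
        if isinstance(ref, int):
            if structure is not None and not 0 <= ref < structure.n_atoms:
                raise ConfigError(f"atom index {ref} out of range (n={structure.n_atoms})")
            if ref < 0:
                raise ConfigError(f"negative atom index {ref}")
            return ref
        if isinstance(ref, str) and structure is not None and structure.names:
            try:
                return structure.names.index(ref)
            except ValueError:
                raise ConfigError(f"atom name {ref!r} not found in structure") from None
        raise ConfigError(f"cannot resolve atom reference {ref!r}")
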