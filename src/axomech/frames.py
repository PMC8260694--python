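"""Bead-resolved coordinate frames for coarse-grained membranes.

A :class:`BilayerFrame` stores every bead of a system (lipids, water, ions,
protein placeholders) in flat numpy arrays — positions in nm, a molecule id,
a species (residue) name and a role per bead — together with an orthorhombic
periodic box. Analysis code selects beads by role: each lipid molecule has
exactly one ``head`` bead (phosphate for phospholipids, hydroxyl for
cholesterol, sugar for glycolipids) and one ``first_tail`` bead, the two
reference beads used for thickness, contact and enrichment calculations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

__all__ = ["Bead", "BilayerFrame", "ROLES", "FrameError"]

ROLES = ("head", "first_tail", "tail", "other", "water", "ion", "protein")

EXTRACELLULAR = "extracellular"
CYTOPLASMIC = "cytoplasmic"

#: Residue names reserved for non-lipid molecules.
WATER_NAME = "W"
ION_NAMES = ("NA", "CL")
PROTEIN_NAME = "PROT"

LIPID_ROLES = ("head", "first_tail", "tail", "other")


class FrameError(ValueError):
    """Raised for structurally invalid frames."""


@dataclass(frozen=True)
class Bead:
    """A single coarse-grained bead (positions in nm)."""

    molecule_id: int
    species: str
    role: str
    position: Tuple[float, float, float]


@dataclass
class BilayerFrame:
    """Beads plus a periodic orthorhombic box.

    Attributes
    ----------
    positions : (N, 3) float array, nm
    molecule_id : (N,) int array
    species : (N,) str array — residue/species name, ``W``/``NA``/``CL``/
        ``PROT`` for non-lipids
    role : (N,) str array — one of :data:`ROLES`
    box : (3,) float array — box edges (lx, ly, lz) in nm
    leaflet_label : optional mapping molecule_id -> ``extracellular`` |
        ``cytoplasmic`` for lipid molecules
    time : frame time in ps
    """

    positions: np.ndarray
    molecule_id: np.ndarray
    species: np.ndarray
    role: np.ndarray
    box: np.ndarray
    leaflet_label: Optional[Dict[int, str]] = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.species = np.asarray(self.species, dtype="U8")
        self.role = np.asarray(self.role, dtype="U12")
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = len(self.positions)
        for name, arr in (
            ("molecule_id", self.molecule_id),
            ("species", self.species),
            ("role", self.role),
        ):
            if len(arr) != n:
                raise FrameError(f"{name} has length {len(arr)}, expected {n}")

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check frame invariants; raise :class:`FrameError` on violation."""
        if not np.all(self.box > 0):
            raise FrameError(f"box edges must be positive, got {self.box}")
        if not np.all(np.isfinite(self.positions)):
            raise FrameError("non-finite coordinates")
        unknown = set(np.unique(self.role)) - set(ROLES)
        if unknown:
            raise FrameError(f"unknown roles {sorted(unknown)}")
        lipid = self.lipid_mask
        for want in ("head", "first_tail"):
            mask = lipid & (self.role == want)
            ids, counts = np.unique(self.molecule_id[mask], return_counts=True)
            lipid_ids = np.unique(self.molecule_id[lipid])
            if len(ids) != len(lipid_ids) or np.any(counts != 1):
                raise FrameError(
                    f"every lipid molecule needs exactly one {want!r} bead"
                )

    # -- masks and selections ------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def lipid_mask(self) -> np.ndarray:
        return np.isin(self.role, LIPID_ROLES)

    @property
    def water_mask(self) -> np.ndarray:
        return self.role == "water"

    @property
    def ion_mask(self) -> np.ndarray:
        return self.role == "ion"

    @property
    def protein_mask(self) -> np.ndarray:
        return self.role == "protein"

    @property
    def head_mask(self) -> np.ndarray:
        return self.role == "head"

    @property
    def first_tail_mask(self) -> np.ndarray:
        return self.role == "first_tail"

    def lipid_molecule_ids(self) -> np.ndarray:
        return np.unique(self.molecule_id[self.lipid_mask])

    def molecule_species(self) -> Dict[int, str]:
        """Map lipid molecule id -> species name (from head beads)."""
        mask = self.head_mask
        return dict(zip(self.molecule_id[mask].tolist(), self.species[mask].tolist()))

    def species_histogram(self, leaflet: str | None = None) -> Dict[str, int]:
        """Lipid molecule counts per species, optionally for one leaflet."""
        mask = self.head_mask
        if leaflet is not None:
            if self.leaflet_label is None:
                raise FrameError("frame has no leaflet labels")
            ids = self.molecule_id[mask]
            keep = np.array(
                [self.leaflet_label.get(int(i)) == leaflet for i in ids], dtype=bool
            )
            mask = np.flatnonzero(mask)[keep]
        names, counts = np.unique(self.species[mask], return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    # -- geometry helpers ----------------------------------------------

    def wrapped(self) -> "BilayerFrame":
        """Copy with all coordinates wrapped into [0, box)."""
        out = self.copy()
        out.positions = np.mod(out.positions, out.box)
        return out

    def translated(self, shift) -> "BilayerFrame":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def copy(self) -> "BilayerFrame":
        return BilayerFrame(
            positions=self.positions.copy(),
            molecule_id=self.molecule_id.copy(),
            species=self.species.copy(),
            role=self.role.copy(),
            box=self.box.copy(),
            leaflet_label=dict(self.leaflet_label) if self.leaflet_label else None,
            time=self.time,
        )

    # -- bead view ------------------------------------------------------

    def iter_beads(self) -> Iterator[Bead]:
        for i in range(self.n_beads):
            yield Bead(
                molecule_id=int(self.molecule_id[i]),
                species=str(self.species[i]),
                role=str(self.role[i]),
                position=tuple(self.positions[i]),
            )

    @property
    def beads(self) -> list:
        return list(self.iter_beads())

    @staticmethod
    def from_beads(beads, box, leaflet_label=None, time=0.0) -> "BilayerFrame":
        beads = list(beads)
        return BilayerFrame(
            positions=np.array([b.position for b in beads], dtype=float),
            molecule_id=np.array([b.molecule_id for b in beads]),
            species=np.array([b.species for b in beads]),
            role=np.array([b.role for b in beads]),
            box=np.asarray(box, dtype=float),
            leaflet_label=leaflet_label,
            time=time,
        )


def concatenate(frames, box, leaflet_label=None, time=0.0) -> BilayerFrame:
    """Concatenate bead arrays of several frames into one (no renumbering)."""
    frames = list(frames)
    return BilayerFrame(
        positions=np.concatenate([f.positions for f in frames]),
        molecule_id=np.concatenate([f.molecule_id for f in frames]),
        species=np.concatenate([f.species for f in frames]),
        role=np.concatenate([f.role for f in frames]),
        box=np.asarray(box, dtype=float),
        leaflet_label=leaflet_label,
        time=time,
    )
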