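"""Leaflet-resolved lipid compositions for axonal membrane models.

The myelin sheath and the node of Ranvier are modelled as asymmetric lipid
bilayers: each leaflet (extracellular vs cytoplasmic) carries its own mole
fractions over a small set of representative coarse-grained lipid species.
This module holds the species registry (names, classes, molar masses, head
and first-tail bead labels), the two shipped presets, and the conversions
between mole fractions, integer lipid counts, and class weight fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "LIPID_CLASSES",
    "LipidSpecies",
    "LeafletComposition",
    "MembraneComposition",
    "default_registry",
    "normalize_composition",
    "get_preset",
    "class_weight_fractions",
    "leaflet_counts",
    "load_registry_tsv",
    "write_registry_tsv",
]

LIPID_CLASSES = ("PC", "PE", "SM", "PS", "PI", "GLYCO", "CHOL", "OTHER")


class CompositionError(ValueError):
    """Raised for invalid compositions or registry lookups."""


@dataclass(frozen=True)
class LipidSpecies:
    """A representative coarse-grained lipid species.

    Parameters
    ----------
    name : str
        Short identifier (residue name in coordinate files).
    lipid_class : str
        One of :data:`LIPID_CLASSES`.
    molar_mass : float
        Molar mass in g/mol.
    head_bead_label : str
        Label of the head/reference bead: the phosphate bead for
        phospholipids, the hydroxyl (polar) bead for cholesterol, the first
        sugar bead for glycolipids.
    first_tail_bead_label : str
        Label of the first tail bead after the headgroup (the contact
        reference bead for neighbour counting).
    tails_carbons : int
        Carbons per acyl tail.
    unsaturations : int
        Double bonds per tail.
    """

    name: str
    lipid_class: str
    molar_mass: float
    head_bead_label: str
    first_tail_bead_label: str
    tails_carbons: int = 16
    unsaturations: int = 0

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise CompositionError(
                f"unknown lipid class {self.lipid_class!r} for species "
                f"{self.name!r}; must be one of {LIPID_CLASSES}"
            )
        if not self.molar_mass > 0:
            raise CompositionError(f"molar mass of {self.name!r} must be > 0")
        if not self.head_bead_label or not self.first_tail_bead_label:
            raise CompositionError(f"{self.name!r}: bead labels must be non-empty")
        if self.head_bead_label == self.first_tail_bead_label:
            raise CompositionError(
                f"{self.name!r}: head and first-tail bead labels must differ"
            )

    @property
    def has_phosphate(self) -> bool:
        """True for phosphodiester lipids (head bead is a phosphate)."""
        return self.lipid_class in ("PC", "PE", "SM", "PS", "PI")

    @property
    def charge(self) -> int:
        """Net charge of the lipid at physiological pH (e)."""
        return -1 if self.lipid_class in ("PS", "PI") else 0


def default_registry() -> Dict[str, LipidSpecies]:
    """Registry of representative species, one per lipid class.

    Molar masses are literature values for the chosen representative:
    POPC 760.1, POPE 718.0, cholesterol 386.7, d18:1/18:0 galactosylceramide
    728.1 (brain cerebroside pools span C16-C24 fatty acids; a mid-chain
    representative keeps the class-average mass realistic), d18:1/18:0
    sphingomyelin 731.1, POPS 761.8, POPI 836.5, plus a generic lipid for
    unclassified ("other") plasma-membrane species.
    """
    species = [
        LipidSpecies("POPC", "PC", 760.1, "PO4", "GL1", 17, 1),
        LipidSpecies("POPE", "PE", 718.0, "PO4", "GL1", 17, 1),
        LipidSpecies("SSM", "SM", 731.1, "PO4", "AM1", 18, 0),
        LipidSpecies("POPS", "PS", 761.8, "PO4", "GL1", 17, 1),
        LipidSpecies("POPI", "PI", 836.5, "PO4", "GL1", 17, 1),
        LipidSpecies("GCER", "GLYCO", 728.1, "GM1", "AM1", 18, 0),
        LipidSpecies("CHOL", "CHOL", 386.7, "ROH", "R1", 8, 0),
        LipidSpecies("OTHR", "OTHER", 750.0, "PO4", "GL1", 17, 1),
    ]
    return {s.name: s for s in species}


@dataclass(frozen=True)
class LeafletComposition:
    """Mole fractions over named species within one leaflet."""

    mole_fraction: Mapping[str, float]

    def __post_init__(self) -> None:
        fracs = dict(self.mole_fraction)
        if not fracs:
            raise CompositionError("leaflet composition is empty")
        for name, f in fracs.items():
            if f < 0:
                raise CompositionError(f"negative mole fraction for {name!r}: {f}")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(
                f"mole fractions sum to {total}, not 1 (normalize first)"
            )
        object.__setattr__(self, "mole_fraction", fracs)

    def species(self) -> tuple:
        return tuple(self.mole_fraction)


@dataclass(frozen=True)
class MembraneComposition:
    """An asymmetric bilayer composition: one leaflet per face."""

    extracellular: LeafletComposition
    cytoplasmic: LeafletComposition
    label: str = ""

    def all_species(self) -> tuple:
        seen = dict.fromkeys(
            (*self.extracellular.mole_fraction, *self.cytoplasmic.mole_fraction)
        )
        return tuple(seen)

    def validate_registry(self, registry: Mapping[str, LipidSpecies]) -> None:
        for name in self.all_species():
            if name not in registry:
                raise CompositionError(f"species {name!r} missing from registry")


def normalize_composition(raw: Mapping[str, float]) -> LeafletComposition:
    """Normalize non-negative weights into a leaflet composition.

    Listed mol% values are treated as weights; they need not sum to 100.
    """
    if not raw:
        raise CompositionError("empty composition")
    bad = [k for k, v in raw.items() if v < 0]
    if bad:
        raise CompositionError(f"negative weights for species: {bad}")
    total = float(sum(raw.values()))
    if total <= 0:
        raise CompositionError(
            f"all-zero composition: {sorted(raw)} have no positive weight"
        )
    return LeafletComposition({k: v / total for k, v in raw.items()})


# Per-leaflet mole percentages of the myelin model. The extracellular list
# sums to 100; the cytoplasmic one to 97, with the residual 3% assigned to a
# PI-like anionic species (the composition names "other anionic lipids"
# without a stated fraction).
_MYELIN_EXTRACELLULAR = {
    "POPC": 7.0,
    "POPE": 8.0,
    "CHOL": 43.0,
    "GCER": 39.0,
    "SSM": 2.0,
    "POPS": 1.0,
}
_MYELIN_CYTOPLASMIC = {
    "POPC": 11.0,
    "POPE": 27.0,
    "CHOL": 44.0,
    "SSM": 3.0,
    "POPS": 12.0,
    "POPI": 3.0,
}

# Class-level plasma-membrane composition used for the node of Ranvier,
# resolved to one representative species per class.
_NODE_EXTRACELLULAR = {
    "POPC": 36.0,
    "POPE": 6.0,
    "CHOL": 31.0,
    "SSM": 19.0,
    "GCER": 6.0,
    "OTHR": 2.0,
}
_NODE_CYTOPLASMIC = {
    "POPC": 17.0,
    "POPE": 25.0,
    "CHOL": 29.0,
    "SSM": 9.0,
    "POPS": 11.0,
    "POPI": 2.0,
    "OTHR": 7.0,
}

_PRESETS = {
    "myelin": (_MYELIN_EXTRACELLULAR, _MYELIN_CYTOPLASMIC),
    "node": (_NODE_EXTRACELLULAR, _NODE_CYTOPLASMIC),
}


def get_preset(name: str) -> MembraneComposition:
    """Return a shipped membrane composition (``myelin`` or ``node``)."""
    try:
        extra, cyto = _PRESETS[name]
    except KeyError:
        raise CompositionError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return MembraneComposition(
        extracellular=normalize_composition(extra),
        cytoplasmic=normalize_composition(cyto),
        label=name,
    )


def class_weight_fractions(
    membrane: MembraneComposition,
    registry: Mapping[str, LipidSpecies] | None = None,
    leaflet_mole_ratio: float = 1.0,
) -> Dict[str, float]:
    """Convert an asymmetric mole composition to overall class weight fractions.

    The two leaflets are combined with ``leaflet_mole_ratio`` moles of
    extracellular lipid per mole of cytoplasmic lipid (default 1:1, matching
    the builder's equal per-leaflet counts). The weight fraction of class C is

        w_C = sum_{s in C} n_s M_s / sum_s n_s M_s

    with n_s the combined mole fraction and M_s the registry molar mass.
    """
    if registry is None:
        registry = default_registry()
    if not leaflet_mole_ratio > 0:
        raise CompositionError("leaflet_mole_ratio must be > 0")
    membrane.validate_registry(registry)
    w_extra = leaflet_mole_ratio / (1.0 + leaflet_mole_ratio)
    w_cyto = 1.0 / (1.0 + leaflet_mole_ratio)
    mass_by_class: Dict[str, float] = {}
    for leaflet, w in (
        (membrane.extracellular, w_extra),
        (membrane.cytoplasmic, w_cyto),
    ):
        for name, frac in leaflet.mole_fraction.items():
            sp = registry[name]
            mass_by_class[sp.lipid_class] = (
                mass_by_class.get(sp.lipid_class, 0.0) + w * frac * sp.molar_mass
            )
    total = sum(mass_by_class.values())
    return {c: m / total for c, m in mass_by_class.items()}


def leaflet_counts(
    comp: LeafletComposition, n_lipids: int, seed: int = 0
) -> Dict[str, int]:
    """Integer lipid counts per species by largest-remainder rounding.

    Counts sum exactly to ``n_lipids``; each count deviates from
    ``n_lipids * fraction`` by less than 1. Remainder ties are broken in a
    seeded random order so the result is deterministic per seed.
    """
    if n_lipids <= 0:
        raise CompositionError("n_lipids must be > 0")
    names = list(comp.mole_fraction)
    fracs = np.array([comp.mole_fraction[n] for n in names])
    ideal = fracs * n_lipids
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    n_left = n_lipids - int(counts.sum())
    if n_left:
        rng = np.random.default_rng(seed)
        tiebreak = rng.permutation(len(names))
        order = np.lexsort((tiebreak, -remainder))
        counts[order[:n_left]] += 1
    return {n: int(c) for n, c in zip(names, counts) if c > 0}


_REGISTRY_COLUMNS = (
    "name",
    "class",
    "molar_mass",
    "head_bead",
    "first_tail_bead",
    "tails_carbons",
    "unsaturations",
)


def load_registry_tsv(path) -> Dict[str, LipidSpecies]:
    """Load a species registry from a TSV file with the documented columns."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise CompositionError(f"registry missing columns: {sorted(missing)}")
    registry = {}
    for row in df.to_dict("records"):
        sp = LipidSpecies(
            name=str(row["name"]),
            lipid_class=str(row["class"]),
            molar_mass=float(row["molar_mass"]),
            head_bead_label=str(row["head_bead"]),
            first_tail_bead_label=str(row["first_tail_bead"]),
            tails_carbons=int(row["tails_carbons"]),
            unsaturations=int(row["unsaturations"]),
        )
        registry[sp.name] = sp
    return registry


def write_registry_tsv(registry: Mapping[str, LipidSpecies], path) -> None:
    import pandas as pd

    rows = [
        {
            "name": s.name,
            "class": s.lipid_class,
            "molar_mass": s.molar_mass,
            "head_bead": s.head_bead_label,
            "first_tail_bead": s.first_tail_bead_label,
            "tails_carbons": s.tails_carbons,
            "unsaturations": s.unsaturations,
        }
        for s in registry.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
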