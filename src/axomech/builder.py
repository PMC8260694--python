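"""Construction of coarse-grained bilayer, multilayer and protein systems.

The builder places lipids on a jittered square lattice, one leaflet per
face of the midplane, with species drawn from an asymmetric
:class:`~axomech.composition.MembraneComposition`. Larger systems are made
by lateral tiling; myelin multilayers by stacking units so that like faces
meet across the experimentally measured aqueous gaps (1.7 nm between
extracellular faces, 1.6 nm between cytoplasmic faces). Ion-channel
placeholders (rigid bead cylinders) and solvent/ions complete the system.

Coordinates are in nm in an orthorhombic box with the origin at a corner,
the membrane midplane at lz/2 and the extracellular leaflet toward +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

from .composition import (
    LipidSpecies,
    MembraneComposition,
    default_registry,
    leaflet_counts,
)
from .frames import (
    CYTOPLASMIC,
    EXTRACELLULAR,
    PROTEIN_NAME,
    WATER_NAME,
    BilayerFrame,
    FrameError,
)

__all__ = [
    "SolvationSpec",
    "build_bilayer",
    "tile_bilayer",
    "stack_multilayer",
    "place_proteins",
    "solvate_and_ionize",
    "achieved_protein_density",
    "DEFAULT_AREA_PER_LIPID",
    "DEFAULT_WATER_BEAD_DENSITY",
    "WATERS_PER_BEAD",
]

AVOGADRO = 6.02214076e23

#: nm² per lipid per leaflet; 2 * 24² / 2000 reproduces the 2,000-lipid
#: patch in a 24 x 24 nm lateral box.
DEFAULT_AREA_PER_LIPID = 2 * 24.0**2 / 2000

#: CG water beads per nm³ (4-to-1 mapped water at ~1 g/mL).
DEFAULT_WATER_BEAD_DENSITY = 8.3

#: Water molecules represented by one CG bead.
WATERS_PER_BEAD = 4

#: Fractions of the leaflet half-thickness at which the beads of one lipid
#: sit, from the head bead down toward the midplane. Cholesterol is shorter
#: and its hydroxyl bead buries near the glycerol level of the surrounding
#: phospholipids, not at the phosphate plane.
_BEAD_Z_FRACTIONS = (1.0, 0.65, 0.40, 0.15)
_CHOL_Z_FRACTIONS = (0.65, 0.45, 0.28, 0.12)
_BEAD_ROLES = ("head", "first_tail", "tail", "tail")


class BuildError(ValueError):
    """Raised when a construction request is geometrically infeasible."""


@dataclass(frozen=True)
class SolvationSpec:
    """How to fill the non-membrane volume with water and ions."""

    water_bead_density: float = DEFAULT_WATER_BEAD_DENSITY
    salt_concentration: float = 0.150  # mol/L
    neutralize: bool = True

    def __post_init__(self) -> None:
        if not self.water_bead_density > 0:
            raise BuildError("water bead density must be > 0")
        if self.salt_concentration < 0:
            raise BuildError("salt concentration must be >= 0")


def _leaflet_lattice(n: int, lx: float, ly: float):
    """Gap-free lattice of ``n`` sites covering the full lateral box.

    Sites are arranged in rows; rows share the box height equally and each
    row spreads its sites over the full box width, so no contiguous hole is
    left when ``n`` is not a perfect square.
    """
    rows = max(1, int(round(math.sqrt(n * ly / lx))))
    base, extra = divmod(n, rows)
    xs, ys = [], []
    for r in range(rows):
        cols = base + (1 if r < extra else 0)
        y = (r + 0.5) * ly / rows
        for c in range(cols):
            xs.append((c + 0.5) * lx / cols)
            ys.append(y)
    return np.array(xs), np.array(ys)


def build_bilayer(
    membrane: MembraneComposition,
    n_lipids: int,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    thickness: float = 4.5,
    box_lz: float = 12.0,
    seed: int = 0,
    lateral_jitter: float = 0.1,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
) -> BilayerFrame:
    """Place ``n_lipids`` on a jittered square lattice, half per leaflet.

    The lateral box edge is ``sqrt(area_per_lipid * n_lipids / 2)`` (a square
    box), head beads sit at ``lz/2 +/- thickness/2`` with the extracellular
    leaflet on the +z side, and each lipid contributes four beads (head,
    first tail, two tail beads) stacked toward the midplane. Species are
    assigned by largest-remainder counts and a seeded shuffle, so repeated
    calls with one seed are bit-identical.
    """
    if registry is None:
        registry = default_registry()
    if n_lipids <= 0 or n_lipids % 2:
        raise BuildError("n_lipids must be positive and even")
    membrane.validate_registry(registry)
    n_leaf = n_lipids // 2
    lxy = math.sqrt(area_per_lipid * n_leaf)
    if box_lz <= thickness:
        raise BuildError(
            f"box_lz={box_lz} nm does not accommodate thickness={thickness} nm"
        )
    rng = np.random.default_rng(seed)
    mid = box_lz / 2.0

    positions, mol_ids, species_arr, roles = [], [], [], []
    leaflet_label: Dict[int, str] = {}
    next_mol = 1
    for leaflet_name, comp, sign in (
        (EXTRACELLULAR, membrane.extracellular, +1.0),
        (CYTOPLASMIC, membrane.cytoplasmic, -1.0),
    ):
        counts = leaflet_counts(comp, n_leaf, seed=seed)
        names = np.repeat(
            np.array(list(counts), dtype="U8"),
            np.array(list(counts.values()), dtype=int),
        )
        rng.shuffle(names)
        gx, gy = _leaflet_lattice(n_leaf, lxy, lxy)
        jit = rng.uniform(-lateral_jitter, lateral_jitter, size=(n_leaf, 2))
        gx = np.mod(gx + jit[:, 0], lxy)
        gy = np.mod(gy + jit[:, 1], lxy)
        half = thickness / 2.0
        for i in range(n_leaf):
            sp = registry[str(names[i])]
            fractions = (
                _CHOL_Z_FRACTIONS
                if sp.lipid_class == "CHOL"
                else _BEAD_Z_FRACTIONS
            )
            for frac, role in zip(fractions, _BEAD_ROLES):
                positions.append((gx[i], gy[i], mid + sign * half * frac))
                mol_ids.append(next_mol)
                species_arr.append(names[i])
                roles.append(role)
            leaflet_label[next_mol] = leaflet_name
            next_mol += 1

    frame = BilayerFrame(
        positions=np.array(positions, dtype=float),
        molecule_id=np.array(mol_ids),
        species=np.array(species_arr),
        role=np.array(roles),
        box=np.array([lxy, lxy, box_lz]),
        leaflet_label=leaflet_label,
    )
    frame.validate()
    return frame


def tile_bilayer(frame: BilayerFrame, nx: int, ny: int) -> BilayerFrame:
    """Replicate a patch ``nx`` by ``ny`` times in the membrane plane.

    Molecule ids are renumbered uniquely; the species composition is
    preserved exactly because every copy is identical.
    """
    if nx < 1 or ny < 1:
        raise BuildError("tile factors must be >= 1")
    if nx == 1 and ny == 1:
        return frame.copy()
    lx, ly, lz = frame.box
    stride = int(frame.molecule_id.max()) + 1
    pos, mids, spec, role = [], [], [], []
    leaflet = {} if frame.leaflet_label is not None else None
    copy_no = 0
    for i in range(nx):
        for j in range(ny):
            shift = np.array([i * lx, j * ly, 0.0])
            pos.append(frame.positions + shift)
            mids.append(frame.molecule_id + copy_no * stride)
            spec.append(frame.species)
            role.append(frame.role)
            if leaflet is not None:
                for mol, lab in frame.leaflet_label.items():
                    leaflet[mol + copy_no * stride] = lab
            copy_no += 1
    return BilayerFrame(
        positions=np.concatenate(pos),
        molecule_id=np.concatenate(mids),
        species=np.concatenate(spec),
        role=np.concatenate(role),
        box=np.array([nx * lx, ny * ly, lz]),
        leaflet_label=leaflet,
        time=frame.time,
    )


def stack_multilayer(
    frame: BilayerFrame,
    n_units: int,
    gap_extracellular: float = 1.7,
    gap_cytoplasmic: float = 1.6,
    max_lz: float = 200.0,
) -> BilayerFrame:
    """Stack bilayer units along z with alternating apposition gaps.

    Successive units are mirrored in z so that like faces meet: extracellular
    faces are separated by ``gap_extracellular`` and cytoplasmic faces by
    ``gap_cytoplasmic``, as in multilamellar myelin. Solvent and ions of the
    input frame are dropped (the stack is meant to be re-solvated); lipid and
    protein beads are kept.
    """
    if n_units < 2:
        raise BuildError("n_units must be >= 2")
    if gap_extracellular <= 0 or gap_cytoplasmic <= 0:
        raise BuildError("apposition gaps must be > 0")
    keep = frame.lipid_mask | frame.protein_mask
    if not keep.any():
        raise FrameError("frame has no membrane beads to stack")
    base_pos = frame.positions[keep]
    zmin, zmax = base_pos[:, 2].min(), base_pos[:, 2].max()
    height = zmax - zmin
    gaps = [
        gap_extracellular if k % 2 == 0 else gap_cytoplasmic
        for k in range(n_units - 1)
    ]
    added = (n_units - 1) * height + sum(gaps)
    new_lz = frame.box[2] + added
    if new_lz > max_lz:
        raise BuildError(f"stacked box lz={new_lz:.1f} nm exceeds max_lz={max_lz}")

    stride = int(frame.molecule_id.max()) + 1
    pos, mids, spec, role = [], [], [], []
    leaflet = {} if frame.leaflet_label is not None else None
    z0 = zmin
    for unit in range(n_units):
        flipped = unit % 2 == 1
        p = base_pos.copy()
        if flipped:
            p[:, 2] = (zmin + zmax) - p[:, 2]
        p[:, 2] += z0 - zmin
        pos.append(p)
        mids.append(frame.molecule_id[keep] + unit * stride)
        spec.append(frame.species[keep])
        role.append(frame.role[keep])
        if leaflet is not None:
            for mol, lab in frame.leaflet_label.items():
                if flipped:
                    lab = CYTOPLASMIC if lab == EXTRACELLULAR else EXTRACELLULAR
                leaflet[mol + unit * stride] = lab
        if unit < n_units - 1:
            z0 += height + gaps[unit]
    return BilayerFrame(
        positions=np.concatenate(pos),
        molecule_id=np.concatenate(mids),
        species=np.concatenate(spec),
        role=np.concatenate(role),
        box=np.array([frame.box[0], frame.box[1], new_lz]),
        leaflet_label=leaflet,
        time=frame.time,
    )


def _protein_cylinder(
    center_xy, z_bottom: float, z_top: float, radius: float
) -> np.ndarray:
    """Bead positions of a rigid placeholder cylinder."""
    layers = np.arange(z_bottom, z_top + 1e-9, 0.5)
    ring_radii = np.arange(0.0, radius + 1e-9, 1.0)
    pts = []
    for z in layers:
        for r in ring_radii:
            if r == 0.0:
                pts.append((center_xy[0], center_xy[1], z))
                continue
            n = max(6, int(round(2 * math.pi * r / 0.6)))
            ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
            for a in ang:
                pts.append(
                    (center_xy[0] + r * math.cos(a), center_xy[1] + r * math.sin(a), z)
                )
    return np.array(pts)


def place_proteins(
    frame: BilayerFrame,
    target_density: Optional[float] = None,
    count: Optional[int] = None,
    footprint_radius: float = 3.0,
    min_separation: float = 5.0,
    seed: int = 0,
) -> BilayerFrame:
    """Embed ion-channel placeholder cylinders spanning both leaflets.

    ``target_density`` is in channels/μm² (the requested count is
    ``round(density x lateral area)``); alternatively pass an explicit
    ``count``. Proteins go on a lateral grid with pairwise centre distance
    at least ``min_separation`` (default 5 nm); lipids whose head bead falls
    inside a footprint are deleted. Use :func:`achieved_protein_density` to
    read back the realized concentration.
    """
    if (target_density is None) == (count is None):
        raise BuildError("give exactly one of target_density or count")
    lx, ly, lz = frame.box
    area_nm2 = lx * ly
    if count is None:
        count = int(round(target_density * 1e-6 * area_nm2))
    if count == 0:
        return frame.copy()
    if count < 0:
        raise BuildError("protein count must be >= 0")

    k = math.ceil(math.sqrt(count))
    sx, sy = lx / k, ly / k
    if min(sx, sy) < min_separation:
        feasible = max(1, math.floor(lx / min_separation)) * max(
            1, math.floor(ly / min_separation)
        )
        raise BuildError(
            f"cannot place {count} proteins at {min_separation} nm separation "
            f"in a {lx:.1f} x {ly:.1f} nm box; at most {feasible} fit"
        )
    if count == 1:
        centers = np.array([[lx / 2, ly / 2]])
    else:
        idx = np.arange(count)
        centers = np.column_stack(
            [(idx % k + 0.5) * sx, (idx // k + 0.5) * sy]
        )

    lipid = frame.lipid_mask
    zmin = frame.positions[lipid, 2].min() - 0.5
    zmax = frame.positions[lipid, 2].max() + 0.5

    # delete lipids whose head bead lies in any footprint (periodic xy)
    head_idx = np.flatnonzero(frame.head_mask)
    head_xy = frame.positions[head_idx, :2]
    doomed: set = set()
    for c in centers:
        d = head_xy - c
        d -= np.round(d / frame.box[:2]) * frame.box[:2]
        hit = np.hypot(d[:, 0], d[:, 1]) <= footprint_radius
        doomed.update(frame.molecule_id[head_idx[hit]].tolist())
    keep = ~np.isin(frame.molecule_id, list(doomed)) if doomed else np.ones(
        frame.n_beads, dtype=bool
    )

    next_mol = int(frame.molecule_id.max()) + 1
    prot_pos, prot_mid = [], []
    for c in centers:
        cyl = _protein_cylinder(c, zmin, zmax, footprint_radius)
        prot_pos.append(cyl)
        prot_mid.append(np.full(len(cyl), next_mol))
        next_mol += 1
    prot_pos = np.concatenate(prot_pos)
    prot_mid = np.concatenate(prot_mid)

    leaflet = dict(frame.leaflet_label) if frame.leaflet_label is not None else None
    if leaflet is not None:
        for mol in doomed:
            leaflet.pop(int(mol), None)
    return BilayerFrame(
        positions=np.concatenate([frame.positions[keep], prot_pos]),
        molecule_id=np.concatenate([frame.molecule_id[keep], prot_mid]),
        species=np.concatenate(
            [frame.species[keep], np.full(len(prot_pos), PROTEIN_NAME, dtype="U8")]
        ),
        role=np.concatenate(
            [frame.role[keep], np.full(len(prot_pos), "protein", dtype="U12")]
        ),
        box=frame.box.copy(),
        leaflet_label=leaflet,
        time=frame.time,
    )


def achieved_protein_density(frame: BilayerFrame) -> float:
    """Realized protein concentration in channels/μm²."""
    n_prot = len(np.unique(frame.molecule_id[frame.protein_mask]))
    return n_prot / (frame.box[0] * frame.box[1] * 1e-6)


def solvate_and_ionize(
    frame: BilayerFrame, spec: SolvationSpec | None = None, seed: int = 0
) -> BilayerFrame:
    """Fill the non-membrane volume with CG water and NaCl.

    Water beads go on a jittered cubic grid at ``spec.water_bead_density``
    outside the membrane slab (the z-extent of lipid beads) and outside
    protein footprints. Ion pairs replace randomly chosen water beads:
    ``n = round(c * N_A * V_water)`` with ``V_water`` the filled volume; when
    ``spec.neutralize`` is set, additional cations cancel the net lipid
    charge so the total system charge is zero.
    """
    if spec is None:
        spec = SolvationSpec()
    lipid = frame.lipid_mask
    if not lipid.any():
        raise FrameError("no lipids to solvate around")
    lx, ly, lz = frame.box
    zmin = frame.positions[lipid, 2].min()
    zmax = frame.positions[lipid, 2].max()
    if zmax - zmin >= lz:
        raise BuildError("box lz does not exceed the membrane extent")

    a = spec.water_bead_density ** (-1.0 / 3.0)
    nx = max(1, int(round(lx / a)))
    ny = max(1, int(round(ly / a)))
    xs = (np.arange(nx) + 0.5) * (lx / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    region_pts = []
    # one grid per solvent region so partial boundary layers are not lost
    for z0, z1 in ((0.0, zmin), (zmax, lz)):
        extent = z1 - z0
        nz = int(round(extent / a))
        if nz < 1:
            continue
        zs = z0 + (np.arange(nz) + 0.5) * (extent / nz)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        region_pts.append(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
    pts = (
        np.concatenate(region_pts) if region_pts else np.empty((0, 3))
    )

    prot = frame.protein_mask
    if prot.any():
        for mol in np.unique(frame.molecule_id[prot]):
            sel = frame.positions[prot & (frame.molecule_id == mol)]
            c = sel[:, :2].mean(axis=0)
            r = np.hypot(*(sel[:, :2] - c).T).max() + 0.3
            d = pts[:, :2] - c
            d -= np.round(d / frame.box[:2]) * frame.box[:2]
            pts = pts[np.hypot(d[:, 0], d[:, 1]) > r]

    if len(pts) == 0:
        raise BuildError("no solvent volume available")
    rng = np.random.default_rng(seed)
    pts = pts + rng.uniform(-0.2 * a, 0.2 * a, size=pts.shape)
    pts = np.mod(pts, frame.box)

    v_water_nm3 = len(pts) / spec.water_bead_density
    n_pairs = int(round(spec.salt_concentration * AVOGADRO * v_water_nm3 * 1e-24))
    n_extra_cation = 0
    if spec.neutralize:
        registry = default_registry()
        charge = 0
        for mol, name in frame.molecule_species().items():
            sp = registry.get(name)
            if sp is not None:
                charge += sp.charge
        n_extra_cation = max(0, -charge)
    n_ions = 2 * n_pairs + n_extra_cation
    if n_ions > len(pts):
        raise BuildError("not enough water beads to place the requested ions")

    species = np.full(len(pts), WATER_NAME, dtype="U8")
    role = np.full(len(pts), "water", dtype="U12")
    ion_idx = rng.choice(len(pts), size=n_ions, replace=False)
    na_idx = ion_idx[: n_pairs + n_extra_cation]
    cl_idx = ion_idx[n_pairs + n_extra_cation :]
    species[na_idx], role[na_idx] = "NA", "ion"
    species[cl_idx], role[cl_idx] = "CL", "ion"

    next_mol = int(frame.molecule_id.max()) + 1
    mids = np.arange(next_mol, next_mol + len(pts))
    return BilayerFrame(
        positions=np.concatenate([frame.positions, pts]),
        molecule_id=np.concatenate([frame.molecule_id, mids]),
        species=np.concatenate([frame.species, species]),
        role=np.concatenate([frame.role, role]),
        box=frame.box.copy(),
        leaflet_label=dict(frame.leaflet_label)
        if frame.leaflet_label is not None
        else None,
        time=frame.time,
    )
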