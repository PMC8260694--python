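"""Structural descriptors of bilayer frames.

Implements the standard leaflet-resolved analyses for flat membranes:

* leaflet assignment from head-bead height,
* bilayer thickness by the vertical-neighbour construction — each phosphate
  head bead is paired with the opposing-leaflet head whose lateral periodic
  Voronoi cell contains its (x, y) projection (equivalently: its nearest
  opposing head in periodic xy distance), and thickness is the mean |dz|
  over both pairing directions,
* lipid-lipid contact counts within a cutoff (default 1.5 nm) using the
  first tail bead after the headgroup, or the polar bead for cholesterol,
* enrichment factors: class abundance in a shell around a reference lipid
  or protein divided by the bulk abundance,
* the water partition coefficient log10(K_mem/wat) from the water content
  of the membrane slab against bulk water at 55.5 mol/L,
* block averaging (5 contiguous blocks by default) for standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .composition import LipidSpecies, default_registry
from .frames import BilayerFrame

__all__ = [
    "ThicknessResult",
    "EnrichmentResult",
    "PartitionResult",
    "assign_leaflets",
    "thickness_voronoi",
    "count_contacts",
    "enrichment_factor",
    "water_partition",
    "block_error",
    "BULK_WATER_MOLAR",
]

AVOGADRO = 6.02214076e23
#: Experimental molar concentration of bulk water, mol/L.
BULK_WATER_MOLAR = 55.5


class AnalysisError(ValueError):
    """Raised when an analysis precondition fails."""


# ---------------------------------------------------------------- leaflets


def assign_leaflets(frame: BilayerFrame) -> Dict[int, str]:
    """Partition lipids into ``upper``/``lower`` by head-bead height.

    The split plane is halfway between the mean head height of the upper and
    lower halves of the z-sorted heads, so it falls strictly between two
    coplanar leaflets even when their lipid counts differ, and labels are
    invariant under any global z-translation of the frame.
    """
    mask = frame.head_mask
    if not mask.any():
        raise AnalysisError("frame contains no lipid head beads")
    z = frame.positions[mask, 2]
    mols = frame.molecule_id[mask]
    zs = np.sort(z)
    half = len(zs) // 2
    zsplit = 0.5 * (zs[:half].mean() + zs[half:].mean())
    upper = z > zsplit
    out = {int(m): ("upper" if u else "lower") for m, u in zip(mols, upper)}
    n_up = sum(1 for v in out.values() if v == "upper")
    if n_up < 2 or len(out) - n_up < 2:
        raise AnalysisError(
            f"degenerate leaflet split: {n_up} upper vs {len(out) - n_up} lower"
        )
    return out


# ---------------------------------------------------------------- thickness


@dataclass
class ThicknessResult:
    """Mean bilayer thickness with per-lipid contributions (nm)."""

    mean_thickness: float
    per_lipid: Dict[int, float]
    standard_error: float


def _phosphate_heads(
    frame: BilayerFrame,
    registry: Mapping[str, LipidSpecies],
    include_species: Sequence[str] = (),
) -> np.ndarray:
    """Indices of head beads carrying a phosphate (or configured proxies)."""
    idx = np.flatnonzero(frame.head_mask)
    keep = []
    for i in idx:
        name = str(frame.species[i])
        sp = registry.get(name)
        if name in include_species or (sp is not None and sp.has_phosphate):
            keep.append(i)
    return np.asarray(keep, dtype=int)


def slab_bounds(
    frame: BilayerFrame,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
) -> Tuple[float, float]:
    """Mean phosphate-plane heights (z_lower, z_upper) bounding the slab.

    Phosphate head beads define the planes; lipids with buried polar heads
    (cholesterol) would bias the planes inward. Falls back to all head beads
    if a leaflet carries no phosphates.
    """
    if registry is None:
        registry = default_registry()
    leaflets = assign_leaflets(frame)
    idx = _phosphate_heads(frame, registry)
    side = np.array([leaflets[int(m)] for m in frame.molecule_id[idx]])
    if len(idx) == 0 or not (side == "upper").any() or not (side == "lower").any():
        idx = np.flatnonzero(frame.head_mask)
        side = np.array([leaflets[int(m)] for m in frame.molecule_id[idx]])
    z = frame.positions[idx, 2]
    return float(z[side == "lower"].mean()), float(z[side == "upper"].mean())


def thickness_voronoi(
    frame: BilayerFrame,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
    include_species: Sequence[str] = (),
) -> ThicknessResult:
    """Vertical-neighbour bilayer thickness.

    For each phosphate head bead, the opposing-leaflet head whose periodic
    lateral Voronoi cell contains its projection is its vertical neighbour;
    that head is exactly the nearest opposing head in periodic xy distance,
    found here with a periodic KD-tree. The per-lipid thickness is |dz| to
    the neighbour (minimum image in z) and the mean runs over both leaflet
    directions. Lipids without phosphate head beads (cholesterol,
    glycolipids) are excluded unless listed in ``include_species``.
    """
    if registry is None:
        registry = default_registry()
    leaflets = assign_leaflets(frame)
    idx = _phosphate_heads(frame, registry, include_species)
    if len(idx) == 0:
        raise AnalysisError("no phosphate-bearing head beads in frame")
    side = np.array([leaflets[int(m)] for m in frame.molecule_id[idx]])
    box = frame.box
    xy = np.mod(frame.positions[idx, :2], box[:2])
    z = frame.positions[idx, 2]
    per_lipid: Dict[int, float] = {}
    for a, b in (("upper", "lower"), ("lower", "upper")):
        ia = np.flatnonzero(side == a)
        ib = np.flatnonzero(side == b)
        if len(ia) < 3 or len(ib) < 3:
            raise AnalysisError(
                "each leaflet needs at least 3 phosphate head beads"
            )
        tree = cKDTree(xy[ib], boxsize=box[:2])
        _, nn = tree.query(xy[ia], k=1)
        dz = np.abs(z[ia] - z[ib][nn])
        dz = np.minimum(dz, box[2] - dz)
        for j, t in zip(ia, dz):
            per_lipid[int(frame.molecule_id[idx[j]])] = float(t)
    values = np.array(list(per_lipid.values()))
    se = values.std(ddof=1) / math.sqrt(len(values)) if len(values) > 1 else 0.0
    return ThicknessResult(
        mean_thickness=float(values.mean()),
        per_lipid=per_lipid,
        standard_error=float(se),
    )


# ---------------------------------------------------------------- contacts


def _reference_beads(
    frame: BilayerFrame, registry: Mapping[str, LipidSpecies]
) -> np.ndarray:
    """Index of the contact reference bead per lipid molecule.

    First tail bead after the headgroup for most lipids; the polar (head)
    bead for cholesterol.
    """
    out = []
    head_idx = np.flatnonzero(frame.head_mask)
    tail_idx = np.flatnonzero(frame.first_tail_mask)
    head_by_mol = dict(zip(frame.molecule_id[head_idx].tolist(), head_idx.tolist()))
    tail_by_mol = dict(zip(frame.molecule_id[tail_idx].tolist(), tail_idx.tolist()))
    for mol, name in frame.molecule_species().items():
        sp = registry.get(name)
        use_head = sp is not None and sp.lipid_class == "CHOL"
        table = head_by_mol if use_head else tail_by_mol
        if mol not in table:
            raise AnalysisError(
                f"species {name!r} (molecule {mol}) lacks a reference bead"
            )
        out.append(table[mol])
    return np.asarray(out, dtype=int)


def count_contacts(
    frame: BilayerFrame,
    radius: float = 1.5,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
    per_leaflet: bool = True,
):
    """Mean neighbour counts per ordered species pair within ``radius`` nm.

    Entry (A, B) is the mean, over lipids of species A, of the number of
    B-lipids whose reference bead lies within ``radius`` under periodic
    boundary conditions; self-contacts are excluded. Returns a DataFrame per
    leaflet (or one for the whole bilayer with ``per_leaflet=False``).
    """
    if registry is None:
        registry = default_registry()
    ref_idx = _reference_beads(frame, registry)
    leaflets = assign_leaflets(frame)
    mols = frame.molecule_id[ref_idx]
    sides = np.array([leaflets[int(m)] for m in mols])
    groups = ("upper", "lower") if per_leaflet else ("all",)
    results = {}
    for g in groups:
        sel = np.ones(len(ref_idx), dtype=bool) if g == "all" else sides == g
        idx = ref_idx[sel]
        names = frame.species[idx]
        pos = np.mod(frame.positions[idx], frame.box)
        tree = cKDTree(pos, boxsize=frame.box)
        neigh = tree.query_ball_point(pos, r=radius)
        uniq = sorted(set(names.tolist()))
        count = {a: {b: 0.0 for b in uniq} for a in uniq}
        n_of = {a: 0 for a in uniq}
        for i, nb in enumerate(neigh):
            a = str(names[i])
            n_of[a] += 1
            for j in nb:
                if j == i:
                    continue
                count[a][str(names[j])] += 1.0
        df = pd.DataFrame(
            {b: [count[a][b] / n_of[a] if n_of[a] else np.nan for a in uniq]
             for b in uniq},
            index=uniq,
        )
        results[g] = df
    return results if per_leaflet else results["all"]


# ---------------------------------------------------------------- enrichment


@dataclass
class EnrichmentResult:
    """Local-vs-bulk lipid class composition around a reference."""

    reference: str
    shell_radius: float
    ratio_x: Dict[str, float]
    ratio_bulk: Dict[str, float]
    enrichment: Dict[str, float]
    n_in_shell: int = 0
    empty_shell: bool = False


def _lipid_classes(
    frame: BilayerFrame, registry: Mapping[str, LipidSpecies]
) -> Dict[int, str]:
    return {
        mol: (registry[name].lipid_class if name in registry else "OTHER")
        for mol, name in frame.molecule_species().items()
    }


def enrichment_factor(
    frame: BilayerFrame,
    reference: str,
    shell_radius: float,
    per_leaflet: bool = True,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
    by_class: bool = True,
):
    """Enrichment factors of lipid classes within a shell of a reference.

    ``reference`` may be a lipid species name, a lipid class, or
    ``"protein"``. Shell membership uses the lipid reference beads (first
    tail, polar bead for cholesterol) and, for proteins, the distance to the
    nearest protein bead. For every counted class L,

        enrichment(L) = ratio_x(L) / ratio_bulk(L)

    where ratio_x is the composition of the shell population (summed over
    all reference centres, centre lipid excluded) and ratio_bulk the global
    composition of the same leaflet (or whole bilayer). Classes absent from
    the bulk get NaN (undefined), never zero.
    """
    if shell_radius <= 0:
        raise AnalysisError("shell_radius must be > 0")
    if registry is None:
        registry = default_registry()
    ref_idx = _reference_beads(frame, registry)
    leaflets = assign_leaflets(frame)
    mols = frame.molecule_id[ref_idx]
    class_of = _lipid_classes(frame, registry)
    labels = (
        np.array([class_of[int(m)] for m in mols])
        if by_class
        else frame.species[ref_idx].astype("U8")
    )
    sides = np.array([leaflets[int(m)] for m in mols])
    box = frame.box
    is_protein_ref = reference.lower() == "protein"
    if is_protein_ref and not frame.protein_mask.any():
        raise AnalysisError("no protein beads in frame")

    groups = ("upper", "lower") if per_leaflet else ("all",)
    results = {}
    for g in groups:
        sel = np.ones(len(ref_idx), dtype=bool) if g == "all" else sides == g
        idx = ref_idx[sel]
        lab = labels[sel]
        mol_g = mols[sel]
        pos = np.mod(frame.positions[idx], box)
        tree = cKDTree(pos, boxsize=box)
        shell_counts: Dict[str, float] = {}
        n_shell = 0
        if is_protein_ref:
            ppos = np.mod(frame.positions[frame.protein_mask], box)
            hit: set = set()
            for nb in cKDTree(ppos, boxsize=box).query_ball_tree(tree, r=shell_radius):
                hit.update(nb)
            for j in sorted(hit):
                shell_counts[str(lab[j])] = shell_counts.get(str(lab[j]), 0) + 1
                n_shell += 1
        else:
            if by_class:
                centers = np.flatnonzero(lab == reference)
            else:
                centers = np.flatnonzero(frame.species[idx] == reference)
            if len(centers) == 0 and g == "all":
                raise AnalysisError(f"reference {reference!r} not present in frame")
            for c in centers:
                for j in tree.query_ball_point(pos[c], r=shell_radius):
                    if mol_g[j] == mol_g[c]:
                        continue
                    shell_counts[str(lab[j])] = shell_counts.get(str(lab[j]), 0) + 1
                    n_shell += 1
        bulk_names, bulk_counts = np.unique(lab, return_counts=True)
        ratio_bulk = {
            str(n): c / len(lab) for n, c in zip(bulk_names, bulk_counts)
        }
        if n_shell == 0:
            results[g] = EnrichmentResult(
                reference=reference,
                shell_radius=shell_radius,
                ratio_x={k: float("nan") for k in ratio_bulk},
                ratio_bulk=ratio_bulk,
                enrichment={k: float("nan") for k in ratio_bulk},
                n_in_shell=0,
                empty_shell=True,
            )
            continue
        ratio_x = {k: shell_counts.get(k, 0) / n_shell for k in ratio_bulk}
        enrich = {
            k: (ratio_x[k] / ratio_bulk[k] if ratio_bulk[k] > 0 else float("nan"))
            for k in ratio_bulk
        }
        results[g] = EnrichmentResult(
            reference=reference,
            shell_radius=shell_radius,
            ratio_x=ratio_x,
            ratio_bulk=ratio_bulk,
            enrichment=enrich,
            n_in_shell=n_shell,
        )
    return results if per_leaflet else results["all"]


# ---------------------------------------------------------------- partition


@dataclass
class PartitionResult:
    """Water partitioning between the membrane slab and bulk water."""

    water_conc_membrane: float  # mol/L
    water_conc_bulk: float  # mol/L
    membrane_volume: float  # nm^3 (protein-corrected, mean over frames)
    protein_volume_correction: float  # nm^3
    log_k: float  # log10(K_mem/wat)
    below_detection: bool = False


def water_partition(
    frames: Sequence[BilayerFrame],
    protein_volume: float = 0.0,
    waters_per_bead: int = 4,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
) -> PartitionResult:
    """Water partition coefficient of the membrane slab.

    Per frame, the slab is the z-interval between the mean phosphate-plane
    heights of the two leaflets (:func:`slab_bounds`); the water
    concentration inside it is the number of water molecules (beads x
    ``waters_per_bead``) divided by the slab volume corrected for
    ``protein_volume``. log10 of the ratio to bulk water (55.5 mol/L) is
    returned; frames without slab water give -inf flagged as below
    detection.
    """
    frames = list(frames)
    if not frames:
        raise AnalysisError("need at least one frame")
    concs, volumes = [], []
    for frame in frames:
        z_lo, z_up = slab_bounds(frame, registry)
        thickness = z_up - z_lo
        area = frame.box[0] * frame.box[1]
        vol = area * thickness - protein_volume
        if vol <= 0:
            raise AnalysisError(
                f"protein-corrected slab volume {vol:.1f} nm^3 is not positive"
            )
        wz = frame.positions[frame.water_mask, 2]
        n_waters = int(np.sum((wz > z_lo) & (wz < z_up))) * waters_per_bead
        concs.append(n_waters / (AVOGADRO * vol * 1e-24))
        volumes.append(vol)
    conc = float(np.mean(concs))
    below = conc == 0.0
    log_k = float("-inf") if below else math.log10(conc / BULK_WATER_MOLAR)
    return PartitionResult(
        water_conc_membrane=conc,
        water_conc_bulk=BULK_WATER_MOLAR,
        membrane_volume=float(np.mean(volumes)),
        protein_volume_correction=protein_volume,
        log_k=log_k,
        below_detection=below,
    )


# ---------------------------------------------------------------- blocks


def block_error(series: Sequence[float], n_blocks: int = 5) -> Tuple[float, float]:
    """Mean and standard error from contiguous block averaging.

    The series is split into ``n_blocks`` contiguous, near-equal blocks (no
    data dropped); the return is the mean of the block means and their
    standard error sd/sqrt(n_blocks).
    """
    if n_blocks < 2:
        raise AnalysisError("n_blocks must be >= 2")
    arr = np.asarray(series, dtype=float)
    if len(arr) < n_blocks:
        raise AnalysisError(
            f"series of length {len(arr)} cannot form {n_blocks} blocks"
        )
    means = np.array([b.mean() for b in np.array_split(arr, n_blocks)])
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(n_blocks))
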