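"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators cover every input the analyses consume, so the package is
testable without any simulation output:

* :func:`synth_frame` — builder-constructed bilayer frames optionally
  modified with a water-filled cylindrical pore and/or a lateral
  composition cluster (a disc where one species is enriched by a known
  multiplier);
* :func:`synth_pressure_series` — constant-strain pressure series whose
  surface tensions realize ``gamma = K_A_true * eps + noise`` exactly, by
  inverting the tension formula for the pressure anisotropy;
* :func:`synth_fe_curves` — finite-element-style local-strain curves from
  closed-form families (linear or saturating) so threshold crossings have
  analytic inverses.

Every artifact is bit-reproducible for a fixed seed. The generators build
on the membrane builder but never call analysis code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .builder import (
    DEFAULT_AREA_PER_LIPID,
    DEFAULT_WATER_BEAD_DENSITY,
    BuildError,
    build_bilayer,
)
from .composition import MembraneComposition
from .frames import WATER_NAME, BilayerFrame
from .mechanics import BAR_NM_TO_MN_PER_M, PressureSample
from .multiscale import FECurve

__all__ = [
    "SynthFrameSpec",
    "SynthPressureSpec",
    "SynthFESpec",
    "synth_frame",
    "synth_pressure_series",
    "synth_fe_curves",
]


@dataclass(frozen=True)
class SynthFrameSpec:
    """Recipe for a structured test frame."""

    composition: MembraneComposition
    n_lipids: int = 512
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID
    thickness: float = 4.5
    box_lz: float = 12.0
    lateral_jitter: float = 0.1
    pore: Optional[Tuple[Tuple[float, float], float]] = None  # (center xy, radius)
    cluster: Optional[Tuple[str, float, float]] = None  # (species, radius, mult)
    seed: int = 0

    def __post_init__(self) -> None:
        lxy = math.sqrt(self.area_per_lipid * self.n_lipids / 2)
        if self.pore is not None and self.pore[1] >= lxy / 2:
            raise BuildError("pore radius must be below half the box edge")
        if self.cluster is not None:
            if self.cluster[2] < 1:
                raise BuildError("cluster multiplier must be >= 1")
            if self.cluster[1] >= lxy / 2:
                raise BuildError("cluster radius must be below half the box edge")


def _punch_pore(
    frame: BilayerFrame, center: Tuple[float, float], radius: float, rng
) -> BilayerFrame:
    """Remove lipids inside a lateral disc and fill the hole with water."""
    head_idx = np.flatnonzero(frame.head_mask)
    d = frame.positions[head_idx, :2] - np.asarray(center)
    d -= np.round(d / frame.box[:2]) * frame.box[:2]
    doomed = frame.molecule_id[head_idx[np.hypot(d[:, 0], d[:, 1]) <= radius]]
    keep = ~np.isin(frame.molecule_id, doomed)

    lipid_z = frame.positions[frame.lipid_mask, 2]
    zmin, zmax = lipid_z.min(), lipid_z.max()
    a = DEFAULT_WATER_BEAD_DENSITY ** (-1.0 / 3.0)
    nr = max(1, int(2 * radius // a))
    xs = center[0] + (np.arange(nr) - (nr - 1) / 2) * a
    ys = center[1] + (np.arange(nr) - (nr - 1) / 2) * a
    nz = max(1, int((zmax - zmin) // a))
    zs = zmin + (np.arange(nz) + 0.5) * ((zmax - zmin) / nz)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lateral = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    pts = pts[lateral <= max(radius - 0.2, 0.1)]
    pts += rng.uniform(-0.2 * a, 0.2 * a, size=pts.shape)
    pts = np.mod(pts, frame.box)

    next_mol = int(frame.molecule_id.max()) + 1
    leaflet = dict(frame.leaflet_label) if frame.leaflet_label else None
    if leaflet is not None:
        for mol in doomed:
            leaflet.pop(int(mol), None)
    return BilayerFrame(
        positions=np.concatenate([frame.positions[keep], pts]),
        molecule_id=np.concatenate(
            [frame.molecule_id[keep], np.arange(next_mol, next_mol + len(pts))]
        ),
        species=np.concatenate(
            [frame.species[keep], np.full(len(pts), WATER_NAME, dtype="U8")]
        ),
        role=np.concatenate(
            [frame.role[keep], np.full(len(pts), "water", dtype="U12")]
        ),
        box=frame.box.copy(),
        leaflet_label=leaflet,
        time=frame.time,
    )


def _plant_cluster(
    frame: BilayerFrame, species: str, radius: float, multiplier: float, rng
) -> BilayerFrame:
    """Reassign species inside a central disc to enrich ``species``.

    The disc is centred on the box; within it, the target species fraction
    is raised to ``multiplier`` times its bulk fraction by converting other
    lipids, per leaflet.
    """
    out = frame.copy()
    center = frame.box[:2] / 2.0
    mol_species = frame.molecule_species()
    head_idx = np.flatnonzero(frame.head_mask)
    d = frame.positions[head_idx, :2] - center
    d -= np.round(d / frame.box[:2]) * frame.box[:2]
    in_disc = np.hypot(d[:, 0], d[:, 1]) <= radius
    labels = frame.leaflet_label or {}
    for leaflet in sorted(set(labels.values())) or [None]:
        if leaflet is None:
            leaf_mols = set(mol_species)
        else:
            leaf_mols = {m for m, l in labels.items() if l == leaflet}
        bulk = [m for m in mol_species if m in leaf_mols]
        n_target_bulk = sum(1 for m in bulk if mol_species[m] == species)
        if n_target_bulk == 0:
            continue
        frac_bulk = n_target_bulk / len(bulk)
        disc_mols = [
            int(frame.molecule_id[head_idx[i]])
            for i in np.flatnonzero(in_disc)
            if int(frame.molecule_id[head_idx[i]]) in leaf_mols
        ]
        want = int(round(multiplier * frac_bulk * len(disc_mols)))
        have = sum(1 for m in disc_mols if mol_species[m] == species)
        if want > len(disc_mols):
            raise BuildError(
                f"cluster multiplier {multiplier} needs {want} lipids of "
                f"{species!r} in a disc holding only {len(disc_mols)}"
            )
        if want > have:
            candidates = [m for m in disc_mols if mol_species[m] != species]
            chosen = rng.choice(len(candidates), size=want - have, replace=False)
            for ci in chosen:
                mol = candidates[int(ci)]
                out.species[out.molecule_id == mol] = species
    return out


def synth_frame(spec: SynthFrameSpec) -> BilayerFrame:
    """Build a frame per spec; without pore/cluster it equals the builder's."""
    frame = build_bilayer(
        spec.composition,
        n_lipids=spec.n_lipids,
        area_per_lipid=spec.area_per_lipid,
        thickness=spec.thickness,
        box_lz=spec.box_lz,
        seed=spec.seed,
        lateral_jitter=spec.lateral_jitter,
    )
    rng = np.random.default_rng(spec.seed + 1)
    if spec.cluster is not None:
        frame = _plant_cluster(frame, *spec.cluster, rng)
    if spec.pore is not None:
        frame = _punch_pore(frame, spec.pore[0], spec.pore[1], rng)
    frame.validate()
    return frame


@dataclass(frozen=True)
class SynthPressureSpec:
    """Recipe for constant-strain pressure series with a known K_A."""

    k_a_true: float  # mN/m
    strains: Tuple[float, ...] = (0.01, 0.03, 0.05)
    l_z: float = 14.0  # nm
    reference_area: float = 576.0  # nm^2
    noise_sd: float = 0.0  # mN/m on the tension
    n_samples_per_strain: int = 200
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strains must be distinct")


def synth_pressure_series(
    spec: SynthPressureSpec,
) -> Dict[float, List[PressureSample]]:
    """Per-strain pressure samples realizing gamma = K_A_true*eps + noise.

    The tension is imposed exactly by setting the pressure anisotropy to
    ``gamma / (0.1 * l_z)`` with P_zz = 1 bar and P_xx = P_yy.
    """
    rng = np.random.default_rng(spec.seed)
    out: Dict[float, List[PressureSample]] = {}
    for eps in spec.strains:
        gammas = spec.k_a_true * eps + rng.normal(
            0.0, spec.noise_sd, size=spec.n_samples_per_strain
        )
        area = spec.reference_area * (1.0 + eps)
        samples = []
        for i, g in enumerate(gammas):
            aniso = g / (BAR_NM_TO_MN_PER_M * spec.l_z)  # bar
            lateral = 1.0 - aniso
            samples.append(
                PressureSample(
                    time=float(i) * 100.0,
                    p_xx=lateral,
                    p_yy=lateral,
                    p_zz=1.0,
                    l_z=spec.l_z,
                    area=area,
                    temperature=spec.temperature,
                )
            )
        out[eps] = samples
    return out


@dataclass(frozen=True)
class SynthFESpec:
    """Recipe for FE-style curves with analytic inverses.

    ``family`` is ``linear`` (local = slope * eps_axon, one slope per rate)
    or ``saturating`` (local = plateau * (1 - exp(-eps_axon/scale))).
    ``eps_y_ratio`` sets eps_y = ratio * eps_x (< 1 so max(...) = eps_x).
    """

    rates: Tuple[float, ...] = (1.0, 20.0, 40.0)
    family: str = "linear"
    slopes: Tuple[float, ...] = (3.0, 3.2, 3.5)
    plateaus: Tuple[float, ...] = ()
    scales: Tuple[float, ...] = ()
    eps_axon_max: float = 0.30
    n_grid: int = 61
    eps_y_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("linear", "saturating"):
            raise ValueError(f"unknown curve family {self.family!r}")
        if not 0 <= self.eps_y_ratio <= 1:
            raise ValueError("eps_y_ratio must be in [0, 1]")


def synth_fe_curves(spec: SynthFESpec) -> List[FECurve]:
    """Generate one curve per rate from the requested closed-form family."""
    grid = np.linspace(0.0, spec.eps_axon_max, spec.n_grid)
    curves = []
    for i, rate in enumerate(spec.rates):
        if spec.family == "linear":
            ex = spec.slopes[i] * grid
        else:
            ex = spec.plateaus[i] * (1.0 - np.exp(-grid / spec.scales[i]))
        ey = spec.eps_y_ratio * ex
        curves.append(
            FECurve(
                strain_rate=rate,
                samples=tuple(
                    (float(a), float(x), float(y)) for a, x, y in zip(grid, ex, ey)
                ),
            )
        )
    return curves
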