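"""Membrane mechanics: tension, compressibility, deformation and rupture.

Unit conventions are fixed package-wide: pressures in bar, lengths in nm,
tensions in mN/m. The lateral surface tension of a periodic bilayer follows
from the diagonal pressure-tensor anisotropy,

    gamma = lz * (Pzz - (Pxx + Pyy)/2)        [bar nm]

with 1 bar nm = 0.1 mN/m. The area compressibility modulus K_A is the slope
of an ordinary least-squares fit of gamma against areal strain
eps_A = A/A0 - 1 in the linear regime (eps_A < 0.05), each strain entering
through block means (4 blocks by default). Rupture under stretching is
detected two ways, reported side by side: a jump (sudden drop) in the
tension-strain series, and a geometric pore search on coordinate frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .frames import BilayerFrame
from .structure import slab_bounds

__all__ = [
    "BAR_NM_TO_MN_PER_M",
    "PressureSample",
    "StrainPoint",
    "CompressibilityFit",
    "DeformationSchedule",
    "Pore",
    "RuptureRecord",
    "areal_strain",
    "surface_tension",
    "fit_area_compressibility",
    "deformation_schedule",
    "detect_tension_jump",
    "detect_pores_geometric",
    "rupture_strain",
]

#: 1 bar nm in mN/m.
BAR_NM_TO_MN_PER_M = 0.1


class MechanicsError(ValueError):
    """Raised for invalid mechanical inputs."""


@dataclass(frozen=True)
class PressureSample:
    """Diagonal pressure components and box height at one time point."""

    time: float  # ps
    p_xx: float  # bar
    p_yy: float  # bar
    p_zz: float  # bar
    l_z: float  # nm
    area: float  # nm^2
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        if self.l_z <= 0 or self.area <= 0:
            raise MechanicsError("l_z and area must be positive")


@dataclass(frozen=True)
class StrainPoint:
    """Block-averaged surface tensions at one constant areal strain."""

    areal_strain: float
    reference_area: float  # nm^2
    gamma_blocks: Tuple[float, ...]  # mN/m

    def __post_init__(self) -> None:
        if len(self.gamma_blocks) < 1:
            raise MechanicsError("need at least one tension block mean")

    @staticmethod
    def from_samples(
        samples: Sequence["PressureSample"],
        reference_area: float,
        n_blocks: int = 4,
    ) -> "StrainPoint":
        """Block-average the tensions of a constant-strain series."""
        gammas = np.array([surface_tension(s) for s in samples])
        if len(gammas) < n_blocks:
            raise MechanicsError("series shorter than the block count")
        blocks = tuple(float(b.mean()) for b in np.array_split(gammas, n_blocks))
        area = float(np.mean([s.area for s in samples]))
        return StrainPoint(
            areal_strain=areal_strain(area, reference_area),
            reference_area=reference_area,
            gamma_blocks=blocks,
        )


@dataclass(frozen=True)
class CompressibilityFit:
    """Area compressibility modulus from the tension-strain regression."""

    k_a: float  # mN/m
    standard_error: float  # mN/m (nan when < 3 points)
    intercept: float  # mN/m
    n_points: int


def areal_strain(area: float, reference_area: float) -> float:
    """eps_A = A/A0 - 1."""
    if reference_area <= 0:
        raise MechanicsError("reference area must be > 0")
    return area / reference_area - 1.0


def surface_tension(sample: PressureSample) -> float:
    """Lateral tension in mN/m from one pressure sample."""
    aniso = sample.p_zz - 0.5 * (sample.p_xx + sample.p_yy)
    return sample.l_z * aniso * BAR_NM_TO_MN_PER_M


def fit_area_compressibility(
    points: Sequence[StrainPoint], n_blocks: int = 4
) -> CompressibilityFit:
    """OLS fit of tension on areal strain over all (block, strain) pairs.

    ``n_blocks`` documents the expected block count; points may carry any
    number >= 1 of block means. Strains at or above 0.05 are outside the
    linear regime and trigger a warning.
    """
    points = list(points)
    strains = sorted({p.areal_strain for p in points})
    if len(strains) < 2:
        raise MechanicsError("need at least 2 distinct areal strains")
    if any(p.areal_strain > 0.05 + 1e-12 for p in points):
        warnings.warn(
            "areal strain above 0.05: outside the linear tension regime",
            stacklevel=2,
        )
    xs, ys = [], []
    for p in points:
        for g in p.gamma_blocks:
            xs.append(p.areal_strain)
            ys.append(g)
    xs, ys = np.array(xs), np.array(ys)
    res = stats.linregress(xs, ys)
    se = float(res.stderr) if len(xs) > 2 else float("nan")
    return CompressibilityFit(
        k_a=float(res.slope),
        standard_error=se,
        intercept=float(res.intercept),
        n_points=len(xs),
    )


@dataclass(frozen=True)
class DeformationSchedule:
    """Piecewise-linear uniaxial (x) deformation protocol.

    A fast pre-deformation at ``pre_speed`` runs up to ``pre_strain``
    engineering strain, followed by the production phase at ``speed``.
    """

    length_0: float  # nm, undeformed box edge along x
    speed: float  # nm/ps, production deformation speed
    pre_strain: float = 0.0
    pre_speed: Optional[float] = None  # nm/ps
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.length_0 <= 0 or self.speed <= 0:
            raise MechanicsError("length and speed must be positive")
        if self.pre_strain < 0:
            raise MechanicsError("pre_strain must be >= 0")
        if self.pre_strain > 0 and (self.pre_speed is None or self.pre_speed <= 0):
            raise MechanicsError("pre_speed must be positive when pre_strain > 0")

    @property
    def _t_pre(self) -> float:
        if self.pre_strain == 0:
            return 0.0
        return self.pre_strain * self.length_0 / self.pre_speed

    def strain_at(self, t: float) -> float:
        """Engineering strain along x at time t (ps)."""
        if t < 0:
            raise MechanicsError("time must be >= 0")
        if t <= self._t_pre:
            return (self.pre_speed or 0.0) * t / self.length_0
        return self.pre_strain + self.speed * (t - self._t_pre) / self.length_0

    def time_to_strain(self, target: float) -> float:
        """Time (ps) at which ``target`` strain is reached."""
        if target < 0:
            raise MechanicsError("target strain must be >= 0")
        if target <= self.pre_strain:
            return target * self.length_0 / (self.pre_speed or self.speed)
        return self._t_pre + (target - self.pre_strain) * self.length_0 / self.speed


def deformation_schedule(
    length_0: float,
    speed: float,
    pre_strain: float = 0.0,
    pre_speed: Optional[float] = None,
) -> DeformationSchedule:
    """Build the uniaxial stretching schedule for one production rate.

    The shipped protocol pre-deforms fast (default 1e-5 nm/ps) to 30%
    strain, then continues at the slower production ``speed``.
    """
    return DeformationSchedule(
        length_0=length_0,
        speed=speed,
        pre_strain=pre_strain,
        pre_speed=pre_speed,
    )


def detect_tension_jump(
    series: Sequence[Tuple[float, float]],
    window: int = 11,
    k: float = 5.0,
) -> Optional[float]:
    """First strain at which the tension drops anomalously (pore formation).

    Scans the (strain, gamma) series in order of strain and reports the
    first point whose tension falls more than ``k`` trailing-window standard
    deviations below the trailing-window median; pore formation relaxes the
    lateral tension, so a rupture appears as a sharp downward step. Returns
    None when no such point exists.
    """
    series = list(series)
    if len(series) <= 2 * window:
        raise MechanicsError(f"series must be longer than 2*window={2 * window}")
    strains = np.array([s for s, _ in series], dtype=float)
    gammas = np.array([g for _, g in series], dtype=float)
    if np.any(np.diff(strains) < 0):
        raise MechanicsError("series must be sorted by non-decreasing strain")
    for i in range(window, len(series)):
        w = gammas[i - window : i]
        med = np.median(w)
        sd = max(float(w.std(ddof=1)), 1e-12)
        if gammas[i] < med - k * sd:
            return float(strains[i])
    return None


@dataclass(frozen=True)
class Pore:
    """A transmembrane pore found on the lateral occupancy grid."""

    center: Tuple[float, float]  # nm
    radius: float  # nm, effective (area-equivalent, erosion-corrected)
    area: float  # nm^2 of empty grid cells
    n_water_in_slab: int
    water_confirmed: bool


@dataclass(frozen=True)
class RuptureRecord:
    """Outcome of one stretching run at one deformation rate."""

    deformation_rate: float  # nm/ps
    rupture_strain: Optional[float]
    detection: str = "tension_jump"  # or "geometric"
    pores: Tuple[Pore, ...] = ()

    def __post_init__(self) -> None:
        if self.rupture_strain is not None and self.rupture_strain < 0:
            raise MechanicsError("rupture strain must be >= 0")
        if self.detection == "geometric" and self.rupture_strain is not None:
            if not self.pores:
                raise MechanicsError(
                    "geometric detection requires at least one pore"
                )


def _periodic_components(empty: np.ndarray) -> List[np.ndarray]:
    """Connected components of a boolean grid under periodic 4-connectivity.

    Returns one (cells, 2) integer index array per component.
    """
    labels, n = ndimage.label(empty)
    if n == 0:
        return []
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(int(a), int(b))
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(int(a), int(b))
    groups: Dict[int, List] = {}
    idx = np.argwhere(labels > 0)
    for ij in idx:
        root = find(int(labels[ij[0], ij[1]]))
        groups.setdefault(root, []).append(ij)
    return [np.array(g) for g in groups.values()]


def _periodic_centroid(coords: np.ndarray, n_cells: int, edge: float) -> float:
    """Circular mean of cell-centre coordinates along one axis."""
    theta = (coords + 0.5) / n_cells * 2 * math.pi
    mean = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    return (mean / (2 * math.pi)) % 1.0 * edge


def detect_pores_geometric(
    frame: BilayerFrame,
    grid_spacing: float = 0.5,
    min_pore_area: float = 1.0,
    occupancy_radius: float = 0.55,
    slab_fraction: float = 0.4,
) -> List[Pore]:
    """Find transmembrane pores on a lateral occupancy grid.

    Lipid tail beads inside the hydrophobic slab (|z - midplane| below
    ``slab_fraction`` of the measured head-to-head thickness) mark grid
    cells occupied when the cell centre lies within ``occupancy_radius`` of
    a bead in periodic xy. Connected empty components (periodic
    4-connectivity) with at least ``min_pore_area`` of empty area are
    reported as pores; the effective radius sqrt(area/pi) is corrected for
    the ``occupancy_radius`` erosion of the void. Water beads found inside
    the slab within a component confirm it as water-filled.
    """
    lx, ly, lz = frame.box
    if grid_spacing > min(lx, ly) / 4:
        raise MechanicsError("grid spacing coarser than a quarter of the box")
    z_lo, z_up = slab_bounds(frame)
    mid = 0.5 * (z_up + z_lo)
    half = slab_fraction * (z_up - z_lo)

    tails = np.isin(frame.role, ("first_tail", "tail"))
    in_slab = np.abs(frame.positions[:, 2] - mid) < half
    bead_xy = np.mod(frame.positions[tails & in_slab, :2], (lx, ly))
    nx = max(4, int(round(lx / grid_spacing)))
    ny = max(4, int(round(ly / grid_spacing)))
    cx = (np.arange(nx) + 0.5) * (lx / nx)
    cy = (np.arange(ny) + 0.5) * (ly / ny)
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    if len(bead_xy) == 0:
        dist = np.full(len(centres), np.inf)
    else:
        tree = cKDTree(bead_xy, boxsize=(lx, ly))
        dist, _ = tree.query(centres, k=1)
    empty = (dist > occupancy_radius).reshape(nx, ny)

    cell_area = (lx / nx) * (ly / ny)
    water_xy = np.mod(
        frame.positions[frame.water_mask & in_slab, :2], (lx, ly)
    )
    pores: List[Pore] = []
    for comp in _periodic_components(empty):
        area = len(comp) * cell_area
        if area < min_pore_area:
            continue
        cx0 = _periodic_centroid(comp[:, 0].astype(float), nx, lx)
        cy0 = _periodic_centroid(comp[:, 1].astype(float), ny, ly)
        radius = math.sqrt(area / math.pi) + occupancy_radius
        n_water = 0
        if len(water_xy):
            wi = np.floor(water_xy[:, 0] / (lx / nx)).astype(int) % nx
            wj = np.floor(water_xy[:, 1] / (ly / ny)).astype(int) % ny
            cells = set(map(tuple, comp.tolist()))
            n_water = sum((int(i), int(j)) in cells for i, j in zip(wi, wj))
        pores.append(
            Pore(
                center=(cx0, cy0),
                radius=radius,
                area=area,
                n_water_in_slab=n_water,
                water_confirmed=n_water > 0,
            )
        )
    pores.sort(key=lambda p: -p.area)
    return pores


def rupture_strain(
    runs: Sequence[RuptureRecord],
) -> Dict[float, Optional[float]]:
    """Lowest observed rupture strain per deformation rate.

    Runs without a detected rupture are ignored; a rate whose runs all lack
    one maps to None.
    """
    runs = list(runs)
    if not runs:
        raise MechanicsError("no rupture records given")
    out: Dict[float, Optional[float]] = {}
    for r in runs:
        cur = out.get(r.deformation_rate)
        if r.rupture_strain is None:
            out.setdefault(r.deformation_rate, None)
        elif cur is None:
            out[r.deformation_rate] = r.rupture_strain
        else:
            out[r.deformation_rate] = min(cur, r.rupture_strain)
    return out
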