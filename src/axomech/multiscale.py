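"""Mapping bilayer rupture strains to axonal deformation thresholds.

Finite-element simulations of a stretched axon yield, per axonal strain
rate, the in-plane principal strains (eps_x, eps_y) of the cortex as a
function of the applied axonal strain. Given the bilayer strain at which a
membrane model ruptures, this module inverts those curves: per rate it
finds the smallest axonal strain whose local (cortex-level) strain first
reaches the rupture strain, and summarizes the rates as an interval that
can be compared against an axonal injury threshold.

The scalar local strain is ``max(eps_x, eps_y)`` by default; an areal form
``(1 + eps_x)(1 + eps_y) - 1`` is available because bilayer rupture is
driven by area growth. Curves may be non-monotone in local strain (the
cortex is viscoelastic, so higher rates need not give higher local
strains); the first crossing is used, which is the conservative, earliest
rupture choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FECurve",
    "RuptureMapping",
    "local_strain",
    "axonal_strain_at_rupture",
]


class MultiscaleError(ValueError):
    """Raised for invalid curves or queries."""


@dataclass(frozen=True)
class FECurve:
    """Cortex principal strains vs axonal strain at one strain rate.

    ``samples`` rows are (axonal strain, eps_x, eps_y) with strictly
    increasing axonal strain; ``strain_rate`` is in 1/s.
    """

    strain_rate: float
    samples: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.strain_rate <= 0:
            raise MultiscaleError("strain rate must be > 0")
        if len(self.samples) < 2:
            raise MultiscaleError("a curve needs at least 2 samples")
        ax = [s[0] for s in self.samples]
        if any(b <= a for a, b in zip(ax, ax[1:])):
            raise MultiscaleError("axonal strain must be strictly increasing")

    def axonal(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    def local(self, mode: str = "max") -> np.ndarray:
        return np.array([local_strain(s, mode) for s in self.samples])


def local_strain(sample: Sequence[float], mode: str = "max") -> float:
    """Scalarize a (eps_axon, eps_x, eps_y) sample's principal strains.

    ``max`` returns max(eps_x, eps_y); ``areal`` returns
    (1 + eps_x)(1 + eps_y) - 1, the relative area change of the element.
    """
    _, ex, ey = sample
    if mode == "max":
        return float(max(ex, ey))
    if mode == "areal":
        return float((1.0 + ex) * (1.0 + ey) - 1.0)
    raise MultiscaleError(f"unknown local-strain mode {mode!r}")


@dataclass(frozen=True)
class RuptureMapping:
    """Axonal strains at which a given bilayer rupture strain is reached."""

    rupture_strain: float
    per_rate_axonal_strain: Dict[float, Optional[float]]
    axonal_interval: Optional[Tuple[float, float]]
    injury_threshold: Optional[float]
    verdict: str


def _first_crossing(
    axonal: np.ndarray, local: np.ndarray, target: float
) -> Optional[float]:
    """Smallest axonal strain at which the local strain reaches ``target``.

    Linear interpolation between samples; first crossing if the local curve
    is non-monotone; None when the target is never reached.
    """
    if local[0] >= target:
        return float(axonal[0])
    for i in range(1, len(local)):
        if local[i] >= target:
            lo, hi = local[i - 1], local[i]
            if hi == lo:
                return float(axonal[i])
            f = (target - lo) / (hi - lo)
            return float(axonal[i - 1] + f * (axonal[i] - axonal[i - 1]))
    return None


def axonal_strain_at_rupture(
    curves: Sequence[FECurve],
    rupture_strain: float,
    injury_threshold: Optional[float] = None,
    mode: str = "max",
) -> RuptureMapping:
    """Invert FE local-strain curves at a bilayer rupture strain.

    Per strain rate, the first axonal strain whose local strain reaches
    ``rupture_strain``; the interval over rates with a defined crossing; and
    a verdict comparing the interval to ``injury_threshold`` when given.
    """
    curves = list(curves)
    if not curves:
        raise MultiscaleError("no FE curves given")
    if rupture_strain < 0:
        raise MultiscaleError("rupture strain must be >= 0")
    per_rate: Dict[float, Optional[float]] = {}
    for c in curves:
        per_rate[c.strain_rate] = _first_crossing(
            c.axonal(), c.local(mode), rupture_strain
        )
    defined = [v for v in per_rate.values() if v is not None]
    interval = (min(defined), max(defined)) if defined else None
    if interval is None:
        verdict = "no rupture within simulated range"
    elif injury_threshold is None:
        verdict = "no injury threshold configured"
    elif interval[1] < injury_threshold:
        verdict = "rupture below injury threshold"
    elif interval[0] > injury_threshold:
        verdict = "no rupture at injury threshold"
    else:
        verdict = "injury threshold inside rupture interval"
    return RuptureMapping(
        rupture_strain=rupture_strain,
        per_rate_axonal_strain=per_rate,
        axonal_interval=interval,
        injury_threshold=injury_threshold,
        verdict=verdict,
    )
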