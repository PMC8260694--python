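"""Independent brute-force oracles for geometric analyses.

These are deliberately naive O(n^2) implementations used only to check the
library's tree-based analyses on small frames; they share no code with the
implementation paths they verify.
"""

from __future__ import annotations

import numpy as np


def periodic_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a (broadcasting)."""
    d = b - a
    return d - np.round(d / box) * box


def brute_thickness(frame, registry) -> float:
    """Vertical-neighbour thickness by exhaustive nearest-in-xy search."""
    from axomech.structure import assign_leaflets

    leaflets = assign_leaflets(frame)
    idx = [
        i
        for i in np.flatnonzero(frame.role == "head")
        if registry.get(str(frame.species[i])) is not None
        and registry[str(frame.species[i])].has_phosphate
    ]
    idx = np.array(idx)
    side = np.array([leaflets[int(m)] for m in frame.molecule_id[idx]])
    pos = frame.positions[idx]
    box = frame.box
    vals = []
    for a, b in (("upper", "lower"), ("lower", "upper")):
        ia, ib = np.flatnonzero(side == a), np.flatnonzero(side == b)
        for i in ia:
            d = periodic_delta(pos[i, :2], pos[ib, :2], box[:2])
            j = ib[int(np.argmin(np.hypot(d[:, 0], d[:, 1])))]
            dz = abs(pos[i, 2] - pos[j, 2])
            vals.append(min(dz, box[2] - dz))
    return float(np.mean(vals))


def brute_contact_count(pos_a, pos_b, box, radius, exclude_same_index=False):
    """Counts of ``pos_b`` points within radius of each ``pos_a`` point."""
    out = []
    for i, p in enumerate(pos_a):
        d = periodic_delta(p, pos_b, box)
        r = np.sqrt((d**2).sum(axis=1))
        n = int((r <= radius).sum())
        if exclude_same_index:
            n -= int(r[i] <= radius) if i < len(pos_b) else 0
        out.append(n)
    return np.array(out)


def brute_shell_ratio(frame, registry, reference_class, shell_radius, leaflet):
    """Shell class composition around every reference-class lipid.

    Returns (ratio_x, ratio_bulk) dicts over lipid classes, mirroring the
    enrichment definition by independent exhaustive counting.
    """
    from axomech.structure import _reference_beads, assign_leaflets

    ref_idx = _reference_beads(frame, registry)
    leaflets = assign_leaflets(frame)
    mols = frame.molecule_id[ref_idx]
    keep = np.array([leaflets[int(m)] == leaflet for m in mols])
    idx = ref_idx[keep]
    mols = mols[keep]
    classes = np.array(
        [
            registry[str(frame.species[i])].lipid_class
            if str(frame.species[i]) in registry
            else "OTHER"
            for i in idx
        ]
    )
    pos = np.mod(frame.positions[idx], frame.box)
    shell: dict = {}
    total = 0
    for c in np.flatnonzero(classes == reference_class):
        d = periodic_delta(pos[c], pos, frame.box)
        r = np.sqrt((d**2).sum(axis=1))
        for j in np.flatnonzero(r <= shell_radius):
            if mols[j] == mols[c]:
                continue
            shell[classes[j]] = shell.get(classes[j], 0) + 1
            total += 1
    names, counts = np.unique(classes, return_counts=True)
    bulk = {str(n): c / len(classes) for n, c in zip(names, counts)}
    ratio_x = {k: shell.get(k, 0) / total for k in bulk} if total else {}
    return ratio_x, bulk
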