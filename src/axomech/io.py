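"""Reading and writing coordinate frames and tabular series.

Coordinate frames go through MDAnalysis: GRO (nm, fixed column; multi-frame
files are accepted as concatenated blocks) and PDB (Å, converted to nm on
read). Bead roles are recovered from atom names via the species registry —
the head bead label and first-tail bead label identify those roles, any
other atom of a known lipid is a tail bead. Unknown residue names load with
a heuristic role assignment and are reported once per file.

Tabular series (pressure/box time series, FE strain curves, results) are
plain text with a header; the delimiter is auto-detected among tab, comma
and whitespace, and ``#`` lines are comments.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .composition import LipidSpecies, default_registry
from .frames import BilayerFrame
from .mechanics import PressureSample
from .multiscale import FECurve

__all__ = [
    "read_frames",
    "write_frames",
    "read_table",
    "read_pressure_samples",
    "write_pressure_samples",
    "read_fe_curves",
    "write_fe_curves",
]

logger = logging.getLogger("axomech")


class IOFormatError(ValueError):
    """Raised for malformed or unsupported files."""


_TAIL_NAMES = ("C1A", "C2A", "C3A", "C4A")
_NONLIPID = {"W": "water", "NA": "ion", "CL": "ion", "PROT": "protein"}


def _atom_name(
    species: str, role: str, tail_counter: int, registry: Mapping[str, LipidSpecies]
) -> str:
    if species in _NONLIPID:
        return {"W": "W", "NA": "NA", "CL": "CL", "PROT": "BB"}[species]
    sp = registry.get(species)
    if role == "head":
        return sp.head_bead_label if sp else "HD"
    if role == "first_tail":
        return sp.first_tail_bead_label if sp else "FT"
    return _TAIL_NAMES[tail_counter % len(_TAIL_NAMES)]


def _to_universe(frame: BilayerFrame, registry: Mapping[str, LipidSpecies]):
    import MDAnalysis as mda

    n = frame.n_beads
    # one residue per molecule, in bead order
    mol = frame.molecule_id
    boundaries = np.flatnonzero(np.diff(mol) != 0)
    resindex = np.zeros(n, dtype=int)
    resindex[boundaries + 1] = 1
    resindex = np.cumsum(resindex)
    n_res = resindex[-1] + 1 if n else 0
    first_of_res = np.concatenate([[0], boundaries + 1])
    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
        velocities=True,
    )
    names = []
    tail_counter = 0
    prev_mol = None
    for i in range(n):
        if frame.molecule_id[i] != prev_mol:
            tail_counter = 0
            prev_mol = frame.molecule_id[i]
        role = str(frame.role[i])
        names.append(
            _atom_name(str(frame.species[i]), role, tail_counter, registry)
        )
        if role in ("tail", "other", "protein"):
            tail_counter += 1
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", frame.species[first_of_res])
    u.add_TopologyAttr("resids", frame.molecule_id[first_of_res] % 100000)
    u.atoms.positions = frame.positions * 10.0  # nm -> A
    u.atoms.velocities = np.zeros((n, 3))
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    return u


def write_frames(
    frames: Sequence[BilayerFrame] | BilayerFrame,
    path,
    registry: Optional[Mapping[str, LipidSpecies]] = None,
) -> None:
    """Write one or more frames to a GRO or PDB file (suffix decides).

    Multi-frame GRO output is a concatenation of single-frame blocks;
    multi-frame PDB uses MODEL records.
    """
    if isinstance(frames, BilayerFrame):
        frames = [frames]
    if registry is None:
        registry = default_registry()
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("gro", "pdb"):
        raise IOFormatError(f"unsupported coordinate format {fmt!r}")
    import MDAnalysis as mda

    if fmt == "gro":
        with open(path, "w") as out:
            for frame in frames:
                u = _to_universe(frame, registry)
                buf = _io.StringIO()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    with mda.coordinates.GRO.GROWriter(
                        mda.lib.util.NamedStream(buf, "block.gro"), n_atoms=len(u.atoms)
                    ) as w:
                        w.write(u.atoms)
                out.write(buf.getvalue())
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.coordinates.PDB.PDBWriter(
                str(path), multiframe=len(frames) > 1
            ) as w:
                for frame in frames:
                    u = _to_universe(frame, registry)
                    w.write(u.atoms)


def _split_gro_blocks(text: str) -> List[str]:
    lines = text.splitlines()
    blocks = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise IOFormatError(
                f"malformed GRO atom-count record at line {i + 2}"
            ) from None
        end = i + 2 + n + 1
        if end > len(lines):
            raise IOFormatError(
                f"GRO block starting at line {i + 1} is truncated"
            )
        blocks.append("\n".join(lines[i:end]) + "\n")
        i = end
    return blocks


def _frame_from_universe(
    u, scale: float, registry: Mapping[str, LipidSpecies], unknown: set
) -> BilayerFrame:
    atoms = u.atoms
    pos = atoms.positions * scale  # nm
    resnames = atoms.resnames
    names = atoms.names
    resids = atoms.resids
    resindices = atoms.resindices
    # fresh molecule ids from residue boundaries (GRO resids wrap at 100000)
    mol_ids = resindices + 1
    roles = np.empty(len(atoms), dtype="U12")
    species = np.array([str(r) for r in resnames], dtype="U8")
    pos_in_mol = np.zeros(len(atoms), dtype=int)
    _, first_idx, counts = np.unique(
        resindices, return_index=True, return_counts=True
    )
    for start, cnt in zip(first_idx, counts):
        pos_in_mol[start : start + cnt] = np.arange(cnt)
    for i in range(len(atoms)):
        rn = str(resnames[i])
        if rn in _NONLIPID:
            roles[i] = _NONLIPID[rn]
            continue
        sp = registry.get(rn)
        if sp is None:
            unknown.add(rn)
            roles[i] = ("head", "first_tail")[pos_in_mol[i]] if pos_in_mol[
                i
            ] < 2 else "tail"
            continue
        nm = str(names[i])
        if nm == sp.head_bead_label:
            roles[i] = "head"
        elif nm == sp.first_tail_bead_label:
            roles[i] = "first_tail"
        else:
            roles[i] = "tail"
    box = u.dimensions[:3] * scale
    return BilayerFrame(
        positions=pos.astype(float),
        molecule_id=mol_ids,
        species=species,
        role=roles,
        box=np.asarray(box, dtype=float),
    )


def read_frames(
    path, registry: Optional[Mapping[str, LipidSpecies]] = None
) -> List[BilayerFrame]:
    """Read GRO (nm) or PDB (Å -> nm) coordinate frames.

    Unknown residue names are collected and reported once via a warning;
    their beads load with species kept and heuristic roles.
    """
    import MDAnalysis as mda

    if registry is None:
        registry = default_registry()
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    text_empty = path.stat().st_size == 0
    if text_empty:
        raise IOFormatError(f"empty coordinate file: {path}")
    fmt = path.suffix.lower().lstrip(".")
    unknown: set = set()
    frames: List[BilayerFrame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "gro":
            blocks = _split_gro_blocks(path.read_text())
            for block in blocks:
                u = mda.Universe(
                    mda.lib.util.NamedStream(_io.StringIO(block), "block.gro")
                )
                frames.append(_frame_from_universe(u, 0.1, registry, unknown))
        elif fmt == "pdb":
            u = mda.Universe(str(path))
            for _ in u.trajectory:
                frames.append(_frame_from_universe(u, 0.1, registry, unknown))
        else:
            raise IOFormatError(f"unsupported coordinate format {fmt!r}")
    if unknown:
        msg = (
            f"{path.name}: unregistered residue names {sorted(unknown)} "
            "loaded with heuristic roles (treated as class OTHER downstream)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not frames:
        raise IOFormatError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------- tables


def read_table(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a delimited text table with a header.

    Column matching is case- and order-insensitive; ``#`` lines are
    comments; the delimiter is auto-detected among tab, comma and
    whitespace. Missing columns and non-numeric cells raise errors naming
    the column or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        raise IOFormatError(f"empty table: {path}") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c.lower() not in df.columns]
    if missing:
        raise IOFormatError(f"missing column {missing[0]}")
    out = df[[c.lower() for c in required]].copy()
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise IOFormatError(
                f"non-numeric value in column {col!r} at data row {row + 1}"
            )
        out[col] = coerced
    out.columns = list(required)
    return out


_PRESSURE_COLUMNS = ("time", "pxx", "pyy", "pzz", "lz", "area")


def read_pressure_samples(path) -> List[PressureSample]:
    """Read a pressure/box time series (columns time, Pxx, Pyy, Pzz, lz, A)."""
    df = read_table(path, _PRESSURE_COLUMNS)
    return [
        PressureSample(
            time=r.time, p_xx=r.pxx, p_yy=r.pyy, p_zz=r.pzz, l_z=r.lz, area=r.area
        )
        for r in df.itertuples(index=False)
    ]


def write_pressure_samples(samples: Sequence[PressureSample], path) -> None:
    pd.DataFrame(
        {
            "time": [s.time for s in samples],
            "pxx": [s.p_xx for s in samples],
            "pyy": [s.p_yy for s in samples],
            "pzz": [s.p_zz for s in samples],
            "lz": [s.l_z for s in samples],
            "area": [s.area for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


_CURVE_COLUMNS = ("rate", "eps_axon", "eps_x", "eps_y")


def read_fe_curves(path) -> List[FECurve]:
    """Read FE local-strain curves; one file may hold several rates."""
    df = read_table(path, _CURVE_COLUMNS)
    curves = []
    for rate, grp in df.groupby("rate", sort=True):
        grp = grp.sort_values("eps_axon")
        curves.append(
            FECurve(
                strain_rate=float(rate),
                samples=tuple(
                    (float(r.eps_axon), float(r.eps_x), float(r.eps_y))
                    for r in grp.itertuples(index=False)
                ),
            )
        )
    return curves


def write_fe_curves(curves: Sequence[FECurve], path) -> None:
    rows = []
    for c in curves:
        for a, x, y in c.samples:
            rows.append(
                {"rate": c.strain_rate, "eps_axon": a, "eps_x": x, "eps_y": y}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
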