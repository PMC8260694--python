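"""Run configuration and the staged pipeline.

A run is configured by a YAML mapping (all keys optional except
``output_dir``) and executes an ordered subset of the stages

    build -> synth -> analyze -> mech -> map

Stage dependencies are checked before anything runs: ``analyze`` needs a
frame source (a ``build``/``synth`` stage in the same run, or a configured
``analyze.frames`` path), ``mech`` needs pressure series, ``map`` needs FE
curves and a rupture strain. Every output file is listed in a manifest
(JSON) with its SHA-256 hash, the seeds and the parameters, so identical
configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import builder, io as aio, mechanics, multiscale, structure, synthetic
from .composition import (
    CompositionError,
    MembraneComposition,
    default_registry,
    get_preset,
    load_registry_tsv,
    normalize_composition,
)

__all__ = ["RunConfig", "run_pipeline", "load_composition", "PipelineError"]

logger = logging.getLogger("axomech")

STAGE_ORDER = ("build", "synth", "analyze", "mech", "map")


class PipelineError(RuntimeError):
    """Raised for unsatisfiable stage dependencies or stage failures."""


def load_composition(source) -> MembraneComposition:
    """Load a composition from a preset name or a YAML file.

    YAML files carry ``extracellular:`` and ``cytoplasmic:`` blocks mapping
    species names to mole percentages (auto-normalized).
    """
    if isinstance(source, MembraneComposition):
        return source
    if source in ("myelin", "node"):
        return get_preset(source)
    path = Path(source)
    if not path.exists():
        raise CompositionError(
            f"composition {source!r} is neither a preset nor an existing file"
        )
    data = yaml.safe_load(path.read_text())
    for key in ("extracellular", "cytoplasmic"):
        if key not in data:
            raise CompositionError(f"composition file missing block {key!r}")
    return MembraneComposition(
        extracellular=normalize_composition(data["extracellular"]),
        cytoplasmic=normalize_composition(data["cytoplasmic"]),
        label=str(data.get("label", path.stem)),
    )


@dataclass
class RunConfig:
    """Validated run configuration."""

    output_dir: Path
    seed: int = 0
    composition: str = "myelin"
    registry_path: Optional[Path] = None
    params: Dict = field(default_factory=dict)
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(data, base=Path(path).parent)

    @staticmethod
    def from_dict(data: Dict, base: Path = Path(".")) -> "RunConfig":
        out = data.get("output_dir", "axomech_out")
        registry = data.get("registry")
        if registry is not None:
            registry = Path(registry)
            if not registry.exists():
                raise PipelineError(f"registry path does not exist: {registry}")
        cfg = RunConfig(
            output_dir=Path(out),
            seed=int(data.get("seed", 0)),
            composition=data.get("composition", "myelin"),
            registry_path=registry,
            params={
                k: v
                for k, v in data.items()
                if k in ("build", "synth", "analyze", "mech", "map")
            },
            log_level=str(data.get("log_level", "INFO")),
        )
        return cfg

    def registry(self):
        if self.registry_path is not None:
            return load_registry_tsv(self.registry_path)
        return default_registry()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_dependencies(config: RunConfig, stages: Sequence[str]) -> None:
    stages = set(stages)
    p = config.params
    if "analyze" in stages:
        has_source = bool(stages & {"build", "synth"}) or p.get("analyze", {}).get(
            "frames"
        )
        if not has_source:
            raise PipelineError(
                "analyze needs frames from a build/synth stage or "
                "an analyze.frames path"
            )
    if "mech" in stages:
        if "synth" not in stages and not p.get("mech", {}).get("pressure_glob"):
            raise PipelineError(
                "mech needs pressure series from a synth stage or a "
                "mech.pressure_glob pattern"
            )
    if "map" in stages:
        if "synth" not in stages and not p.get("map", {}).get("curves"):
            raise PipelineError(
                "map needs FE curves from a synth stage or a map.curves path"
            )


def run_pipeline(config: RunConfig, stages: Sequence[str]) -> Dict:
    """Execute the requested stages in canonical order; return the manifest.

    Raises :class:`PipelineError` before any stage runs if a dependency is
    unsatisfiable. All outputs land inside ``config.output_dir``.
    """
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    _check_dependencies(config, stages)
    ordered = [s for s in STAGE_ORDER if s in set(stages)]
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = config.registry()
    comp = load_composition(config.composition)
    outputs: List[Path] = []

    for stage in ordered:
        logger.info("stage %s", stage)
        p = config.params.get(stage, {}) or {}
        if stage == "build":
            frame = builder.build_bilayer(
                comp,
                n_lipids=int(p.get("n_lipids", 512)),
                area_per_lipid=float(
                    p.get("area_per_lipid", builder.DEFAULT_AREA_PER_LIPID)
                ),
                thickness=float(p.get("thickness", 4.5)),
                box_lz=float(p.get("box_lz", 12.0)),
                seed=config.seed,
                registry=registry,
            )
            if int(p.get("tile_nx", 1)) > 1 or int(p.get("tile_ny", 1)) > 1:
                frame = builder.tile_bilayer(
                    frame, int(p.get("tile_nx", 1)), int(p.get("tile_ny", 1))
                )
            dest = outdir / "frames.gro"
            aio.write_frames(frame, dest, registry)
            outputs.append(dest)
        elif stage == "synth":
            fspec = synthetic.SynthFrameSpec(
                composition=comp,
                n_lipids=int(p.get("n_lipids", 512)),
                pore=tuple(p["pore"]) if p.get("pore") else None,
                cluster=tuple(p["cluster"]) if p.get("cluster") else None,
                seed=config.seed,
            )
            dest = outdir / "frames.gro"
            aio.write_frames(synthetic.synth_frame(fspec), dest, registry)
            outputs.append(dest)
            pspec = synthetic.SynthPressureSpec(
                k_a_true=float(p.get("k_a_true", 339.0)),
                strains=tuple(p.get("strains", (0.01, 0.03, 0.05))),
                noise_sd=float(p.get("noise_sd", 2.0)),
                seed=config.seed,
            )
            for eps, samples in synthetic.synth_pressure_series(pspec).items():
                dest = outdir / f"pressure_strain_{eps:.4f}.tsv"
                aio.write_pressure_samples(samples, dest)
                outputs.append(dest)
            curves = synthetic.synth_fe_curves(
                synthetic.SynthFESpec(
                    rates=tuple(p.get("rates", (1.0, 20.0, 40.0))),
                    slopes=tuple(p.get("slopes", (3.0, 3.2, 3.5))),
                )
            )
            dest = outdir / "fe_curves.tsv"
            aio.write_fe_curves(curves, dest)
            outputs.append(dest)
        elif stage == "analyze":
            src = Path(p.get("frames", outdir / "frames.gro"))
            frames = aio.read_frames(src, registry)
            rows = []
            thick = [
                structure.thickness_voronoi(f, registry).mean_thickness
                for f in frames
            ]
            if len(thick) >= 2:
                val, se = structure.block_error(
                    thick, n_blocks=min(5, len(thick))
                )
            else:
                res = structure.thickness_voronoi(frames[0], registry)
                val, se = res.mean_thickness, res.standard_error
            rows.append(("thickness_nm", val, se, len(frames)))
            part = structure.water_partition(
                frames, protein_volume=float(p.get("protein_volume", 0.0))
            )
            rows.append(("log_k_mem_wat", part.log_k, float("nan"), len(frames)))
            ref = p.get("enrichment_reference")
            if ref:
                enr = structure.enrichment_factor(
                    frames[0],
                    ref,
                    shell_radius=float(p.get("shell_radius", 1.5)),
                    per_leaflet=False,
                    registry=registry,
                )
                for cls, v in sorted(enr.enrichment.items()):
                    rows.append(
                        (f"enrichment_{ref}_{cls}", v, float("nan"), 1)
                    )
            dest = outdir / "analysis.tsv"
            pd.DataFrame(
                rows, columns=["quantity", "value", "se", "n_frames"]
            ).to_csv(dest, sep="\t", index=False)
            outputs.append(dest)
        elif stage == "mech":
            pattern = p.get("pressure_glob", "pressure_strain_*.tsv")
            files = sorted(outdir.glob(pattern)) or sorted(
                Path(".").glob(pattern)
            )
            if not files:
                raise PipelineError(f"no pressure series match {pattern!r}")
            a0 = float(p.get("reference_area", 576.0))
            points = [
                mechanics.StrainPoint.from_samples(
                    aio.read_pressure_samples(f),
                    reference_area=a0,
                    n_blocks=int(p.get("n_blocks", 4)),
                )
                for f in files
            ]
            fit = mechanics.fit_area_compressibility(
                points, n_blocks=int(p.get("n_blocks", 4))
            )
            dest = outdir / "mech.tsv"
            pd.DataFrame(
                [
                    (
                        "k_a_mN_per_m",
                        fit.k_a,
                        fit.standard_error,
                        fit.n_points,
                    )
                ],
                columns=["quantity", "value", "se", "n"],
            ).to_csv(dest, sep="\t", index=False)
            outputs.append(dest)
        elif stage == "map":
            src = Path(p.get("curves", outdir / "fe_curves.tsv"))
            curves = aio.read_fe_curves(src)
            mapping = multiscale.axonal_strain_at_rupture(
                curves,
                rupture_strain=float(p.get("rupture_strain", 0.36)),
                injury_threshold=p.get("injury_threshold", 0.10),
                mode=p.get("mode", "max"),
            )
            rows = [
                (f"axonal_strain_rate_{rate:g}", v if v is not None else float("nan"))
                for rate, v in sorted(mapping.per_rate_axonal_strain.items())
            ]
            if mapping.axonal_interval:
                rows.append(("interval_min", mapping.axonal_interval[0]))
                rows.append(("interval_max", mapping.axonal_interval[1]))
            dest = outdir / "map.tsv"
            df = pd.DataFrame(rows, columns=["quantity", "value"])
            df.to_csv(dest, sep="\t", index=False)
            (outdir / "map_verdict.txt").write_text(mapping.verdict + "\n")
            outputs.append(dest)
            outputs.append(outdir / "map_verdict.txt")

    manifest = {
        "stages": ordered,
        "seed": config.seed,
        "composition": str(config.composition),
        "parameters": config.params,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
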