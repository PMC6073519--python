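"""End-to-end pipeline: build -> validate -> coarse-grain -> solve -> label.

Each stage logs bead/spring counts and timings; outputs are byte-stable for
a given configuration (the configuration hash is recorded in the result
summary, and any iterative solver start vector is seeded from the config).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as dio
from .builder import (assembly_topology, build_assembly, build_tile,
                      interfaces_from_model, measure_ring_diameters,
                      validate_structure)
from .coarse_grain import coarse_grain, connected_components
from .designs import get_design
from .mode_metrics import label_modes, label_table
from .nma import analyze
from .scenm import analyze_symmetric
from .symmetry import get_group

log = logging.getLogger("dnanma")


@dataclass
class RunConfig:
    design: str = "r1c"
    design_overrides: dict = field(default_factory=dict)
    cutoff: float = 0.8              # nm, van der Waals cutoff
    n_modes: int = 16
    method: str = "auto"             # nma | scenm | auto
    zero_tol: float = 1e-11
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if self.cutoff <= 0 or self.n_modes < 1 or self.zero_tol <= 0:
            raise ValueError("physical parameters must be positive")
        if self.method not in ("auto", "nma", "scenm"):
            raise ValueError(f"unknown method {self.method!r}")


def structure_class(design) -> str:
    if design.family in ("ring", "toy_ring"):
        return "ring"
    if design.family == "three_point_star":
        return "buckyball" if design.group_name != "c1" else "tile"
    raise ValueError(design.family)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis for one design; returns the result bundle."""
    config.validate()
    t_all = time.time()
    cfg_dict = asdict(config)
    cfg_dict.pop("outdir", None)      # output location never affects results
    cfg_hash = dio.config_hash(cfg_dict)
    log.info("run %s: config hash %s", config.design, cfg_hash)

    design = get_design(config.design, **config.design_overrides)
    group = get_group(design.group_name)
    t0 = time.time()
    if group.order > 1:
        model = build_assembly(design)
    else:
        model = build_tile(design)
    log.info("build: %d atoms, %d nucleotides, %d base pairs (%.1fs)",
             model.n_atoms, model.n_nucleotides, len(model.pairing),
             time.time() - t0)

    t0 = time.time()
    report = validate_structure(model)
    log.info("validate: %d H-bond sites in [%.3f, %.3f] nm, %d clashes (%.1fs)",
             len(report.hbond_lengths), report.hbond_lengths.min(),
             report.hbond_lengths.max(), report.n_clashes, time.time() - t0)

    t0 = time.time()
    cg = coarse_grain(model, cutoff=config.cutoff)
    ncomp = connected_components(cg)
    log.info("coarse-grain: %d beads (%d per tile), %d springs, "
             "%d component(s) (%.1fs)", cg.n_beads,
             cg.n_beads // max(group.order, 1), len(cg.springs), ncomp,
             time.time() - t0)

    method = config.method
    if method == "auto":
        method = "scenm" if (design.family == "three_point_star"
                             and group.order > 1) else "nma"
    t0 = time.time()
    if method == "scenm":
        modes = analyze_symmetric(cg, group, n_modes=config.n_modes)
    else:
        modes = analyze(cg, n_modes=config.n_modes,
                        zero_tol=config.zero_tol, seed=config.seed)
    log.info("%s: %d modes, %d rigid (%.1fs)", method, modes.n_modes,
             modes.zero_mode_count, time.time() - t0)

    sclass = structure_class(design)
    labels = label_modes(modes, cg, sclass)

    result = {
        "design": config.design,
        "config_hash": cfg_hash,
        "method": method,
        "structure_class": sclass,
        "group": group.name,
        "q": group.order,
        "counts": {
            "atoms": model.n_atoms,
            "nucleotides": model.n_nucleotides,
            "base_pairs": len(model.pairing),
            "beads": cg.n_beads,
            "beads_per_tile": cg.n_beads // max(group.order, 1),
            "springs": len(cg.springs),
            "components": ncomp,
        },
        "validation": {
            "hbond_min": float(report.hbond_lengths.min()),
            "hbond_max": float(report.hbond_lengths.max()),
            "clashes": report.n_clashes,
            "min_interatomic_distance": report.min_interatomic_distance,
        },
        "zero_modes": modes.zero_mode_count,
        "eigenvalues": modes.eigenvalues.tolist(),
        "labels": {lab.mode_number: lab.label for lab in labels},
        "model": model,
        "cg": cg,
        "modes": modes,
        "wall_time_s": round(time.time() - t_all, 2),
    }
    if sclass == "ring" and design.family == "ring":
        result["diameters"] = measure_ring_diameters(model)
    if method == "scenm":
        result["reduction"] = {k: modes.meta[k] for k in
                               ("q", "m", "asymmetry_residual", "max_residual")}
    if group.order > 2 and len(model.pairing):
        centers, interfaces = interfaces_from_model(model)
        try:
            topo = assembly_topology(centers, interfaces)
            result["topology"] = {k: topo[k] for k in
                                  ("vertices", "edges", "faces",
                                   "faces_by_size")}
        except ValueError:
            pass

    if config.outdir:
        _export(result, config, Path(config.outdir))
    return result


def _export(result: dict, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_pdb(result["model"], outdir / "structure.pdb")
    dio.write_pdb(result["cg"], outdir / "cg.pdb")
    dio.write_springs_csv(result["cg"], outdir / "springs.csv")
    dio.write_modes_csv(result["modes"], outdir / "modes.csv")
    dio.write_nmd(result["cg"], result["modes"], outdir / "modes.nmd",
                  title=result["design"])
    label_table(result["modes"].labels,
                result["structure_class"]).to_csv(outdir / "labels.csv",
                                                  index=False,
                                                  float_format="%.17g")
    summary = {k: v for k, v in result.items()
               if k not in ("model", "cg", "modes", "wall_time_s")}
    cfg = asdict(config)
    cfg.pop("outdir", None)
    summary["config"] = dio._public(cfg)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(dio._public(summary), fh, indent=2, sort_keys=True)
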