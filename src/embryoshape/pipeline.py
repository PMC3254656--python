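"""End-to-end runs: configuration, staging, provenance.

A run is described by a JSON-serializable config dict; `run_pipeline`
executes the requested stages (synthesize geometry, simulate the equilibrium
shape, render a confocal-like stack, segment it, grid-search tensions against
the segmented contour) and writes stage outputs plus a provenance manifest.
Reruns with an identical config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ellipsoid import Ellipsoid
from .fitting import GridSpec, fit_tensions
from .imaging import (
    LABEL_AB,
    LABEL_BOUNDARY,
    LABEL_P1,
    preprocess_stack,
    segment_stack,
)
from .mesh import Body
from .meshio import save_ellipsoid, save_ply
from .simulator import (
    MinimizeOptions,
    TensionParams,
    mesh_curve_depth,
    minimize_shape,
)
from .synth import SynthConfig, default_markers, generate_embryo_geometry, render_stack

log = logging.getLogger("embryoshape")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},                  # SynthConfig field overrides
    "tensions": {"gamma_ab": 3.4, "gamma_cnt": 3.4},
    "simulate": {"resolution": "fast"},   # "fast" | "default"
    "render": {"enabled": False, "noise": True},
    "fit": {
        "enabled": True,
        "grid": {"min": 3.0, "max": 3.8, "step": 0.4},
    },
}

_RESOLUTIONS = {
    "coarse": MinimizeOptions(faces_per_edge=1, subdivisions=2,
                              max_iters=(300, 250, 200), polish_iters=300),
    "fast": MinimizeOptions(faces_per_edge=1, max_iters=(400, 300, 250, 200), polish_iters=500),
    "default": MinimizeOptions(),
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        cfg = _merge(cfg, json.loads(Path(path).read_text()))
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Schema and cross-field checks; returns a list of violations (empty = valid)."""
    problems: list[str] = []
    if not isinstance(cfg.get("seed"), int) or cfg["seed"] < 0:
        problems.append("seed must be a nonnegative integer")
    ten = cfg.get("tensions", {})
    ga, gc = ten.get("gamma_ab"), ten.get("gamma_cnt")
    if not isinstance(ga, (int, float)) or ga <= 0:
        problems.append("tensions.gamma_ab must be positive")
    if not isinstance(gc, (int, float)) or gc <= 0:
        problems.append("tensions.gamma_cnt must be positive")
    if isinstance(ga, (int, float)) and isinstance(gc, (int, float)) and ga > 0 and gc > 0:
        if not (abs(ga - 1.0) <= gc <= ga + 1.0):
            problems.append("tensions violate |g_AB - 1| <= g_cnt <= g_AB + 1")
    grid = cfg.get("fit", {}).get("grid", {})
    try:
        GridSpec(**grid)
    except (TypeError, ValueError) as exc:
        problems.append(f"fit.grid invalid: {exc}")
    synth = cfg.get("synth", {})
    try:
        SynthConfig(**synth)
    except (TypeError, ValueError) as exc:
        problems.append(f"synth config invalid: {exc}")
    res = cfg.get("simulate", {}).get("resolution", "fast")
    if res not in _RESOLUTIONS:
        problems.append(f"simulate.resolution must be one of {sorted(_RESOLUTIONS)}")
    for key in ("target", "input"):
        p = cfg.get(key)
        if p is not None and not Path(p).exists():
            problems.append(f"{key} file does not exist: {p}")
    return problems


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and write artifacts under outdir.

    Returns a summary dict (also written as report.json).  Raises on invalid
    configs or stage failure; partial outputs are left in place for
    inspection.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    synth_cfg = SynthConfig(**_merge({"seed": cfg["seed"]}, cfg.get("synth", {})))
    e, V_AB, V_P1 = generate_embryo_geometry(synth_cfg)
    save_ellipsoid(e, outdir / "eggshell.json")
    log.info("geometry: axes=%s V_AB=%.1f V_P1=%.1f", e.semi_axes.round(2), V_AB, V_P1)

    opts = _RESOLUTIONS[cfg.get("simulate", {}).get("resolution", "fast")]
    ten = cfg["tensions"]
    t = TensionParams(float(ten["gamma_ab"]), float(ten["gamma_cnt"]))
    shape = minimize_shape(t, V_AB, V_P1, e=e, opts=opts)
    save_ply(shape.mesh, outdir / "shape.ply")
    depth = mesh_curve_depth(shape)
    report = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg["seed"],
        "geometry": {
            "semi_axes_um": e.semi_axes.tolist(),
            "V_AB_um3": V_AB,
            "V_P1_um3": V_P1,
        },
        "simulate": {
            "gamma_ab": t.gamma_ab,
            "gamma_cnt": t.gamma_cnt,
            "energy": shape.energy,
            "P_AB": shape.pressures[Body.AB],
            "P_P1": shape.pressures[Body.P1],
            "pressure_ratio": shape.pressure_ratio,
            "curve_depth_um": depth,
            "converged": shape.converged,
            "iterations": shape.info.get("iterations"),
            "n_triangles": shape.info.get("n_triangles"),
        },
    }

    target_points = shape.mesh.vertices
    fit_volumes = (V_AB, V_P1)
    fit_shell = e
    if cfg.get("render", {}).get("enabled", False):
        import tifffile

        mem, egg = render_stack(shape, e, synth_cfg, noise=cfg["render"].get("noise", True))
        tifffile.imwrite(outdir / "membrane.tif", mem.data.astype(np.float32))
        tifffile.imwrite(outdir / "eggshell.tif", egg.data.astype(np.float32))
        pre = preprocess_stack(mem)
        markers = default_markers(shape, e, pre.spacing[0], margin=synth_cfg.margin)
        seg = segment_stack(pre, markers, eggshell=preprocess_stack(egg))
        tifffile.imwrite(outdir / "labels.tif", seg.label_volume.labels.astype(np.uint8))
        report["segment"] = {
            "V_AB_um3": seg.V_AB,
            "V_P1_um3": seg.V_P1,
            "eggshell_axes_um": seg.eggshell.semi_axes.tolist() if seg.eggshell else None,
        }
        lab = seg.label_volume.labels
        bnd = np.argwhere(lab == LABEL_BOUNDARY)
        # membrane contour: boundary voxels touching a cell region
        from scipy import ndimage as ndi

        cells = (lab == LABEL_AB) | (lab == LABEL_P1)
        touch = ndi.binary_dilation(cells) & (lab == LABEL_BOUNDARY)
        idx = np.argwhere(touch)
        sp = seg.label_volume.spacing
        target_points = (idx[:, ::-1] + 0.5) * sp  # (x, y, z) in grid frame
        fit_volumes = (seg.V_AB, seg.V_P1)
        fit_shell = seg.eggshell or e
        del bnd

    if cfg.get("fit", {}).get("enabled", True):
        grid = GridSpec(**cfg["fit"].get("grid", {}))
        fr = fit_tensions(target_points, fit_volumes[0], fit_volumes[1], fit_shell, grid, opts=opts)
        fr.table.to_csv(outdir / "fit.csv", index=False)
        report["fit"] = {
            "best_gamma_ab": fr.best[0],
            "best_gamma_cnt": fr.best[1],
            "best_rmse_um": float(fr.best_row.rmse_um),
            "n_combinations": int(len(fr.table)),
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "synth_config": dataclasses.asdict(synth_cfg),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
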