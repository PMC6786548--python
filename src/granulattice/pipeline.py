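"""End-to-end pipeline: simulate -> detect -> morphometry -> lattice ->
twins -> class averaging -> energetics, with a single JSON report.

Every stage is individually toggleable and every stochastic stage derives
its seed from the one global seed, so a configuration reruns bit-identically.
Defaults reproduce the study conditions: a five-sector cyclic twin of
body-centered tetragonal hIAPP granule lattices (a = 27.9 nm, c = 33 nm) in
a 600 x 600 x 85 nm volume at 1.1 nm voxels, ~20 nm granules with (001)
in-plane linkers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .cells import FIVEFOLD_WEDGE_ANGLES, HIAPP_BCT_CELL, UnitCell
from .detect import detect_granules, measure_diameter
from .energetics import (
    HamakerParams,
    ResolutionParams,
    axial_resolution,
    hamaker_energy,
    hamaker_sensitivity,
)
from .lattice import NoLatticeError, infer_lattice
from .morphometry import MorphometryReport, nn_spacing
from .synthetic import (
    DisorderSpec,
    RenderSpec,
    Volume3D,
    apply_disorder,
    build_twinned_assembly,
    build_unit_cell_points,
    extract_slab_projection,
    make_cyclic_twin,
)
from .twinning import analyze_twins


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic 31-bit stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_full_pipeline` (defaults = study values)."""

    seed: int = 0
    # simulate
    simulate: bool = True
    twin: bool = True
    wedge_angles: tuple = FIVEFOLD_WEDGE_ANGLES
    cell: UnitCell = field(default_factory=lambda: HIAPP_BCT_CELL)
    box_nm: tuple = (600.0, 600.0, 85.0)
    disorder: Optional[DisorderSpec] = None
    render: bool = True
    render_spec: RenderSpec = field(
        default_factory=lambda: RenderSpec(linker_planes=((0.0, 0.0, 1.0),))
    )
    # detect
    detect: bool = True
    expected_diameter: float = 20.1
    # morphometry
    morphometry: bool = True
    group: str = "hIAPP"
    max_diameter_measurements: int = 120
    # lattice
    lattice: bool = True
    # twins
    twins: bool = True
    orientation_symmetry_deg: float = 90.0
    # class averaging
    classavg: bool = True
    n_particles: int = 30
    n_classes: int = 3
    n_iterations: int = 8
    slab_thickness_nm: float = 20.0
    # energetics
    energetics: bool = True
    hamaker: HamakerParams = field(default_factory=HamakerParams)
    resolution: ResolutionParams = field(default_factory=ResolutionParams)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the configured stages in order and return the report dict.

    Any stage failure raises ``RuntimeError`` naming the stage; the partial
    report accumulated so far is written to ``outdir`` (when given) first.
    """
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_run": [],
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("detect", _stage_detect),
        ("morphometry", _stage_morphometry),
        ("twins", _stage_twins),
        ("lattice", _stage_lattice),
        ("classavg", _stage_classavg),
        ("energetics", _stage_energetics),
    ]
    for name, fn in stages:
        if not getattr(config, name if name != "simulate" else "simulate"):
            continue
        t0 = time.time()
        try:
            fn(config, state, report, outdir)
        except Exception as exc:
            if outdir is not None:
                _write_report(report, outdir)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report["stages_run"].append(name)
        report.setdefault("stage_seconds", {})[name] = round(time.time() - t0, 2)

    if outdir is not None:
        _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    from .io import save_json

    save_json(report, outdir / "report.json")


def _stage_simulate(config, state, report, outdir):
    if config.twin:
        spec = make_cyclic_twin(config.cell, config.wedge_angles)
        points, labels = build_twinned_assembly(spec, box=config.box_nm)
    else:
        points = build_unit_cell_points(config.cell, box=config.box_nm)
        labels = np.zeros(len(points), dtype=int)
    if config.disorder is not None:
        dis = replace(config.disorder, seed=derive_seed(config.seed, "disorder"))
        points, kept = apply_disorder(points, dis, return_kept=True)
        labels = labels[kept]
    state["points"], state["gen_labels"] = points, labels
    report["simulate"] = {
        "n_granules": int(len(points)),
        "twin": bool(config.twin),
        "box_nm": list(config.box_nm),
    }
    if config.render:
        rspec = replace(config.render_spec, seed=derive_seed(config.seed, "render"))
        state["volume"] = _render(points, rspec, config.box_nm)
        report["simulate"]["volume_shape_zyx"] = list(state["volume"].shape)
    if outdir is not None:
        from .io import save_mrc, save_points_csv

        save_points_csv(points, outdir / "centers.csv", labels)
        if "volume" in state:
            save_mrc(state["volume"], outdir / "volume.mrc")


def _render(points, rspec, box_nm) -> Volume3D:
    from .synthetic import render_volume

    box = np.stack([np.zeros(3), np.asarray(box_nm, dtype=float)], axis=1)
    return render_volume(points, rspec, box=box)


def _stage_detect(config, state, report, outdir):
    if "volume" not in state:
        # Point-only runs skip image detection; downstream stages use the
        # generator centres directly.
        state["centers"] = state["points"]
        report["detect"] = {"mode": "generator_points", "n": int(len(state["points"]))}
        return
    granules = detect_granules(state["volume"], config.expected_diameter)
    state["centers"] = granules.centers
    state["granules"] = granules
    report["detect"] = {"mode": "volume", "n": int(len(granules))}
    if outdir is not None:
        from .io import save_points_csv

        save_points_csv(granules.centers, outdir / "detected_centers.csv")


def _stage_morphometry(config, state, report, outdir):
    centers = state["centers"]
    spacings = nn_spacing(centers)
    diameters = np.empty(0)
    if "volume" in state:
        vol = state["volume"]
        ext = vol.physical_extent()
        margin = config.expected_diameter
        inside = np.all(
            (centers >= ext[:, 0] + margin) & (centers <= ext[:, 1] - margin), axis=1
        )
        sel = np.where(inside)[0][: config.max_diameter_measurements]
        diameters = np.array(
            [measure_diameter(vol, centers[i], config.expected_diameter) for i in sel]
        )
    rep = MorphometryReport(config.group, diameters=diameters, spacings=spacings)
    state["morphometry"] = rep
    report["morphometry"] = rep.summary()


def _stage_twins(config, state, report, outdir):
    centers = state["centers"]
    partition = analyze_twins(centers, symmetry_deg=config.orientation_symmetry_deg)
    state["twin_partition"] = partition
    report["twins"] = partition.to_dict()
    if outdir is not None:
        from .io import save_points_csv

        save_points_csv(centers, outdir / "domains.csv", partition.labels)


def _stage_lattice(config, state, report, outdir):
    centers = state["centers"]
    labels = (
        state["twin_partition"].labels
        if "twin_partition" in state
        else np.zeros(len(centers), dtype=int)
    )
    fits = {}
    for lab in np.unique(labels):
        sub = centers[labels == lab]
        if len(sub) < 30:
            continue
        try:
            fits[int(lab)] = infer_lattice(sub).to_dict()
        except NoLatticeError as exc:
            fits[int(lab)] = {"label": "no_lattice", "reason": str(exc)}
    state["lattice_fits"] = fits
    report["lattice"] = fits


def _stage_classavg(config, state, report, outdir):
    if "volume" not in state:
        report["classavg"] = {"skipped": "no rendered volume"}
        return
    from .classavg import box_particles, classify_iterate, measure_linker_angles

    vol = state["volume"]
    centers = state["centers"]
    # Particles come from a single crystalline domain (the largest), so the
    # stack shares one row orientation and the linker angles are meaningful.
    if "twin_partition" in state:
        labels = state["twin_partition"].labels
        largest = np.bincount(labels).argmax()
        centers = centers[labels == largest]
    # Slab through the granule plane nearest the volume's mid-height.
    z_mid = vol.physical_extent()[2].mean()
    z_planes = centers[:, 2]
    anchor_z = z_planes[np.argmin(np.abs(z_planes - z_mid))]
    img = extract_slab_projection(
        vol, normal=(0, 0, 1), anchor=(0, 0, anchor_z), thickness=config.slab_thickness_nm
    )
    in_plane = np.abs(centers[:, 2] - anchor_z) < vol.voxel_size
    box_px = int(round(2.5 * config.expected_diameter / vol.voxel_size))
    half = box_px // 2 + 1
    picks = []
    for p in centers[in_plane]:
        row = int(round((p[1] - vol.origin[1]) / vol.voxel_size - 0.5))
        col = int(round((p[0] - vol.origin[0]) / vol.voxel_size - 0.5))
        if half <= row < img.shape[0] - half and half <= col < img.shape[1] - half:
            picks.append((row, col))
    rng = np.random.default_rng(derive_seed(config.seed, "classavg"))
    if len(picks) > config.n_particles:
        idx = rng.choice(len(picks), size=config.n_particles, replace=False)
        picks = [picks[i] for i in sorted(idx)]
    stack = box_particles(img, picks, box_px, vol.voxel_size, source=f"(001) z={anchor_z:.1f}")
    cs = classify_iterate(
        stack, k=config.n_classes, iterations=config.n_iterations,
        seed=derive_seed(config.seed, "classavg"),
    )
    radius_px = config.expected_diameter / 2.0 / vol.voxel_size
    spacing_px = config.cell.a / vol.voxel_size
    best = int(np.argmax(np.bincount(cs.assignments, minlength=cs.k)))
    angles = measure_linker_angles(cs.averages[best], radius_px, spacing_px)
    report["classavg"] = {
        "n_particles": len(stack),
        "class_sizes": np.bincount(cs.assignments, minlength=cs.k).tolist(),
        "best_class": best,
        "linker_orientations_deg": np.round(angles.orientations, 2).tolist(),
        "linker_primary_angle_deg": None
        if not np.isfinite(angles.primary_angle)
        else round(float(angles.primary_angle), 2),
        "antipodal_linkers": angles.has_antipodal.tolist(),
    }
    if outdir is not None:
        from .io import save_tiff

        save_tiff(img, outdir / "slab.tif", vol.voxel_size)
        for c in range(cs.k):
            save_tiff(cs.averages[c], outdir / f"class_avg_{c}.tif", vol.voxel_size)


def _stage_energetics(config, state, report, outdir):
    report["energetics"] = {
        **hamaker_energy(config.hamaker),
        "sensitivity": hamaker_sensitivity(config.hamaker),
        "axial_resolution_nm": axial_resolution(config.resolution),
    }
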