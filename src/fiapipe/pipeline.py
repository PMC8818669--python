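"""Per-case orchestration: profile -> detect -> restore -> stent -> indices,
plus the fusiform/healthy/treated comparison."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import Any

import numpy as np

from . import formats
from .geometry import Centerline, SurfaceMesh
from .healthy import remove_dilation, target_radius_profile
from .indices import (
    IndexField,
    VolumeSeries,
    WallSeries,
    awss,
    index_summary,
    kinetic_energy,
    last_cycle,
    osi,
    ovi,
    rrt,
)
from .morphology import csa_profile, detect_fusiform, morphology_report, nominal_diameter
from .stenting import StentSpec, apposition_map, deploy_stent, metal_coverage
from .synthetic import VesselSpec, make_vessel, three_state_fields

logger = logging.getLogger(__name__)

__all__ = ["CaseConfig", "run_case", "compare_states", "compute_state_indices"]

STATES = ("fusiform", "healthy", "treated")
# indices where "toward healthy" comparisons use the max statistic
_COMPARE_STAT = "max"


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


@dataclasses.dataclass
class CaseConfig:
    """Inputs and parameters of a full case run.

    Either ``mesh_path``/``centerline_path`` point at files, or ``synthetic``
    holds a :class:`~fiapipe.synthetic.VesselSpec` parameter dict.  Field
    manifests per state are optional; absent states are skipped and marked.
    """

    mesh_path: str | None = None
    centerline_path: str | None = None
    synthetic: dict | None = None
    field_manifests: dict | None = None  # state -> {"wall": path, "volume": path}
    spacing: float = 0.25
    n_rays: int = 360
    huber_ratio: float = 1.5
    window: float = 3.0  # proximal/distal nominal-diameter window, mm
    stent: dict | None = None  # StentSpec fields + "s_distal"
    smoothing_lambda: float = 0.5
    smoothing_iterations: int = 20
    bc_method: str = "shape_based"
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_geometry(cfg: CaseConfig):
    if cfg.synthetic is not None:
        spec = VesselSpec(**cfg.synthetic)
        mesh, cl, _ = make_vessel(spec, seed=cfg.seed)
        return mesh, cl, spec
    if not cfg.mesh_path or not cfg.centerline_path:
        raise ValueError("config needs either synthetic spec or mesh+centerline paths")
    return (
        formats.read_mesh(cfg.mesh_path),
        formats.read_centerline_csv(cfg.centerline_path),
        None,
    )


def compute_state_indices(ws: WallSeries | None, vs: VolumeSeries | None) -> dict:
    """Index summaries for one state; series are windowed to the last cycle."""
    out: dict[str, Any] = {}
    if ws is not None:
        ws = last_cycle(ws)
        f_awss = awss(ws)
        f_osi = osi(ws)
        f_rrt = rrt(f_awss, f_osi)
        for f in (f_awss, f_osi, f_rrt):
            out[f.name] = index_summary(f, weights=ws.weights)
    if vs is not None:
        vs = last_cycle(vs)
        f_ovi = ovi(vs)
        _, f_ke = kinetic_energy(vs)
        for f in (f_ovi, f_ke):
            out[f.name] = index_summary(f, weights=vs.weights)
    return out


def run_case(cfg: CaseConfig) -> dict:
    """Execute the full per-case workflow; returns the case report dict.

    Stages with missing inputs are skipped and marked ``"absent"``; stage
    failures raise :class:`StageError` naming the stage.
    """
    report: dict[str, Any] = {
        "schema": "fiapipe-case-report/1",
        "provenance": {"config_hash": cfg.config_hash, "seed": cfg.seed},
    }
    try:
        mesh, cl, synth_spec = _load_geometry(cfg)
    except Exception as exc:
        raise StageError("load", exc)

    try:
        profile = csa_profile(mesh, cl, spacing=cfg.spacing, n_rays=cfg.n_rays)
        d_nom = nominal_diameter(profile, cfg.window, cfg.window)
        region = detect_fusiform(profile, d_nom, cfg.huber_ratio)
    except Exception as exc:
        raise StageError("morphology", exc)
    report["nominal_diameter_mm"] = d_nom
    if region is None:
        report["morphology"] = "no dilation detected"
    else:
        morph = morphology_report(profile, region)
        report["morphology"] = morph.to_dict()
        report["region"] = {
            "s_start": region.s_start,
            "s_end": region.s_end,
            "s_max": region.s_max,
            "ratio_max": region.ratio_max,
        }

    if region is not None:
        try:
            target = target_radius_profile(profile, region)
            restored = remove_dilation(
                mesh, cl, region, target,
                lam=cfg.smoothing_lambda, iterations=cfg.smoothing_iterations,
            )
            report["healthy_reconstruction"] = {
                "n_vertices_moved": int(
                    np.sum(np.any(restored.vertices != mesh.vertices, axis=1))
                )
            }
            if cfg.output_dir:
                formats.write_obj(restored, f"{cfg.output_dir}/healthy.obj")
        except Exception as exc:
            raise StageError("healthy_reconstruction", exc)
    else:
        report["healthy_reconstruction"] = "absent"

    if cfg.stent:
        try:
            params = dict(cfg.stent)
            s_distal = params.pop("s_distal")
            spec = StentSpec(**params)
            stent = deploy_stent(spec, mesh, cl, s_distal, profile=profile)
            appo = apposition_map(stent, mesh)
            lo, hi = stent.s_span
            cov = metal_coverage(stent, lo + 1e-6, hi - 1e-6)
            report["stent"] = {
                **stent.to_dict(),
                "malapposed_fraction": appo["malapposed_fraction"],
                "max_gap_mm": appo["max_gap_mm"],
                "metal_coverage": cov,
            }
        except Exception as exc:
            raise StageError("stenting", exc)
    else:
        report["stent"] = "absent"

    indices: dict[str, Any] = {}
    if cfg.field_manifests:
        from . import fieldio

        for state, paths in cfg.field_manifests.items():
            try:
                ws = fieldio.read_series_csv(paths["wall"]) if "wall" in paths else None
                vs = fieldio.read_series_csv(paths["volume"]) if "volume" in paths else None
                indices[state] = compute_state_indices(ws, vs)
            except Exception as exc:
                raise StageError(f"indices[{state}]", exc)
    elif synth_spec is not None:
        fields = three_state_fields(seed=cfg.seed)
        for state, (vs, ws) in fields.items():
            indices[state] = compute_state_indices(ws, vs)
    for state in STATES:
        indices.setdefault(state, "absent")
    report["indices"] = indices

    present = [s for s in STATES if indices[s] != "absent"]
    if set(present) == set(STATES):
        report["comparison"] = compare_states(
            indices["fusiform"], indices["healthy"], indices["treated"]
        )
    return report


def compare_states(fusiform: dict, healthy: dict, treated: dict) -> dict:
    """Per-index ratios and restored-toward-healthy flags.

    For each index summary statistic the flag is true when the treated value
    is closer to the healthy one than the fusiform value is.
    """
    if set(fusiform) != set(healthy) or set(fusiform) != set(treated):
        raise ValueError("mismatched index sets between states")
    out = {}
    for name in fusiform:
        f, h, t = fusiform[name], healthy[name], treated[name]
        stat = _COMPARE_STAT
        ratio_tf = t[stat] / f[stat] if f[stat] else None
        ratio_th = t[stat] / h[stat] if h[stat] else None
        out[name] = {
            "treated_over_fusiform": ratio_tf,
            "treated_over_healthy": ratio_th,
            "restored_toward_healthy": bool(
                abs(t[stat] - h[stat]) <= abs(f[stat] - h[stat])
            ),
        }
    return out
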