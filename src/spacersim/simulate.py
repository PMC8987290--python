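"""End-to-end virtual spacer simulation for one case and scenario.

Builds the hollow duodenal wall and target tet models from the masks, tags
the anatomical boundary conditions, constructs one insertion plan per
injected interface section (approach radially outward from the target, so
the advancing gel pushes the duodenal wall away from the head of
pancreas), solves the incremental insertion, rasterizes the DVF and warps
the structure set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
from scipy import ndimage

from . import fem, meshing, phantom
from .grid import StructureSet

__all__ = ["SimulationSettings", "SimulationResult", "build_insertion_plans", "simulate_scenario"]


@dataclass
class SimulationSettings:
    """Problem-size and physics knobs for the insertion solve."""

    push_mm: float = 8.0  # spacer travel toward the duodenum
    n_steps: int = 6  # insertion increments
    mesh_step: int = 2  # marching-cubes coarsening for FE surfaces
    max_edge_mm: float = 5.0  # tet lattice target edge
    smooth_iterations: int = 8
    materials: fem.MaterialTable = field(default_factory=lambda: dict(fem.DEFAULT_MATERIALS))
    displacement_cap_mm: float = 25.0


@dataclass
class SimulationResult:
    pre: StructureSet  # with placed spacer
    post: StructureSet  # warped, with final spacer mask
    dvf: fem.DeformationField
    displacements: Dict[str, np.ndarray]
    models: Dict[str, meshing.TetModel]
    info: Dict[str, object]


def _surface(mask, grid, settings: SimulationSettings, sigma=1.0) -> trimesh.Trimesh:
    m = meshing.mask_to_surface(mask, grid, sigma_vox=sigma, step_size=settings.mesh_step)
    if settings.smooth_iterations > 0:
        m = meshing.smooth_surface(m, iterations=settings.smooth_iterations)
    return m


def _angular_chunks(mask: np.ndarray, grid, center: np.ndarray, max_span_deg: float = 40.0):
    """Split a pocket into angular sectors about the loop axis.

    A long lens wrapped around the loop cannot be pushed outward by one
    rigid translation (its flanks would move tangentially or inward), so
    each sector gets its own radial approach vector.
    """
    idx = np.argwhere(mask)
    pts = grid.index_to_world(idx)
    ang = np.degrees(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
    ang = np.mod(ang, 360.0)
    # unwrap the sector so a pocket crossing 0 deg stays contiguous
    hist = np.histogram(ang, bins=72, range=(0, 360))[0]
    gap_bin = int(np.argmax(hist == 0)) if (hist == 0).any() else 0
    ang = np.mod(ang - gap_bin * 5.0, 360.0)
    n_chunks = max(1, int(np.ceil((ang.max() - ang.min()) / max_span_deg)))
    edges = np.linspace(ang.min() - 1e-6, ang.max() + 1e-6, n_chunks + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (ang >= lo) & (ang < hi)
        if sel.sum() < 8:  # too few voxels to mesh
            continue
        m = np.zeros(mask.shape, dtype=bool)
        m[tuple(idx[sel].T)] = True
        mid = np.deg2rad(np.mod((lo + hi) / 2 + gap_bin * 5.0, 360.0))
        v = np.array([np.cos(mid), np.sin(mid), 0.0])
        out.append((m, v))
    return out


def build_insertion_plans(
    placed: StructureSet, settings: SimulationSettings
) -> List[fem.InsertionPlan]:
    """Insertion plans for every injected pocket.

    Each interface pocket is split into angular sectors; a sector's final
    position is the placed geometry pushed ``push_mm`` radially outward
    (away from the target), and the placed geometry itself is the tangent
    initial position."""
    center = np.asarray(placed.meta.get("loop_center_mm", placed.centroid_mm("HOP")))
    plans: List[fem.InsertionPlan] = []
    for group, mask in placed.meta["spacer_sections"].items():
        for chunk, v in _angular_chunks(mask, placed.grid, center):
            # one-voxel dilation: the gel front engages the wall it presses
            # on even where the discretized pocket thins out
            chunk = ndimage.binary_dilation(chunk)
            surf = meshing.mask_to_surface(
                chunk, placed.grid, sigma_vox=0.8, step_size=settings.mesh_step
            )
            final = surf.copy()
            final.vertices = final.vertices + settings.push_mm * v
            final.metadata["field_origin"] = surf.metadata["field_origin"] + settings.push_mm * v
            plans.append(
                fem.InsertionPlan(
                    spacer_surface=final,
                    approach_vector=v,
                    travel_mm=settings.push_mm,
                    n_steps=settings.n_steps,
                )
            )
    return plans


def _final_spacer_mask(placed: StructureSet, settings: SimulationSettings) -> np.ndarray:
    """Translate each placed pocket sector to its final (pushed) position."""
    grid = placed.grid
    center = np.asarray(placed.meta.get("loop_center_mm", placed.centroid_mm("HOP")))
    out = np.zeros(grid.shape, dtype=bool)
    for group, mask in placed.meta["spacer_sections"].items():
        for chunk, v in _angular_chunks(mask, grid, center):
            idx = np.argwhere(chunk)
            shifted = idx + np.round(settings.push_mm * v / np.asarray(grid.spacing)).astype(int)
            ok = np.all((shifted >= 0) & (shifted < np.asarray(grid.shape)), axis=1)
            out[tuple(shifted[ok].T)] = True
    return out


def simulate_scenario(
    s: StructureSet,
    scenario: phantom.SpacerScenario,
    settings: Optional[SimulationSettings] = None,
) -> SimulationResult:
    """Simulate one spacer scenario on a (pre-injection) structure set."""
    settings = settings or SimulationSettings()
    placed = (
        s
        if "spacer" in s and s.meta.get("spacer_scenario") == scenario.label
        else phantom.place_virtual_spacer(s, scenario)
    )
    grid = s.grid

    duo_outer = _surface(placed["duodenum"], grid, settings)
    duo_inner = _surface(placed["duodenum_lumen"], grid, settings)
    duo_model = meshing.nested_tetrahedralize(
        duo_outer, duo_inner, settings.max_edge_mm,
        wall_material=1, inner_material=3,
    )
    hop_surf = _surface(placed["HOP"], grid, settings)
    hop_model = meshing.tetrahedralize(
        hop_surf, settings.max_edge_mm, material=2, material_name="HOP"
    )
    duo_model, hop_model = meshing.tag_boundary_sets(
        duo_model,
        hop_model,
        placed["stomach"],
        grid,
        {k: placed[k] for k in ("D1", "D2", "D3", "D4")},
        lumen_mask=placed["duodenum_lumen"],
    )

    plans = build_insertion_plans(placed, settings)
    disp, info = fem.solve_insertion(
        duo_model,
        hop_model,
        plans,
        settings.materials,
        displacement_cap_mm=settings.displacement_cap_mm,
    )
    dvf = fem.displacements_to_dvf(
        [(duo_model, disp["duodenum"]), (hop_model, disp["HOP"])],
        grid,
        cap_mm=settings.displacement_cap_mm,
        regions=[placed["duodenum"], placed["HOP"]],
    )
    # each organ family is warped by its own model's field: the duodenum
    # rides the wall solution, the target follows its own (held) nodes
    dvf_duo = fem.displacements_to_dvf(
        [(duo_model, disp["duodenum"])],
        grid,
        cap_mm=settings.displacement_cap_mm,
        regions=[placed["duodenum"]],
    )
    dvf_hop = fem.displacements_to_dvf(
        [(hop_model, disp["HOP"])],
        grid,
        cap_mm=settings.displacement_cap_mm,
        regions=[placed["HOP"]],
    )
    fields = {
        "duodenum": dvf_duo,
        "duodenum_lumen": dvf_duo,
        "HOP": dvf_hop,
        "GTV": dvf_hop,
        "GTV_multabc": dvf_hop,
        "PTV": dvf_hop,
    }
    post = fem.warp_structures(
        placed, dvf, spacer_final=_final_spacer_mask(placed, settings), fields=fields
    )
    post.meta["scenario"] = scenario.label
    return SimulationResult(
        pre=placed,
        post=post,
        dvf=dvf,
        displacements=disp,
        models={"duodenum": duo_model, "HOP": hop_model},
        info=info,
    )
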