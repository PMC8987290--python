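"""Procedural abdominal phantoms, spacer scenarios and synthetic SBRT dose.

The generator emulates the anatomy at the duodenum–pancreas interface: a
hollow C-shaped duodenal tube (sections D1–D4, wall 2–3 mm) wrapping the
head-of-pancreas target, a stomach blob abutting D1 and a bowel blob
inferior to the target.  Every geometric parameter is drawn from a seeded
RNG so cohorts of arbitrary size can be sampled; the same seed always
yields bit-identical masks.

Dose is synthesized from a signed-distance falloff around the PTV rather
than by plan optimization: inside the PTV a mild hotspot ramps the dose
above prescription, outside it decays exponentially with a configurable
falloff length.  The profile preserves the property the decision support
system relies on — organ-at-risk dose is determined by its distance to the
target — and is rescaled so PTV V33Gy sits in the (95%, 96%) band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import DoseGrid, StructureSet, VoxelGrid

__all__ = [
    "AnatomyParams",
    "SpacerScenario",
    "PhantomSizingError",
    "SpacerPlacementError",
    "SCENARIO_SECTIONS",
    "SECTION_GROUPS",
    "generate_phantom",
    "place_virtual_spacer",
    "synthesize_dose",
    "wall_thickness_stats",
]


class PhantomSizingError(ValueError):
    """The requested grid cannot accommodate the anatomy."""


class SpacerPlacementError(ValueError):
    """The requested spacer volume does not fit in the available space."""


#: scenario label -> injected interface sections
SCENARIO_SECTIONS: Dict[str, Tuple[str, ...]] = {
    "S0": (),
    "S1": ("D1D2",),
    "S2": ("D1D2", "D3"),
    "S3": ("D1D2", "D3", "D4"),
}

#: interface section -> anatomical duodenal sections it spans
SECTION_GROUPS: Dict[str, Tuple[str, ...]] = {
    "D1D2": ("D1", "D2"),
    "D3": ("D3",),
    "D4": ("D4",),
}

#: fraction of the duodenal arc covered by each anatomical section
_SECTION_BREAKS = {"D1": (0.0, 0.12), "D2": (0.12, 0.45), "D3": (0.45, 0.75), "D4": (0.75, 1.0)}

# GTV -> GTV_multabc (breathing-control mock margin) and -> PTV (setup margin)
GTV_TO_MULTABC_MM = 3.0
MULTABC_TO_PTV_MM = 2.0


@dataclass(frozen=True)
class SpacerScenario:
    """Virtual spacer placement scenario.

    S0 is no spacer; S1 injects the D1–D2 interface; S2 adds D3; S3 covers
    the full loop (D1–D2, D3 and D4).  The injected volume per interface
    section is limited to less than 10 ml.
    """

    label: str
    per_section_volume_ml: float = 9.0

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_SECTIONS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if not self.per_section_volume_ml < 10.0:
            raise ValueError(
                f"per-section spacer volume must be < 10 ml, got {self.per_section_volume_ml}"
            )
        if self.per_section_volume_ml <= 0:
            raise ValueError("per-section spacer volume must be positive")

    @property
    def sections(self) -> Tuple[str, ...]:
        return SCENARIO_SECTIONS[self.label]


@dataclass
class AnatomyParams:
    """Anatomy parameters; ``None`` fields are drawn from the seeded RNG.

    Distances in mm.  ``gap_mm`` is the minimum distance between the
    head-of-pancreas (HOP) surface and the duodenal tube; the default
    uniform 0–4 mm range straddles the planning constraints, which is what
    makes the cohort informative for the decision models.
    """

    loop_radius_mm: Optional[float] = None
    tube_outer_radius_mm: Optional[float] = None
    wall_thickness_mm: Optional[float] = None
    gap_mm: Optional[float] = None
    arc_deg: Optional[float] = None
    section_offsets_mm: Optional[Dict[str, float]] = None
    hop_z_radius_mm: Optional[float] = None
    stomach_radii_mm: Optional[Tuple[float, float, float]] = None
    bowel_gap_mm: Optional[float] = None
    bowel_radii_mm: Optional[Tuple[float, float, float]] = None
    bowel_xy_offset_mm: Optional[Tuple[float, float]] = None
    z_tilt_mm: Optional[float] = None
    center_jitter_mm: Optional[Tuple[float, float, float]] = None
    # negative: the stomach interpenetrates the tube and is carved back to
    # contact, mimicking the contiguous pylorus junction at D1
    stomach_gap_mm: float = -3.0
    gap_range_mm: Tuple[float, float] = (0.0, 4.0)

    def resolve(self, rng: np.random.Generator) -> Dict[str, object]:
        """Draw every unset parameter; returns a plain dict of numbers."""
        pick = lambda v, draw: draw() if v is None else v
        out: Dict[str, object] = {}
        out["loop_radius_mm"] = float(
            pick(self.loop_radius_mm, lambda: np.clip(rng.normal(27.0, 1.5), 24.0, 30.0))
        )
        out["tube_outer_radius_mm"] = float(
            pick(self.tube_outer_radius_mm, lambda: rng.uniform(8.0, 9.5))
        )
        out["wall_thickness_mm"] = float(
            pick(self.wall_thickness_mm, lambda: rng.uniform(2.4, 2.9))
        )
        out["gap_mm"] = float(pick(self.gap_mm, lambda: rng.uniform(*self.gap_range_mm)))
        out["arc_deg"] = float(pick(self.arc_deg, lambda: rng.uniform(285.0, 315.0)))
        if self.section_offsets_mm is None:
            # D2 hugs the pancreatic head (reference radius); D1 sits a few
            # mm farther out toward the pylorus where the stomach pins it
            offs = {
                "D1": float(rng.uniform(2.0, 4.0)),
                "D2": 0.0,
                "D3": float(rng.uniform(0.0, 5.0)),
                "D4": float(rng.uniform(0.0, 5.0)),
            }
        else:
            offs = dict(self.section_offsets_mm)
            m = min(offs.values())
            offs = {k: v - m for k, v in offs.items()}
        out["section_offsets_mm"] = {k: float(v) for k, v in offs.items()}
        out["hop_z_radius_mm"] = float(pick(self.hop_z_radius_mm, lambda: rng.uniform(13.0, 16.0)))
        # stomach long axis tangential (x), short axis radial (y, toward D1)
        out["stomach_radii_mm"] = tuple(
            pick(
                self.stomach_radii_mm,
                lambda: tuple(np.array([22.0, 12.0, 18.0]) * rng.uniform(0.9, 1.1)),
            )
        )
        out["bowel_gap_mm"] = float(pick(self.bowel_gap_mm, lambda: rng.uniform(1.0, 10.0)))
        # broad, flat superior face: the bowel bag presents a wide surface
        # to the target from below, so it can become dose-limiting
        out["bowel_radii_mm"] = tuple(
            pick(
                self.bowel_radii_mm,
                lambda: tuple(np.array([22.0, 20.0, 11.0]) * rng.uniform(0.9, 1.1)),
            )
        )
        out["bowel_xy_offset_mm"] = tuple(
            pick(self.bowel_xy_offset_mm, lambda: tuple(rng.uniform(-6.0, 6.0, size=2)))
        )
        out["z_tilt_mm"] = float(pick(self.z_tilt_mm, lambda: rng.uniform(0.0, 3.0)))
        out["center_jitter_mm"] = tuple(
            pick(self.center_jitter_mm, lambda: tuple(rng.uniform(-2.0, 2.0, size=3)))
        )
        out["stomach_gap_mm"] = float(self.stomach_gap_mm)
        return out


def default_grid(n: int = 72, spacing: float = 2.0) -> VoxelGrid:
    """Isotropic grid centered on the origin."""
    half = (n - 1) * spacing / 2.0
    return VoxelGrid(shape=(n, n, n), spacing=(spacing,) * 3, origin=(-half, -half, -half))


# ---------------------------------------------------------------------------
# centerline helpers
# ---------------------------------------------------------------------------

def _centerline(p: Dict[str, object], center: np.ndarray, n_samples: int = 400):
    """Sample the duodenal C-loop centerline.

    Returns (points (n,3), u (n,), section label per sample).  The loop
    starts at D1 near the stomach (superior, +y) and runs clockwise through
    D2 (descending), D3 (horizontal/inferior) and D4 (ascending).
    """
    u = np.linspace(0.0, 1.0, n_samples)
    sections = np.empty(n_samples, dtype=object)
    raw_off = np.zeros(n_samples)
    offs = p["section_offsets_mm"]
    for name, (lo, hi) in _SECTION_BREAKS.items():
        sel = (u >= lo) & (u <= hi if hi == 1.0 else u < hi)
        sections[sel] = name
        raw_off[sel] = offs[name]
    # smooth the per-section radial offsets so the tube has no kinks
    off = ndimage.gaussian_filter1d(raw_off, sigma=n_samples / 18.0, mode="nearest")
    theta0 = np.deg2rad(90.0)
    theta = theta0 - u * np.deg2rad(p["arc_deg"])
    radius = p["loop_radius_mm"] + off
    z = p["z_tilt_mm"] * (0.5 - u) * 2.0
    pts = np.stack(
        [
            center[0] + radius * np.cos(theta),
            center[1] + radius * np.sin(theta),
            center[2] + z,
        ],
        axis=1,
    )
    return pts, u, sections


def _ellipsoid(coords: np.ndarray, center: np.ndarray, radii) -> np.ndarray:
    d = (coords - center) / np.asarray(radii, dtype=float)
    return np.einsum("...i,...i->...", d, d) <= 1.0


def _check_fit(grid: VoxelGrid, center: np.ndarray, reaches: Dict[str, Tuple[float, float]]):
    """Ensure every structure stays >= 2 voxels inside the grid."""
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    margin = 2.0 * np.asarray(grid.spacing)
    for name, (down, up) in reaches.items():
        for axis, (d, u) in enumerate(zip(down, up)):
            if center[axis] - d < lo[axis] + margin[axis] or center[axis] + u > hi[axis] - margin[axis]:
                ax = "xyz"[axis]
                raise PhantomSizingError(
                    f"grid too small along {ax}: structure {name} needs "
                    f"[{center[axis]-d:.1f}, {center[axis]+u:.1f}] mm but grid spans "
                    f"[{lo[axis]+margin[axis]:.1f}, {hi[axis]-margin[axis]:.1f}] mm"
                )


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(
    seed: int,
    grid: Optional[VoxelGrid] = None,
    anatomy_params: Optional[AnatomyParams] = None,
) -> StructureSet:
    """Generate a synthetic abdominal case.

    Deterministic given ``seed``; raises :class:`PhantomSizingError` naming
    the violated axis when the grid cannot hold the anatomy.
    """
    grid = grid or default_grid()
    params = anatomy_params or AnatomyParams()
    rng = np.random.default_rng(seed)
    p = params.resolve(rng)

    center = grid.center_mm.copy()
    center += np.asarray(p["center_jitter_mm"])[: 3]

    r_out = p["tube_outer_radius_mm"]
    r_in = r_out - p["wall_thickness_mm"]
    r_hop_xy = p["loop_radius_mm"] - r_out - p["gap_mm"]
    if r_hop_xy <= 5.0:
        raise ValueError("anatomy parameters leave no room for the target")
    rz_hop = p["hop_z_radius_mm"]

    cl_pts, cl_u, cl_sec = _centerline(p, center)

    # stomach abuts the D1 end of the loop
    start = cl_pts[0]
    radial = start - center
    radial[2] = 0.0
    radial /= np.linalg.norm(radial)
    st_r = np.asarray(p["stomach_radii_mm"])
    # ellipsoid radius along the (unit) radial direction
    st_r_radial = 1.0 / np.sqrt(np.sum((radial / st_r) ** 2))
    st_center = start + radial * (r_out + p["stomach_gap_mm"] + st_r_radial) + np.array([0.0, 0.0, 4.0])

    # bowel sits inferior to the target at a variable vertical gap
    bw_r = np.asarray(p["bowel_radii_mm"])
    bw_center = center + np.array(
        [
            p["bowel_xy_offset_mm"][0],
            p["bowel_xy_offset_mm"][1],
            -(rz_hop + p["bowel_gap_mm"] + bw_r[2]),
        ]
    )

    loop_reach = p["loop_radius_mm"] + max(p["section_offsets_mm"].values()) + r_out
    _check_fit(
        grid,
        center,
        {
            "duodenum": ((loop_reach, loop_reach, r_out + p["z_tilt_mm"]),
                         (loop_reach, loop_reach, r_out + p["z_tilt_mm"])),
            "stomach": (tuple(center - (st_center - st_r)), tuple(st_center + st_r - center)),
            "bowel": (tuple(center - (bw_center - bw_r)), tuple(bw_center + bw_r - center)),
            "PTV": ((r_hop_xy + 3.5,) * 2 + (rz_hop + 3.5,),
                    (r_hop_xy + 3.5,) * 2 + (rz_hop + 3.5,)),
        },
    )

    coords = grid.dense_coordinates()
    flat = coords.reshape(-1, 3)

    # distance of every voxel to the centerline polyline (KD-tree on samples)
    tree = cKDTree(cl_pts)
    d_cl, nearest = tree.query(flat, workers=-1)
    d_cl = d_cl.reshape(grid.shape)
    nearest = nearest.reshape(grid.shape)

    tube = d_cl <= r_out
    lumen = d_cl <= r_in
    section_of = cl_sec[nearest]

    masks: Dict[str, np.ndarray] = {}
    masks["duodenum"] = tube
    masks["duodenum_lumen"] = lumen
    for s in ("D1", "D2", "D3", "D4"):
        masks[s] = tube & (section_of == s)

    # target structures: GTV -> +3 mm mock margin -> +2 mm setup margin
    gtv = _ellipsoid(coords, center, (r_hop_xy - 1.5, r_hop_xy - 1.5, rz_hop - 1.5))
    if not gtv.any():
        raise ValueError("GTV is empty; anatomy parameters are degenerate")
    d_gtv = ndimage.distance_transform_edt(~gtv, sampling=grid.spacing)
    masks["GTV"] = gtv
    masks["GTV_multabc"] = gtv | (d_gtv <= GTV_TO_MULTABC_MM)
    masks["PTV"] = gtv | (d_gtv <= GTV_TO_MULTABC_MM + MULTABC_TO_PTV_MM)
    masks["HOP"] = _ellipsoid(coords, center, (r_hop_xy, r_hop_xy, rz_hop))

    masks["stomach"] = _ellipsoid(coords, st_center, st_r) & ~tube
    masks["bowel"] = _ellipsoid(coords, bw_center, bw_r) & ~tube

    out = StructureSet(grid=grid, masks={})
    for name, m in masks.items():
        out.add(name, m)
    out.meta["anatomy"] = p
    out.meta["seed"] = int(seed)
    out.meta["loop_center_mm"] = tuple(float(v) for v in center)
    out.validate()
    return out


def wall_thickness_stats(s: StructureSet) -> Dict[str, float]:
    """Duodenal wall thickness measured by distance transforms.

    For each wall voxel the thickness sample is the distance to the tube
    exterior plus the distance to the lumen; voxel-center quantisation
    biases the sum upward by about one voxel, which is subtracted.
    """
    grid = s.grid
    tube = s["duodenum"]
    lumen = s["duodenum_lumen"]
    wall = tube & ~lumen
    if not wall.any():
        raise ValueError("empty duodenal wall")
    d_out = ndimage.distance_transform_edt(tube, sampling=grid.spacing)
    d_in = ndimage.distance_transform_edt(~lumen, sampling=grid.spacing)
    samples = (d_out + d_in)[wall] - float(np.mean(grid.spacing))
    return {
        "median_mm": float(np.median(samples)),
        "p10_mm": float(np.percentile(samples, 10)),
        "p90_mm": float(np.percentile(samples, 90)),
    }


# ---------------------------------------------------------------------------
# spacer placement
# ---------------------------------------------------------------------------

def place_virtual_spacer(
    s: StructureSet,
    scenario: SpacerScenario,
    max_shell_mm: float = 18.0,
    hop_reach_mm: float = 32.0,
) -> StructureSet:
    """Place the virtual spacer in the para-duodenal space.

    The spacer forms lens-shaped pockets hugging the inner (target-facing)
    duodenal wall of the scenario's interface sections: candidate voxels
    are ranked by distance to the duodenum, so each pocket grows from the
    interface outward until the requested per-section volume is reached.
    The returned mask is disjoint from every organ; it is the spacer's
    configuration before any tissue deformation (the insertion solve is the
    fem module's job).
    """
    if not scenario.sections:
        raise ValueError("S0 has no spacer to place")
    grid = s.grid
    duo = s["duodenum"]
    d_duo, idx = ndimage.distance_transform_edt(
        ~duo, sampling=grid.spacing, return_indices=True
    )
    d_hop = ndimage.distance_transform_edt(~s["HOP"], sampling=grid.spacing)

    organs = duo | s["HOP"] | s["stomach"] | s["bowel"] | s["GTV"]

    coords = grid.dense_coordinates()
    center = np.asarray(
        s.meta.get("loop_center_mm", s.centroid_mm("HOP")), dtype=float
    )
    r_vox = np.hypot(coords[..., 0] - center[0], coords[..., 1] - center[1])
    nearest_xy = np.stack(
        [
            grid.origin[0] + idx[0] * grid.spacing[0],
            grid.origin[1] + idx[1] * grid.spacing[1],
        ],
        axis=-1,
    )
    r_wall = np.hypot(nearest_xy[..., 0] - center[0], nearest_xy[..., 1] - center[1])
    inner_side = r_vox < r_wall  # voxel radially inside its nearest wall point

    # assign candidate voxels to the duodenal section of their nearest wall voxel
    section_id = np.zeros(grid.shape, dtype=np.int8)
    for i, name in enumerate(("D1", "D2", "D3", "D4"), start=1):
        section_id[s[name]] = i
    owner = section_id[tuple(idx)]

    candidates = (
        (d_duo > 0)
        & (d_duo <= max_shell_mm)
        & (d_hop <= hop_reach_mm)
        & inner_side
        & ~organs
    )

    voxvol_ml = grid.voxel_volume_cc
    n_per_section = int(np.floor(scenario.per_section_volume_ml / voxvol_ml))
    spacer = np.zeros(grid.shape, dtype=bool)
    section_masks: Dict[str, np.ndarray] = {}
    for group in scenario.sections:
        ids = [("D1", "D2", "D3", "D4").index(x) + 1 for x in SECTION_GROUPS[group]]
        cand = candidates & np.isin(owner, ids)
        order = np.argsort(d_duo[cand], kind="stable")
        avail = order.size
        if avail < n_per_section:
            raise SpacerPlacementError(
                f"section {group}: requested {scenario.per_section_volume_ml:.1f} ml "
                f"but only {avail * voxvol_ml:.1f} ml available"
            )
        sel_flat = np.flatnonzero(cand.ravel())[order[:n_per_section]]
        m = np.zeros(grid.shape, dtype=bool)
        m.ravel()[sel_flat] = True
        # keep the pocket a single lens: drop stray disconnected crumbs
        labels, ncomp = ndimage.label(m)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
            m = labels == (1 + int(np.argmax(sizes)))
        section_masks[group] = m
        spacer |= m

    out = s.copy()
    out.add("spacer", spacer)
    out.meta["spacer_scenario"] = scenario.label
    out.meta["spacer_sections"] = section_masks
    out.meta["spacer_volume_ml"] = {
        g: float(m.sum() * voxvol_ml) for g, m in section_masks.items()
    }
    return out


# ---------------------------------------------------------------------------
# synthetic dose
# ---------------------------------------------------------------------------

#: fixed length scale of the in-target hotspot ramp (mm); independent of the
#: exterior falloff so that changing `falloff_mm` does not alter the
#: coverage-scaling factor.
HOTSPOT_SCALE_MM = 5.0


def synthesize_dose(
    s: StructureSet,
    prescription: float = 33.0,
    fractions: int = 5,
    falloff_mm: float = 5.0,
    seed: int = 0,
    noise_amp: float = 0.0,
    hotspot_frac: float = 0.10,
    scale: bool = True,
) -> DoseGrid:
    """Distance-falloff stand-in for an optimized SBRT plan.

    Let ``sd`` be the signed Euclidean distance to the PTV surface
    (negative inside).  The profile is ``prescription`` at the surface,
    ramps to ``(1 + hotspot_frac) * prescription`` deep inside, and decays
    as ``exp(-sd / falloff_mm)`` outside.  Optional multiplicative seeded
    noise emulates plan-to-plan variability.  When ``scale`` is true the
    result is rescaled so PTV V33Gy lies in the (95%, 96%) band.
    """
    if falloff_mm <= 0:
        raise ValueError("falloff_mm must be > 0")
    ptv = s["PTV"]
    if not ptv.any():
        raise ValueError("PTV is empty")
    grid = s.grid
    sd = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing) - \
        ndimage.distance_transform_edt(ptv, sampling=grid.spacing)
    # light smoothing: sub-voxel continuity (real dose gradients are smooth)
    # and no large tie blocks at quantized EDT values, so coverage scaling
    # can always cut inside its band
    sd = ndimage.gaussian_filter(sd, sigma=0.7)
    dose = np.where(
        sd > 0,
        prescription * np.exp(-np.maximum(sd, 0.0) / falloff_mm),
        prescription * (1.0 + hotspot_frac * (1.0 - np.exp(np.minimum(sd, 0.0) / HOTSPOT_SCALE_MM))),
    )
    if noise_amp > 0:
        rng = np.random.default_rng(seed)
        g = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=1.5)
        g /= max(g.std(), 1e-12)
        dose = np.clip(dose * (1.0 + noise_amp * g), 0.0, None)
    dg = DoseGrid(grid=grid, dose=dose, prescription=prescription, fractions=fractions)
    dg.meta["falloff_mm"] = falloff_mm
    dg.meta["noise_amp"] = noise_amp
    if scale:
        from .dosimetry import scale_to_coverage

        dg = scale_to_coverage(dg, ptv)
    return dg
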