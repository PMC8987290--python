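"""Quasi-static linear-elastic simulation of hydrogel spacer insertion.

The spacer is modelled as a rigid surface translated in increments from an
initial position tangent to the organ surfaces toward its final location.
Organ nodes that penetrate the advancing surface receive Dirichlet
displacements projecting them back onto it (projection contact); the
anatomical node sets tagged by :mod:`spacersim.meshing` are held fixed.
Each increment solves the constrained small-strain isotropic elasticity
system exactly (constant-strain 4-node tetrahedra, direct sparse solve).
The node displacements are rasterized to a deformation vector field (DVF)
and applied to the structure masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree
from scipy.interpolate import LinearNDInterpolator

from .grid import GridMismatchError, StructureSet, VoxelGrid
from .meshing import TetModel, points_inside

__all__ = [
    "Material",
    "MaterialTable",
    "DEFAULT_MATERIALS",
    "InsertionPlan",
    "DeformationField",
    "FEMError",
    "assemble_stiffness",
    "solve_dirichlet",
    "solve_insertion",
    "displacements_to_dvf",
    "warp_structures",
]


class FEMError(RuntimeError):
    pass


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic tissue parameters."""

    youngs_kpa: float
    poisson: float

    def __post_init__(self) -> None:
        if self.youngs_kpa <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")

    @property
    def lame(self) -> Tuple[float, float]:
        e, nu = self.youngs_kpa, self.poisson
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


MaterialTable = Dict[str, Material]

# Soft-tissue placeholders (configurable, not literature claims): the
# hydrogel itself is treated as a rigid moving boundary, not meshed.
DEFAULT_MATERIALS: MaterialTable = {
    "duodenum_wall": Material(5.0, 0.45),
    "HOP": Material(10.0, 0.45),
    "tissue": Material(5.0, 0.45),
    # soft, nearly incompressible luminal contents: lets the tube deform
    # without its cross-section collapsing
    "lumen_content": Material(1.0, 0.49),
}


@dataclass
class InsertionPlan:
    """One spacer component's insertion trajectory.

    ``spacer_surface`` sits at the final target position; the initial
    position is ``travel_mm`` back along ``approach_vector`` and must be
    tangent to (not penetrating) the organ surfaces.
    """

    spacer_surface: trimesh.Trimesh
    approach_vector: np.ndarray
    travel_mm: float
    n_steps: int = 10

    def __post_init__(self) -> None:
        v = np.asarray(self.approach_vector, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("approach_vector must be nonzero")
        self.approach_vector = v / n
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.travel_mm < 0:
            raise ValueError("travel_mm must be >= 0")


@dataclass
class DeformationField:
    """Per-voxel displacement in mm, zero on the grid border."""

    grid: VoxelGrid
    displacement: np.ndarray  # shape (*grid.shape, 3)
    cap_mm: float = 25.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float32)
        if self.displacement.shape != (*self.grid.shape, 3):
            raise GridMismatchError("displacement array does not conform to grid")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        mag = self.magnitude_mm()
        if mag.max() > self.cap_mm:
            raise FEMError(
                f"displacement {mag.max():.1f} mm exceeds the {self.cap_mm} mm cap"
            )
        border = np.zeros(self.grid.shape, dtype=bool)
        border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
        if mag[border].max() > 1e-6:
            raise ValueError("displacement must vanish on the grid border")

    def magnitude_mm(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)


# ---------------------------------------------------------------------------
# stiffness assembly
# ---------------------------------------------------------------------------

def _shape_gradients(model: TetModel) -> Tuple[np.ndarray, np.ndarray]:
    """Constant shape-function gradients (m, 4, 3) and tet volumes (m,)."""
    p = model.nodes[model.tets]
    edges = p[:, 1:] - p[:, :1]  # rows e_j = x_{j+1} - x_1
    vol = np.linalg.det(edges) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise FEMError(f"inverted tetrahedron at element {bad}")
    ginv = np.linalg.inv(edges)  # (m,3,3); grad N_{j+1} = ginv[:, :, j]
    grads = np.empty((len(vol), 4, 3))
    grads[:, 1:, :] = np.transpose(ginv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vol


def assemble_stiffness(model: TetModel, materials: MaterialTable = DEFAULT_MATERIALS) -> sparse.csr_matrix:
    """Global stiffness (3n x 3n), symmetric positive semi-definite.

    Small-strain isotropic elasticity with exact constant-strain element
    matrices; before constraints the matrix carries the 6-dimensional
    rigid-body null space.
    """
    grads, vol = _shape_gradients(model)
    lam = np.empty(len(vol))
    mu = np.empty(len(vol))
    for tag in np.unique(model.material_tag):
        name = model.tag_names.get(int(tag), "tissue")
        if name not in materials:
            raise KeyError(f"no material for tissue {name!r}")
        l, m = materials[name].lame
        sel = model.material_tag == tag
        lam[sel], mu[sel] = l, m

    # K[e, a, i, b, j] = V (lam ga_i gb_j + mu ga_j gb_i + mu delta_ij ga.gb)
    gg = np.einsum("eak,ebk->eab", grads, grads)
    ke = (
        lam[:, None, None, None, None] * np.einsum("eai,ebj->eaibj", grads, grads)
        + mu[:, None, None, None, None] * np.einsum("eaj,ebi->eaibj", grads, grads)
        + mu[:, None, None, None, None] * np.einsum("eab,ij->eaibj", gg, np.eye(3))
    )
    ke *= vol[:, None, None, None, None]
    ke = ke.reshape(len(vol), 12, 12)

    dof = (3 * model.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(vol), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * model.n_nodes
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def solve_dirichlet(
    K: sparse.csr_matrix,
    fixed_dof: np.ndarray,
    fixed_val: np.ndarray,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Solve K u = 0 subject to u[fixed] = values; returns the full u."""
    n = K.shape[0]
    u = np.zeros(n)
    fixed_dof = np.asarray(fixed_dof, dtype=np.int64)
    u[fixed_dof] = fixed_val
    free = np.ones(n, dtype=bool)
    free[fixed_dof] = False
    if not free.any():
        return u
    kff = K[free][:, free]
    rhs = -K[free][:, ~free] @ u[~free]
    if np.linalg.norm(rhs) == 0:
        return u
    uf = spsolve(kff.tocsc(), rhs)
    res = np.linalg.norm(kff @ uf - rhs) / np.linalg.norm(rhs)
    if not np.isfinite(res) or res > rtol:
        raise FEMError(f"linear solve did not converge (relative residual {res:.2e})")
    u[free] = uf
    return u


# ---------------------------------------------------------------------------
# insertion solve
# ---------------------------------------------------------------------------

def _closest_on_surface(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    closest, _, _ = trimesh.proximity.closest_point_naive(mesh, points)
    return closest


def strain_energy(K: sparse.csr_matrix, u: np.ndarray) -> float:
    return 0.5 * float(u @ (K @ u))


def solve_insertion(
    duo: TetModel,
    hop: TetModel,
    plan: Union[InsertionPlan, Sequence[InsertionPlan]],
    materials: MaterialTable = DEFAULT_MATERIALS,
    displacement_cap_mm: float = 25.0,
    contact_names: Tuple[str, ...] = ("duodenum",),
) -> Tuple[Dict[str, np.ndarray], Dict[str, object]]:
    """Incremental rigid-spacer insertion against the tagged organ models.

    For every increment each spacer surface advances ``travel / n_steps``
    along its approach vector; organ nodes found inside a spacer are
    assigned Dirichlet displacements projecting them onto the surface,
    the tagged anatomical sets stay pinned at zero, and the constrained
    elastic system is re-solved.  Returns per-model node displacements and
    diagnostics (per-increment strain energies, contact counts).

    Only the models named in ``contact_names`` receive contact conditions:
    by default the gel dissects along the target surface and displaces the
    mobile duodenal wall, while the head of pancreas (held by its fixed
    margins) deforms only through its own constraints.
    """
    plans = [plan] if isinstance(plan, InsertionPlan) else list(plan)
    n_steps = max(p.n_steps for p in plans) if plans else 1

    results: Dict[str, np.ndarray] = {}
    info: Dict[str, object] = {"energy": {}, "contacts": {}}
    for name, model in (("duodenum", duo), ("HOP", hop)):
        K = assemble_stiffness(model, materials)
        fixed_nodes = np.unique(np.concatenate([v for v in model.node_sets.values()]))
        u = np.zeros((model.n_nodes, 3))
        contacted = [np.zeros(model.n_nodes, dtype=bool) for _ in plans]
        energies: List[float] = []
        ncontacts: List[int] = []
        model_plans = plans if name in contact_names else []
        for k in range(1, n_steps + 1):
            # spacer at step k sits `back` behind its final position
            targets: Dict[int, np.ndarray] = {}
            for ip, p in enumerate(model_plans):
                back = max(0.0, (1.0 - k / p.n_steps) * p.travel_mm)
                shift = back * p.approach_vector
                pos = model.nodes + u + shift  # organ nodes in the spacer's final frame
                pen = points_inside(p.spacer_surface, pos)
                contacted[ip] |= pen
                probe = np.flatnonzero(pen)
                if probe.size:
                    proj = _closest_on_surface(p.spacer_surface, pos[probe]) - shift
                    for node, target in zip(probe, proj):
                        node = int(node)
                        # overlapping fronts: the most advanced one wins
                        if node in targets and np.linalg.norm(
                            targets[node] - model.nodes[node]
                        ) >= np.linalg.norm(target - model.nodes[node]):
                            continue
                        targets[node] = target
            # assemble Dirichlet data: anatomical sets pinned, contacts projected
            nodes_c = np.array(sorted(targets), dtype=np.int64)
            vals_c = np.array([targets[i] - model.nodes[i] for i in nodes_c]).reshape(-1, 3) if nodes_c.size else np.zeros((0, 3))
            keep = ~np.isin(nodes_c, fixed_nodes)
            nodes_c, vals_c = nodes_c[keep], vals_c[keep]
            dof = np.concatenate(
                [
                    (3 * fixed_nodes[:, None] + np.arange(3)).ravel(),
                    (3 * nodes_c[:, None] + np.arange(3)).ravel() if nodes_c.size else np.empty(0, np.int64),
                ]
            ).astype(np.int64)
            vals = np.concatenate([np.zeros(3 * fixed_nodes.size), vals_c.ravel()])
            uflat = solve_dirichlet(K, dof, vals)
            u = uflat.reshape(-1, 3)
            energies.append(strain_energy(K, uflat))
            ncontacts.append(int(nodes_c.size))
        mag = np.linalg.norm(u, axis=1)
        if mag.max() > displacement_cap_mm:
            raise FEMError(
                f"{name}: displacement {mag.max():.1f} mm exceeds cap {displacement_cap_mm} mm"
            )
        results[name] = u
        info["energy"][name] = energies
        info["contacts"][name] = ncontacts
    return results, info


# ---------------------------------------------------------------------------
# DVF rasterization and structure warping
# ---------------------------------------------------------------------------

def _model_interpolate(
    model: TetModel, u: np.ndarray, pts: np.ndarray, nearest: np.ndarray
) -> np.ndarray:
    """Barycentric interpolation restricted to the model's own tets.

    A Delaunay triangulation of the node cloud also contains sliver
    simplices spanning concavities (the lumen of a hollow organ); values
    interpolated there would blend opposite walls.  Points outside the
    kept tets therefore take their nearest node's displacement instead.
    """
    from scipy.spatial import Delaunay

    tri = Delaunay(model.nodes)
    kept = np.zeros(len(tri.simplices), dtype=bool)
    model_keys = np.sort(model.tets, axis=1)
    order = np.lexsort(model_keys.T[::-1])
    sorted_keys = model_keys[order]
    tri_keys = np.sort(tri.simplices, axis=1)
    pos = np.searchsorted(
        sorted_keys.view([("", sorted_keys.dtype)] * 4).ravel(),
        tri_keys.view([("", tri_keys.dtype)] * 4).ravel(),
    )
    pos = np.clip(pos, 0, len(sorted_keys) - 1)
    kept = np.all(sorted_keys[pos] == tri_keys, axis=1)

    out = u[nearest].astype(float)
    simp = tri.find_simplex(pts)
    ok = (simp >= 0) & kept[np.clip(simp, 0, None)]
    if ok.any():
        si = simp[ok]
        T = tri.transform[si]  # (n, 4, 3)
        b3 = np.einsum("nij,nj->ni", T[:, :3, :], pts[ok] - T[:, 3, :])
        bary = np.concatenate([b3, 1.0 - b3.sum(axis=1, keepdims=True)], axis=1)
        verts = tri.simplices[si]
        out[ok] = np.einsum("ni,nij->nj", bary, u[verts])
    return out


def displacements_to_dvf(
    models: Sequence[Tuple[TetModel, np.ndarray]],
    grid: VoxelGrid,
    falloff_scale_mm: float = 10.0,
    cutoff_mm: float = 30.0,
    cap_mm: float = 25.0,
    regions: Optional[Sequence[Optional[np.ndarray]]] = None,
) -> DeformationField:
    """Rasterize node displacements to a voxel deformation field.

    Inside the meshed regions the field is the barycentric (piecewise
    linear) interpolation of the node displacements; away from the meshes
    it decays exponentially with distance (scale ``falloff_scale_mm``) and
    is exactly zero beyond ``cutoff_mm``.  ``regions`` optionally gives a
    binary mask per model claiming its voxels outright (e.g. the full tube
    for the hollow wall model), which keeps one organ's motion from
    bleeding into its neighbor across a thin gap.
    """
    all_nodes = np.vstack([m.nodes for m, _ in models])
    if not all(np.all(np.isfinite(u)) for _, u in models):
        raise ValueError("node displacements must be finite")

    out = np.zeros((*grid.shape, 3), dtype=np.float32)
    hmax = max(m.mean_edge_mm for m, _ in models)
    lo = all_nodes.min(axis=0) - (cutoff_mm + hmax)
    hi = all_nodes.max(axis=0) + (cutoff_mm + hmax)
    ilo = np.maximum(np.floor(grid.world_to_index(lo)[0]).astype(int), 1)
    ihi = np.minimum(np.ceil(grid.world_to_index(hi)[0]).astype(int), np.asarray(grid.shape) - 2)
    if np.any(ihi <= ilo):
        return DeformationField(grid=grid, displacement=out, cap_mm=cap_mm)
    axes = [np.arange(ilo[i], ihi[i] + 1) for i in range(3)]
    sub = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid.index_to_world(sub)

    # Interpolate each model independently and assign every voxel to its
    # nearest model; this prevents interpolation simplices from bridging
    # the thin gap between organs (which would drag the fixed target with
    # the moving wall).
    best_d = np.full(len(pts), np.inf)
    vals = np.zeros((len(pts), 3))
    claimed = np.zeros(len(pts), dtype=bool)
    region_list = list(regions) if regions is not None else [None] * len(models)
    for (model, u), region in zip(models, region_list):
        u = np.asarray(u, dtype=float)
        d, j = cKDTree(model.nodes).query(pts, workers=-1)
        v = _model_interpolate(model, u, pts, nearest=j)
        if region is not None:
            own = grid.check_mask(region)[sub[:, 0], sub[:, 1], sub[:, 2]]
            vals[own] = v[own]
            best_d[own] = 0.0
            claimed |= own
        closer = (d < best_d) & ~claimed
        vals[closer] = v[closer]
        best_d[closer] = d[closer]

    w = np.ones(len(pts))
    far = best_d > hmax
    w[far] = np.exp(-(best_d[far] - hmax) / falloff_scale_mm)
    w *= np.clip((cutoff_mm - best_d) / (0.2 * cutoff_mm), 0.0, 1.0)
    vals *= w[:, None]

    out[sub[:, 0], sub[:, 1], sub[:, 2]] = vals
    return DeformationField(grid=grid, displacement=out, cap_mm=cap_mm)


def sample_dvf_mm(dvf: DeformationField, points: np.ndarray) -> np.ndarray:
    """Trilinear sample of the DVF (mm) at world points."""
    ijk = dvf.grid.world_to_index(points).T
    return np.stack(
        [
            ndimage.map_coordinates(dvf.displacement[..., c], ijk, order=1, mode="constant")
            for c in range(3)
        ],
        axis=-1,
    )


def _backward_coordinates(
    dvf: DeformationField,
    n_bulk: int = 15,
    n_refine: int = 200,
    damping: float = 0.25,
    tol_vox: float = 0.02,
) -> np.ndarray:
    """Damped fixed-point inversion of the forward DVF (index units).

    Solves y + u(y) = x per voxel.  Damping keeps the iteration
    contractive where the field is strongly stretched (displacement
    gradients above one, e.g. the squeezed gap in front of the spacer);
    compressed zones converge slowly, so after ``n_bulk`` full-grid sweeps
    the iteration continues only on the voxels whose residual still
    exceeds ``tol_vox`` — typically a thin shell around the moving wall.
    """
    sp = np.asarray(dvf.grid.spacing)
    disp_idx = (dvf.displacement / sp).astype(np.float32)  # mm -> index units

    def sample(y):
        return np.stack(
            [
                ndimage.map_coordinates(disp_idx[..., c], y, order=1, mode="constant")
                for c in range(3)
            ],
            axis=0,
        )

    base = np.stack(
        np.meshgrid(*[np.arange(n) for n in dvf.grid.shape], indexing="ij"), axis=0
    ).astype(np.float32)
    y = base.copy()
    for _ in range(n_bulk):
        y = y + damping * (base - y - sample(y))

    flat_y = y.reshape(3, -1)
    flat_x = base.reshape(3, -1)
    res = np.abs(flat_x - flat_y - sample(y).reshape(3, -1)).max(axis=0)
    active = np.flatnonzero(res > tol_vox)
    for _ in range(n_refine):
        if active.size == 0:
            break
        ya = flat_y[:, active]
        d = np.stack(
            [
                ndimage.map_coordinates(disp_idx[..., c], ya, order=1, mode="constant")
                for c in range(3)
            ],
            axis=0,
        )
        r = flat_x[:, active] - ya - d
        flat_y[:, active] = ya + damping * r
        still = np.abs(r).max(axis=0) > tol_vox
        active = active[still]
    return flat_y.reshape(y.shape)


def warp_structures(
    s: StructureSet,
    dvf: DeformationField,
    spacer_final: Optional[np.ndarray] = None,
    fields: Optional[Mapping[str, Optional[DeformationField]]] = None,
) -> StructureSet:
    """Apply the deformation field to a structure set.

    Masks are resampled through the inverted field (voxel-wise backward
    warp with damped fixed-point inversion of the forward DVF); duodenal
    sections are re-partitioned from the warped duodenum so they stay
    disjoint with union equal to the tube.  ``fields`` optionally assigns
    individual structures their own organ model's field — each organ then
    moves with its own tissue and the space vacated in front of a pushed
    wall is not back-filled from its unmoved neighbor.  When
    ``spacer_final`` is given it is inserted (minus the warped organs) as
    the ``spacer`` mask.
    """
    if not s.grid.same_as(dvf.grid):
        raise GridMismatchError("structure set and DVF grids differ")
    fields = dict(fields or {})
    cache: Dict[int, Optional[np.ndarray]] = {}

    def backward(field: DeformationField) -> Optional[np.ndarray]:
        key = id(field)
        if key not in cache:
            if np.abs(field.displacement).max() < 1e-9:
                cache[key] = None  # identity
            else:
                cache[key] = _backward_coordinates(field)
        return cache[key]

    def resample(mask: np.ndarray, name: str) -> np.ndarray:
        field = fields.get(name, dvf)
        if field is None:
            return mask.astype(np.float32)
        y = backward(field)
        if y is None:
            return mask.astype(np.float32)
        return ndimage.map_coordinates(mask.astype(np.float32), y, order=1, mode="constant")

    out = s.copy()
    sections = ("D1", "D2", "D3", "D4")
    for name in s.names():
        if name in sections or name == "spacer":
            continue
        out.masks[name] = resample(s[name], name) > 0.5

    duo = out.masks["duodenum"]
    sect_fields = np.stack([resample(s[n], "duodenum") for n in sections])
    label = np.argmax(sect_fields, axis=0)
    for i, name in enumerate(sections):
        out.masks[name] = duo & (label == i)

    if spacer_final is not None:
        organs = duo | out["HOP"] | out["stomach"] | out["bowel"] | out["GTV"]
        out.add("spacer", s.grid.check_mask(spacer_final) & ~organs)
    out.meta["warped"] = True
    return out
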