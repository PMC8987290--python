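"""NIfTI and JSON I/O for masks, dose grids, deformation fields and models.

Conventions: arrays are indexed (x, y, z); the NIfTI affine is the
axis-aligned diagonal ``diag(spacing) + origin`` (RAS, world mm).  Oblique
or negatively-scaled affines are rejected rather than silently
reinterpreted — the pipeline only defines axis-aligned grids.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from .grid import DoseGrid, StructureSet, VoxelGrid
from .fem import DeformationField

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "read_structure_set",
    "write_structure_set",
    "read_dvf",
    "write_dvf",
]

#: precedence for the convenience label map (overlapping target volumes
#: are resolved innermost-last; per-structure binaries are authoritative)
LABEL_ORDER = (
    "bowel",
    "stomach",
    "duodenum",
    "D1",
    "D2",
    "D3",
    "D4",
    "PTV",
    "GTV_multabc",
    "HOP",
    "GTV",
    "spacer",
)


class AffineError(ValueError):
    """Non-axis-aligned (oblique) or mirrored affine."""


def _affine(grid: VoxelGrid) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = np.diag(grid.spacing)
    a[:3, 3] = grid.origin
    return a


def _grid_from_affine(affine: np.ndarray, shape: Tuple[int, ...]) -> VoxelGrid:
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise AffineError(
            "oblique affine: only axis-aligned grids are supported "
            f"(rotation block {rot.tolist()})"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise AffineError(f"affine has non-positive scales {spacing.tolist()}")
    return VoxelGrid(shape=tuple(shape[:3]), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def write_mask(path: Path, mask: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(grid.check_mask(mask).astype(np.uint8), _affine(grid))
    nib.save(img, str(path))


def read_mask(path: Path) -> Tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return np.asarray(img.dataobj).astype(bool), grid


def write_dose(path: Path, dose: DoseGrid) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float32), _affine(dose.grid))
    img.header["descrip"] = f"Gy; Rx {dose.prescription:g}Gy/{dose.fractions}fx".encode()
    nib.save(img, str(path))


def read_dose(path: Path, prescription: float = 33.0, fractions: int = 5) -> DoseGrid:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return DoseGrid(
        grid=grid,
        dose=np.asarray(img.dataobj, dtype=np.float64),
        prescription=prescription,
        fractions=fractions,
    )


def write_dvf(path: Path, dvf: DeformationField) -> None:
    img = nib.Nifti1Image(dvf.displacement.astype(np.float32), _affine(dvf.grid))
    img.header["descrip"] = b"displacement mm, world axes"
    nib.save(img, str(path))


def read_dvf(path: Path, cap_mm: float = 25.0) -> DeformationField:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return DeformationField(
        grid=grid, displacement=np.asarray(img.dataobj, dtype=np.float32), cap_mm=cap_mm
    )


def write_structure_set(out_dir: Path, s: StructureSet) -> None:
    """Per-structure binary NIfTIs plus a convenience label map and index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = sorted(s.names())
    for name in names:
        write_mask(out_dir / f"{name}.nii.gz", s[name], s.grid)
    label = np.zeros(s.grid.shape, dtype=np.uint8)
    labels: Dict[str, int] = {}
    nxt = 1
    for name in LABEL_ORDER:
        if name in s:
            label[s[name]] = nxt
            labels[name] = nxt
            nxt += 1
    nib.save(nib.Nifti1Image(label, _affine(s.grid)), str(out_dir / "labels.nii.gz"))
    meta = {
        "structures": names,
        "label_values": labels,
        "spacing_mm": list(s.grid.spacing),
        "origin_mm": list(s.grid.origin),
        "shape": list(s.grid.shape),
        "scenario": s.meta.get("spacer_scenario"),
        "seed": s.meta.get("seed"),
        "loop_center_mm": s.meta.get("loop_center_mm"),
    }
    (out_dir / "structures.json").write_text(json.dumps(meta, indent=2))


def read_structure_set(out_dir: Path) -> StructureSet:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "structures.json").read_text())
    masks = {}
    grid: Optional[VoxelGrid] = None
    for name in meta["structures"]:
        mask, g = read_mask(out_dir / f"{name}.nii.gz")
        if grid is None:
            grid = g
        elif not grid.same_as(g):
            raise ValueError(f"structure {name} is on a different grid")
        masks[name] = mask
    s = StructureSet(grid=grid, masks=masks)
    if meta.get("loop_center_mm"):
        s.meta["loop_center_mm"] = tuple(meta["loop_center_mm"])
    if meta.get("seed") is not None:
        s.meta["seed"] = meta["seed"]
    return s


# ---------------------------------------------------------------------------
# DSS model persistence
# ---------------------------------------------------------------------------

def save_dss_models(path: Path, nn, threshold, bayes, thin_to: int = 2000) -> None:
    """Persist the trained decision models as one JSON file.

    The network is stored as raw layer weights plus the input scaler;
    posterior draws are thinned to ``thin_to`` for file size (the full
    chain can be regenerated from the cohort with the stored seed).
    """
    scaler = nn.pipeline.named_steps["standardscaler"]
    mlp = nn.pipeline.named_steps["mlpregressor"]
    step = max(1, bayes.n_draws // thin_to)
    payload = {
        "nn": {
            "scaler_mean": scaler.mean_.tolist(),
            "scaler_scale": scaler.scale_.tolist(),
            "coefs": [w.tolist() for w in mlp.coefs_],
            "intercepts": [b.tolist() for b in mlp.intercepts_],
            "activation": mlp.activation,
            "train_rmse_gy": nn.train_rmse_gy,
            "test_rmse_gy": nn.test_rmse_gy,
            "seed": nn.seed,
        },
        "threshold": {
            "intercept": threshold.intercept,
            "slope": threshold.slope,
            "cov_params": threshold.cov_params.tolist(),
            "dof": threshold.dof,
            "r_squared": threshold.r_squared,
            "usable": threshold.usable,
        },
        "bayes": {
            "beta_draws": bayes.beta_draws[::step].tolist(),
            "sigma2_draws": bayes.sigma2_draws[::step].tolist(),
            "n_obs": bayes.n_obs,
            "seed": bayes.seed,
        },
    }
    Path(path).write_text(json.dumps(payload))


class _RawNN:
    """Minimal forward pass over stored layer weights."""

    def __init__(self, d: Dict):
        self.mean = np.asarray(d["scaler_mean"])
        self.scale = np.asarray(d["scaler_scale"])
        self.coefs = [np.asarray(w) for w in d["coefs"]]
        self.intercepts = [np.asarray(b) for b in d["intercepts"]]
        if d["activation"] != "relu":
            raise ValueError("only relu networks are persisted")

    def predict(self, x: np.ndarray) -> np.ndarray:
        h = (np.atleast_2d(x) - self.mean) / self.scale
        for w, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return (h @ self.coefs[-1] + self.intercepts[-1]).ravel()


def load_dss_models(path: Path):
    """Load models saved by :func:`save_dss_models`."""
    from .dss import BayesianSpacerModel, NNMaxBEDModel, ThresholdModel

    d = json.loads(Path(path).read_text())
    nn = NNMaxBEDModel(
        pipeline=_RawNN(d["nn"]),
        train_rmse_gy=d["nn"]["train_rmse_gy"],
        test_rmse_gy=d["nn"]["test_rmse_gy"],
        seed=d["nn"]["seed"],
    )
    t = d["threshold"]
    threshold = ThresholdModel(
        intercept=t["intercept"],
        slope=t["slope"],
        cov_params=np.asarray(t["cov_params"]),
        dof=t["dof"],
        r_squared=t["r_squared"],
        usable=t["usable"],
    )
    b = d["bayes"]
    bayes = BayesianSpacerModel(
        beta_draws=np.asarray(b["beta_draws"]),
        sigma2_draws=np.asarray(b["sigma2_draws"]),
        n_obs=b["n_obs"],
        seed=b["seed"],
    )
    return nn, threshold, bayes
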