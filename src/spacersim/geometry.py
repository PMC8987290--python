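"""Separation metrics between target and organs at risk.

Three figures of merit quantify the target–duodenum geometry:

* **DSC** — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``.
* **OVH** — overlap volume histogram: the cumulative OAR volume within
  each uniform expansion distance of the target.  The scalar summaries
  ``L_vcc`` (v in {1, 3, 5, 10, 20} cc) are the smallest expansion at
  which v cc of the OAR is overlapped; negative when the structures
  already overlap.
* **RNND** — radial nearest-neighbor distance: margins of both structures
  are binned by planar azimuth about the superior–inferior axis through an
  anatomical origin, and within each bin the nearest-neighbor distances
  from one margin to the other are summarised by their mean and 5th
  percentile.

A paired sign-flip permutation test supports the scenario comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridMismatchError, StructureSet, VoxelGrid

__all__ = [
    "OVHCurve",
    "RNNDProfile",
    "dsc",
    "extract_margin",
    "ovh",
    "rnnd",
    "duodenal_rnnd",
    "normalize_profiles",
    "paired_permutation_test",
]

DEFAULT_OVH_VOLUMES_CC = (1.0, 3.0, 5.0, 10.0, 20.0)


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on the same grid.

    Returns NaN (the defined "undefined" value) when both masks are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return float("nan")
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


def extract_margin(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """World coordinates (N, 3) of margin voxels of a mask.

    A margin voxel is a mask voxel with at least one face neighbor outside
    the mask (voxels on the array border count as margin).
    """
    mask = grid.check_mask(mask)
    if not mask.any():
        raise ValueError("cannot extract the margin of an empty mask")
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    margin_idx = np.argwhere(mask & ~interior)
    return grid.index_to_world(margin_idx)


@dataclass
class OVHCurve:
    """Overlap volume histogram between a target and one OAR."""

    distances_mm: np.ndarray
    overlap_cc: np.ndarray
    thresholds_mm: Dict[float, Optional[float]]
    oar_volume_cc: float

    def threshold(self, v_cc: float) -> Optional[float]:
        """L_vcc in mm, or None when the OAR is smaller than v cc."""
        return self.thresholds_mm[float(v_cc)]


def target_signed_distance(target: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Signed Euclidean distance to the target surface (negative inside)."""
    target = grid.check_mask(target)
    if not target.any():
        raise ValueError("empty target mask")
    return ndimage.distance_transform_edt(~target, sampling=grid.spacing) - \
        ndimage.distance_transform_edt(target, sampling=grid.spacing)


def ovh(
    target: np.ndarray,
    oar: np.ndarray,
    grid: VoxelGrid,
    volumes_cc: Sequence[float] = DEFAULT_OVH_VOLUMES_CC,
    sd: Optional[np.ndarray] = None,
) -> OVHCurve:
    """Overlap volume histogram via the signed Euclidean distance transform.

    Each OAR voxel is assigned its signed distance to the target (negative
    inside); ``overlap_cc(t)`` is the OAR volume at distance <= t.  The
    curve is sampled at half the minimum voxel spacing and each L_vcc is
    the smallest sampled distance whose overlap reaches v cc.  ``sd`` may
    carry a precomputed :func:`target_signed_distance` for the same
    target to avoid repeating the transform across OARs.
    """
    target = grid.check_mask(target)
    oar = grid.check_mask(oar)
    if not target.any() or not oar.any():
        raise ValueError("ovh requires nonempty target and OAR masks")
    if sd is None:
        sd = target_signed_distance(target, grid)
    d_oar = np.sort(sd[oar])
    voxvol = grid.voxel_volume_cc
    total = d_oar.size * voxvol

    step = min(grid.spacing) / 2.0
    lo = np.floor(d_oar[0] / step) * step
    hi = np.ceil(d_oar[-1] / step) * step
    distances = np.arange(lo, hi + step / 2, step)
    counts = np.searchsorted(d_oar, distances, side="right")
    overlap = counts * voxvol

    thresholds: Dict[float, Optional[float]] = {}
    for v in volumes_cc:
        v = float(v)
        if total < v:
            thresholds[v] = None  # OAR smaller than v cc: undefined, not +inf
            continue
        i = int(np.searchsorted(overlap, v, side="left"))
        thresholds[v] = float(distances[min(i, distances.size - 1)])
    return OVHCurve(
        distances_mm=distances,
        overlap_cc=overlap,
        thresholds_mm=thresholds,
        oar_volume_cc=float(total),
    )


@dataclass
class RNNDProfile:
    """Angle-binned nearest-neighbor distances between two margins."""

    bin_width_deg: float
    bin_centers_deg: np.ndarray
    samples_mm: List[np.ndarray]  # per-bin NND samples (from-margin points)
    mean_mm: np.ndarray  # NaN where empty
    p5_mm: np.ndarray
    empty: np.ndarray  # True where the bin has no usable pair
    origin_mm: np.ndarray
    reference_deg: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.bin_centers_deg.size


def _azimuth_deg(points: np.ndarray, origin: np.ndarray, reference_deg: float) -> np.ndarray:
    rel = np.atleast_2d(points) - np.asarray(origin)
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    return np.mod(ang - reference_deg, 360.0)


def rnnd(
    margin_a: np.ndarray,
    margin_b: np.ndarray,
    origin: np.ndarray,
    bin_width_deg: float = 5.0,
    reference_deg: float = 0.0,
) -> RNNDProfile:
    """Radial nearest-neighbor distance profile.

    Margin points are binned by the azimuth of ``point - origin`` projected
    onto the axial plane, measured from ``reference_deg``.  Within each
    bin, the distance from every a-point to its nearest same-bin b-point
    is collected; the per-bin mean and 5th percentile (linear
    interpolation between order statistics) are reported.  Bins containing
    a-points but no b-points are flagged empty rather than set to zero.
    """
    margin_a = np.atleast_2d(np.asarray(margin_a, float))
    margin_b = np.atleast_2d(np.asarray(margin_b, float))
    if margin_a.size == 0 or margin_b.size == 0:
        raise ValueError("both margins must be nonempty")
    n_bins = int(round(360.0 / bin_width_deg))
    if not np.isclose(n_bins * bin_width_deg, 360.0):
        raise ValueError("bin_width_deg must divide 360")
    origin = np.asarray(origin, dtype=float)

    bin_a = np.minimum((_azimuth_deg(margin_a, origin, reference_deg) / bin_width_deg).astype(int), n_bins - 1)
    bin_b = np.minimum((_azimuth_deg(margin_b, origin, reference_deg) / bin_width_deg).astype(int), n_bins - 1)

    centers = (np.arange(n_bins) + 0.5) * bin_width_deg
    samples: List[np.ndarray] = []
    mean = np.full(n_bins, np.nan)
    p5 = np.full(n_bins, np.nan)
    empty = np.ones(n_bins, dtype=bool)
    for k in range(n_bins):
        pa = margin_a[bin_a == k]
        if pa.size == 0:
            samples.append(np.empty(0))
            continue
        pb = margin_b[bin_b == k]
        if pb.size == 0:
            samples.append(np.empty(0))
            continue
        d, _ = cKDTree(pb).query(pa, workers=-1)
        samples.append(d)
        mean[k] = d.mean()
        p5[k] = np.percentile(d, 5.0)  # linear interpolation
        empty[k] = False
    return RNNDProfile(
        bin_width_deg=float(bin_width_deg),
        bin_centers_deg=centers,
        samples_mm=samples,
        mean_mm=mean,
        p5_mm=p5,
        empty=empty,
        origin_mm=origin,
        reference_deg=float(reference_deg),
    )


def duodenal_rnnd(
    s: StructureSet,
    from_structure: str = "duodenum",
    to_structure: str = "HOP",
    bin_width_deg: float = 5.0,
) -> RNNDProfile:
    """RNND between the duodenal and target margins in anatomical frame.

    The origin is the centroid of the full duodenal loop (so the C-loop
    wraps the origin and the profile spans 0-360 degrees) and 0 deg points
    toward the D1 centroid, the section adjacent to the stomach, which
    stays relatively fixed.
    """
    origin = s.centroid_mm("duodenum")
    d1 = s.centroid_mm("D1")
    ref = float(np.degrees(np.arctan2(d1[1] - origin[1], d1[0] - origin[0])))
    ma = extract_margin(s[from_structure], s.grid)
    mb = extract_margin(s[to_structure], s.grid)
    return rnnd(ma, mb, origin=origin, bin_width_deg=bin_width_deg, reference_deg=ref)


def section_bins(s: StructureSet, profile: RNNDProfile, section: str) -> np.ndarray:
    """Indices of profile bins covered by one duodenal section's margin."""
    pts = extract_margin(s[section], s.grid)
    b = np.minimum(
        (
            _azimuth_deg(pts, profile.origin_mm, profile.reference_deg)
            / profile.bin_width_deg
        ).astype(int),
        profile.n_bins - 1,
    )
    return np.unique(b)


def normalize_profiles(
    per_case_samples: Sequence[np.ndarray],
    references: Sequence[float],
) -> np.ndarray:
    """Pool per-case RNND samples after per-case normalization.

    Each case's samples are divided by that case's reference scalar (the
    maximum post-injection RNND of the same case) before pooling, removing
    between-case scale variability.
    """
    if len(per_case_samples) != len(references):
        raise ValueError("one reference per case is required")
    pooled = []
    for samples, ref in zip(per_case_samples, references):
        ref = float(ref)
        if ref <= 0:
            raise ValueError("per-case reference must be > 0")
        pooled.append(np.asarray(samples, float).ravel() / ref)
    return np.concatenate(pooled) if pooled else np.empty(0)


def pooled_histogram(samples: np.ndarray, bins: int = 40) -> Tuple[np.ndarray, np.ndarray]:
    """Unit-mass histogram (density * bin width sums to 1)."""
    hist, edges = np.histogram(samples, bins=bins, density=True)
    return hist, edges


def paired_permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided paired permutation (sign-flip) test on the mean difference.

    The null distribution is generated by random sign flips of the paired
    differences; the p-value uses the add-one estimator
    ``(1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with >= 2 pairs")
    d = x - y
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(int(n_perm), d.size))
    stats = np.abs((signs * d).mean(axis=1))
    return float((1 + np.count_nonzero(stats >= obs - 1e-12)) / (n_perm + 1))
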