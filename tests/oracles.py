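"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the OVH oracles use
morphological dilation and explicit pairwise distances instead of the
signed distance transform, and the RNND oracle is a plain O(N^2) same-bin
search.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def ovh_overlap_by_dilation(target, oar, grid, n_iter):
    """Overlap curve by iterative 1-voxel morphological dilation.

    Alternating 6- and 26-connected structuring elements give an
    octagonal approximation of Euclidean ball growth; agreement with the
    continuous-distance implementation is expected within one voxel
    diagonal.  Returns (expansion_mm, overlap_cc) per iteration.
    """
    cross = ndimage.generate_binary_structure(3, 1)
    full = ndimage.generate_binary_structure(3, 3)
    voxvol = grid.voxel_volume_cc
    step = float(np.mean(grid.spacing))
    cur = target.copy()
    out = [(0.0, np.count_nonzero(cur & oar) * voxvol)]
    for k in range(1, n_iter + 1):
        cur = ndimage.binary_dilation(cur, structure=cross if k % 2 else full)
        out.append((k * step, np.count_nonzero(cur & oar) * voxvol))
    return out


def l_vcc_by_dilation(target, oar, grid, v_cc, n_iter=25):
    """Smallest dilation (mm) at which the overlap reaches v cc."""
    for dist, overlap in ovh_overlap_by_dilation(target, oar, grid, n_iter):
        if overlap >= v_cc:
            return dist
    return None


def ovh_distances_pairwise(target, oar, grid):
    """Exact signed voxel-center distances from OAR voxels to the target
    surface (negative inside), by explicit nearest-neighbor search."""
    from scipy.spatial import cKDTree

    oar_idx = np.argwhere(oar)
    opts = grid.index_to_world(oar_idx)
    tpts = grid.index_to_world(np.argwhere(target))
    d, _ = cKDTree(tpts).query(opts, workers=-1)
    inside = target[tuple(oar_idx.T)]
    if inside.any():
        cpts = grid.index_to_world(np.argwhere(~target))
        din, _ = cKDTree(cpts).query(opts[inside], workers=-1)
        d[inside] = -din
    return d


def rnnd_bruteforce(margin_a, margin_b, origin, bin_width_deg, reference_deg=0.0):
    """O(N^2) same-bin nearest-neighbor search; mirrors the binning rules."""
    n_bins = int(round(360.0 / bin_width_deg))

    def bins(points):
        rel = points - origin
        ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        return np.minimum(
            (np.mod(ang - reference_deg, 360.0) / bin_width_deg).astype(int),
            n_bins - 1,
        )

    ba, bb = bins(margin_a), bins(margin_b)
    mean = np.full(n_bins, np.nan)
    p5 = np.full(n_bins, np.nan)
    for k in range(n_bins):
        pa = margin_a[ba == k]
        pb = margin_b[bb == k]
        if pa.size == 0 or pb.size == 0:
            continue
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min(axis=1)
        mean[k] = d.mean()
        p5[k] = np.percentile(d, 5.0)
    return mean, p5


def exhaustive_signflip_p(diffs):
    """Exact two-sided sign-flip p-value by full enumeration."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    obs = abs(d.mean())
    count = 0
    total = 2 ** n
    for m in range(total):
        signs = np.array([1.0 if (m >> i) & 1 else -1.0 for i in range(n)])
        if abs((signs * d).mean()) >= obs - 1e-12:
            count += 1
    return count / total


def max_bed_grid_search(dose, structures, variant, scale_cap=3.0, step=0.001):
    """Grid-search oracle for the maxBED scale factor."""
    from spacersim import dosimetry

    scales = np.arange(step, scale_cap + step / 2, step)
    best = 0.0
    for s in scales:
        res = dosimetry.check_constraints(
            dose.scaled(s),
            structures,
            dosimetry.DUODENUM_ONLY_CONSTRAINTS
            if variant == "duodenum_only"
            else dosimetry.OAR_CONSTRAINTS,
        )
        if dosimetry.all_pass(res):
            best = s
        else:
            break
    return best
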