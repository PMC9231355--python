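"""Gray-level texture matrix builders (GLCM, GLRLM, GLSZM, NGTDM, GLDM).

All builders work on a :class:`~dosestab.dosiomics.discretize.DiscretizedRoi`
and are fully vectorized.  Conventions:

* 3D, 26-connectivity: the 13 unique direction vectors at Chebyshev
  distance 1 (each paired with its negation for symmetric counts).
* GLCM: symmetric co-occurrence counts per direction, distance 1.
* GLRLM: maximal runs of equal gray level per direction; a masked-out voxel
  breaks a run.
* GLSZM: 26-connected zones of equal gray level, one aggregate matrix.
* NGTDM: per-level sums of |level - mean 26-neighborhood level| over voxels
  with at least one in-mask neighbor.
* GLDM: dependence of a voxel = 1 + number of in-mask 26-neighbors whose
  level differs by at most alpha, so the dependence column index starts at 1
  for an isolated voxel.

Matrices are sized (n_levels, observed maximum) in the run/zone/dependence
dimension; every feature downstream is invariant to trailing empty columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .discretize import DiscretizedRoi

# 13 unique directions covering the 26-neighborhood up to sign.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy, dz) > (0, 0)))
)
assert len(OFFSETS_13) == 13

OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass
class TextureMatrices:
    """The five texture-count structures for one discretized ROI."""

    glcm: np.ndarray  # (13, Ng, Ng) symmetric counts per direction
    glrlm: np.ndarray  # (13, Ng, Lmax) run counts per direction
    glszm: np.ndarray  # (Ng, Smax) zone counts
    ngtdm_s: np.ndarray  # (Ng,) coarseness sums per level
    ngtdm_n: np.ndarray  # (Ng,) voxel counts per level (valid-neighbor voxels)
    gldm: np.ndarray  # (Ng, Dmax) dependence counts
    n_levels: int
    n_voxels: int  # in-mask voxel count


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray):
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def _pair_slices(offset):
    src, dst = [], []
    for d in offset:
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(0, -d if d else None))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(0, d))
    return tuple(src), tuple(dst)


def glcm_stack(droi: DiscretizedRoi) -> np.ndarray:
    levels, mask = _crop_to_mask(droi.levels, droi.mask)
    ng = droi.n_levels
    out = np.zeros((13, ng, ng), dtype=np.int64)
    for d, off in enumerate(OFFSETS_13):
        s_src, s_dst = _pair_slices(off)
        both = mask[s_src] & mask[s_dst]
        if not both.any():
            continue
        a = levels[s_src][both] - 1
        b = levels[s_dst][both] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        out[d] = counts + counts.T  # count each pair in both directions
    return out


# Cache of voxel traversal orders per (shape, direction) for run-length scans.
_ORDER_CACHE: dict = {}


def _direction_order(shape, offset):
    """Permutation that visits voxels line-by-line along ``offset``.

    Returns (order, line_id_sorted): applying ``order`` to a raveled volume
    yields voxels grouped by geometric line along ``offset`` and, within a
    line, in traversal order; ``line_id_sorted`` identifies the line of each
    position in that permuted sequence.
    """
    key = (tuple(shape), tuple(offset))
    cached = _ORDER_CACHE.get(key)
    if cached is not None:
        return cached
    d = np.asarray(offset)
    axis = int(np.nonzero(d)[0][0])
    coords = np.indices(shape)
    if d[axis] == 1:
        k = coords[axis]
    else:
        k = shape[axis] - 1 - coords[axis]
    # Line anchor: project each voxel back k steps along the direction; all
    # voxels of one geometric line share the anchor.  Anchor coordinates can
    # range over [-(k_max), shape-1 + k_max], so offset by k_max per axis to
    # keep the positional encoding collision-free.
    k_max = shape[axis] - 1
    line_id = np.zeros(shape, dtype=np.int64)
    for ax in range(3):
        base = coords[ax] - k * d[ax] + k_max  # in [0, shape[ax]-1 + 2*k_max]
        line_id = line_id * (shape[ax] + 2 * k_max) + base
    order = np.lexsort((k.ravel(), line_id.ravel()))
    result = (order, line_id.ravel()[order])
    _ORDER_CACHE[key] = result
    return result


def glrlm_stack(droi: DiscretizedRoi) -> np.ndarray:
    levels, mask = _crop_to_mask(droi.levels, droi.mask)
    ng = droi.n_levels
    lv_flat = levels.ravel()
    mk_flat = mask.ravel()
    per_dir = []
    max_len = 1
    for off in OFFSETS_13:
        order, line = _direction_order(levels.shape, off)
        lv = lv_flat[order]
        mk = mk_flat[order]
        prev_mk = np.empty_like(mk)
        prev_mk[0] = False
        prev_mk[1:] = mk[:-1]
        same_line = np.empty_like(mk)
        same_line[0] = False
        same_line[1:] = line[1:] == line[:-1]
        same_lv = np.empty_like(mk)
        same_lv[0] = False
        same_lv[1:] = lv[1:] == lv[:-1]
        start = mk & ~(prev_mk & same_line & same_lv)
        n_runs = int(start.sum())
        if n_runs == 0:
            per_dir.append((np.empty(0, np.int64), np.empty(0, np.int64)))
            continue
        rid = np.cumsum(start) - 1
        run_len = np.bincount(rid[mk], minlength=n_runs)
        run_lv = lv[start]
        max_len = max(max_len, int(run_len.max()))
        per_dir.append((run_lv, run_len))
    out = np.zeros((13, ng, max_len), dtype=np.int64)
    for d, (run_lv, run_len) in enumerate(per_dir):
        if run_lv.size:
            np.add.at(out[d], (run_lv - 1, run_len - 1), 1)
    return out


def glszm_matrix(droi: DiscretizedRoi) -> np.ndarray:
    levels, mask = _crop_to_mask(droi.levels, droi.mask)
    ng = droi.n_levels
    n = int(mask.sum())
    node = -np.ones(levels.shape, dtype=np.int64)
    node[mask] = np.arange(n)
    rows, cols = [], []
    for off in OFFSETS_13:
        s_src, s_dst = _pair_slices(off)
        both = mask[s_src] & mask[s_dst] & (levels[s_src] == levels[s_dst])
        if both.any():
            rows.append(node[s_src][both])
            cols.append(node[s_dst][both])
    if rows:
        graph = coo_matrix(
            (np.ones(sum(r.size for r in rows), dtype=np.int8),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    sizes = np.bincount(labels)
    zone_level = np.zeros(labels.max() + 1, dtype=np.int64)
    zone_level[labels] = levels[mask]
    out = np.zeros((ng, int(sizes.max())), dtype=np.int64)
    np.add.at(out, (zone_level - 1, sizes - 1), 1)
    return out


def _neighbor_sums(levels, mask):
    """Per-voxel sum and count of in-mask 26-neighbor levels."""
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        s_src, s_dst = _pair_slices(off)
        both = mask[s_src] & mask[s_dst]
        nb_sum[s_src] += np.where(both, levels[s_dst], 0)
        nb_cnt[s_src] += both
        nb_sum[s_dst] += np.where(both, levels[s_src], 0)
        nb_cnt[s_dst] += both
    return nb_sum, nb_cnt


def ngtdm_table(droi: DiscretizedRoi):
    """Per-level (s_i, n_i) over voxels with >= 1 in-mask 26-neighbor."""
    levels, mask = _crop_to_mask(droi.levels, droi.mask)
    ng = droi.n_levels
    nb_sum, nb_cnt = _neighbor_sums(levels, mask)
    valid = mask & (nb_cnt > 0)
    lv = levels[valid]
    abar = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(lv - abar)
    s = np.bincount(lv - 1, weights=diff, minlength=ng)
    n = np.bincount(lv - 1, minlength=ng).astype(np.int64)
    return s, n


def gldm_matrix(droi: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    levels, mask = _crop_to_mask(droi.levels, droi.mask)
    ng = droi.n_levels
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        s_src, s_dst = _pair_slices(off)
        both = mask[s_src] & mask[s_dst]
        close = both & (np.abs(levels[s_src] - levels[s_dst]) <= alpha)
        dep[s_src] += close
        dep[s_dst] += close
    dep_in = dep[mask] + 1  # isolated voxel -> dependence column 1
    lv = levels[mask]
    out = np.zeros((ng, int(dep_in.max())), dtype=np.int64)
    np.add.at(out, (lv - 1, dep_in - 1), 1)
    return out


def build_texture_matrices(droi: DiscretizedRoi, alpha: int = 0) -> TextureMatrices:
    """Build all five texture-count structures for one discretized ROI."""
    s, n = ngtdm_table(droi)
    return TextureMatrices(
        glcm=glcm_stack(droi),
        glrlm=glrlm_stack(droi),
        glszm=glszm_matrix(droi),
        ngtdm_s=s,
        ngtdm_n=n,
        gldm=gldm_matrix(droi, alpha=alpha),
        n_levels=droi.n_levels,
        n_voxels=int(droi.mask.sum()),
    )
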