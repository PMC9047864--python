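"""Construction of the five gray-level texture matrices.

All matrices are built on the cropped level array of a
:class:`~radrepro.features.discretize.DiscretizedRoi` (0 = outside ROI,
1..N_g inside), with neighbourhoods defined in voxel units: the 26-voxel
neighbourhood at Chebyshev distance 1, reduced to its 13 unique direction
vectors where a direction and its negation are equivalent (GLCM, GLRLM).
No resampling to isotropic voxels is performed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_stack",
    "glrlm_stack",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

# 13 unique 3D directions: one representative of each {d, -d} pair of the
# 26-neighbourhood, in a fixed documented order.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
)

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (d0, d1, d2)
    for d0 in (-1, 0, 1)
    for d1 in (-1, 0, 1)
    for d2 in (-1, 0, 1)
    if (d0, d1, d2) != (0, 0, 0)
)


def _shift_slices(shape, d):
    """Slices (src, dst) so that src indexes voxel p and dst voxel p + d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_stack(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence count matrices, one per direction.

    Returns an array of shape ``(13, n_levels, n_levels)`` of pair counts at
    Chebyshev distance 1 (each pair counted in both orders, i.e. the matrix
    is symmetrized).
    """
    ng = n_levels
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.float64)
    for a, d in enumerate(DIRECTIONS_13):
        src, dst = _shift_slices(levels.shape, d)
        li = levels[src]
        lj = levels[dst]
        ok = (li > 0) & (lj > 0)
        if not ok.any():
            continue
        pairs = (li[ok] - 1) * ng + (lj[ok] - 1)
        counts = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng)
        out[a] = counts + counts.T
    return out


def glrlm_stack(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length count matrices, one per direction.

    ``out[a, i - 1, r - 1]`` is the number of maximal runs of gray level
    ``i`` and length ``r`` along direction ``DIRECTIONS_13[a]``. Voxels
    outside the ROI break runs. The run-length axis has length
    ``max(shape)`` padded to at least 1.
    """
    shape = levels.shape
    max_run = int(np.ceil(np.sqrt(3) * max(shape))) + 1
    ng = n_levels
    out = np.zeros((len(DIRECTIONS_13), ng, max_run), dtype=np.float64)

    coords = np.argwhere(levels > 0)
    if coords.size == 0:
        return out[:, :, :1]
    vals = levels[levels > 0]

    for a, d in enumerate(DIRECTIONS_13):
        dv = np.array(d)
        c = int(np.sum(dv * dv))  # t-step between consecutive voxels on a line
        t = coords @ dv
        # q is constant along a line of direction d and unique per line
        q = coords * c - t[:, None] * dv[None, :]
        order = np.lexsort((t, q[:, 0], q[:, 1], q[:, 2]))
        ts = t[order]
        qs = q[order]
        vs = vals[order]
        # a new run starts where the line changes, the step is broken, or the
        # level changes
        same_line = np.all(qs[1:] == qs[:-1], axis=1) & (ts[1:] - ts[:-1] == c)
        new_run = np.empty(len(vs), dtype=bool)
        new_run[0] = True
        new_run[1:] = ~(same_line & (vs[1:] == vs[:-1]))
        starts = np.flatnonzero(new_run)
        run_len = np.diff(np.append(starts, len(vs)))
        run_lev = vs[starts]
        np.add.at(out[a], (run_lev - 1, run_len - 1), 1.0)
    # trim trailing all-zero run lengths (keep at least one column)
    nz = np.nonzero(out.sum(axis=(0, 1)))[0]
    last = int(nz[-1]) + 1 if nz.size else 1
    return out[:, :, :last]


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix: ``out[i - 1, z - 1]`` = number of
    26-connected zones of gray level ``i`` with ``z`` voxels."""
    structure = np.ones((3, 3, 3), dtype=int)
    ng = n_levels
    rows: list[np.ndarray] = []
    max_zone = 1
    counts_per_level = []
    for lev in range(1, ng + 1):
        blob = levels == lev
        if not blob.any():
            counts_per_level.append(np.zeros(1))
            continue
        lab, n = ndimage.label(blob, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zc = np.bincount(sizes)  # zc[z] = number of zones of size z
        counts_per_level.append(zc)
        max_zone = max(max_zone, len(zc) - 1)
    out = np.zeros((ng, max_zone), dtype=np.float64)
    for i, zc in enumerate(counts_per_level):
        out[i, : len(zc) - 1] = zc[1:]
    return out


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix with 26-neighbourhood and threshold ``alpha``.

    A neighbour is *dependent* iff its absolute level difference is <= alpha;
    the dependence of a voxel is 1 + its number of dependent in-ROI
    neighbours, so ``out[i - 1, j - 1]`` counts ROI voxels of level ``i``
    with dependence ``j`` (j ranges 1..27).
    """
    fg = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        li = levels[src]
        lj = levels[dst]
        hit = (li > 0) & (lj > 0) & (np.abs(li - lj) <= alpha)
        contrib = np.zeros(levels.shape, dtype=np.int64)
        contrib[src] = hit
        dep += contrib
    ng = n_levels
    jmax = int(dep[fg].max()) + 1 if fg.any() else 1
    out = np.zeros((ng, jmax + 1), dtype=np.float64)
    np.add.at(out, (levels[fg] - 1, dep[fg]), 1.0)  # column j-1 = dep
    return out


def ngtdm_table(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Neighbourhood gray-tone difference table.

    Returns an ``(n_levels, 3)`` array with columns ``n_i`` (voxel count of
    level i), ``p_i`` (probability) and ``s_i`` (sum over voxels of level i
    of |i - mean level of its in-ROI 26-neighbours|). Voxels with no in-ROI
    neighbour contribute to ``n_i`` but add 0 to ``s_i``.
    """
    fg = levels > 0
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        li = levels[src]
        lj = levels[dst]
        hit = (li > 0) & (lj > 0)
        add_s = np.zeros(levels.shape, dtype=np.float64)
        add_c = np.zeros(levels.shape, dtype=np.int64)
        add_s[src] = np.where(hit, lj, 0)
        add_c[src] = hit
        nsum += add_s
        ncnt += add_c
    ng = n_levels
    out = np.zeros((ng, 3), dtype=np.float64)
    lv = levels[fg]
    cnt = ncnt[fg]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nb = np.where(cnt > 0, nsum[fg] / np.maximum(cnt, 1), 0.0)
    diff = np.where(cnt > 0, np.abs(lv - mean_nb), 0.0)
    np.add.at(out[:, 0], lv - 1, 1.0)
    np.add.at(out[:, 2], lv - 1, diff)
    total = out[:, 0].sum()
    if total > 0:
        out[:, 1] = out[:, 0] / total
    return out
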