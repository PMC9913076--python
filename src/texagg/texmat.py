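"""Texture-matrix construction and the aggregation algebra.

Six matrix families are built from a :class:`~texagg.image.DiscretizedVOI`:

* GLCM  — grey level co-occurrence (per direction, distance 1)
* GLRLM — grey level run length (per direction)
* GLSZM — grey level size zone (per slice or whole volume)
* GLDZM — grey level distance zone
* NGTDM — neighbourhood grey tone difference (stored as per-grey (n_i, s_i))
* NGLDM — neighbourhood grey level dependence (coarseness alpha = 0)

GLCM/GLRLM support six aggregation methods (2D_averaged, 2D_s_merged,
2.5D_d_merged, 2.5D_merged, 3D_averaged, 3D_merged); the zone and
neighbourhood families support three (2D, 2.5D, 3D).  "Averaged" computes the
feature per unit matrix and takes the unweighted mean over non-empty units;
"merged" sums the count matrices first and computes the feature once.

The grey axis of every matrix spans the full 1..D range of the VOI so that
per-unit matrices are always conformable for merging; feature code masks out
grey levels without mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .image import DiscretizedVOI

__all__ = [
    "Direction",
    "TextureMatrix",
    "directions_2d",
    "directions_3d",
    "glcm_unit",
    "glrlm_unit",
    "glszm_unit",
    "gldzm_unit",
    "ngtdm_unit",
    "ngldm_unit",
    "merge",
    "aggregate",
    "GLCM_GLRLM_METHODS",
    "SINGLE_MATRIX_METHODS",
    "methods_for_family",
]

FAMILIES = ("GLCM", "GLRLM", "GLSZM", "GLDZM", "NGTDM", "NGLDM")

GLCM_GLRLM_METHODS = (
    "2D_averaged",
    "2D_s_merged",
    "2.5D_d_merged",
    "2.5D_merged",
    "3D_averaged",
    "3D_merged",
)
SINGLE_MATRIX_METHODS = ("2D", "2.5D", "3D")


def methods_for_family(family: str) -> tuple[str, ...]:
    """Legal aggregation methods: six for GLCM/GLRLM, three otherwise."""
    if family in ("GLCM", "GLRLM"):
        return GLCM_GLRLM_METHODS
    if family in ("GLSZM", "GLDZM", "NGTDM", "NGLDM"):
        return SINGLE_MATRIX_METHODS
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class Direction:
    """A voxel offset (dz, dy, dx) with Chebyshev norm 1 (distance D = 1)."""

    offset: tuple[int, int, int]

    def __post_init__(self) -> None:
        if max(abs(c) for c in self.offset) != 1:
            raise ValueError("direction must have Chebyshev norm 1")


def directions_2d() -> list[Direction]:
    """The 4 unique in-plane offsets (up to sign): 0, 45, 90, 135 degrees."""
    return [Direction(o) for o in ((0, 0, 1), (0, 1, 1), (0, 1, 0), (0, 1, -1))]


def directions_3d() -> list[Direction]:
    """The 13 unique 3D offsets up to sign (half of the 26 neighbours)."""
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if (dz, dy, dx) > (0, 0, 0):  # lexicographically positive half
                    out.append(Direction((dz, dy, dx)))
    assert len(out) == 13
    return out


@dataclass
class TextureMatrix:
    """A count matrix for one unit (slice and/or direction) of one family.

    ``counts`` rows index grey level 1..D.  The column axis is family
    specific: grey level (GLCM), run length (GLRLM), zone size (GLSZM), zone
    distance (GLDZM), dependence count k+1 (NGLDM).  NGTDM instead stores two
    columns (n_i, s_i).  ``n_voxels`` is the in-ROI voxel count of the unit
    (summed over constituents after merging).
    """

    family: str
    counts: np.ndarray
    n_voxels: int
    empty: bool = False
    unit: tuple = ()

    def total(self) -> float:
        return float(self.counts.sum())


def _shift(a: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """Return array whose voxel x holds a[x + d]; out-of-grid reads give fill."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, di in zip(a.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _unit_arrays(voi: DiscretizedVOI, unit: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Grey and mask arrays for a unit: one axial slice (kept 3D) or the volume."""
    if unit is None:
        return voi.grey, voi.mask
    return voi.grey[unit : unit + 1], voi.mask[unit : unit + 1]


def glcm_unit(voi: DiscretizedVOI, unit: int | None, d: Direction) -> TextureMatrix:
    """Symmetric co-occurrence matrix at distance 1 along ``d``.

    Each ordered in-ROI pair is counted in both orientations; pairs crossing
    the mask boundary are skipped.  A unit with no valid pair along ``d`` is
    flagged empty.
    """
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    g2 = _shift(g, d.offset)
    valid = m & _shift(m, d.offset, fill=False)
    mat = np.zeros((D, D), dtype=np.float64)
    if valid.any():
        a = g[valid] - 1
        b = g2[valid] - 1
        np.add.at(mat, (a, b), 1.0)
        mat += mat.T.copy()
        empty = False
    else:
        empty = True
    return TextureMatrix("GLCM", mat, int(m.sum()), empty, (unit, d.offset))


def glrlm_unit(voi: DiscretizedVOI, unit: int | None, d: Direction) -> TextureMatrix:
    """Run-length matrix along ``d``: counts of maximal constant-grey runs.

    Out-of-mask voxels break runs; an isolated in-ROI voxel is a run of
    length 1.  Empty only when the unit has no in-ROI voxel.
    """
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    n_vox = int(m.sum())
    if n_vox == 0:
        return TextureMatrix("GLRLM", np.zeros((D, 1)), 0, True, (unit, d.offset))
    off = d.offset
    neg = tuple(-c for c in off)
    # has a same-grey in-ROI predecessor along d
    same_prev = m & _shift(m, neg, fill=False) & (g == _shift(g, neg))
    # run length ending at each voxel: L(x) = L(x - d) + 1 where same_prev, else 1
    max_steps = max(
        (n for n, di in zip(g.shape, off) if di != 0), default=1
    )
    L = np.ones(g.shape, dtype=np.int32)
    for _ in range(max_steps):
        Lp = np.where(same_prev, _shift(L, neg) + 1, 1)
        if np.array_equal(Lp, L):
            break
        L = Lp
    # run ends: no same-grey in-ROI successor
    run_end = m & ~(_shift(m, off, fill=False) & (g == _shift(g, off)))
    lengths = L[run_end]
    greys = g[run_end]
    max_len = int(lengths.max())
    mat = np.zeros((D, max_len), dtype=np.float64)
    np.add.at(mat, (greys - 1, lengths - 1), 1.0)
    return TextureMatrix("GLRLM", mat, n_vox, False, (unit, d.offset))


def _zone_labels(g: np.ndarray, m: np.ndarray, structure: np.ndarray):
    """Label connected constant-grey zones; yields (grey, labels, n_zones)."""
    for grey in np.unique(g[m]) if m.any() else []:
        lab, n = ndimage.label((g == grey) & m, structure=structure)
        yield int(grey), lab, n


def _unit_structure(g: np.ndarray) -> np.ndarray:
    # full connectivity: 8-connected in a single 2D slice, 26-connected in 3D
    return np.ones((3, 3, 3), dtype=bool)


def glszm_unit(voi: DiscretizedVOI, unit: int | None) -> TextureMatrix:
    """Size-zone matrix: connected components of constant grey, by (grey, size).

    8-connectivity within a slice, 26-connectivity in 3D.
    """
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    n_vox = int(m.sum())
    if n_vox == 0:
        return TextureMatrix("GLSZM", np.zeros((D, 1)), 0, True, (unit,))
    rows, cols = [], []
    for grey, lab, n in _zone_labels(g, m, _unit_structure(g)):
        sizes = np.bincount(lab.ravel())[1:]
        rows.extend([grey - 1] * n)
        cols.extend(sizes - 1)
    mat = np.zeros((D, max(cols) + 1), dtype=np.float64)
    np.add.at(mat, (np.asarray(rows), np.asarray(cols)), 1.0)
    return TextureMatrix("GLSZM", mat, n_vox, False, (unit,))


def _roi_distance_map(m: np.ndarray) -> np.ndarray:
    """City-block distance to the nearest outside-ROI voxel; border voxels = 1.

    The grid boundary counts as outside the ROI (pad-with-zero convention).
    """
    padded = np.pad(m, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[tuple(slice(1, -1) for _ in m.shape)]


def gldzm_unit(voi: DiscretizedVOI, unit: int | None) -> TextureMatrix:
    """Distance-zone matrix: zones as in GLSZM, column = min distance to ROI edge.

    For a 2D unit the distance map is computed in-plane.
    """
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    n_vox = int(m.sum())
    if n_vox == 0:
        return TextureMatrix("GLDZM", np.zeros((D, 1)), 0, True, (unit,))
    if unit is None:
        dist = _roi_distance_map(m)
    else:
        dist = _roi_distance_map(m[0])[None]
    rows, cols = [], []
    for grey, lab, n in _zone_labels(g, m, _unit_structure(g)):
        dmin = ndimage.minimum(dist, labels=lab, index=np.arange(1, n + 1))
        rows.extend([grey - 1] * n)
        cols.extend(np.atleast_1d(dmin).astype(int) - 1)
    mat = np.zeros((D, max(cols) + 1), dtype=np.float64)
    np.add.at(mat, (np.asarray(rows), np.asarray(cols)), 1.0)
    return TextureMatrix("GLDZM", mat, n_vox, False, (unit,))


def _neighbour_offsets(two_d: bool) -> list[tuple[int, int, int]]:
    offs = []
    for dz in ((0,) if two_d else (-1, 0, 1)):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) != (0, 0, 0):
                    offs.append((dz, dy, dx))
    return offs


def ngtdm_unit(voi: DiscretizedVOI, unit: int | None) -> TextureMatrix:
    """Neighbourhood grey tone difference: per grey i, columns (n_i, s_i).

    n_i counts ROI voxels of grey i having at least one in-ROI Chebyshev-1
    neighbour; s_i sums |i - mean grey of in-ROI neighbours| over them.
    """
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    n_vox = int(m.sum())
    offs = _neighbour_offsets(two_d=unit is not None)
    nb_sum = np.zeros(g.shape, dtype=np.float64)
    nb_cnt = np.zeros(g.shape, dtype=np.float64)
    gm = np.where(m, g, 0).astype(np.float64)
    for off in offs:
        nb_sum += _shift(gm, off)
        nb_cnt += _shift(m, off, fill=False)
    valid = m & (nb_cnt > 0)
    counts = np.zeros((D, 2), dtype=np.float64)
    if not valid.any():
        return TextureMatrix("NGTDM", counts, n_vox, True, (unit,))
    diff = np.abs(g[valid] - nb_sum[valid] / nb_cnt[valid])
    idx = g[valid] - 1
    np.add.at(counts[:, 0], idx, 1.0)
    np.add.at(counts[:, 1], idx, diff)
    return TextureMatrix("NGTDM", counts, n_vox, False, (unit,))


def ngldm_unit(voi: DiscretizedVOI, unit: int | None, alpha: int = 0) -> TextureMatrix:
    """Dependence matrix: k = number of Chebyshev-1 in-ROI neighbours with
    |grey difference| <= alpha (default 0); counts indexed by (grey, k + 1)."""
    g, m = _unit_arrays(voi, unit)
    D = voi.n_bins
    n_vox = int(m.sum())
    if n_vox == 0:
        return TextureMatrix("NGLDM", np.zeros((D, 1)), 0, True, (unit,))
    offs = _neighbour_offsets(two_d=unit is not None)
    k = np.zeros(g.shape, dtype=np.int32)
    for off in offs:
        dep = m & _shift(m, off, fill=False) & (np.abs(g - _shift(g, off)) <= alpha)
        k += dep
    kk = k[m]
    gg = g[m]
    mat = np.zeros((D, int(kk.max()) + 1), dtype=np.float64)
    np.add.at(mat, (gg - 1, kk), 1.0)
    return TextureMatrix("NGLDM", mat, n_vox, False, (unit,))


def merge(matrices: Sequence[TextureMatrix]) -> TextureMatrix:
    """Element-wise sum of count matrices (second axis padded to the widest).

    Empty-flagged units contribute zero counts and zero voxels.  Voxel counts
    of the constituents are summed, so e.g. run percentage of a merged matrix
    uses the total voxel tally of all contributing units.
    """
    if not matrices:
        raise ValueError("nothing to merge")
    fam = matrices[0].family
    if any(t.family != fam for t in matrices):
        raise ValueError("cannot merge matrices of mixed families")
    live = [t for t in matrices if not t.empty]
    if not live:
        D = matrices[0].counts.shape[0]
        return TextureMatrix(fam, np.zeros((D, 1)), 0, True, ("merged",))
    ncols = max(t.counts.shape[1] for t in live)
    out = np.zeros((live[0].counts.shape[0], ncols), dtype=np.float64)
    for t in live:
        out[:, : t.counts.shape[1]] += t.counts
    return TextureMatrix(fam, out, sum(t.n_voxels for t in live), False, ("merged",))


def _roi_slices(voi: DiscretizedVOI) -> list[int]:
    return [z for z in range(voi.mask.shape[0]) if voi.mask[z].any()]


def build_units(voi: DiscretizedVOI, family: str, method: str) -> list[TextureMatrix]:
    """All unit matrices the given aggregation method operates on."""
    slices = _roi_slices(voi)
    if family in ("GLCM", "GLRLM"):
        ctor = glcm_unit if family == "GLCM" else glrlm_unit
        if method.startswith(("2D", "2.5D")):
            return [ctor(voi, z, d) for z in slices for d in directions_2d()]
        return [ctor(voi, None, d) for d in directions_3d()]
    ctors = {
        "GLSZM": glszm_unit,
        "GLDZM": gldzm_unit,
        "NGTDM": ngtdm_unit,
        "NGLDM": ngldm_unit,
    }
    ctor = ctors[family]
    if method in ("2D", "2.5D"):
        return [ctor(voi, z) for z in slices]
    return [ctor(voi, None)]


def aggregate(
    voi: DiscretizedVOI,
    family: str,
    method: str,
    feature_fn: Callable[[TextureMatrix], dict[str, float]],
    units: list[TextureMatrix] | None = None,
) -> dict[str, float]:
    """Dispatch unit construction, merging, feature computation and averaging.

    ``feature_fn`` maps one (possibly merged) matrix to named feature values;
    averaged methods take the unweighted mean over non-empty units.  Raises if
    every unit is empty.  ``units`` lets callers reuse unit matrices across
    methods of the same dimensionality (they are rebuilt from the VOI if not
    given).
    """
    if method not in methods_for_family(family):
        raise ValueError(f"method {method!r} not legal for family {family}")
    if units is None:
        units = build_units(voi, family, method)
    live = [u for u in units if not u.empty]
    if not live:
        raise ValueError(f"all {family} units empty for method {method}")

    def avg(dicts: list[dict[str, float]]) -> dict[str, float]:
        keys = dicts[0].keys()
        return {k: float(np.mean([d[k] for d in dicts])) for k in keys}

    if family in ("GLCM", "GLRLM"):
        n_dir2 = len(directions_2d())
        if method in ("2D_averaged", "3D_averaged"):
            return avg([feature_fn(u) for u in live])
        if method in ("2.5D_merged", "3D_merged"):
            return feature_fn(merge(live))
        if method == "2D_s_merged":  # merge directions within each slice
            per_slice: dict[int, list[TextureMatrix]] = {}
            for u in live:
                per_slice.setdefault(u.unit[0], []).append(u)
            return avg([feature_fn(merge(v)) for v in per_slice.values()])
        if method == "2.5D_d_merged":  # merge slices within each direction
            per_dir: dict[tuple, list[TextureMatrix]] = {}
            for u in live:
                per_dir.setdefault(u.unit[1], []).append(u)
            return avg([feature_fn(merge(v)) for v in per_dir.values()])
        raise AssertionError(method)
    # zone / neighbourhood families
    if method == "2D":
        return avg([feature_fn(u) for u in live])
    if method == "2.5D":
        return feature_fn(merge(live))
    return feature_fn(live[0])  # 3D: single matrix
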