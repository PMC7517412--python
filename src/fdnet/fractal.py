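"""3D box-counting fractal dimension of binary voxel masks.

A binary object's box-counting dimension is estimated from the power law
``N(r) ∝ r^-FD``: cubic boxes of edge ``r`` are tiled over the object's
bounding box, the number of boxes containing at least one occupied voxel is
counted at a decreasing sequence of ``r``, and FD is the ordinary
least-squares slope of ``log N(r)`` against ``log(1/r)``.

Conventions (documented, since none of them is standardized):

* the mask is cropped to its occupied bounding box before counting, so
  translation inside a larger empty grid cannot change the counts;
* the counting grid is anchored at the bounding-box minimum corner, with no
  multi-offset minimization;
* box sizes default to powers of 2 (powers of 3 selectable, which makes
  triadic phantoms such as the Menger sponge exact);
* counting is in voxel units; anisotropic voxel sizes are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .atlas import Atlas, rois_in
from .exceptions import DomainError, ValidationError

__all__ = [
    "VoxelMask",
    "BoxCountCurve",
    "FdEstimate",
    "box_counts",
    "default_sizes",
    "estimate_fd",
    "fd_per_roi",
    "aggregate_lobe_fd",
]


@dataclass
class VoxelMask:
    """A 3D binary occupancy grid, optionally with physical voxel size (mm)."""

    occupancy: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.occupancy)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {arr.ndim}D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("mask values must be strictly binary")
            arr = arr.astype(bool)
        self.occupancy = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def cropped(self) -> "VoxelMask":
        """Mask restricted to its occupied bounding box."""
        if self.n_occupied == 0:
            raise DomainError("empty mask has no bounding box")
        idx = np.nonzero(self.occupancy)
        sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
        return VoxelMask(self.occupancy[sl], self.voxel_size)


@dataclass
class BoxCountCurve:
    """Occupied-box counts N(r) at strictly increasing box sizes r."""

    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.sizes.shape != self.counts.shape or self.sizes.ndim != 1:
            raise ValidationError("sizes and counts must be equal-length vectors")
        if not (np.diff(self.sizes) > 0).all():
            raise ValidationError("sizes must be strictly increasing")
        if (self.sizes < 1).any():
            raise ValidationError("sizes must be >= 1")
        if (self.counts < 1).any():
            raise ValidationError("all counts must be >= 1")
        if (np.diff(self.counts) > 0).any():
            raise ValidationError("counts must be non-increasing in r")


@dataclass
class FdEstimate:
    """OLS fit of log N(r) on log(1/r): slope (the FD), intercept, R²."""

    fd: float
    intercept: float
    r_squared: float
    n_points: int


def box_counts(mask: VoxelMask, sizes: Sequence[int]) -> BoxCountCurve:
    """Count occupied boxes of each edge length over the mask's bounding box.

    The grid is axis-aligned and anchored at the bounding-box minimum corner;
    partial boxes at the far faces count like full ones. A size exceeding the
    cropped extent yields a count of 1.
    """
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if sizes.size == 0:
        raise ValidationError("need at least one box size")
    if (sizes < 1).any():
        raise ValidationError("box sizes must be >= 1")
    if len(set(sizes.tolist())) != sizes.size:
        raise ValidationError("box sizes must be distinct")
    if mask.n_occupied == 0:
        raise DomainError("cannot box-count an empty mask")
    occ = mask.cropped().occupancy
    counts = []
    for r in sizes:
        if r == 1:
            counts.append(int(occ.sum()))
            continue
        pad = [(0, (-d) % r) for d in occ.shape]
        padded = np.pad(occ, pad, constant_values=False)
        bx, by, bz = (d // r for d in padded.shape)
        blocks = padded.reshape(bx, r, by, r, bz, r)
        counts.append(int(blocks.any(axis=(1, 3, 5)).sum()))
    return BoxCountCurve(sizes=sizes, counts=np.asarray(counts))


def default_sizes(mask: VoxelMask, base: int = 2) -> list[int]:
    """Geometric box-size progression base^0 ... base^K.

    K is the largest exponent with base^K not exceeding the maximum
    bounding-box extent. Raises if fewer than 3 sizes are available, since a
    2-point log-log regression carries no goodness-of-fit information.
    """
    if base not in (2, 3):
        raise ValidationError(f"base must be 2 or 3, got {base}")
    max_extent = max(mask.cropped().shape)
    sizes = []
    s = 1
    while s <= max_extent:
        sizes.append(s)
        s *= base
    if len(sizes) < 3:
        raise DomainError(
            f"mask extent {max_extent} yields only {len(sizes)} box size(s) "
            f"at base {base}; need >= 3"
        )
    return sizes


def estimate_fd(curve: BoxCountCurve) -> FdEstimate:
    """Least-squares slope of log N(r) on log(1/r).

    A flat curve (all counts equal) has slope 0 and, having zero response
    variance, is reported with R² = 1 by convention (the fit is exact).
    """
    if curve.sizes.size < 2:
        raise DomainError("FD regression needs at least 2 box sizes")
    x = -np.log(curve.sizes.astype(float))
    y = np.log(curve.counts.astype(float))
    if np.allclose(y, y[0]):
        return FdEstimate(fd=0.0, intercept=float(y[0]), r_squared=1.0,
                          n_points=int(curve.sizes.size))
    res = _sps.linregress(x, y)
    return FdEstimate(
        fd=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(curve.sizes.size),
    )


def fd_of_mask(mask: VoxelMask, base: int = 2) -> FdEstimate:
    """Convenience: default sizes + box counts + regression on one mask."""
    return estimate_fd(box_counts(mask, default_sizes(mask, base=base)))


def fd_per_roi(
    label_volume: np.ndarray,
    atlas: Atlas,
    min_voxels: int = 8,
    base: int = 2,
) -> np.ndarray:
    """Per-region FD values from a labeled parcellation volume.

    Parameters
    ----------
    label_volume : 3D integer array
        Voxel labels in {0} ∪ {1..68}; 0 is background.
    min_voxels : int
        Regions with fewer occupied voxels than this yield NaN — below ~8
        voxels the log-log regression is meaningless. Regions too small for
        three box sizes likewise yield NaN.

    Returns
    -------
    numpy.ndarray of shape (68,); entry i-1 is the FD of ROI i, NaN if the
    region is absent or too small.
    """
    labels = np.asarray(label_volume)
    if labels.ndim != 3:
        raise ValidationError("label volume must be 3D")
    codes = np.unique(labels)
    bad = codes[(codes < 0) | (codes > 68)]
    if bad.size:
        raise ValidationError(f"label codes outside 0-68: {bad.tolist()}")
    out = np.full(68, np.nan)
    for roi in atlas:
        occ = labels == roi.index
        n = int(occ.sum())
        if n < max(min_voxels, 1):
            continue
        mask = VoxelMask(occ)
        try:
            out[roi.index - 1] = fd_of_mask(mask, base=base).fd
        except DomainError:
            # bounding box too small for a 3-size progression
            continue
    return out


def aggregate_lobe_fd(cohort, atlas: Atlas) -> "object":
    """Mean ± SD of FD per (lobe × hemisphere cell), per group.

    Pools all (subject, ROI-in-cell) values, matching how lobe-level
    summaries are reported: the SD therefore mixes between-subject and
    between-region variation. NaN entries are excluded pairwise. The
    ``both``-hemisphere row pools the whole lobe.

    Returns a pandas DataFrame with columns
    ``group, lobe, hemisphere, mean, sd, n_values``.
    """
    import pandas as pd

    rows = []
    for group in cohort.groups():
        fd = cohort.fd[cohort.group == group]
        for lobe in ("frontal", "temporal", "parietal", "occipital"):
            for hemi in ("both", "left", "right"):
                cols = sorted(rois_in(atlas, lobe, hemi))
                vals = fd[:, [c - 1 for c in cols]].ravel()
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    raise DomainError(f"no FD values in {lobe}/{hemi} cell")
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                rows.append(
                    {
                        "group": group,
                        "lobe": lobe,
                        "hemisphere": hemi,
                        "mean": float(vals.mean()),
                        "sd": sd,
                        "n_values": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)
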