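"""Synthetic inputs: fractal phantoms and two-group FD cohorts.

Phantoms are deterministic binary masks with known box-counting dimension,
used to validate the FD estimator: filled cube (FD 3), slab (2), line (1),
point (0), the level-L Menger sponge (log 20 / log 3 ≈ 2.7268) and Cantor
dust (3·log 2 / log 3 ≈ 1.8928).

Cohorts emulate the study design the pipeline targets: two groups of 100
subjects (50 women / 50 men each) with 68 regional FD values per subject.
Regional values are drawn from a multivariate normal whose correlation is
compound-symmetric within 5 planted blocks (within-block correlation 0.5,
between 0.1) — the blocks are the module structure a covariance network
built from the cohort should recover. Default regional means sit on the
empirical scale of cortical FD (≈2.0-2.45, per-lobe means), with a common
subject SD of 0.10; the second group's means are shifted in 16 lateralized
regions by the reference group differences (e.g. left pericalcarine
+0.0519). FD is treated as Gaussian: real FD values are bounded, but at
these SDs the normal approximation is safe and truncation is never hit in
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, load_default_atlas, rois_in
from .community import ModulePartition
from .exceptions import ConfigError, DomainError, ValidationError
from .fractal import VoxelMask
from .network import FdCohortTable, N_ROI
from . import reference

__all__ = [
    "PhantomSpec",
    "CohortConfig",
    "make_phantom",
    "make_cohort",
    "planted_truth",
    "MENGER_FD",
    "CANTOR_DUST_FD",
]

MENGER_FD = math.log(20) / math.log(3)
CANTOR_DUST_FD = 3 * math.log(2) / math.log(3)

_ANALYTIC_FD = {
    "cube": 3.0,
    "slab": 2.0,
    "line": 1.0,
    "point": 0.0,
    "menger_sponge": MENGER_FD,
    "cantor_dust": CANTOR_DUST_FD,
}

_MAX_GRID = 512  # largest phantom edge we will materialize


@dataclass(frozen=True)
class PhantomSpec:
    """A named deterministic phantom.

    ``level_or_size`` is the cube edge for cube/slab/line/point and the
    recursion level for menger_sponge/cantor_dust (grid edge 3^level).
    """

    kind: str
    level_or_size: int

    def __post_init__(self) -> None:
        if self.kind not in _ANALYTIC_FD:
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.level_or_size < 1:
            raise ValidationError("level_or_size must be >= 1")

    @property
    def analytic_fd(self) -> float:
        return _ANALYTIC_FD[self.kind]


def _cantor_1d(level: int) -> np.ndarray:
    keep = np.array([True])
    for _ in range(level):
        n = keep.size
        out = np.zeros(3 * n, dtype=bool)
        out[:n] = keep
        out[2 * n:] = keep
        keep = out
    return keep


def make_phantom(spec: PhantomSpec) -> VoxelMask:
    """Build the phantom's occupancy grid."""
    kind, lv = spec.kind, spec.level_or_size
    if kind in ("menger_sponge", "cantor_dust"):
        edge = 3**lv
    else:
        edge = lv
    if edge > _MAX_GRID:
        raise DomainError(f"phantom edge {edge} exceeds limit {_MAX_GRID}")
    if kind == "cube":
        occ = np.ones((edge, edge, edge), dtype=bool)
    elif kind == "slab":
        occ = np.zeros((edge, edge, edge), dtype=bool)
        occ[:, :, 0] = True
    elif kind == "line":
        occ = np.zeros((edge, edge, edge), dtype=bool)
        occ[:, 0, 0] = True
    elif kind == "point":
        occ = np.zeros((1, 1, 1), dtype=bool)
        occ[0, 0, 0] = True
    elif kind == "menger_sponge":
        occ = np.ones((1, 1, 1), dtype=bool)
        for _ in range(lv):
            n = occ.shape[0]
            new = np.zeros((3 * n, 3 * n, 3 * n), dtype=bool)
            for ix in range(3):
                for iy in range(3):
                    for iz in range(3):
                        # drop the center of each face and the body center:
                        # keep a subcube unless >= 2 of its offsets are central
                        if (ix == 1) + (iy == 1) + (iz == 1) >= 2:
                            continue
                        new[ix * n:(ix + 1) * n, iy * n:(iy + 1) * n, iz * n:(iz + 1) * n] = occ
            occ = new
    else:  # cantor_dust
        c = _cantor_1d(lv)
        occ = c[:, None, None] & c[None, :, None] & c[None, None, :]
    return VoxelMask(occ)


# --- cohorts --------------------------------------------------------------


def _default_blocks() -> list[list[int]]:
    """Planted block partition: the reference middle-aged module memberships
    (sizes 22/14/13/11/8)."""
    part = reference.module_partition("middle")
    return [sorted(np.nonzero(part == m)[0] + 1) for m in range(1, part.max() + 1)]


def _default_means(atlas: Atlas) -> np.ndarray:
    """Per-lobe baseline means, overridden at the 16 reference effect regions
    by their group-A (middle-aged) values."""
    lobes = reference.lobe_fd()
    by_lobe = {
        row["lobe"]: row["middle_mean"]
        for _, row in lobes[lobes.hemisphere == "both"].iterrows()
    }
    means = np.array([by_lobe[r.lobe] for r in atlas])
    for _, row in reference.regional_differences().iterrows():
        means[int(row["roi_index"]) - 1] = row["middle_mean"]
    return means


def _default_effects() -> list[tuple[int, float]]:
    """(roi_index, delta) pairs: group-B mean shifts equal to the reference
    elderly − middle differences (negative = atrophy, positive = increase)."""
    diffs = reference.regional_differences()
    return [
        (int(row["roi_index"]), float(row["elderly_mean"] - row["middle_mean"]))
        for _, row in diffs.iterrows()
    ]


@dataclass
class CohortConfig:
    """Generator configuration for a two-group synthetic FD cohort.

    Defaults reproduce the study conditions the pipeline targets: 100
    subjects per group (sex-balanced 50/50), regional means on the cortical
    FD scale, subject SD 0.10, five planted correlation blocks of sizes
    22/14/13/11/8 with within/between correlations 0.5/0.1, and group-B
    mean shifts at the 16 lateralized reference regions.
    """

    n_per_group: int = 100
    roi_means: np.ndarray | None = None
    roi_sd: float = 0.10
    module_blocks: list[list[int]] | None = None
    within_block_corr: float = 0.5
    between_block_corr: float = 0.1
    effect_rois: list[tuple[int, float]] | None = None
    within_boost_a: float = 0.0
    group_labels: tuple = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2 or self.n_per_group % 2:
            raise ConfigError("n_per_group must be an even integer >= 2")
        if self.roi_sd <= 0:
            raise ConfigError("roi_sd must be positive")
        atlas = load_default_atlas()
        if self.roi_means is None:
            self.roi_means = _default_means(atlas)
        self.roi_means = np.asarray(self.roi_means, dtype=float)
        if self.roi_means.shape != (N_ROI,):
            raise ConfigError(f"roi_means must have {N_ROI} entries")
        if self.module_blocks is None:
            self.module_blocks = _default_blocks()
        flat = sorted(i for block in self.module_blocks for i in block)
        if flat != list(range(1, N_ROI + 1)):
            raise ConfigError("module_blocks must partition 1..68")
        if self.effect_rois is None:
            self.effect_rois = _default_effects()
        for roi, _delta in self.effect_rois:
            if not 1 <= roi <= N_ROI:
                raise ConfigError(f"effect ROI {roi} outside 1..68")

    def correlation(self, group_index: int = 1) -> np.ndarray:
        """Implied 68×68 correlation matrix (validated PSD).

        Group 0 (A) gets ``within_block_corr + within_boost_a`` inside
        blocks, letting tests plant a group difference in network structure
        rather than in means.
        """
        within = self.within_block_corr + (self.within_boost_a if group_index == 0 else 0.0)
        c = np.full((N_ROI, N_ROI), self.between_block_corr)
        for block in self.module_blocks:
            idx = [i - 1 for i in block]
            c[np.ix_(idx, idx)] = within
        np.fill_diagonal(c, 1.0)
        lo = np.linalg.eigvalsh(c)[0]
        if lo < -1e-10:
            raise ConfigError(
                f"implied correlation matrix is not PSD (min eigenvalue {lo:.3e})"
            )
        return c

    def group_means(self, group_index: int) -> np.ndarray:
        means = self.roi_means.copy()
        if group_index == 1:
            for roi, delta in self.effect_rois:
                means[roi - 1] += delta
        return means


def make_cohort(config: CohortConfig) -> FdCohortTable:
    """Draw a seed-deterministic two-group cohort from the configured model."""
    rng = np.random.default_rng(config.seed)
    ids, groups, sexes, rows = [], [], [], []
    half = config.n_per_group // 2
    for gi, label in enumerate(config.group_labels):
        cov = config.correlation(gi) * config.roi_sd**2
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(N_ROI))
        mu = config.group_means(gi)
        z = rng.standard_normal((config.n_per_group, N_ROI))
        rows.append(mu + z @ chol.T)
        ids += [f"{label}{i + 1:03d}" for i in range(config.n_per_group)]
        groups += [label] * config.n_per_group
        sexes += ["F"] * half + ["M"] * half
    return FdCohortTable(
        subject_ids=ids,
        group=np.array(groups, dtype=object),
        sex=np.array(sexes, dtype=object),
        fd=np.vstack(rows),
    )


def planted_truth(config: CohortConfig) -> tuple[ModulePartition, pd.DataFrame]:
    """Ground truth for recovery scoring: the planted block partition (as a
    ModulePartition with q = NaN) and the per-ROI effect table."""
    assignment = np.zeros(N_ROI, dtype=int)
    order = sorted(
        range(len(config.module_blocks)),
        key=lambda b: (-len(config.module_blocks[b]), min(config.module_blocks[b])),
    )
    for new_id, b in enumerate(order, start=1):
        for roi in config.module_blocks[b]:
            assignment[roi - 1] = new_id
    partition = ModulePartition(assignment=assignment, q=float("nan"))
    deltas = np.zeros(N_ROI)
    for roi, delta in config.effect_rois:
        deltas[roi - 1] += delta
    effects = pd.DataFrame(
        {"roi_index": np.arange(1, N_ROI + 1), "delta": deltas}
    )
    return partition, effects
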