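"""Structural covariance network construction.

For each group, the Pearson correlation of regional FD values across the
group's subjects gives a 68 × 68 inter-regional correlation matrix — the
structural covariance network before thresholding. A proportional threshold
then keeps the strongest 20% (by default) of the unique positive
off-diagonal coefficients as weighted edges; negative correlations and the
diagonal are removed. Edge weights are the retained correlation
coefficients, not binarized, since node degree is defined downstream as a
sum of coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas
from .exceptions import DomainError, ValidationError

__all__ = [
    "FdCohortTable",
    "CorrelationMatrix",
    "BrainNetwork",
    "correlation_matrix",
    "threshold_proportional",
]

N_ROI = 68


@dataclass
class FdCohortTable:
    """Per-subject regional FD values with group and sex labels.

    ``fd`` is a (n_subjects × 68) float matrix; missing regional values are
    NaN. ``group`` and ``sex`` are per-subject label arrays (any two group
    labels; sex labels "F"/"M").
    """

    subject_ids: list[str]
    group: np.ndarray
    sex: np.ndarray
    fd: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.group = np.asarray(self.group, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.fd = np.asarray(self.fd, dtype=float)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicated subject ids")
        if self.group.shape != (n,) or self.sex.shape != (n,):
            raise ValidationError("group/sex must have one entry per subject")
        if self.fd.shape != (n, N_ROI):
            raise ValidationError(
                f"fd must be (n_subjects, {N_ROI}), got {self.fd.shape}"
            )
        finite = self.fd[~np.isnan(self.fd)]
        if finite.size and ((finite <= 0) | (finite >= 3.5)).any():
            raise ValidationError("FD values must lie in (0, 3.5) or be NaN")
        bad_sex = set(self.sex) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"sex labels must be F/M, got {bad_sex}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def groups(self) -> list:
        """Distinct group labels, in order of first appearance."""
        seen: dict = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, rows: np.ndarray) -> "FdCohortTable":
        rows = np.asarray(rows)
        return FdCohortTable(
            subject_ids=[self.subject_ids[i] for i in rows],
            group=self.group[rows],
            sex=self.sex[rows],
            fd=self.fd[rows],
        )

    # -- delimited-text representation ------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fd, columns=[f"roi_{i}" for i in range(1, N_ROI + 1)])
        df.insert(0, "sex", self.sex)
        df.insert(0, "group", self.group)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FdCohortTable":
        roi_cols = [f"roi_{i}" for i in range(1, N_ROI + 1)]
        missing = [c for c in ["subject_id", "group", "sex", *roi_cols] if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns {missing[:5]}...")
        fd = df[roi_cols].to_numpy(dtype=float)
        return cls(
            subject_ids=df["subject_id"].astype(str).tolist(),
            group=df["group"].to_numpy(),
            sex=df["sex"].astype(str).to_numpy(),
            fd=fd,
        )


@dataclass
class CorrelationMatrix:
    """Symmetric 68 × 68 Pearson correlation matrix for one group.

    ``n_subjects`` is the group size; ``n_pairwise`` records the per-entry
    number of complete subject pairs when FD values are missing;
    ``n_undefined`` counts entries that were undefined (constant column or
    too few pairs) and recorded as 0.
    """

    values: np.ndarray
    n_subjects: int
    n_pairwise: np.ndarray | None = None
    n_undefined: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ROI, N_ROI):
            raise ValidationError(f"correlation matrix must be {N_ROI}x{N_ROI}")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValidationError("correlations must lie in [-1, 1]")
        self.values = v


@dataclass
class BrainNetwork:
    """Thresholded weighted adjacency matrix over the 68 atlas regions.

    Zero diagonal, symmetric, non-negative weights (retained correlation
    coefficients). ``threshold_proportion`` records the proportional
    threshold that produced it.
    """

    adjacency: np.ndarray
    atlas: Atlas | None = None
    threshold_proportion: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValidationError("adjacency weights must be non-negative")
        if np.diagonal(a).any():
            raise ValidationError("adjacency diagonal must be zero")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of strictly positive unique (unordered) edges."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int((self.adjacency[iu] > 0).sum())

    @property
    def total_strength(self) -> float:
        """Sum of all edge weights (each unordered edge counted once)."""
        return float(self.adjacency.sum() / 2.0)

    def strengths(self) -> np.ndarray:
        """Node strengths k_i = row sums of the adjacency."""
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> pd.DataFrame:
        """3-column weighted edge list with 1-based node indices."""
        iu = np.triu_indices(self.n_nodes, k=1)
        w = self.adjacency[iu]
        keep = w > 0
        return pd.DataFrame(
            {
                "roi_i": iu[0][keep] + 1,
                "roi_j": iu[1][keep] + 1,
                "weight": w[keep],
            }
        )


def correlation_matrix(cohort: FdCohortTable, group) -> CorrelationMatrix:
    """Pearson correlation of FD across one group's subjects, per ROI pair.

    Missing FD values are handled pairwise-complete. Undefined entries
    (constant column, or fewer than 3 complete pairs) are recorded as 0 and
    counted in ``n_undefined``.
    """
    rows = np.nonzero(cohort.group == group)[0]
    if rows.size == 0:
        raise DomainError(f"no subjects in group {group!r}")
    if rows.size < 3:
        raise DomainError(f"group {group!r} has {rows.size} subjects; need >= 3")
    fd = cohort.fd[rows]
    if np.isnan(fd).any():
        df = pd.DataFrame(fd)
        corr = df.corr(min_periods=3).to_numpy()
        notna = (~np.isnan(fd)).astype(int)
        n_pairwise = notna.T @ notna
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(fd, rowvar=False)
        n_pairwise = np.full((N_ROI, N_ROI), rows.size)
    np.fill_diagonal(corr, 1.0)
    undefined = int(np.isnan(corr).sum())
    if undefined:
        warnings.warn(
            f"{undefined} undefined correlation entries recorded as 0",
            stacklevel=2,
        )
        corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(
        values=corr,
        n_subjects=int(rows.size),
        n_pairwise=np.asarray(n_pairwise),
        n_undefined=undefined,
    )


def threshold_proportional(
    corr: CorrelationMatrix | np.ndarray,
    proportion: float = 0.20,
    atlas: Atlas | None = None,
) -> BrainNetwork:
    """Keep the strongest positive coefficients as weighted edges.

    Among the E = n(n−1)/2 unique off-diagonal entries, the ⌈proportion·E⌉
    largest positive values are retained with their weights; everything
    else — weaker positives, all negatives, and the diagonal — is set to 0.
    Entries tied exactly at the cutoff value are all kept, so the realized
    edge count can exceed the requested one; it can fall short if there are
    fewer positive entries than requested.
    """
    if not 0 < proportion <= 1:
        raise ValidationError(f"proportion must be in (0, 1], got {proportion}")
    values = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr, float)
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = values[iu]
    n_unique = upper.size
    k = math.ceil(proportion * n_unique)
    positive = upper[upper > 0]
    if positive.size == 0:
        warnings.warn("no positive off-diagonal entries; network is empty", stacklevel=2)
        adj = np.zeros_like(values)
        return BrainNetwork(adj, atlas=atlas, threshold_proportion=proportion)
    if positive.size <= k:
        cutoff = positive.min()
    else:
        cutoff = np.sort(positive)[::-1][k - 1]
    adj = np.where(values >= cutoff, values, 0.0)
    np.fill_diagonal(adj, 0.0)
    adj = np.where(adj > 0, adj, 0.0)
    return BrainNetwork(adj, atlas=atlas, threshold_proportion=proportion)
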