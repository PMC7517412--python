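"""Model/Results interface over the covariance-network pipeline.

Two model classes mirror the familiar fit-then-inspect pattern:

* :class:`BrainNetworkModel` — one group's structural covariance network.
  ``fit()`` computes the correlation matrix, applies the proportional
  threshold, detects modules and evaluates node/lobe metrics, returning a
  :class:`BrainNetworkResults` whose ``summary()`` prints the network's
  headline numbers (Q, module sizes, Z/P lobe means, hubs).

* :class:`GroupComparison` — the two-group analysis. ``fit()`` runs the
  regional Welch-t/FDR comparison and the sex-balanced permutation test on
  the requested network properties, returning a
  :class:`GroupComparisonResults`.

Both models take an :class:`~fdnet.network.FdCohortTable` (or a pandas
DataFrame in the cohort-table layout via ``from_dataframe``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas, LOBES, load_default_atlas
from .community import ModulePartition, detect_modules
from .exceptions import DomainError
from .metrics import (
    NodeMetrics,
    compute_node_metrics,
    connectivity_report,
    group_ratio,
    node_metric_report,
)
from .network import (
    BrainNetwork,
    CorrelationMatrix,
    FdCohortTable,
    correlation_matrix,
    threshold_proportional,
)
from .stats import (
    PermutationResult,
    RegionalTestResult,
    permutation_compare_many,
    regional_fd_ttests,
)

__all__ = [
    "BrainNetworkModel",
    "BrainNetworkResults",
    "GroupComparison",
    "GroupComparisonResults",
]


class BrainNetworkModel:
    """Structural covariance network model for one group of subjects.

    Parameters
    ----------
    cohort : FdCohortTable
    group : hashable, optional
        Which group to model; defaults to the cohort's first group.
    proportion : float
        Proportional threshold (fraction of strongest positive unique
        correlations retained), default 0.20.
    weighted : bool
        Whether node metrics use retained weights (default) or edge counts.
    hub_z_threshold : float
        Within-module degree z cutoff for hub classification.
    """

    def __init__(
        self,
        cohort: FdCohortTable,
        group=None,
        atlas: Atlas | None = None,
        proportion: float = 0.20,
        weighted: bool = True,
        hub_z_threshold: float = 2.5,
    ):
        self.cohort = cohort
        self.group = cohort.groups()[0] if group is None else group
        self.atlas = atlas if atlas is not None else load_default_atlas()
        self.proportion = proportion
        self.weighted = weighted
        self.hub_z_threshold = hub_z_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BrainNetworkModel":
        """Build from a cohort-layout DataFrame
        (subject_id, group, sex, roi_1..roi_68)."""
        return cls(FdCohortTable.from_frame(df), **kwargs)

    def fit(self, seed: int = 0, n_restarts: int = 100) -> "BrainNetworkResults":
        corr = correlation_matrix(self.cohort, self.group)
        net = threshold_proportional(corr, self.proportion, atlas=self.atlas)
        if net.n_edges == 0:
            raise DomainError("thresholded network has no edges")
        partition = detect_modules(net, seed=seed, n_restarts=n_restarts)
        metrics = compute_node_metrics(
            net, partition, weighted=self.weighted, z_threshold=self.hub_z_threshold
        )
        return BrainNetworkResults(
            model=self,
            correlation=corr,
            network=net,
            partition=partition,
            node_metrics=metrics,
            seed=seed,
            n_restarts=n_restarts,
        )


@dataclass
class BrainNetworkResults:
    """Fitted covariance network: estimates, partition and diagnostics."""

    model: BrainNetworkModel
    correlation: CorrelationMatrix
    network: BrainNetwork
    partition: ModulePartition
    node_metrics: NodeMetrics
    seed: int
    n_restarts: int

    @property
    def q(self) -> float:
        """Modularity of the detected partition."""
        return self.partition.q

    def z_report(self) -> pd.DataFrame:
        """Lobe × hemisphere means of within-module degree z."""
        return node_metric_report(self.node_metrics.z, self.model.atlas)

    def p_report(self) -> pd.DataFrame:
        """Lobe × hemisphere means of the participation coefficient."""
        return node_metric_report(self.node_metrics.p, self.model.atlas)

    def lobe_connectivity(self, scope: str, mode: str = "mean") -> pd.DataFrame:
        """Intra- or inter-lobe edge-weight table (lobe × total/left/right)."""
        return connectivity_report(self.network, self.model.atlas, scope, mode)

    def hubs(self) -> pd.DataFrame:
        df = self.node_metrics.to_frame(self.model.atlas)
        return df[df["is_hub"]]

    def summary(self) -> str:
        part = self.partition
        lines = [
            "Structural covariance network",
            "=" * 45,
            f"group:                {self.model.group}",
            f"subjects:             {self.correlation.n_subjects}",
            f"threshold proportion: {self.model.proportion:.2f}",
            f"edges retained:       {self.network.n_edges}",
            f"modularity Q:         {part.q:.4f}",
            f"modules (sizes):      {part.n_modules} ({'/'.join(map(str, part.sizes()))})",
            f"hubs (z >= {self.model.hub_z_threshold:.1f}):      "
            + (", ".join(self.hubs()["label"]) if len(self.hubs()) else "none"),
            "",
            "Within-module degree z (lobe means)",
            self.z_report().round(4).to_string(),
            "",
            "Participation coefficient (lobe means)",
            self.p_report().round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_correlation(self, ax=None):
        """Heatmap of the group correlation matrix with lobe boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.correlation.values, vmin=-1, vmax=1, cmap="RdBu_r")
        for edge in (28, 46, 60):
            ax.axhline(edge - 0.5, color="k", lw=0.5)
            ax.axvline(edge - 0.5, color="k", lw=0.5)
        ax.set_xlabel("ROI index")
        ax.set_ylabel("ROI index")
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax

    def plot_adjacency(self, ax=None):
        """Heatmap of the thresholded weighted adjacency."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.network.adjacency, vmin=0, vmax=1, cmap="viridis")
        ax.set_xlabel("ROI index")
        ax.set_ylabel("ROI index")
        ax.figure.colorbar(im, ax=ax, label="edge weight")
        return ax


class GroupComparison:
    """Two-group comparison: regional FD tests + network permutation tests."""

    def __init__(
        self,
        cohort: FdCohortTable,
        group_a=None,
        group_b=None,
        atlas: Atlas | None = None,
        proportion: float = 0.20,
        weighted: bool = True,
    ):
        groups = cohort.groups()
        if group_a is None or group_b is None:
            if len(groups) != 2:
                raise DomainError("cohort must contain exactly 2 groups or specify them")
            group_a, group_b = groups
        self.cohort = cohort
        self.group_a = group_a
        self.group_b = group_b
        self.atlas = atlas if atlas is not None else load_default_atlas()
        self.proportion = proportion
        self.weighted = weighted

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GroupComparison":
        return cls(FdCohortTable.from_frame(df), **kwargs)

    def fit(
        self,
        seed: int = 0,
        properties=("Q", "Z_total", "P_total"),
        n_permutations: int = 1000,
        per_sex_draw: int = 25,
        n_restarts: int = 10,
    ) -> "GroupComparisonResults":
        regional = regional_fd_ttests(self.cohort, self.group_a, self.group_b)
        permutations = permutation_compare_many(
            self.cohort,
            properties=properties,
            n_permutations=n_permutations,
            per_sex_draw=per_sex_draw,
            proportion=self.proportion,
            seed=seed,
            n_restarts=n_restarts,
            weighted=self.weighted,
            atlas=self.atlas,
            group_a=self.group_a,
            group_b=self.group_b,
        )
        return GroupComparisonResults(
            model=self, regional=regional, permutations=permutations, seed=seed
        )


@dataclass
class GroupComparisonResults:
    """Regional test table plus permutation results per network property."""

    model: GroupComparison
    regional: RegionalTestResult
    permutations: dict[str, PermutationResult]
    seed: int

    def permutation_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.permutations.values()])

    def summary(self, q_threshold: float = 0.05) -> str:
        sig = self.regional.significant(q_threshold)
        atlas = self.model.atlas
        labels = [atlas.roi(int(i)).label for i in sig["roi_index"]]
        lines = [
            "Two-group comparison",
            "=" * 45,
            f"groups:   {self.model.group_a} vs {self.model.group_b}",
            f"regions with q < {q_threshold}: {len(sig)}"
            + (f" ({', '.join(labels)})" if labels else ""),
            "",
            "Network-property permutation tests",
            self.permutation_table().round(4).to_string(index=False),
        ]
        return "\n".join(lines)
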