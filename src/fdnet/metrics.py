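"""Node-level and lobe-level connectivity metrics.

Two node roles are quantified relative to a module partition:

* within-module degree z-score  z_i = (k_i − mean_c) / sd_c, where k_i is
  node i's connectivity to other members of its own module c and the
  mean/SD are taken over c's members (population SD). High z marks
  intra-module hubs; the conventional hub cutoff is z ≥ 2.5.
* participation coefficient  P_i = 1 − Σ_c (k_ci / k_i)², where k_ci is
  node i's connectivity into module c and k_i its total. P_i = 0 means all
  of i's edges stay in one module; P_i → 1 means they spread evenly.

Both accept weighted (connectivity = strength) or binary (connectivity =
edge count) mode; the network's retained correlation weights are the
default.

Lobe-level summaries aggregate either node metrics (mean z / mean P over a
lobe's regions) or raw edge weight: intra-lobe connectivity sums the
weights of edges with both endpoints in the lobe selection, inter-lobe
connectivity those with exactly one endpoint inside. A density-normalized
mean (sum divided by the number of eligible node pairs) is reported
alongside the raw sum, since the two groups' networks hold edge count
fixed, not weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Atlas, LOBES, rois_in
from .community import ModulePartition
from .exceptions import DomainError, ValidationError
from .network import BrainNetwork

__all__ = [
    "NodeMetrics",
    "within_module_z",
    "participation_coeff",
    "classify_hubs",
    "compute_node_metrics",
    "lobe_mean",
    "node_metric_report",
    "lobe_weight_connectivity",
    "connectivity_report",
    "group_ratio",
]

_COLUMNS = ("total", "left", "right")
_HEMI_OF = {"total": "both", "left": "left", "right": "right"}


@dataclass
class NodeMetrics:
    """Per-node z, P and hub flags for one network + partition."""

    z: np.ndarray
    p: np.ndarray
    is_hub: np.ndarray
    z_threshold: float

    def to_frame(self, atlas: Atlas | None = None) -> pd.DataFrame:
        n = self.z.size
        df = pd.DataFrame(
            {
                "roi_index": np.arange(1, n + 1),
                "z": self.z,
                "p": self.p,
                "is_hub": self.is_hub,
            }
        )
        if atlas is not None and n == 68:
            df.insert(1, "label", [r.label for r in atlas])
            df.insert(2, "lobe", [r.lobe for r in atlas])
        return df


def _within_connectivity(w: np.ndarray, comm: np.ndarray, weighted: bool) -> np.ndarray:
    m = w if weighted else (w > 0).astype(float)
    same = comm[:, None] == comm[None, :]
    return (m * same).sum(axis=1)


def within_module_z(network, partition: ModulePartition, weighted: bool = True) -> np.ndarray:
    """Within-module degree z-scores.

    Modules whose members all have the same within-module connectivity
    (SD = 0, including singletons) get z = 0 for every member.
    """
    w = network.adjacency if isinstance(network, BrainNetwork) else np.asarray(network, float)
    comm = partition.assignment
    k_within = _within_connectivity(w, comm, weighted)
    z = np.zeros_like(k_within)
    for c in range(1, partition.n_modules + 1):
        idx = comm == c
        mu = k_within[idx].mean()
        sigma = k_within[idx].std()  # population SD over the module
        if sigma > 0:
            z[idx] = (k_within[idx] - mu) / sigma
    return z


def participation_coeff(network, partition: ModulePartition, weighted: bool = True) -> np.ndarray:
    """Participation coefficients; isolated nodes (k_i = 0) get P = 0."""
    w = network.adjacency if isinstance(network, BrainNetwork) else np.asarray(network, float)
    m = w if weighted else (w > 0).astype(float)
    comm = partition.assignment
    k = m.sum(axis=1)
    p = np.zeros_like(k)
    nz = k > 0
    acc = np.zeros_like(k)
    for c in range(1, partition.n_modules + 1):
        k_c = m[:, comm == c].sum(axis=1)
        acc[nz] += (k_c[nz] / k[nz]) ** 2
    p[nz] = 1.0 - acc[nz]
    # guard the [0, 1] range against floating-point residue when acc == 1
    return np.clip(p, 0.0, 1.0)


def classify_hubs(z: np.ndarray, z_threshold: float = 2.5) -> np.ndarray:
    """Hub flags: z_i ≥ z_threshold."""
    return np.asarray(z, float) >= z_threshold


def compute_node_metrics(
    network,
    partition: ModulePartition,
    weighted: bool = True,
    z_threshold: float = 2.5,
) -> NodeMetrics:
    z = within_module_z(network, partition, weighted=weighted)
    p = participation_coeff(network, partition, weighted=weighted)
    return NodeMetrics(z=z, p=p, is_hub=classify_hubs(z, z_threshold), z_threshold=z_threshold)


def lobe_mean(values: np.ndarray, atlas: Atlas, lobe: str = "all", hemisphere: str = "both") -> float:
    """Arithmetic mean of a 68-vector over a lobe/hemisphere selection."""
    values = np.asarray(values, float)
    if values.shape != (68,):
        raise ValidationError("values must be a 68-vector")
    sel = sorted(rois_in(atlas, lobe, hemisphere))
    if not sel:
        raise DomainError(f"empty selection {lobe}/{hemisphere}")
    return float(values[[i - 1 for i in sel]].mean())


def node_metric_report(values: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Lobe × (total/left/right) means of a node metric, plus a whole-network
    row (the metric's network-wide mean over all 68 nodes)."""
    rows = {}
    for lobe in LOBES:
        rows[lobe] = {
            col: lobe_mean(values, atlas, lobe, _HEMI_OF[col]) for col in _COLUMNS
        }
    rows["whole"] = {col: lobe_mean(values, atlas, "all", _HEMI_OF[col]) for col in _COLUMNS}
    return pd.DataFrame(rows).T[list(_COLUMNS)]


def lobe_weight_connectivity(
    network: BrainNetwork,
    atlas: Atlas,
    scope: str,
    lobe: str,
    hemisphere: str = "both",
    mode: str = "sum",
) -> float:
    """Aggregate edge weight within (intra) or out of (inter) a lobe selection.

    intra: edges with both endpoints inside the selection;
    inter: edges with exactly one endpoint inside the selection.
    ``mode="mean"`` divides by the number of eligible node pairs
    (C(s,2) for intra, s·(n−s) for inter), giving a density-normalized
    value comparable across selections of different size.
    """
    if scope not in ("intra", "inter"):
        raise ValidationError(f"scope must be intra/inter, got {scope!r}")
    if mode not in ("sum", "mean"):
        raise ValidationError(f"mode must be sum/mean, got {mode!r}")
    w = network.adjacency
    n = w.shape[0]
    sel = np.zeros(n, dtype=bool)
    sel[[i - 1 for i in rois_in(atlas, lobe, hemisphere)]] = True
    s = int(sel.sum())
    if scope == "intra":
        total = float(w[np.ix_(sel, sel)].sum() / 2.0)
        n_pairs = s * (s - 1) // 2
    else:
        total = float(w[np.ix_(sel, ~sel)].sum())
        n_pairs = s * (n - s)
    if mode == "sum":
        return total
    return total / n_pairs if n_pairs else 0.0


def connectivity_report(
    network: BrainNetwork, atlas: Atlas, scope: str, mode: str = "sum"
) -> pd.DataFrame:
    """Lobe × (total/left/right) table of intra- or inter-lobe connectivity."""
    rows = {
        lobe: {
            col: lobe_weight_connectivity(network, atlas, scope, lobe, _HEMI_OF[col], mode)
            for col in _COLUMNS
        }
        for lobe in LOBES
    }
    return pd.DataFrame(rows).T[list(_COLUMNS)]


def group_ratio(report_elderly: pd.DataFrame, report_middle: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise percentage 100 · elderly / middle, rounded to 1 decimal.

    Cells with a zero denominator are NaN.
    """
    if not report_elderly.index.equals(report_middle.index) or list(
        report_elderly.columns
    ) != list(report_middle.columns):
        raise ValidationError("reports must share layout")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 100.0 * report_elderly.to_numpy() / report_middle.to_numpy()
    ratio[~np.isfinite(ratio)] = np.nan
    return pd.DataFrame(
        np.round(ratio, 1), index=report_elderly.index, columns=report_elderly.columns
    )
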