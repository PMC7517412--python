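"""Bundled reference summary tables from the aging-cohort study design.

The pipeline's worked examples and fixtures use the published group-level
summaries of two 100-subject cohorts (a middle-aged and an elderly group):

* per-lobe FD means ± SD and group p-values;
* the 16 lateralized regions whose FD differed significantly between the
  groups, with both group means;
* each group's five-module partition of the 68 regions;
* intra- and inter-lobe connectivity tables (lobe × total/left/right) for
  both groups, with the printed elderly/middle percentage ratio rows.

These are summary statistics only — the underlying per-subject data are not
distributed — so they serve as fixtures for worked-example arithmetic
(recomputing ratio rows, counting module sizes) and as the scale reference
for the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .community import ModulePartition
from .exceptions import ValidationError

__all__ = [
    "lobe_fd",
    "regional_differences",
    "module_partition",
    "module_tables",
    "intra_lobe_connectivity",
    "inter_lobe_connectivity",
    "connectivity_values",
]

_GROUP_FILES = {"middle": "reference_modules_middle.csv",
                "elderly": "reference_modules_elderly.csv"}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("fdnet") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def lobe_fd() -> pd.DataFrame:
    """Per-lobe FD means ± SD for both groups (lobe, hemisphere rows)."""
    return _read("reference_lobe_fd.csv")


def regional_differences() -> pd.DataFrame:
    """The 16 regions with significant group FD differences."""
    return _read("reference_regional_differences.csv")


def module_partition(group: str) -> np.ndarray:
    """Reference module assignment for one group as a 68-vector of 1-based
    module ids (entry i-1 = module of ROI i)."""
    if group not in _GROUP_FILES:
        raise ValidationError(f"group must be 'middle' or 'elderly', got {group!r}")
    df = _read(_GROUP_FILES[group])
    assignment = np.zeros(68, dtype=int)
    for _, row in df.iterrows():
        assignment[int(row["roi_index"]) - 1] = int(row["module"])
    if (assignment == 0).any():
        raise ValidationError("reference partition does not cover all 68 ROIs")
    return assignment


def module_tables(group: str) -> ModulePartition:
    """Reference partition wrapped as a ModulePartition (q unknown → NaN)."""
    return ModulePartition(assignment=module_partition(group), q=float("nan"))


def intra_lobe_connectivity() -> pd.DataFrame:
    """Intra-lobe connectivity (lobe, column, middle, elderly, printed ratio)."""
    return _read("reference_intra_lobe.csv")


def inter_lobe_connectivity() -> pd.DataFrame:
    """Inter-lobe connectivity (lobe, column, middle, elderly, printed ratio)."""
    return _read("reference_inter_lobe.csv")


def connectivity_values(scope: str) -> pd.DataFrame:
    """Connectivity table by scope name ('intra' or 'inter')."""
    if scope == "intra":
        return intra_lobe_connectivity()
    if scope == "inter":
        return inter_lobe_connectivity()
    raise ValidationError(f"scope must be intra/inter, got {scope!r}")
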