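"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI (.nii/.nii.gz) via nibabel; tables are delimited text
(comma or tab, auto-detected, header required); configs and run manifests
are JSON. All tables round-trip through their reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas
from .community import ModulePartition
from .exceptions import ValidationError
from .network import BrainNetwork, FdCohortTable, N_ROI

__all__ = [
    "read_table",
    "read_cohort",
    "write_cohort",
    "read_label_volume",
    "write_label_volume",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "write_partition",
    "read_partition",
    "RunConfig",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing input file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_cohort(path: str | Path) -> FdCohortTable:
    """Read an FD cohort table (subject_id, group, sex, roi_1..roi_68)."""
    df = read_table(path)
    roi_cols = [f"roi_{i}" for i in range(1, N_ROI + 1)]
    for col in roi_cols:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().sum() > df[col].isna().sum():
                raise ValidationError(f"non-numeric FD values in column {col}")
            df[col] = coerced
    return FdCohortTable.from_frame(df)


def write_cohort(cohort: FdCohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_label_volume(path: str | Path) -> np.ndarray:
    """Read an integer label volume from NIfTI."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing input file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"label volume must be 3D, got {data.ndim}D")
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValidationError("label volume contains non-integer values")
    return rounded.astype(np.int32)


def write_label_volume(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label volume as NIfTI with identity affine."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine=np.eye(4))
    nib.save(img, str(path))


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Write a square ROI × ROI matrix with 1-based header labels."""
    n = values.shape[0]
    cols = [f"roi_{i}" for i in range(1, n + 1)]
    pd.DataFrame(values, columns=cols).to_csv(path, index=False)


def read_matrix(path: str | Path) -> np.ndarray:
    df = read_table(path)
    return df.to_numpy(dtype=float)


def write_edge_list(network: BrainNetwork, path: str | Path) -> None:
    """Write a weighted edge list (roi_i, roi_j, weight), 1-based indices."""
    network.edge_list().to_csv(path, index=False)


def write_partition(partition: ModulePartition, atlas: Atlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "roi_index": [r.index for r in atlas],
            "abbreviation": [r.abbreviation for r in atlas],
            "hemisphere": [r.hemisphere for r in atlas],
            "lobe": [r.lobe for r in atlas],
            "module_id": partition.assignment,
        }
    )
    df.to_csv(path, index=False)


def read_partition(path: str | Path) -> ModulePartition:
    df = read_table(path)
    if "module_id" not in df.columns or "roi_index" not in df.columns:
        raise ValidationError("partition table needs roi_index and module_id columns")
    df = df.sort_values("roi_index")
    return ModulePartition(
        assignment=df["module_id"].to_numpy(dtype=int), q=float("nan")
    )


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration persisted next to every CLI run's outputs."""

    command: str
    inputs: dict
    threshold_proportion: float = 0.20
    weighted: bool = True
    hub_z_threshold: float = 2.5
    n_permutations: int = 1000
    per_sex_draw: int = 25
    n_restarts: int = 100
    seed: int = 0
    output_dir: str = "."

    def validate(self) -> None:
        if not 0 < self.threshold_proportion <= 1:
            raise ValidationError("threshold_proportion must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.per_sex_draw < 1 or self.n_restarts < 1:
            raise ValidationError("per_sex_draw and n_restarts must be >= 1")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
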