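"""Rearranged Desikan-Killiany cortical parcellation (68 ROIs).

The 34 Desikan-Killiany regions per hemisphere are rearranged by cerebral
lobe and interleaved left/right: frontal lobe indices 1-28, temporal 29-46,
parietal 47-60, occipital 61-68; odd indices are left-hemisphere regions and
even indices right-hemisphere ones. Every downstream stage (fractal
estimation, network construction, lobe summaries) addresses regions through
this 1-based indexing.

The atlas ships as a versioned CSV inside the package; its SHA-256 checksum
is verified on load so a corrupted transcription fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .exceptions import AtlasIntegrityError, ValidationError

__all__ = [
    "RoiDescriptor",
    "Atlas",
    "load_default_atlas",
    "rois_in",
    "LOBES",
    "HEMISPHERES",
]

LOBES = ("frontal", "temporal", "parietal", "occipital")
HEMISPHERES = ("left", "right")

#: SHA-256 of the packaged atlas.csv (bytes on disk); guards transcription.
_ATLAS_SHA256 = "2d9e7509119568e36c57a4cef2e69c3d9e4894282d976638656eb65a9eb8c77f"


@dataclass(frozen=True)
class RoiDescriptor:
    """One cortical region of interest.

    Attributes
    ----------
    index : int
        1-based atlas index (1-68).
    name : str
        Full region name, e.g. ``"Caudal anterior cingulate"``.
    abbreviation : str
        Short code, e.g. ``"CACg"``; unique per hemisphere pair.
    hemisphere : str
        ``"left"`` (odd indices) or ``"right"`` (even indices).
    lobe : str
        One of ``frontal``, ``temporal``, ``parietal``, ``occipital``.
    """

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    lobe: str

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 68:
            raise ValidationError(f"ROI index {self.index} outside 1-68")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"bad hemisphere {self.hemisphere!r}")
        if self.lobe not in LOBES:
            raise ValidationError(f"bad lobe {self.lobe!r}")
        expected = "left" if self.index % 2 == 1 else "right"
        if self.hemisphere != expected:
            raise ValidationError(
                f"ROI {self.index} must be {expected}-hemisphere "
                f"(odd=left, even=right), got {self.hemisphere!r}"
            )

    @property
    def label(self) -> str:
        """Report label, e.g. ``"CACg(L)"``."""
        return f"{self.abbreviation}({'L' if self.hemisphere == 'left' else 'R'})"


class Atlas:
    """Ordered collection of the 68 ROI descriptors.

    Regions are addressed by their 1-based atlas index. The constructor
    validates the structural invariants of the rearranged parcellation:
    exactly 68 regions, 34 per hemisphere, lobe block sizes 28/18/14/8,
    and unique (abbreviation, hemisphere) pairs.
    """

    _LOBE_RANGES = {
        "frontal": range(1, 29),
        "temporal": range(29, 47),
        "parietal": range(47, 61),
        "occipital": range(61, 69),
    }

    def __init__(self, rois: Iterable[RoiDescriptor]):
        rois = tuple(rois)
        if len(rois) != 68:
            raise ValidationError(f"atlas needs 68 ROIs, got {len(rois)}")
        if [r.index for r in rois] != list(range(1, 69)):
            raise ValidationError("atlas ROIs must be indexed 1-68 in order")
        for lobe, rng in self._LOBE_RANGES.items():
            for i in rng:
                if rois[i - 1].lobe != lobe:
                    raise ValidationError(
                        f"ROI {i} must belong to the {lobe} lobe"
                    )
        pairs = {(r.abbreviation, r.hemisphere) for r in rois}
        if len(pairs) != 68:
            raise ValidationError("duplicated (abbreviation, hemisphere) pair")
        self._rois = rois
        self._by_label = {(r.abbreviation, r.hemisphere): r for r in rois}

    def __len__(self) -> int:
        return 68

    def __iter__(self) -> Iterator[RoiDescriptor]:
        return iter(self._rois)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Atlas) and self._rois == other._rois

    @property
    def rois(self) -> tuple[RoiDescriptor, ...]:
        return self._rois

    def roi(self, index: int) -> RoiDescriptor:
        """Look up a region by its 1-based atlas index."""
        if not 1 <= index <= 68:
            raise ValidationError(f"ROI index {index} outside 1-68")
        return self._rois[index - 1]

    def by_label(self, abbreviation: str, hemisphere: str) -> RoiDescriptor:
        """Look up a region by abbreviation and hemisphere."""
        try:
            return self._by_label[(abbreviation, hemisphere)]
        except KeyError:
            raise ValidationError(
                f"no ROI {abbreviation!r} in {hemisphere} hemisphere"
            ) from None

    def indices(self, lobe: str = "all", hemisphere: str = "both") -> frozenset[int]:
        """Indices matching a lobe and hemisphere filter (see :func:`rois_in`)."""
        return rois_in(self, lobe, hemisphere)

    # -- on-disk representation -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self._rois],
                "name": [r.name for r in self._rois],
                "abbreviation": [r.abbreviation for r in self._rois],
                "hemisphere": [r.hemisphere for r in self._rois],
                "lobe": [r.lobe for r in self._rois],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Export as delimited text, one row per ROI."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        required = {"index", "name", "abbreviation", "hemisphere", "lobe"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"atlas table missing columns {sorted(missing)}")
        df = df.sort_values("index")
        return cls(
            RoiDescriptor(
                index=int(row["index"]),
                name=str(row["name"]),
                abbreviation=str(row["abbreviation"]),
                hemisphere=str(row["hemisphere"]),
                lobe=str(row["lobe"]),
            )
            for _, row in df.iterrows()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Atlas":
        return cls.from_frame(pd.read_csv(path))


def load_default_atlas() -> Atlas:
    """Load the packaged 68-region rearranged Desikan-Killiany atlas.

    Raises
    ------
    AtlasIntegrityError
        If the packaged CSV does not match its recorded SHA-256 checksum.
    """
    ref = resources.files("fdnet") / "data" / "atlas.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _ATLAS_SHA256:
        raise AtlasIntegrityError(
            f"packaged atlas checksum mismatch: {digest} != {_ATLAS_SHA256}"
        )
    import io as _io

    return Atlas.from_frame(pd.read_csv(_io.BytesIO(raw)))


def rois_in(atlas: Atlas, lobe: str = "all", hemisphere: str = "both") -> frozenset[int]:
    """Set of 1-based ROI indices matching both filters.

    Parameters
    ----------
    lobe : {"frontal", "temporal", "parietal", "occipital", "all"}
    hemisphere : {"left", "right", "both"}
    """
    if lobe not in LOBES and lobe != "all":
        raise ValidationError(f"bad lobe filter {lobe!r}")
    if hemisphere not in HEMISPHERES and hemisphere != "both":
        raise ValidationError(f"bad hemisphere filter {hemisphere!r}")
    return frozenset(
        r.index
        for r in atlas
        if (lobe == "all" or r.lobe == lobe)
        and (hemisphere == "both" or r.hemisphere == hemisphere)
    )
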