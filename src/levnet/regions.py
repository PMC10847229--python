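"""Brain-region vocabulary and the bilateral region pairing.

The analysis operates on 28 bilateral regions of the mouse brain atlas
(27 cortical/subcortical analysis regions plus the cerebellum, which serves
as the normalization reference for SUVr and is excluded from network
construction).  Unilateral atlas extractions carry 56 labels (left/right of
each bilateral region); :class:`RegionPairing` holds the 56 -> 28 mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "REFERENCE_REGION",
    "DEFAULT_REGIONS",
    "RegionPairing",
    "load_default_pairing",
]

#: Reference region used for SUVr normalization.
REFERENCE_REGION = "Cerebellum"

#: The 27 bilateral analysis regions (reference region excluded).
DEFAULT_REGIONS: tuple[str, ...] = (
    "AI", "AuDMV", "CC", "Cg", "CPu", "DI", "DLIVEnt", "DLO", "ECT",
    "Fornix", "FrA", "HIP", "LO", "M1", "M2", "MO", "PRH", "PrL", "PtA",
    "PtPR", "RSC", "S1", "S2", "TeA", "TH", "V1V2", "VO",
)


@dataclass(frozen=True)
class RegionPairing:
    """Mapping from unilateral atlas labels to bilateral region names.

    Each bilateral region must have exactly two unilateral members
    (left and right); each unilateral label maps to exactly one bilateral
    label.
    """

    mapping: Mapping[str, str]
    full_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for bilateral in self.mapping.values():
            counts[bilateral] = counts.get(bilateral, 0) + 1
        bad = {b: c for b, c in counts.items() if c != 2}
        if bad:
            raise ValueError(
                f"every bilateral region needs exactly two unilateral members; got {bad}"
            )

    @property
    def unilateral_labels(self) -> list[str]:
        return list(self.mapping)

    @property
    def bilateral_labels(self) -> list[str]:
        seen: list[str] = []
        for b in self.mapping.values():
            if b not in seen:
                seen.append(b)
        return seen

    def members(self, bilateral: str) -> list[str]:
        """The two unilateral labels of ``bilateral``, in file order."""
        return [u for u, b in self.mapping.items() if b == bilateral]

    @classmethod
    def from_csv(cls, path) -> "RegionPairing":
        df = pd.read_csv(path)
        if not {"unilateral", "bilateral"} <= set(df.columns):
            raise ValueError("pairing file needs 'unilateral' and 'bilateral' columns")
        mapping = dict(zip(df["unilateral"], df["bilateral"]))
        if len(mapping) != len(df):
            raise ValueError("duplicate unilateral labels in pairing file")
        full = (
            dict(zip(df["bilateral"], df["full_name"]))
            if "full_name" in df.columns
            else {}
        )
        return cls(mapping=mapping, full_names=full)


def load_default_pairing() -> RegionPairing:
    """Load the packaged 56 -> 28 atlas pairing table."""
    with resources.files("levnet").joinpath("data/region_pairing.csv").open() as fh:
        return RegionPairing.from_csv(fh)
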