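"""The DescriptorBlock container shared by all descriptor-producing modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognised block tags.
BLOCK_TAGS = (
    "aligned_z", "acc", "macc", "ctd", "so_paa", "aac_dc", "ligand", "cross",
)


@dataclass
class DescriptorBlock:
    """A named numeric matrix (entities x descriptors).

    ``data`` is a DataFrame whose index holds entity ids and whose columns hold
    unique descriptor names.  ``tag`` identifies the description scheme and
    ``scaled`` records whether unit-variance (and block) scaling has been
    applied.
    """

    data: pd.DataFrame
    tag: str
    scaled: bool = False
    block_weight: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate descriptor names in block")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate entity ids in block")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("block contains missing or non-finite values")

    @property
    def n_entities(self) -> int:
        return self.data.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    @property
    def entity_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, entity_ids) -> "DescriptorBlock":
        return replace(self, data=self.data.loc[list(entity_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str) -> "DescriptorBlock":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=df, tag=tag)
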