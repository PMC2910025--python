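"""Kinase x inhibitor interaction activity matrices.

Activities are pK_d values (negative log10 of the dissociation constant).
Pairs that did not interact in the primary screen (detection limit pK_d = 5)
carry a floor value (pK_d = 4 by convention, one unit below the detection
limit) and are flagged in the ``inactive`` mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_FLOOR = 4.0
DEFAULT_DETECTION_LIMIT = 5.0


@dataclass
class ActivityMatrix:
    """pK_d values (kinases x inhibitors) plus the inactive mask."""

    values: pd.DataFrame
    inactive: pd.DataFrame
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.inactive.index) or not (
            self.values.columns.equals(self.inactive.columns)
        ):
            raise ValueError("values and inactive mask must share axes")
        vals = self.values.to_numpy(dtype=float)
        mask = self.inactive.to_numpy(dtype=bool)
        if not np.allclose(vals[mask], self.floor):
            raise ValueError("inactive cells must equal the floor value")
        if np.any(np.isclose(vals, self.floor) & ~mask):
            raise ValueError("floor-valued cells must be flagged inactive")

    @property
    def kinase_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def inhibitor_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_pairs(self) -> int:
        return int(self.values.size)

    def active_fraction(self) -> float:
        return float(1.0 - self.inactive.to_numpy().mean())

    def to_long(self) -> pd.DataFrame:
        """One row per kinase-inhibitor pair: kinase, inhibitor, pkd, inactive."""
        long = self.values.stack().rename("pkd").reset_index()
        long.columns = ["kinase", "inhibitor", "pkd"]
        long["inactive"] = self.inactive.stack().to_numpy()
        return long

    def to_tsv(self, values_path: str | Path, mask_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="kinase")
        self.inactive.astype(int).to_csv(mask_path, sep="\t", index_label="kinase")

    @classmethod
    def from_tsv(cls, values_path: str | Path, mask_path: str | Path,
                 floor: float = DEFAULT_FLOOR) -> "ActivityMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
        return cls(values=values, inactive=mask, floor=floor)
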