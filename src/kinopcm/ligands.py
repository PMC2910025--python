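"""Ligand (inhibitor) descriptor table ingestion and redundancy pruning.

Descriptor computation itself (Dragon/Corina-style software) is out of scope;
any numeric table with one row per compound is accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import DescriptorBlock


def load_ligand_table(path: str | Path, sep: str | None = None) -> DescriptorBlock:
    """Read a CSV/TSV ligand table (id column first, numeric columns after).

    Constant (zero-variance) columns are dropped with a warning; non-numeric
    cells and duplicate compound ids are rejected.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant descriptor(s): "
                      f"{constant[:5]}{'...' if len(constant) > 5 else ''}")
        df = df.drop(columns=constant)
    return DescriptorBlock(data=df, tag="ligand")


def prune_correlated(
    table: DescriptorBlock, r2_threshold: float = 0.9
) -> tuple[DescriptorBlock, pd.DataFrame]:
    """Iteratively remove redundant descriptors until no pair has r^2 above
    the threshold.

    At each step the pair with the highest squared Pearson correlation is
    located and the member whose maximum r^2 against the *other* remaining
    descriptors (the partner excluded) is larger gets dropped; ties break
    lexicographically by name so the result is order-independent.  Returns
    the surviving table and a removal log (descriptor, partner, r2).
    """
    df = table.data.copy()
    if df.shape[0] < 2:
        raise ValueError("need at least 2 compounds to compute correlations")
    removed: list[tuple[str, str, float]] = []
    while df.shape[1] >= 2:
        r2 = df.corr().to_numpy() ** 2
        np.fill_diagonal(r2, 0.0)
        r2 = np.nan_to_num(r2)
        i, j = np.unravel_index(np.argmax(r2), r2.shape)
        if r2[i, j] <= r2_threshold:
            break
        names = list(df.columns)
        # worst offender: larger max r^2 vs the rest of the set
        r2_i = np.delete(r2[i], [i, j]).max() if df.shape[1] > 2 else 0.0
        r2_j = np.delete(r2[j], [i, j]).max() if df.shape[1] > 2 else 0.0
        if r2_i > r2_j:
            drop, keep = i, j
        elif r2_j > r2_i:
            drop, keep = j, i
        else:  # tie: drop the lexicographically later name
            drop, keep = (i, j) if names[i] > names[j] else (j, i)
        removed.append((names[drop], names[keep], float(r2[i, j])))
        df = df.drop(columns=[names[drop]])
    log = pd.DataFrame(removed, columns=["removed", "partner", "r2"])
    pruned = DescriptorBlock(data=df, tag=table.tag, meta=dict(table.meta))
    return pruned, log
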