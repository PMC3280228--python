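"""Cross-organism family accounting over presence/absence matrices.

The substrate is an organisms x family-numbers matrix of member counts
(families 1-24), with group labels (vascular plant, moss, alga, mammal,
fungus). Fungal inventories are recorded as presence flags only, so
their totals are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

N_FAMILIES = 24


@dataclass
class FamilyMatrix:
    counts: pd.DataFrame    # organisms x 1..24, float with NaN where absent/unknown
    presence: pd.DataFrame  # organisms x 1..24, bool
    groups: pd.Series       # organism -> group label

    def __post_init__(self):
        if not self.counts.index.equals(self.presence.index):
            raise InputError("counts and presence row sets differ")
        if (self.counts.fillna(1) < 1).any().any():
            raise InputError("family counts must be >= 1 where present")

    @property
    def organisms(self) -> list[str]:
        return list(self.counts.index)

    def organisms_in_group(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("organism")
        groups = df.pop("group")
        fam_cols = [int(c) for c in df.columns]
        if fam_cols != list(range(1, N_FAMILIES + 1)):
            raise InputError("expected family columns 1..24")
        counts = pd.DataFrame(np.nan, index=df.index, columns=fam_cols)
        presence = pd.DataFrame(False, index=df.index, columns=fam_cols)
        for org in df.index:
            for col, fam in zip(df.columns, fam_cols):
                cell = df.loc[org, col]
                if cell == "-":
                    continue
                presence.loc[org, fam] = True
                if cell != "+":
                    counts.loc[org, fam] = int(cell)
        return cls(counts, presence, groups)


def _check_organisms(fm: FamilyMatrix, organisms: Iterable[str]) -> list[str]:
    organisms = list(organisms)
    unknown = [o for o in organisms if o not in fm.presence.index]
    if unknown:
        raise InputError(f"unknown organisms: {unknown}")
    return organisms


def core_families(fm: FamilyMatrix, organisms: Sequence[str]) -> set[int]:
    """Families present in every listed organism."""
    organisms = _check_organisms(fm, organisms)
    if not organisms:
        return set()
    mask = fm.presence.loc[organisms].all(axis=0)
    return set(mask[mask].index)


def shared_with(
    fm: FamilyMatrix,
    core: set[int],
    organisms: Sequence[str],
    mode: Literal["any", "all"] = "any",
) -> set[int]:
    """Core families also present in (any|all) of the listed organisms."""
    organisms = _check_organisms(fm, organisms)
    if not organisms:
        return set()
    sub = fm.presence.loc[organisms]
    mask = sub.any(axis=0) if mode == "any" else sub.all(axis=0)
    return core & set(mask[mask].index)


def organism_totals(fm: FamilyMatrix) -> pd.Series:
    """Per-organism gene totals (row sums).

    Organisms recorded with presence flags only (no numeric counts, like
    the fungal row) have undefined totals, reported as NaN.
    """
    totals = fm.counts.sum(axis=1, min_count=0)
    flags_only = fm.presence.any(axis=1) & fm.counts.isna().all(axis=1)
    totals[flags_only] = np.nan
    return totals
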