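"""Tissue-specificity index and cross-pipeline set comparison.

The tissue-specificity index of miRNA j over N tissues is

    TSI_j = sum_i (1 - x_ij) / (N - 1)

where x_ij is the (TMM) expression of miRNA j in tissue i divided by the
maximal expression of j over the N tissues.  TSI is 0 for a perfectly
uniform profile and 1 for expression confined to a single tissue.

Set comparison reconciles miRNA identifiers across pipelines through an
optional alias map (different pipelines may annotate against different
reference versions) and partitions two or three call sets into their exact
Venn regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import FLOAT_PRECISION, GroupMeanMatrix


@dataclass
class TSITable:
    """Per-miRNA tissue-specificity index with the normalized profile."""

    tsi: pd.Series                 # index: mirna_id, values in [0, 1]
    normalized_profile: pd.DataFrame  # x_ij in [0, 1], row max 1
    n_tissues: int

    def __post_init__(self) -> None:
        v = self.tsi.to_numpy(dtype=float)
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("TSI values must lie in [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("TSI needs at least 2 tissues")

    def write(self, path, delimiter: str = "\t") -> None:
        out = self.tsi.rename("tsi")
        out.index.name = "mirna_id"
        out.to_csv(path, sep=delimiter, float_format=f"%.{FLOAT_PRECISION}g")


def compute_tsi(means: GroupMeanMatrix) -> TSITable:
    """TSI per miRNA from a miRNA x tissue (or organ) mean-expression matrix.

    miRNAs with zero expression everywhere are excluded with a warning (the
    index is undefined for them).
    """
    df = means.df
    n = df.shape[1]
    if n < 2:
        raise ValueError(f"TSI needs at least 2 groups, got {n}")
    row_max = df.max(axis=1)
    zero = row_max <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} miRNAs with zero expression from TSI"
        )
    kept = df.loc[~zero]
    x = kept.div(row_max.loc[~zero], axis=0)
    tsi = (1.0 - x).sum(axis=1) / (n - 1)
    return TSITable(tsi=tsi, normalized_profile=x, n_tissues=n)


def reconcile_ids(
    sets: Mapping[str, Iterable[str]],
    alias: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Map every id-list through an alias table onto a common namespace.

    The alias map must be functional (one output per input); ids without an
    alias pass through unchanged.  Two members of one set collapsing onto the
    same target are deduplicated with a warning.
    """
    alias = dict(alias) if alias is not None else {}
    out: dict[str, set[str]] = {}
    for name, ids in sets.items():
        mapped: set[str] = set()
        for i in ids:
            target = alias.get(i, i)
            if target in mapped and alias.get(i, None) is not None:
                warnings.warn(
                    f"set {name!r}: {i!r} collides with an existing member "
                    f"under alias {target!r}; deduplicated"
                )
            mapped.add(target)
        out[name] = mapped
    return out


def read_alias_map(path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column alias file (old id -> common id); must be functional."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("alias map needs two columns")
    dup = df[df.iloc[:, 0].duplicated(keep=False)]
    conflicting = dup.groupby(dup.columns[0]).nunique()
    bad = conflicting[conflicting.iloc[:, 0] > 1]
    if len(bad):
        raise ValueError(f"non-functional alias map; multiple targets for {list(bad.index)}")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


@dataclass
class OverlapReport:
    """Exact Venn-region partition of 2 or 3 named id-sets.

    ``regions`` maps a sorted tuple of set names to the ids belonging to
    exactly those sets; regions are disjoint and cover the union.
    """

    set_names: list[str]
    regions: dict[tuple[str, ...], set[str]]

    def region(self, *names: str) -> set[str]:
        return self.regions.get(tuple(sorted(names)), set())

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(k), "n": len(v), "members": ";".join(sorted(v))}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["region", "n", "members"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def overlap(sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Partition 2 or 3 id-sets into their exact intersection regions."""
    named = {name: set(ids) for name, ids in sets.items()}
    if not (2 <= len(named) <= 3):
        raise ValueError(f"overlap supports 2 or 3 sets, got {len(named)}")
    names = list(named)
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set().union(*(named[n] for n in names if n not in combo))
            regions[tuple(sorted(combo))] = inside - outside
    return OverlapReport(set_names=names, regions=regions)
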