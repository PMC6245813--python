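"""Core containers and tabular I/O for multi-tissue miRNA count atlases.

The universal input is a miRNA x sample count matrix (raw read counts, or
fractional values after locus scaling / normalization) together with a sample
sheet mapping each sample to a tissue and each tissue to exactly one organ.
The default tissue->organ grouping ships with the package and reproduces the
23-tissue / 14-organ layout of the rat body atlas this tool was designed
around (kidney cortex/kidney/medulla -> Kidney; glandular and non-glandular
stomach -> Stomach; duodenum/ileum/jejunum -> Intestine; brainstem/cerebellum/
cerebrum/hippocampus -> Brain; biceps/soleus -> Muscle; every other tissue is
its own organ).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: Decimal places used when writing numeric tables; values round-trip at this
#: precision.
FLOAT_PRECISION = 6

#: Default field delimiter for all tabular I/O (configurable per call).
DEFAULT_DELIMITER = "\t"

GroupKind = Literal["tissue", "organ"]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen[lab] = seen.get(lab, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative miRNA x sample matrix.

    Rows are miRNA identifiers (mature, precursor or isomiR -- opaque labels),
    columns are sample identifiers.  Values are raw counts or any non-negative
    derived quantity (locus-scaled counts, TMM-normalized expression, ...).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if not isinstance(df, pd.DataFrame):
            raise TypeError("CountMatrix expects a pandas DataFrame")
        df = df.copy()
        df.index = [str(i).strip() for i in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        _check_unique(list(df.index), "miRNA ids")
        _check_unique(list(df.columns), "sample ids")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in count matrix: {exc}") from exc
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[r, c]} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        self.df = df.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (column sums)."""
        return self.df.sum(axis=0)

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        mirna_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "CountMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(mirna_ids), columns=list(sample_ids)))


def read_count_matrix(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> CountMatrix:
    """Read a count matrix: first column = miRNA ids, header row = sample ids."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, encoding="utf-8")
    df.index.name = None
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (TypeError, ValueError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell at row {bad.index[0]!r}, column {col!r} "
                f"(value {bad.iloc[0]!r})"
            )
    return CountMatrix(out)


def write_count_matrix(
    counts: CountMatrix,
    path: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
    precision: int = FLOAT_PRECISION,
) -> None:
    df = counts.df.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep=delimiter, float_format=f"%.{precision}g", encoding="utf-8")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "tissue", "organ", "sex", "animal"]


def default_organ_map() -> dict[str, str]:
    """The packaged 23-tissue / 14-organ grouping."""
    with resources.files("mirtisect.data").joinpath("tissue_organ_map.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["tissue"], df["organ"]))


@dataclass
class SampleSheet:
    """Sample -> tissue -> organ mapping with replicate structure."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        for c in SAMPLE_SHEET_COLUMNS:
            df[c] = df[c].astype(str).str.strip()
        _check_unique(list(df["sample_id"]), "sample ids")
        organs_per_tissue = df.groupby("tissue")["organ"].nunique()
        bad = organs_per_tissue[organs_per_tissue > 1]
        if len(bad):
            raise ValueError(
                f"tissues mapped to more than one organ: {list(bad.index)}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.df["tissue"]))

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(self.df["organ"]))

    def tissue_to_organ(self) -> dict[str, str]:
        return dict(zip(self.df["tissue"], self.df["organ"]))

    def groups(self, kind: GroupKind) -> dict[str, list[str]]:
        """Ordered mapping group label -> member sample ids."""
        if kind not in ("tissue", "organ"):
            raise ValueError(f"unknown group kind {kind!r}")
        out: dict[str, list[str]] = {}
        for _, row in self.df.iterrows():
            out.setdefault(row[kind], []).append(row["sample_id"])
        return out

    def require_covers(self, counts: CountMatrix) -> None:
        """Hard error if the matrix has samples the sheet does not describe."""
        known = set(self.sample_ids)
        orphans = [s for s in counts.sample_ids if s not in known]
        if orphans:
            raise ValueError(
                f"samples present in the count matrix but absent from the "
                f"sample sheet: {orphans}"
            )


def read_sample_sheet(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8"))


def write_sample_sheet(
    sheet: SampleSheet, path: str | Path, delimiter: str = DEFAULT_DELIMITER
) -> None:
    sheet.df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Per-miRNA annotation: genomic locus count, isomiR parentage, class."""

    df: pd.DataFrame  # mirna_id, n_loci, parent_mature_id, feature_class

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = ["mirna_id", "n_loci"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if "parent_mature_id" not in df.columns:
            df["parent_mature_id"] = ""
        if "feature_class" not in df.columns:
            df["feature_class"] = "mature"
        df["mirna_id"] = df["mirna_id"].astype(str).str.strip()
        df["parent_mature_id"] = df["parent_mature_id"].fillna("").astype(str).str.strip()
        _check_unique(list(df["mirna_id"]), "annotation miRNA ids")
        df["n_loci"] = pd.to_numeric(df["n_loci"], errors="raise").astype(int)
        if (df["n_loci"] < 1).any():
            bad = df.loc[df["n_loci"] < 1, "mirna_id"].tolist()
            raise ValueError(f"n_loci must be >= 1; violated for {bad}")
        bad_class = set(df["feature_class"]) - {"mature", "pre", "isomiR"}
        if bad_class:
            raise ValueError(f"unknown feature_class values: {sorted(bad_class)}")
        iso = df[df["feature_class"] == "isomiR"]
        orphan = iso.loc[iso["parent_mature_id"] == "", "mirna_id"].tolist()
        if orphan:
            raise ValueError(f"isomiR records without parent_mature_id: {orphan}")
        self.df = df.reset_index(drop=True)

    def n_loci(self) -> pd.Series:
        return self.df.set_index("mirna_id")["n_loci"]

    def parents(self) -> pd.Series:
        iso = self.df[self.df["feature_class"] == "isomiR"]
        return iso.set_index("mirna_id")["parent_mature_id"]


def read_annotation(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8"))


# ---------------------------------------------------------------------------
# EnrichmentCall
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentCall:
    """A per-miRNA verdict from one pipeline.

    ``score`` is the pipeline's natural evidence scale: share of total
    expression (nmf, proportion) or excess percentage points / log mean ratio
    (quasipoisson).  ``p_value`` is present only for the quasi-Poisson
    pipeline.
    """

    mirna_id: str
    pipeline: Literal["nmf", "quasipoisson", "proportion"]
    status: Literal["TE", "TS", "OS", "none"]
    target: str
    score: float
    p_value: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def calls_to_frame(calls: Iterable[EnrichmentCall]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": c.mirna_id,
            "pipeline": c.pipeline,
            "status": c.status,
            "target": c.target,
            "score": c.score,
            "p_value": np.nan if c.p_value is None else c.p_value,
            "flags": ";".join(c.flags),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "pipeline", "status", "target", "score", "p_value", "flags"]
    )


def write_calls(
    calls: Iterable[EnrichmentCall], path: str | Path,
    delimiter: str = DEFAULT_DELIMITER, header_comment: str | None = None,
) -> None:
    df = calls_to_frame(calls)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=delimiter, index=False, float_format=f"%.{FLOAT_PRECISION}g")


# ---------------------------------------------------------------------------
# GroupMeanMatrix and group-level operations
# ---------------------------------------------------------------------------

@dataclass
class GroupMeanMatrix:
    """miRNA x group matrix of mean expression over each group's samples."""

    df: pd.DataFrame
    group_kind: GroupKind

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ValueError("group means must be non-negative")

    @property
    def groups(self) -> list[str]:
        return list(self.df.columns)


def group_means(counts: CountMatrix, sheet: SampleSheet, kind: GroupKind) -> GroupMeanMatrix:
    """Arithmetic mean of each miRNA over the samples of each tissue/organ.

    Every sample in ``counts`` must be described by ``sheet``; a group whose
    samples are entirely absent from the matrix is an error.
    """
    sheet.require_covers(counts)
    present = set(counts.sample_ids)
    cols = {}
    for grp, samples in sheet.groups(kind).items():
        members = [s for s in samples if s in present]
        if not members:
            raise ValueError(f"{kind} {grp!r} has no samples in the count matrix")
        cols[grp] = counts.df[members].mean(axis=1)
    return GroupMeanMatrix(pd.DataFrame(cols), group_kind=kind)


def group_sums(counts: CountMatrix, sheet: SampleSheet, kind: GroupKind = "tissue") -> CountMatrix:
    """Per-group summed counts (pooling replicates), as a miRNA x group matrix."""
    sheet.require_covers(counts)
    present = set(counts.sample_ids)
    cols = {}
    for grp, samples in sheet.groups(kind).items():
        members = [s for s in samples if s in present]
        if not members:
            raise ValueError(f"{kind} {grp!r} has no samples in the count matrix")
        cols[grp] = counts.df[members].sum(axis=1)
    return CountMatrix(pd.DataFrame(cols))


def aggregate_to_organ_max(
    tissue_matrix: CountMatrix | GroupMeanMatrix,
    organ_map: Mapping[str, str] | SampleSheet,
) -> CountMatrix:
    """Collapse tissue columns to organ columns by element-wise maximum.

    Single-tissue organs pass through unchanged.  The max (rather than the
    mean) avoids diluting an organ-level signal carried by one member tissue.
    """
    df = tissue_matrix.df
    mapping = organ_map.tissue_to_organ() if isinstance(organ_map, SampleSheet) else dict(organ_map)
    missing = [t for t in df.columns if t not in mapping]
    if missing:
        raise ValueError(f"tissues missing from the organ map: {missing}")
    organ_members: dict[str, list[str]] = {}
    for tissue in df.columns:
        organ_members.setdefault(mapping[tissue], []).append(tissue)
    cols = {organ: df[members].max(axis=1) for organ, members in organ_members.items()}
    return CountMatrix(pd.DataFrame(cols))
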