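"""Proportion-of-total detection of enriched/specific miRNAs, and isomiR
dominance comparison.

Raw counts are first divided by each miRNA's number of assigned genomic loci
(multi-locus reads would otherwise be counted once per locus), TMM-normalized,
and floored (rows below 10 TMM in every sample are dropped).  A miRNA is
called tissue-enriched when a single tissue carries more than half of its
total mean expression, and tissue-/organ-specific when a single tissue/organ
carries more than 0.9 of it.

For isomiRs, each variant's expression is expressed as a proportion of its
parent mature miRNA's total within a tissue; the tool reports matures whose
dominant (most expressed) isomiR is not the same in every tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .datamodel import (
    AnnotationTable,
    CountMatrix,
    EnrichmentCall,
    GroupKind,
    GroupMeanMatrix,
    SampleSheet,
    group_means,
)
from .normalization import filter_counts, tmm_normalize

DEFAULT_TE_THRESHOLD = 0.5
DEFAULT_TS_THRESHOLD = 0.9


@dataclass
class ProportionProfile:
    """A miRNA's share of total mean expression per tissue (or organ)."""

    mirna_id: str
    shares: pd.Series       # per-group fractions summing to 1
    max_group: str
    max_share: float

    def __post_init__(self) -> None:
        s = self.shares.to_numpy(dtype=float)
        if (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise ValueError("shares must lie in [0, 1]")
        if abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("shares must sum to 1")


@dataclass
class IsomiRDominance:
    mature_id: str
    per_tissue: dict[str, tuple[str, float]]  # tissue -> (dominant isomiR, proportion)
    differs_across_tissues: bool
    flags: tuple[str, ...] = ()


def scale_by_loci(counts: CountMatrix, annot: AnnotationTable) -> CountMatrix:
    """Divide each miRNA row by its number of assigned genomic loci."""
    loci = annot.n_loci()
    missing = [m for m in counts.mirna_ids if m not in loci.index]
    if missing:
        raise ValueError(f"miRNAs without a loci annotation: {missing}")
    return CountMatrix(counts.df.div(loci.loc[counts.mirna_ids], axis=0))


def proportion_profile(means: GroupMeanMatrix) -> list[ProportionProfile]:
    """Per-miRNA group shares (mean / row total); zero-total rows are skipped."""
    profiles: list[ProportionProfile] = []
    for mid, row in means.df.iterrows():
        total = row.sum()
        if total <= 0:
            warnings.warn(f"miRNA {mid!r} has zero total expression; excluded")
            continue
        shares = row / total
        top = shares.idxmax()
        profiles.append(ProportionProfile(
            mirna_id=str(mid), shares=shares,
            max_group=str(top), max_share=float(shares.loc[top]),
        ))
    return profiles


def classify_proportion(
    profiles: Iterable[ProportionProfile],
    te_threshold: float = DEFAULT_TE_THRESHOLD,
    ts_threshold: float = DEFAULT_TS_THRESHOLD,
    level: GroupKind = "tissue",
) -> list[EnrichmentCall]:
    """TE when the top share is strictly above ``te_threshold``; TS (tissue
    level) or OS (organ level) strictly above ``ts_threshold``."""
    if not (0 < te_threshold <= 1 and 0 < ts_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if te_threshold > ts_threshold:
        raise ValueError("te_threshold must not exceed ts_threshold")
    specific_status = "TS" if level == "tissue" else "OS"
    calls: list[EnrichmentCall] = []
    for prof in profiles:
        if prof.max_share > te_threshold:
            calls.append(EnrichmentCall(
                prof.mirna_id, "proportion", "TE", prof.max_group, prof.max_share
            ))
            if prof.max_share > ts_threshold:
                calls.append(EnrichmentCall(
                    prof.mirna_id, "proportion", specific_status,
                    prof.max_group, prof.max_share,
                ))
    return calls


def isomir_dominance(
    iso_counts: CountMatrix,
    annot: AnnotationTable,
    sheet: SampleSheet,
) -> list[IsomiRDominance]:
    """Dominant isomiR per tissue and whether it changes across tissues.

    Within a tissue, an isomiR's proportion is its mean count divided by the
    summed mean count of all isomiRs of the same mature miRNA.  Exact ties
    are broken lexicographically and flagged.  Tissues where the mature total
    is zero are skipped with a warning.
    """
    parents = annot.parents()
    orphan = [m for m in iso_counts.mirna_ids if m not in parents.index]
    if orphan:
        raise ValueError(f"isomiR rows without a parent mature annotation: {orphan}")
    means = group_means(iso_counts, sheet, "tissue")
    by_mature: dict[str, list[str]] = {}
    for iso in iso_counts.mirna_ids:
        by_mature.setdefault(parents.loc[iso], []).append(iso)

    out: list[IsomiRDominance] = []
    for mature, isos in by_mature.items():
        per_tissue: dict[str, tuple[str, float]] = {}
        flags: list[str] = []
        for tissue in means.df.columns:
            col = means.df.loc[isos, tissue]
            total = col.sum()
            if total <= 0:
                warnings.warn(
                    f"mature {mature!r} has zero expression in {tissue!r}; skipped"
                )
                continue
            props = (col / total).sort_index()
            best = props.max()
            winners = list(props.index[props == best])
            if len(winners) > 1:
                flags.append(f"tie:{tissue}")
            per_tissue[str(tissue)] = (str(winners[0]), float(best))
        dominant_ids = {d for d, _ in per_tissue.values()}
        out.append(IsomiRDominance(
            mature_id=str(mature), per_tissue=per_tissue,
            differs_across_tissues=len(dominant_ids) > 1, flags=tuple(flags),
        ))
    return out


def run_proportion_pipeline(
    counts: CountMatrix,
    sheet: SampleSheet,
    annot: AnnotationTable | None = None,
    te_threshold: float = DEFAULT_TE_THRESHOLD,
    ts_threshold: float = DEFAULT_TS_THRESHOLD,
    level: GroupKind = "tissue",
    use_tmm: bool = True,
    filter_threshold: float | None = None,
) -> list[EnrichmentCall]:
    """Full pipeline: loci scaling, TMM, abundance floor, shares, thresholds.

    ``use_tmm=False`` computes shares on raw (loci-scaled) counts instead of
    TMM-normalized values, for a strict reads-aligned reading of the rule.
    """
    work = scale_by_loci(counts, annot) if annot is not None else counts
    if use_tmm:
        work = tmm_normalize(work)
        work = filter_counts(work, sheet, "maastricht", threshold=filter_threshold)
    means = group_means(work, sheet, level)
    profiles = proportion_profile(means)
    return classify_proportion(profiles, te_threshold, ts_threshold, level=level)
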