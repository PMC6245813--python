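"""Count normalization and read-count filtering.

TMM (trimmed mean of M-values) follows the Robinson-Oshlack procedure with
the standard defaults: the reference sample is the one whose 75th-percentile
count fraction is closest to the mean over samples; per sample, log2 ratios
(M) and average log2 abundances (A) against the reference are doubly trimmed
(30% on M, 5% on A) and the retained M-values are combined by a
precision-weighted mean.  Factors are rescaled so their geometric mean is 1,
making them comparable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import CountMatrix, GroupKind, SampleSheet, aggregate_to_organ_max, group_sums

TRIM_LOGRATIO = 0.30
TRIM_ABS = 0.05

#: Default read-count filter thresholds per pipeline rule.
FILTER_DEFAULTS = {"lilly": 10.0, "niehs": 3.0, "maastricht": 10.0}


@dataclass
class TMMFactors:
    """Per-sample TMM scaling factors (geometric mean 1)."""

    factors: pd.Series
    reference_sample: str
    trim_logratio: float = TRIM_LOGRATIO
    trim_abs: float = TRIM_ABS

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")

    def write(self, path, delimiter: str = "\t") -> None:
        out = self.factors.rename("tmm_factor")
        out.index.name = "sample_id"
        out.to_csv(path, sep=delimiter, float_format="%.10g")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_logratio: float, trim_abs: float,
) -> float:
    """Pairwise TMM factor of one library against the reference."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method precision weights for a binomial count proportion
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_abs) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    log2f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(log2f):
        return 1.0
    return float(2.0 ** log2f)


def tmm_factors(
    counts: CountMatrix,
    trim_logratio: float = TRIM_LOGRATIO,
    trim_abs: float = TRIM_ABS,
) -> TMMFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample."""
    libs = counts.library_sizes()
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    zero = list(libs[libs <= 0].index)
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")

    values = counts.values
    # reference: sample whose upper-quartile count fraction is closest to the mean
    f75 = np.array([
        np.quantile(values[:, j], 0.75) / libs.iloc[j] for j in range(values.shape[1])
    ])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = values[:, ref_idx]
    n_ref = libs.iloc[ref_idx]

    raw = np.array([
        _tmm_pair(values[:, j], ref, libs.iloc[j], n_ref, trim_logratio, trim_abs)
        for j in range(values.shape[1])
    ])
    factors = raw / np.exp(np.mean(np.log(raw)))  # geometric mean 1
    return TMMFactors(
        factors=pd.Series(factors, index=counts.sample_ids),
        reference_sample=counts.sample_ids[ref_idx],
        trim_logratio=trim_logratio,
        trim_abs=trim_abs,
    )


def apply_tmm(counts: CountMatrix, factors: TMMFactors) -> CountMatrix:
    """Effective-library normalization: count / (library x factor) x 1e6."""
    missing = [s for s in counts.sample_ids if s not in factors.factors.index]
    if missing:
        raise ValueError(f"no TMM factor for samples: {missing}")
    libs = counts.library_sizes()
    scale = 1e6 / (libs * factors.factors.loc[counts.sample_ids])
    return CountMatrix(counts.df * scale)


def tmm_normalize(counts: CountMatrix) -> CountMatrix:
    """Convenience: estimate factors and apply them in one step."""
    return apply_tmm(counts, tmm_factors(counts))


def per_million_ceil(counts: CountMatrix) -> CountMatrix:
    """Reads-per-million scaling followed by an element-wise ceiling.

    The ceiling converts the float per-million values back to integers so a
    count model can be fit downstream.  Despite the field's occasional "TPM"
    label for this quantity, no transcript-length normalization is involved.
    """
    libs = counts.library_sizes()
    zero = list(libs[libs <= 0].index)
    if zero:
        raise ValueError(f"samples with zero library size: {zero}")
    return CountMatrix(np.ceil(counts.df / libs * 1e6))


def filter_counts(
    counts: CountMatrix,
    sheet: SampleSheet,
    rule: str,
    threshold: float | None = None,
    level: GroupKind = "tissue",
) -> CountMatrix:
    """Remove miRNAs below a pipeline's abundance floor; row order preserved.

    - ``lilly``: keep rows whose tissue/organ-level summed count is strictly
      above the threshold (default 10) in at least one group.
    - ``niehs``: the same with default threshold 3.
    - ``maastricht``: ``counts`` is expected to be TMM-normalized; keep rows
      with at least one sample at or above the threshold (default 10), i.e.
      drop rows below it in *all* samples.
    """
    if rule not in FILTER_DEFAULTS:
        raise ValueError(f"unknown filter rule {rule!r}; expected one of {sorted(FILTER_DEFAULTS)}")
    thr = FILTER_DEFAULTS[rule] if threshold is None else float(threshold)
    if rule == "maastricht":
        keep = (counts.df >= thr).any(axis=1)
    else:
        sums = group_sums(counts, sheet, "tissue")
        if level == "organ":
            sums = aggregate_to_organ_max(sums, sheet)
        keep = (sums.df > thr).any(axis=1)
    return CountMatrix(counts.df.loc[keep])
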