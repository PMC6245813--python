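"""One-vs-rest quasi-Poisson detection of enriched/specific miRNAs.

Per miRNA, a log-link Poisson-mean GLM with variance phi*mu is fit to the
per-million-ceiled counts with a single indicator covariate (target tissue or
organ vs the pooled rest).  The quasi-likelihood dispersion phi is estimated
by Pearson chi-square / residual df, and the target coefficient is tested
with a dispersion-adjusted Wald statistic against a t distribution on the
residual df.  This is a deliberate simplification of spline-adjusted
quasi-likelihood machinery: plain IRLS, Pearson dispersion, t reference.

TE: two-sided p < alpha with a positive target coefficient (nominal p-values
by default; Benjamini-Hochberg available).  TS: a TE miRNA whose group mean
exceeds every other group's mean by a percentage-point margin.  OS: the same
model and manner as TE with organ-vs-rest grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .datamodel import CountMatrix, EnrichmentCall, GroupKind, GroupMeanMatrix, SampleSheet

#: Cap used for the log mean-ratio under complete separation (one side all zero).
COEF_CAP = 700.0

DEFAULT_ALPHA = 0.05
DEFAULT_PERCENT_POINTS = 90.0


@dataclass
class QuasiPoissonResult:
    mirna_id: str
    target_group: str
    coefficient: float      # log mean ratio, target vs rest
    dispersion: float       # Pearson chi2 / df
    p_value: float
    direction_positive: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _irls_two_group(y: np.ndarray, ind: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for a log-link Poisson GLM with design [1, indicator].

    Returns (beta, mu).  Convergence is on the deviance-free score scale;
    with this saturated-by-group design the optimum is reached in a few
    steps.
    """
    X = np.column_stack([np.ones_like(ind, dtype=float), ind.astype(float)])
    mean_all = max(y.mean(), 1e-8)
    beta = np.array([np.log(mean_all), 0.0])
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu          # working response
        W = mu                            # IRLS weights for log-link Poisson
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(X @ beta, -30, 30))
    return beta, mu


def _target_indicator(
    counts: CountMatrix, sheet: SampleSheet, target: str, level: GroupKind
) -> np.ndarray:
    sheet.require_covers(counts)
    if target not in sheet.groups(level):
        raise ValueError(f"unknown {level} {target!r}")
    membership = dict(zip(sheet.df["sample_id"], sheet.df[level]))
    return np.array([membership[s] == target for s in counts.sample_ids])


def _fit_single(
    y: np.ndarray, in_target: np.ndarray, mirna_id: str, target: str
) -> QuasiPoissonResult:
    n_t = int(in_target.sum())
    n_r = int((~in_target).sum())
    if n_t < 2 or n_r < 2:
        raise ValueError(
            f"need >= 2 samples on each side; target has {n_t}, rest has {n_r}"
        )
    mean_t = y[in_target].mean()
    mean_r = y[~in_target].mean()
    if mean_t == 0 and mean_r == 0:
        return QuasiPoissonResult(mirna_id, target, 0.0, 1.0, 1.0, False, ("all_zero",))
    if mean_r == 0 or mean_t == 0:
        coef = COEF_CAP if mean_r == 0 else -COEF_CAP
        return QuasiPoissonResult(
            mirna_id, target, coef, 1.0, 0.0, mean_r == 0, ("separation",)
        )
    beta, mu = _irls_two_group(y, in_target)
    df_resid = y.size - 2
    pearson = float(((y - mu) ** 2 / mu).sum())
    dispersion = max(pearson / df_resid, 1e-12)
    # [X' W X]^-1 [1,1] for the two-group design collapses to a harmonic form
    var_beta1 = dispersion * (1.0 / (n_t * np.exp(beta[0] + beta[1]))
                              + 1.0 / (n_r * np.exp(beta[0])))
    se = float(np.sqrt(var_beta1))
    tstat = beta[1] / se
    p = float(2.0 * stats.t.sf(abs(tstat), df_resid))
    return QuasiPoissonResult(
        mirna_id, target, float(beta[1]), dispersion, p, beta[1] > 0
    )


def fit_one_vs_rest(
    counts: CountMatrix,
    sheet: SampleSheet,
    target: str,
    mirna_id: str,
    level: GroupKind = "tissue",
) -> QuasiPoissonResult:
    """Quasi-Poisson Wald test of one miRNA, target group vs pooled rest.

    ``counts`` should already be on the per-million-ceiled scale.  Complete
    separation (all-zero rest with a positive target, or vice versa) is
    reported with the coefficient capped at +/-700 and a ``separation`` flag
    rather than hidden behind pseudocounts.
    """
    if mirna_id not in counts.df.index:
        raise KeyError(f"unknown miRNA {mirna_id!r}")
    in_target = _target_indicator(counts, sheet, target, level)
    y = counts.df.loc[mirna_id].to_numpy(dtype=float)
    return _fit_single(y, in_target, mirna_id, target)


def fit_all_one_vs_rest(
    counts: CountMatrix,
    sheet: SampleSheet,
    target: str,
    level: GroupKind = "tissue",
) -> list[QuasiPoissonResult]:
    in_target = _target_indicator(counts, sheet, target, level)
    values = counts.values
    return [
        _fit_single(values[j], in_target, mid, target)
        for j, mid in enumerate(counts.mirna_ids)
    ]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def detect_te_qp(
    results: Iterable[QuasiPoissonResult],
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
) -> list[EnrichmentCall]:
    """TE calls: p < alpha (strict) and positive target-vs-rest coefficient."""
    results = list(results)
    pvals = np.array([r.p_value for r in results])
    if adjust and pvals.size:
        pvals = _bh_adjust(pvals)
    calls = []
    for r, p in zip(results, pvals):
        if p < alpha and r.direction_positive:
            calls.append(EnrichmentCall(
                r.mirna_id, "quasipoisson", "TE", r.target_group,
                float(np.clip(r.coefficient, -COEF_CAP, COEF_CAP)),
                p_value=float(p), flags=r.flags,
            ))
    return calls


def excess_percent_points(means_row: "np.ndarray | Sequence[float]", target_idx: int) -> float:
    """100 * (mean_target - max other mean) / mean_target."""
    row = np.asarray(means_row, dtype=float)
    m_t = row[target_idx]
    if m_t <= 0:
        return -np.inf
    others = np.delete(row, target_idx)
    return float(100.0 * (m_t - others.max()) / m_t)


def detect_ts_qp(
    te_calls: Iterable[EnrichmentCall],
    means: GroupMeanMatrix,
    percent_points: float = DEFAULT_PERCENT_POINTS,
    mode: Literal["excess", "share"] = "excess",
) -> list[EnrichmentCall]:
    """TS calls among TE calls, by a percentage-point margin on group means.

    ``excess`` (default): the target mean must exceed the maximum mean of any
    other group by >= ``percent_points`` percentage points of itself.
    ``share``: the target mean must account for >= ``percent_points`` percent
    of the summed group means.  TS is always a subset of TE.
    """
    ts: list[EnrichmentCall] = []
    cols = list(means.df.columns)
    for call in te_calls:
        if call.status != "TE":
            continue
        if call.target not in cols or call.mirna_id not in means.df.index:
            continue
        row = means.df.loc[call.mirna_id].to_numpy(dtype=float)
        idx = cols.index(call.target)
        if row[idx] <= 0:
            warnings.warn(f"zero target mean for {call.mirna_id!r}; not TS")
            continue
        if mode == "excess":
            score = excess_percent_points(row, idx)
        elif mode == "share":
            score = float(100.0 * row[idx] / row.sum())
        else:
            raise ValueError(f"unknown TS mode {mode!r}")
        if score >= percent_points:
            ts.append(EnrichmentCall(
                call.mirna_id, "quasipoisson", "TS", call.target,
                float(score), p_value=call.p_value, flags=call.flags,
            ))
    return ts


def detect_os_qp(
    counts: CountMatrix,
    sheet: SampleSheet,
    target_organ: str,
    alpha: float = DEFAULT_ALPHA,
    percent_points: float | None = None,
    organ_means: GroupMeanMatrix | None = None,
    adjust: bool = False,
) -> list[EnrichmentCall]:
    """OS calls: the TE machinery with organ-vs-rest grouping.

    By default an OS call needs only organ-level significance with a positive
    direction (the same manner as TE); passing ``percent_points`` additionally
    applies the excess-margin rule on organ means (requires ``organ_means``).
    """
    if target_organ not in set(sheet.df["organ"]):
        raise ValueError(f"no organ grouping for {target_organ!r}")
    results = fit_all_one_vs_rest(counts, sheet, target_organ, level="organ")
    te_like = detect_te_qp(results, alpha=alpha, adjust=adjust)
    if percent_points is not None:
        if organ_means is None:
            raise ValueError("percent_points rule needs organ_means")
        te_like = detect_ts_qp(te_like, organ_means, percent_points=percent_points)
    return [
        EnrichmentCall(c.mirna_id, "quasipoisson", "OS", c.target, c.score,
                       p_value=c.p_value, flags=c.flags)
        for c in te_like
    ]
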