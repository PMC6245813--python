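"""Expression-stratified NMF detection of enriched/specific miRNAs.

The pipeline runs on an organ-level count matrix X (miRNA x organ), obtained
by summing replicate samples within each tissue and taking the element-wise
maximum over a organ's member tissues.  Because a single factorization of a
matrix spanning five orders of magnitude is dominated by the most abundant
miRNAs, the miRNAs are first split into a high- and a low-expression stratum
with a two-component Poisson mixture fitted (EM) to their total counts, and
NMF is applied per stratum.  W rows (factor loadings per miRNA) and H rows
(organ profile per factor) are normalized to sum to 1, so W_norm @ H_norm is
each miRNA's share-of-total-expression distribution over organs; thresholds
on the maximal share yield TE / OS / TS calls, with the constraint that a
tissue-specific call requires an organ-specific call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .datamodel import (
    CountMatrix,
    EnrichmentCall,
    SampleSheet,
    aggregate_to_organ_max,
    group_sums,
)
from .normalization import filter_counts

_EPS = 1e-12

DEFAULT_TE_SHARE = 0.60
DEFAULT_TS_SHARE = 0.80
DEFAULT_RANK = 14  # one factor per organ in the default atlas layout


# ---------------------------------------------------------------------------
# Two-component Poisson mixture (EM)
# ---------------------------------------------------------------------------

@dataclass
class PoissonMixtureFit:
    weight_low: float
    weight_high: float
    lambda_low: float
    lambda_high: float
    responsibilities: np.ndarray  # posterior P(high | y_i)
    loglik_trace: list[float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if abs(self.weight_low + self.weight_high - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.lambda_low > self.lambda_high + 1e-12:
            raise ValueError("lambda_low must not exceed lambda_high")


def _poisson_logpmf(y: np.ndarray, lam: float) -> np.ndarray:
    # continuous extension via the gamma function: tolerates fractional counts
    lam = max(lam, _EPS)
    return y * np.log(lam) - lam - gammaln(y + 1.0)


def fit_poisson_mixture(
    values: Sequence[float],
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> PoissonMixtureFit:
    """EM fit of a two-component Poisson mixture to non-negative counts."""
    y = np.asarray(values, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if (y < 0).any():
        raise ValueError("observations must be non-negative")
    if not y.any():
        raise ValueError("all observations are zero")

    if np.ptp(y) == 0:  # all equal: mixture is unidentifiable
        lam = float(y[0])
        return PoissonMixtureFit(
            weight_low=0.5, weight_high=0.5, lambda_low=lam, lambda_high=lam,
            responsibilities=np.full(y.size, 0.5),
            loglik_trace=[float(_poisson_logpmf(y, lam).sum())],
            degenerate=True,
        )

    rng = np.random.default_rng(seed)
    lam = np.array([np.quantile(y, 0.25), np.quantile(y, 0.75)])
    lam = lam * (1.0 + 0.05 * rng.random(2))
    if lam[1] - lam[0] < _EPS:
        lam = np.array([0.5 * y.mean(), 1.5 * y.mean() + 1.0])
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    resp = np.full(y.size, 0.5)
    for _ in range(max_iter):
        logp = np.stack([
            np.log(w[0] + _EPS) + _poisson_logpmf(y, lam[0]),
            np.log(w[1] + _EPS) + _poisson_logpmf(y, lam[1]),
        ])
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        resp = np.exp(logp[1] - norm)  # posterior of the high component
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            break
        trace.append(ll)
        # M-step
        r1 = resp.sum()
        r0 = y.size - r1
        w = np.array([r0, r1]) / y.size
        lam = np.array([
            ((1.0 - resp) * y).sum() / max(r0, _EPS),
            (resp * y).sum() / max(r1, _EPS),
        ])
        if lam[0] > lam[1]:  # keep component 1 the high-expression one
            lam = lam[::-1]
            w = w[::-1]
            resp = 1.0 - resp

    return PoissonMixtureFit(
        weight_low=float(w[0]), weight_high=float(w[1]),
        lambda_low=float(lam[0]), lambda_high=float(lam[1]),
        responsibilities=resp, loglik_trace=trace,
    )


def stratify_by_expression(
    fit: PoissonMixtureFit, mirna_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Split miRNAs into (high, low) strata by posterior > 0.5 (ties -> low)."""
    ids = list(mirna_ids)
    if len(ids) != fit.responsibilities.size:
        raise ValueError("mirna_ids length does not match the fitted responsibilities")
    high = [m for m, r in zip(ids, fit.responsibilities) if r > 0.5]
    low = [m for m, r in zip(ids, fit.responsibilities) if r <= 0.5]
    return high, low


# ---------------------------------------------------------------------------
# NMF with generalized Kullback-Leibler multiplicative updates
# ---------------------------------------------------------------------------

@dataclass
class NMFDecomposition:
    W: np.ndarray  # miRNA x K, non-negative
    H: np.ndarray  # K x organ, non-negative
    rank: int
    objective_trace: list[float]
    seed: int
    mirna_ids: list[str] = field(default_factory=list)
    organ_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH); the Poisson-compatible objective."""
    WH = np.maximum(WH, _EPS)
    pos = X > 0
    term = np.where(pos, X * (np.log(np.maximum(X, _EPS)) - np.log(WH)), 0.0)
    return float((term - X + WH).sum())


def _nmf_single(
    X: np.ndarray, rank: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = X.shape
    scale = np.sqrt(X.mean() / rank) + _EPS
    W = scale * rng.random((n, rank)) + _EPS
    H = scale * rng.random((rank, m)) + _EPS
    trace = [_kl_divergence(X, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= (X / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (X / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = _kl_divergence(X, W @ H)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(obj), 1.0):
            break
    return W, H, trace


def nmf_decompose(
    X: CountMatrix,
    rank: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFDecomposition:
    """Factor X ~ W @ H by multiplicative updates on the generalized KL loss.

    The best of ``n_restarts`` seeded random initializations (by final
    objective; ties broken by lowest restart index) is returned, making the
    result deterministic given ``seed``.
    """
    values = X.values
    if rank < 1 or rank > min(values.shape):
        raise ValueError(f"rank must be in [1, {min(values.shape)}], got {rank}")
    best: tuple[float, int, np.ndarray, np.ndarray, list[float]] | None = None
    for i in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        W, H, trace = _nmf_single(values, rank, rng, max_iter, tol)
        if best is None or trace[-1] < best[0] - 1e-12:
            best = (trace[-1], i, W, H, trace)
    _, _, W, H, trace = best
    # canonical scaling: absorb each factor's H scale into W so rows of H sum
    # to 1; W @ H (and the objective) are unchanged, and a miRNA's normalized
    # W row combined with H then reads directly as share-of-total-expression
    h_scale = H.sum(axis=1)
    pos = h_scale > 0
    W[:, pos] = W[:, pos] * h_scale[pos]
    H[pos] = H[pos] / h_scale[pos, None]
    return NMFDecomposition(
        W=W, H=H, rank=rank, objective_trace=trace, seed=seed,
        mirna_ids=X.mirna_ids, organ_ids=X.sample_ids,
    )


# ---------------------------------------------------------------------------
# Classification from the factorization
# ---------------------------------------------------------------------------

def organ_shares(dec: NMFDecomposition) -> np.ndarray:
    """Per-miRNA share-of-total-expression over organs, from W and H.

    Rows of W are normalized to sum 1 (the miRNA's loading distribution over
    factors) and rows of H to sum 1 (each factor's organ distribution); their
    product is a probability vector over organs for every miRNA.  miRNAs with
    an all-zero W row yield an all-zero share row.
    """
    w_sums = dec.W.sum(axis=1, keepdims=True)
    h_sums = dec.H.sum(axis=1, keepdims=True)
    Wn = np.divide(dec.W, w_sums, out=np.zeros_like(dec.W), where=w_sums > 0)
    Hn = np.divide(dec.H, h_sums, out=np.zeros_like(dec.H), where=h_sums > 0)
    return Wn @ Hn


def classify_nmf(
    dec: NMFDecomposition,
    X: CountMatrix,
    te_share: float = DEFAULT_TE_SHARE,
    ts_share: float = DEFAULT_TS_SHARE,
    te_mode: Literal["any", "exclusive"] = "any",
) -> list[EnrichmentCall]:
    """TE/OS/TS calls from the factorization's organ-share vectors.

    TE: share >= ``te_share`` (under ``te_mode='any'`` a miRNA may be TE in
    several organs; under ``'exclusive'`` only when a single organ qualifies).
    OS: the maximal share reaches ``ts_share``.  TS: exactly one organ reaches
    ``ts_share`` *and* the miRNA is OS there -- a tissue-specific call always
    implies an organ-specific one.
    """
    shares = organ_shares(dec)
    organs = dec.organ_ids
    calls: list[EnrichmentCall] = []
    for j, mid in enumerate(dec.mirna_ids):
        row = shares[j]
        total = row.sum()
        if total <= 0:
            warnings.warn(f"miRNA {mid!r} has zero expression; status none")
            calls.append(EnrichmentCall(mid, "nmf", "none", "", 0.0))
            continue
        te_idx = np.flatnonzero(row >= te_share)
        if te_mode == "any" or te_idx.size == 1:
            for i in te_idx:
                calls.append(EnrichmentCall(mid, "nmf", "TE", organs[i], float(row[i])))
        top = int(np.argmax(row))
        os_call = row[top] >= ts_share
        if os_call:
            calls.append(EnrichmentCall(mid, "nmf", "OS", organs[top], float(row[top])))
            if np.count_nonzero(row >= ts_share) == 1:
                calls.append(EnrichmentCall(mid, "nmf", "TS", organs[top], float(row[top])))
    return calls


def run_nmf_pipeline(
    counts: CountMatrix,
    sheet: SampleSheet,
    rank: int | None = None,
    te_share: float = DEFAULT_TE_SHARE,
    ts_share: float = DEFAULT_TS_SHARE,
    seed: int = 0,
    n_restarts: int = 10,
    filter_threshold: float | None = None,
    stratify: bool = True,
    te_mode: Literal["any", "exclusive"] = "any",
) -> list[EnrichmentCall]:
    """Full pipeline: filter, organ aggregation, mixture stratification, NMF.

    Tissue-level counts are replicate sums; the organ matrix takes the max
    over member tissues.  When ``stratify`` is on, NMF runs separately on the
    high- and low-expression strata from the Poisson mixture.
    """
    filtered = filter_counts(counts, sheet, "lilly", threshold=filter_threshold)
    tissue_sums = group_sums(filtered, sheet, "tissue")
    X = aggregate_to_organ_max(tissue_sums, sheet)
    n_organs = X.shape[1]
    k = DEFAULT_RANK if rank is None else rank
    k = min(k, n_organs)

    if stratify and X.shape[0] >= 8:
        totals = X.df.sum(axis=1).to_numpy()
        fit = fit_poisson_mixture(totals, seed=seed)
        high, low = stratify_by_expression(fit, X.mirna_ids)
        strata = [s for s in (high, low) if s]
    else:
        strata = [X.mirna_ids]

    calls: list[EnrichmentCall] = []
    for stratum in strata:
        sub = CountMatrix(X.df.loc[stratum])
        k_s = min(k, sub.shape[0])
        dec = nmf_decompose(sub, rank=k_s, seed=seed, n_restarts=n_restarts)
        calls.extend(classify_nmf(dec, sub, te_share=te_share, ts_share=ts_share, te_mode=te_mode))
    return calls
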