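"""Run configuration, orchestration of the three pipelines, and static plots.

``run_detection`` is the one-stop entry point: it validates the inputs, runs
every selected pipeline, writes one calls table per pipeline, a cross-pipeline
overlap report when two or more pipelines are selected, and a TSI table --
each output stamped with a hash of the serialized configuration so results
remain traceable to their parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import (
    AnnotationTable,
    CountMatrix,
    EnrichmentCall,
    GroupKind,
    SampleSheet,
    group_means,
    write_calls,
)
from .normalization import per_million_ceil, tmm_normalize
from .nmf_pipeline import run_nmf_pipeline
from .proportion_pipeline import run_proportion_pipeline
from .qp_pipeline import detect_te_qp, detect_ts_qp, fit_all_one_vs_rest
from .specificity import compute_tsi, overlap, reconcile_ids

logger = logging.getLogger("mirtisect")

HEATMAP_CLIP = 4.0  # row z-scores displayed within [-4, 4]


@dataclass
class RunConfig:
    """All detection parameters; serialized alongside every result."""

    pipelines: list[str] = field(default_factory=lambda: ["nmf", "quasipoisson", "proportion"])
    level: GroupKind = "tissue"
    targets: list[str] = field(default_factory=list)  # quasipoisson targets
    alpha: float = 0.05
    percent_points: float = 90.0
    ts_mode: str = "excess"
    te_share: float = 0.60
    ts_share: float = 0.80
    prop_te: float = 0.5
    prop_ts: float = 0.9
    nmf_rank: int | None = None
    n_restarts: int = 10
    overlap_status: str = "TE"
    seed: int = 0
    out_prefix: str = "mirtisect"

    def __post_init__(self) -> None:
        known = {"nmf", "quasipoisson", "proportion"}
        bad = set(self.pipelines) - known
        if bad:
            raise ValueError(f"unknown pipelines: {sorted(bad)}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.prop_te <= self.prop_ts <= 1):
            raise ValueError("proportion thresholds must satisfy 0 < te <= ts <= 1")
        if not (0 < self.te_share <= self.ts_share <= 1):
            raise ValueError("share thresholds must satisfy 0 < te <= ts <= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_detection(
    config: RunConfig,
    counts: CountMatrix,
    sheet: SampleSheet,
    annot: AnnotationTable | None = None,
    outdir: str | Path = ".",
) -> dict:
    """Run the selected pipelines and write the result bundle.

    Returns a dict with per-pipeline calls, the overlap report (when >= 2
    pipelines ran) and the TSI table.  A failing pipeline does not silence
    the others: their outputs are written first, then the failure is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet.require_covers(counts)
    chash = config.config_hash()
    prefix = outdir / config.out_prefix

    log_path = f"{prefix}.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("config hash %s: %s", chash, json.dumps(asdict(config), default=str))

    config.to_yaml(f"{prefix}.config.yaml")
    tmm = tmm_normalize(counts)

    bundle: dict = {"config_hash": chash, "calls": {}, "errors": {}}
    for pipeline in config.pipelines:
        try:
            calls = _run_one(pipeline, config, counts, sheet, annot, tmm)
            bundle["calls"][pipeline] = calls
            write_calls(calls, f"{prefix}.{pipeline}.calls.tsv",
                        header_comment=f"config {chash}")
            logger.info("%s: %d calls", pipeline, len(calls))
        except Exception as exc:  # noqa: BLE001 - reported, then re-raised below
            bundle["errors"][pipeline] = exc
            logger.error("%s failed: %s", pipeline, exc)

    if len(bundle["calls"]) >= 2:
        sets = {
            name: [c.mirna_id for c in calls if c.status == config.overlap_status]
            for name, calls in bundle["calls"].items()
        }
        report = overlap(reconcile_ids(sets))
        report.write_csv(f"{prefix}.overlap.csv")
        bundle["overlap"] = report

    means = group_means(tmm, sheet, config.level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsi = compute_tsi(means)
    tsi.write(f"{prefix}.tsi.tsv")
    bundle["tsi"] = tsi
    bundle["means"] = means

    logger.removeHandler(handler)
    handler.close()
    if bundle["errors"]:
        failed = ", ".join(bundle["errors"])
        raise RuntimeError(f"pipeline(s) failed: {failed}") from next(iter(bundle["errors"].values()))
    return bundle


def _run_one(
    pipeline: str,
    config: RunConfig,
    counts: CountMatrix,
    sheet: SampleSheet,
    annot: AnnotationTable | None,
    tmm: CountMatrix,
) -> list[EnrichmentCall]:
    if pipeline == "nmf":
        return run_nmf_pipeline(
            counts, sheet, rank=config.nmf_rank, te_share=config.te_share,
            ts_share=config.ts_share, seed=config.seed, n_restarts=config.n_restarts,
        )
    if pipeline == "proportion":
        return run_proportion_pipeline(
            counts, sheet, annot=annot, te_threshold=config.prop_te,
            ts_threshold=config.prop_ts, level=config.level,
        )
    if pipeline == "quasipoisson":
        if not config.targets:
            raise ValueError("quasipoisson pipeline needs at least one target group")
        pm = per_million_ceil(counts)
        means = group_means(tmm, sheet, config.level)
        calls: list[EnrichmentCall] = []
        for target in config.targets:
            results = fit_all_one_vs_rest(pm, sheet, target, level=config.level)
            te = detect_te_qp(results, alpha=config.alpha)
            ts = detect_ts_qp(te, means, percent_points=config.percent_points,
                              mode=config.ts_mode)  # type: ignore[arg-type]
            calls.extend(te)
            calls.extend(ts)
        return calls
    raise ValueError(f"unknown pipeline {pipeline!r}")


# ---------------------------------------------------------------------------
# Static plots
# ---------------------------------------------------------------------------

def export_plots(
    tmm: CountMatrix,
    sheet: SampleSheet,
    mirna_ids: Sequence[str],
    out_prefix: str | Path,
    level: GroupKind = "tissue",
    fmt: str = "png",
) -> list[Path]:
    """Bar chart (group means with SD error bars), box plot of log2(TMM+1),
    and a clustered heat map of row z-scores clipped to [-4, 4].

    The +1 pseudocount in the box plot keeps zero counts finite on the log
    scale.  Clustering uses Euclidean distance with complete linkage; a
    single-miRNA heat map is rendered without clustering (warning).
    """
    mirna_ids = [m for m in mirna_ids if m in tmm.df.index]
    if not mirna_ids:
        raise ValueError("no miRNAs to plot")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    groups = sheet.groups(level)
    present = set(tmm.sample_ids)
    groups = {g: [s for s in ss if s in present] for g, ss in groups.items()}
    groups = {g: ss for g, ss in groups.items() if ss}
    labels = list(groups)
    sub = tmm.df.loc[mirna_ids]
    made: list[Path] = []

    # bar chart: mean with SD error bars, averaged over the selected miRNAs
    means = np.array([sub[ss].mean(axis=1).mean() for ss in groups.values()])
    sds = np.array([sub[ss].to_numpy().std(ddof=1) if len(ss) * len(mirna_ids) > 1 else 0.0
                    for ss in groups.values()])
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), 4))
    ax.bar(labels, means, yerr=sds, capsize=2, color="#4878a8")
    ax.set_ylabel("TMM")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out_prefix.with_suffix(f".bar.{fmt}")
    fig.savefig(p)
    plt.close(fig)
    made.append(p)

    # box plot of log2(TMM + 1) per group
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), 4))
    data = [np.log2(sub[ss].to_numpy().ravel() + 1.0) for ss in groups.values()]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("log2(TMM + 1)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out_prefix.with_suffix(f".box.{fmt}")
    fig.savefig(p)
    plt.close(fig)
    made.append(p)

    # clustered heat map of per-row z-scores
    mat = pd.DataFrame({g: sub[ss].mean(axis=1) for g, ss in groups.items()})
    z = zscore_rows(mat.to_numpy(), clip=HEATMAP_CLIP)
    row_order = np.arange(z.shape[0])
    if z.shape[0] > 1:
        link = hierarchy.linkage(pdist(z, metric="euclidean"), method="complete")
        row_order = hierarchy.leaves_list(link)
    else:
        warnings.warn("single-miRNA heat map rendered without clustering")
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labels)), max(3, 0.25 * len(mirna_ids))))
    im = ax.imshow(z[row_order], aspect="auto", cmap="RdBu_r",
                   vmin=-HEATMAP_CLIP, vmax=HEATMAP_CLIP)
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(mirna_ids)), [mirna_ids[i] for i in row_order], fontsize=6)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    p = out_prefix.with_suffix(f".heatmap.{fmt}")
    fig.savefig(p)
    plt.close(fig)
    made.append(p)
    return made


def zscore_rows(values: np.ndarray, clip: float = HEATMAP_CLIP) -> np.ndarray:
    """Per-row z-scores (constant rows -> 0), clipped to +/- ``clip``."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(values - mean, sd, out=np.zeros_like(values, dtype=float), where=sd > 0)
    return np.clip(z, -clip, clip)
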