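"""Seeded generator of multi-tissue miRNA count atlases with planted signal.

The default design mirrors the rat body-atlas layout this tool targets:
23 tissues grouped into 14 organs, 10 samples per tissue (5 male + 5 female
animals) except the sex-specific tissues (ovary, uterus: 5 female; testicle:
5 male).  Counts are negative-binomial around a common baseline mean with a
per-sample log-normal library-size factor; chosen miRNAs carry a fold-change
in one target tissue or organ.  The negative binomial (rather than Poisson)
default makes downstream overdispersion estimates meaningful; Poisson noise
is recovered by ``dispersion=inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationTable,
    CountMatrix,
    SampleSheet,
    default_organ_map,
)

#: Tissues sampled from one sex only in the default design.
FEMALE_ONLY = ("ovary", "uterus")
MALE_ONLY = ("testicle",)
REDUCED_N = {"ovary": 5, "uterus": 5, "testicle": 5}

DEFAULT_N_MIRNAS = 300
DEFAULT_BASELINE_MEAN = 100.0
DEFAULT_DISPERSION = 5.0          # negative-binomial size
DEFAULT_LIBSIZE_SIGMA = 0.25      # log-normal sd of the library factor
DEFAULT_LOCI_PROBS = (0.80, 0.15, 0.05)  # P(n_loci = 1, 2, 3)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted enrichment: miRNA row index, target group, fold, status."""

    mirna_index: int
    target: str
    fold: float
    status: str = "TS"  # intended verdict: TE, TS or OS

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted folds must exceed 1")
        if self.status not in ("TE", "TS", "OS"):
            raise ValueError(f"unknown planted status {self.status!r}")


@dataclass
class TruthTable:
    """Intended status/target/fold of every planted miRNA."""

    df: pd.DataFrame  # mirna_id, status, target, fold

    def ids_with_status(self, status: str) -> list[str]:
        return list(self.df.loc[self.df["status"] == status, "mirna_id"])


@dataclass
class AtlasDesign:
    organ_map: dict[str, str] = field(default_factory=default_organ_map)
    samples_per_tissue: dict[str, int] | int = 10
    n_mirnas: int = DEFAULT_N_MIRNAS
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    dispersion: float = DEFAULT_DISPERSION
    libsize_sigma: float = DEFAULT_LIBSIZE_SIGMA
    loci_probs: Sequence[float] = DEFAULT_LOCI_PROBS
    planted: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be non-negative")
        if abs(sum(self.loci_probs) - 1.0) > 1e-9:
            raise ValueError("loci_probs must sum to 1")
        groups = set(self.organ_map) | set(self.organ_map.values())
        for eff in self.planted:
            if not (0 <= eff.mirna_index < self.n_mirnas):
                raise ValueError(f"planted index {eff.mirna_index} out of range")
            if eff.target not in groups:
                raise ValueError(f"planted target {eff.target!r} is not a tissue or organ")

    def n_samples(self, tissue: str) -> int:
        if isinstance(self.samples_per_tissue, int):
            return REDUCED_N.get(tissue, self.samples_per_tissue)
        return self.samples_per_tissue[tissue]


def _build_sheet(design: AtlasDesign) -> SampleSheet:
    rows = []
    for tissue in design.organ_map:
        n = design.n_samples(tissue)
        if tissue in FEMALE_ONLY:
            animals = [f"F{i + 1}" for i in range(n)]
        elif tissue in MALE_ONLY:
            animals = [f"M{i + 1}" for i in range(n)]
        else:
            half = n // 2
            animals = [f"M{i + 1}" for i in range(half)] + \
                      [f"F{i + 1}" for i in range(n - half)]
        for animal in animals:
            rows.append({
                "sample_id": f"{tissue}_{animal}",
                "tissue": tissue,
                "organ": design.organ_map[tissue],
                "sex": "F" if animal.startswith("F") else "M",
                "animal": animal,
            })
    return SampleSheet(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    if math.isinf(size):
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_atlas(
    design: AtlasDesign,
) -> tuple[CountMatrix, SampleSheet, AnnotationTable, TruthTable]:
    """Draw a seeded count atlas with the design's planted enrichments.

    A planted effect targeting a tissue raises that miRNA's mean in the
    target tissue's samples by ``fold``; targeting an organ raises it in all
    member tissues.  Byte-identical output for identical designs.
    """
    rng = np.random.default_rng(design.seed)
    sheet = _build_sheet(design)
    sample_ids = sheet.sample_ids
    tissues = sheet.df["tissue"].to_numpy()
    organs = sheet.df["organ"].to_numpy()
    n_s = len(sample_ids)
    n_m = design.n_mirnas

    lib = np.exp(rng.normal(0.0, design.libsize_sigma, size=n_s))
    mean = np.full((n_m, n_s), design.baseline_mean)
    for eff in design.planted:
        in_target = (tissues == eff.target) | (organs == eff.target)
        mean[eff.mirna_index, in_target] *= eff.fold
    mean = mean * lib

    counts = _nb_draw(rng, mean, design.dispersion).astype(float)
    mirna_ids = [f"syn-miR-{j + 1:04d}" for j in range(n_m)]
    cm = CountMatrix(pd.DataFrame(counts, index=mirna_ids, columns=sample_ids))

    loci = rng.choice(
        np.arange(1, len(design.loci_probs) + 1), size=n_m, p=list(design.loci_probs)
    )
    annot = AnnotationTable(pd.DataFrame({
        "mirna_id": mirna_ids,
        "n_loci": loci,
        "parent_mature_id": "",
        "feature_class": "mature",
    }))
    truth = TruthTable(pd.DataFrame([
        {
            "mirna_id": mirna_ids[eff.mirna_index],
            "status": eff.status,
            "target": eff.target,
            "fold": eff.fold,
        }
        for eff in design.planted
    ], columns=["mirna_id", "status", "target", "fold"]))
    return cm, sheet, annot, truth


def plant_ts_effects(
    n: int,
    fold: float,
    targets: Sequence[str],
    start_index: int = 0,
) -> list[PlantedEffect]:
    """Spread ``n`` tissue-specific plants round-robin over ``targets``."""
    return [
        PlantedEffect(start_index + i, targets[i % len(targets)], fold, "TS")
        for i in range(n)
    ]


def generate_isomir_table(
    design: AtlasDesign,
    dominant_switch: Sequence[tuple[str, str, str]] = (),
    n_matures: int = 10,
    base_props: Sequence[float] = (0.7, 0.2, 0.1),
) -> tuple[CountMatrix, AnnotationTable]:
    """IsomiR counts whose expected dominant isoform follows the switches.

    Each of the first ``n_matures`` matures gets ``len(base_props)`` isomiRs
    with expected within-mature proportions ``base_props`` in every tissue.
    A switch ``(mature, tissue, isomiR)`` swaps that isomiR's proportion with
    the default dominant one in that tissue.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=design.seed, spawn_key=(1,)))
    sheet = _build_sheet(design)
    sample_ids = sheet.sample_ids
    tissues = sheet.df["tissue"].to_numpy()
    n_s = len(sample_ids)

    matures = [f"syn-miR-{j + 1:04d}" for j in range(n_matures)]
    iso_ids = [f"{m}.iso{k + 1}" for m in matures for k in range(len(base_props))]
    for mature, tissue, iso in dominant_switch:
        if mature not in matures:
            raise ValueError(f"switch names unknown mature {mature!r}")
        if tissue not in set(tissues):
            raise ValueError(f"switch names unknown tissue {tissue!r}")
        if iso not in iso_ids:
            raise ValueError(f"switch names unknown isomiR {iso!r}")

    lib = np.exp(rng.normal(0.0, design.libsize_sigma, size=n_s))
    props = np.asarray(base_props, dtype=float)
    mean = np.zeros((len(iso_ids), n_s))
    for mi, mature in enumerate(matures):
        tissue_props = {t: props.copy() for t in dict.fromkeys(tissues)}
        for sm, st, siso in dominant_switch:
            if sm != mature:
                continue
            k = int(siso.rsplit("iso", 1)[1]) - 1
            p = tissue_props[st]
            dom = int(np.argmax(props))
            p[dom], p[k] = p[k], props[dom]
        for si in range(n_s):
            p = tissue_props[tissues[si]]
            base = design.baseline_mean * 10.0  # high counts: stable proportions
            for k in range(len(props)):
                mean[mi * len(props) + k, si] = base * p[k] * lib[si]
    counts = _nb_draw(rng, mean, design.dispersion).astype(float)
    cm = CountMatrix(pd.DataFrame(counts, index=iso_ids, columns=sample_ids))
    annot = AnnotationTable(pd.DataFrame({
        "mirna_id": iso_ids,
        "n_loci": 1,
        "parent_mature_id": [i.rsplit(".", 1)[0] for i in iso_ids],
        "feature_class": "isomiR",
    }))
    return cm, annot
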