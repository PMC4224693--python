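"""Benchmarking: ROC/AUC, region spike-in, and the negative control.

Benchmarks score variants with the *continuous* weighted rank sum rather
than the final integer rank, so ties are resolved exactly as in the
prioritisation itself.  The AUC equals the Mann–Whitney probability that
a randomly chosen positive outscores a randomly chosen negative, with
ties counted one half.

The spike-in design: known functional variants are pooled ("spiked") into
each named background region's variants, the pooled set is prioritised
*together* (ranks are relative, so pooling is required), and a per-region
AUC is computed; regions are averaged with equal weight.

The negative control relabels random subsets of background variants as
"known" and asks whether the ranker can tell them from the rest of the
background.  Because the subsets are exchangeable with their complement,
the expected AUC is 0.5 — a calibrated ranker must not prioritise
background over background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .aggregation import WeightModel, prioritise, weighted_sums
from .annotation import AnnotationBundle, GenomicInterval, VariantRecord
from .ranking import RankConfig

__all__ = [
    "RegionSet",
    "BenchmarkReport",
    "NegativeControlResult",
    "roc_auc",
    "auc_mann_whitney",
    "auc_columns",
    "spike_in",
    "negative_control",
]


@dataclass
class RegionSet:
    """Named non-overlapping genomic regions, each with its own background
    variant list (the analogue of a panel of benchmark regions sampled
    across the genome)."""

    regions: dict[str, GenomicInterval]
    backgrounds: dict[str, list[VariantRecord]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.regions.values():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError("regions overlap")
        for name, variants in self.backgrounds.items():
            region = self.regions.get(name)
            if region is None:
                raise ValueError(f"background for unknown region {name!r}")
            for v in variants:
                if not region.contains(v.chrom, v.pos):
                    raise ValueError(
                        f"background variant {v.id or v.pos} outside "
                        f"region {name!r}")


@dataclass
class BenchmarkReport:
    """ROC points, overall AUC, and per-region AUCs from a spike-in run."""

    roc_points: pd.DataFrame            # columns fpr, tpr (pooled pairs)
    auc: float                          # AUC over all pooled (score, label)
    region_aucs: dict[str, float] = field(default_factory=dict)
    mean_region_auc: float = float("nan")
    n_positives: int = 0
    n_negatives: int = 0
    seed: int | None = None


@dataclass
class NegativeControlResult:
    mean_auc: float
    se: float                           # Monte-Carlo standard error of the mean
    aucs: np.ndarray
    seed: int


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the rank-sum identity (ties counted half).

    Used in inner loops where the ROC curve itself is not needed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present to compute an AUC")
    r = rankdata(s)
    return (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auc_columns(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column-wise Mann–Whitney AUCs for an (n_variants × m) score matrix
    against one label vector; vectorised for grid-search loops."""
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both labels must be present to compute an AUC")
    r = rankdata(score_matrix, axis=0)
    return (r[y].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep over unique scores) and its AUC.

    The AUC equals the Mann–Whitney statistic with ties counted half;
    the curve starts at (0, 0), ends at (1, 1) and is monotone
    non-decreasing.  Raises on single-class input.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present to compute an AUC")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return points, float(roc_auc_score(y, scores))


def spike_in(positives: Sequence[VariantRecord], regions: RegionSet,
             wm: WeightModel, bundle: AnnotationBundle,
             config: RankConfig | None = None) -> BenchmarkReport:
    """Spike known positives into each region's background and benchmark.

    Positives must be disjoint (by id) from every region background.  For
    each region the positives and that region's backgrounds are prioritised
    jointly and an AUC computed; the report carries the per-region AUCs,
    their (equal-weight) mean, and a pooled ROC over all regions' scored
    pairs.  Regions with no background variants are skipped with a warning.
    """
    pos_ids = {v.id for v in positives if v.id is not None}
    region_aucs: dict[str, float] = {}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for name in sorted(regions.regions):
        background = regions.backgrounds.get(name, [])
        if not background:
            warnings.warn(f"region {name!r} has no background variants; skipped")
            continue
        clash = pos_ids & {v.id for v in background if v.id is not None}
        if clash:
            raise ValueError(
                f"positives overlap region {name!r} background: {sorted(clash)[:5]}")
        pool = list(positives) + list(background)
        labels = np.array([1] * len(positives) + [0] * len(background))
        res = prioritise(pool, bundle, wm, config)
        scores = res["weighted_sum"].to_numpy()
        region_aucs[name] = auc_mann_whitney(scores, labels)
        pooled_scores.append(scores)
        pooled_labels.append(labels)
    if not region_aucs:
        raise ValueError("no region had background variants")
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    points, overall = roc_auc(all_scores, all_labels)
    return BenchmarkReport(
        roc_points=points,
        auc=overall,
        region_aucs=region_aucs,
        mean_region_auc=float(np.mean(list(region_aucs.values()))),
        n_positives=len(positives),
        n_negatives=int((all_labels == 0).sum()),
    )


def negative_control(background: Sequence[VariantRecord],
                     wm: WeightModel, bundle: AnnotationBundle,
                     subset_size: int = 95, n_repeats: int = 100,
                     seed: int = 0, config: RankConfig | None = None
                     ) -> NegativeControlResult:
    """Background-versus-background negative control.

    ``n_repeats`` times, a random subset of ``subset_size`` background
    variants is redefined as "known" and scored against the rest of the
    background; the mean AUC over the repeats is returned with its
    Monte-Carlo standard error.  The scores of the pooled set are those of
    the full background (relabelling does not change any annotation), so
    the background is prioritised once and only the labels vary per
    repeat.  Under exchangeability the expected AUC is 0.5.
    """
    n = len(background)
    if subset_size >= n:
        raise ValueError(
            f"subset_size ({subset_size}) must be smaller than the "
            f"background ({n})")
    res = prioritise(list(background), bundle, wm, config)
    scores = res["weighted_sum"].to_numpy()
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_repeats)
    for i in range(n_repeats):
        pos_idx = rng.choice(n, size=subset_size, replace=False)
        labels = np.zeros(n, dtype=int)
        labels[pos_idx] = 1
        aucs[i] = auc_mann_whitney(scores, labels)
    se = (float(aucs.std(ddof=1) / np.sqrt(n_repeats))
          if n_repeats > 1 else float("nan"))
    return NegativeControlResult(
        mean_auc=float(aucs.mean()),
        se=se,
        aucs=aucs,
        seed=seed,
    )
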