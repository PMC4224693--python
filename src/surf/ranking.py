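"""Per-category ranking of feature-table columns.

Each annotation category is converted into a rank vector over the variant
set with the convention that a *larger* rank value means *more likely
functional*, so the weighted sum in the aggregation step is maximised by
the best candidate.  Ties receive average ("fractional") ranks, making
every rank column a tie-averaged permutation of 1..n (column sum
n(n+1)/2).  Category-specific directionality:

* MAF — rarer is more functional; an optional frequency window puts
  in-window variants strictly above all out-of-window ones; variants with
  unknown MAF rank worst (absence of frequency evidence is not rewarded).
* Conservation — negative RS scores are clamped to zero before ranking so
  positive selection and alignment artefacts cannot distort the ranking;
  higher (clamped) score is more functional.
* Chromatin state / position — categorical, ranked by a best→worst order
  list (state order typically fitted by logistic regression, see
  :mod:`surf.training`; position order is a precedence configuration).
* DNase HS / footprint count / TFBS — higher signal is more functional.
* Enhancer overlap — boolean, overlap above non-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import DEFAULT_POSITION_ORDER

__all__ = [
    "CATEGORIES",
    "RankConfig",
    "rank_values",
    "rank_maf",
    "rank_conservation",
    "rank_categorical",
    "rank_binary",
    "build_rank_matrix",
    "write_rank_matrix",
]

#: Fixed category order of the rank matrix (and of weight vectors).
CATEGORIES = [
    "MAF", "Conservation", "Chromatin states", "DNase HS",
    "Position", "DNase footprints", "Enhancers", "TFBSs",
]

#: Default chromatin-state palette, most to least informative.  Promoter
#: and strong-enhancer states outrank the other classes; "none" (no
#: coverage) always ranks below every named state.
DEFAULT_STATE_ORDER = [
    "Active Promoter", "Strong Enhancer", "Weak Promoter", "Weak Enhancer",
    "Poised Promoter", "Insulator", "Transcribed", "Weak Transcribed",
    "Repressed", "Heterochromatin",
]


@dataclass
class RankConfig:
    """Orderings and tunables consumed by :func:`build_rank_matrix`."""

    state_order: list[str] = field(default_factory=lambda: list(DEFAULT_STATE_ORDER))
    position_order: list[str] = field(default_factory=lambda: list(DEFAULT_POSITION_ORDER))
    maf_window: tuple[float, float] | None = None


def rank_values(values: Sequence[float], direction: str = "higher_is_functional"
                ) -> np.ndarray:
    """Tie-averaged ranks in 1..n; larger rank = more functional.

    ``direction="lower_is_functional"`` reverses the ordering before
    ranking (used for MAF, where rare variants rank highest).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if direction == "higher_is_functional":
        return rankdata(arr)
    if direction == "lower_is_functional":
        return rankdata(-arr)
    raise ValueError(f"unknown direction: {direction!r}")


def rank_maf(mafs: Sequence[float], window: tuple[float, float] | None = None
             ) -> np.ndarray:
    """Rank by minor allele frequency, rarest highest.

    ``window=(lo, hi)`` implements the tunable frequency range: variants
    with MAF inside [lo, hi] are ranked (rarest best) strictly above all
    variants outside it; within each tier ordering is by rarity.  Missing
    MAFs (NaN/None) fall in a third, worst tier.
    """
    arr = np.array([np.nan if m is None else m for m in mafs], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    known = ~np.isnan(arr)
    if np.any((arr[known] < 0) | (arr[known] > 0.5)):
        raise ValueError("MAF outside [0, 0.5]")
    if window is not None:
        lo, hi = window
        if lo > hi:
            raise ValueError(f"MAF window inverted: {window}")
        tier = np.where(known & (arr >= lo) & (arr <= hi), 0.0, 1.0)
    else:
        tier = np.zeros(arr.size)
    tier[~known] = 2.0
    # tiers are spaced by 1.0 > any MAF (≤ 0.5), so the composite key sorts
    # by tier first, then by frequency; unknown MAF carries no frequency key
    composite = tier + np.where(known, arr, 0.0)
    return rankdata(-composite)


def rank_conservation(rs_scores: Sequence[float]) -> np.ndarray:
    """Rank on RS score with negative scores clamped to zero first
    (clamped sites tie at the bottom)."""
    arr = np.asarray(rs_scores, dtype=float)
    return rank_values(np.maximum(arr, 0.0), "higher_is_functional")


def rank_categorical(values: Sequence[str], order: Sequence[str],
                     neutral: str | None = None) -> np.ndarray:
    """Rank category labels by a best→worst ``order`` list.

    Labels are mapped to ordinal scores (earlier in ``order`` = better),
    then ranked higher-is-functional with tie averaging within identical
    labels.  ``neutral`` (e.g. ``"none"`` for chromatin state) is allowed
    even when absent from ``order`` and always ranks worst.
    """
    n_ord = len(order)
    ordinal = {lab: float(n_ord - i) for i, lab in enumerate(order)}
    if neutral is not None:
        ordinal.setdefault(neutral, 0.0)
    try:
        scores = [ordinal[v] for v in values]
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} absent from order list") from exc
    return rank_values(scores, "higher_is_functional")


def rank_binary(flags: Sequence[bool]) -> np.ndarray:
    """Rank booleans: True above False, ties averaged within each group."""
    return rank_values(np.asarray(flags, dtype=float), "higher_is_functional")


def build_rank_matrix(ft: pd.DataFrame, config: RankConfig | None = None
                      ) -> pd.DataFrame:
    """Convert a feature table into the n×8 rank matrix.

    Columns follow :data:`CATEGORIES`; the index carries the variant ids
    in input order.  Every column is a tie-averaged permutation of 1..n.
    """
    if len(ft) == 0:
        raise ValueError("empty feature table")
    config = config or RankConfig()
    rm = pd.DataFrame(
        {
            "MAF": rank_maf(ft["maf"].to_numpy(), config.maf_window),
            "Conservation": rank_conservation(ft["rs_score"].to_numpy()),
            "Chromatin states": rank_categorical(
                ft["chromatin_state_best"], config.state_order, neutral="none"),
            "DNase HS": rank_values(ft["dnase_hs_max"].to_numpy()),
            "Position": rank_categorical(
                ft["position_category"], config.position_order,
                neutral="intergenic"),
            "DNase footprints": rank_values(
                ft["footprint_cell_count"].to_numpy(dtype=float)),
            "Enhancers": rank_binary(ft["enhancer_overlap"].to_numpy()),
            "TFBSs": rank_values(ft["tfbs_max"].to_numpy()),
        },
        index=pd.Index(ft["id"], name="id"),
    )
    return rm[CATEGORIES]


def write_rank_matrix(rm: pd.DataFrame, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        rm.to_csv(fh, sep="\t")
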