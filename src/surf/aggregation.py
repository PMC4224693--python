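"""Weighted rank-of-ranks aggregation — the scoring core.

The final priority of variant *i* is the rank of its weighted rank sum

    R_i = rank_i( sum_j  r_ij * w_j )

where ``r_ij`` is variant *i*'s rank in annotation category *j* (larger =
more functional, see :mod:`surf.ranking`) and ``w_j`` is the category's
non-negative weight.  Only the relative sizes of the weights matter:
scaling every weight by a positive constant leaves the ordering unchanged,
and a zero-weight category contributes nothing (which is why a model with
MAF weight 0 accepts input with no frequency data at all).

Three pre-trained weight models ship with the package:

=====  ====================================================================
name   intended use
=====  ====================================================================
ALL    general-purpose prioritisation of functional variants
DM     (rare, highly penetrant) disease mutations — leans on rarity (MAF)
DFP    complex-disease / common functional variants — conservation unused
=====  ====================================================================

Custom models are plain YAML/key-value files mapping category names to
non-negative numbers; unknown categories are rejected rather than ignored
so that a misspelt category cannot silently drop out of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from . import annotation, ranking
from .annotation import AnnotationBundle, VariantRecord, build_feature_table
from .ranking import CATEGORIES, RankConfig, build_rank_matrix

__all__ = [
    "WeightModel",
    "BUILTIN_MODELS",
    "load_weight_model",
    "combine_ranks",
    "prioritise",
    "weighted_sums",
]


@dataclass(frozen=True)
class WeightModel:
    """A named vector of eight non-negative category weights."""

    name: str
    weights: dict[str, float]
    metadata: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")

    def vector(self, categories: Sequence[str] = CATEGORIES) -> np.ndarray:
        """Weights as an array in ``categories`` order (absent = 0)."""
        return np.array([self.weights.get(c, 0.0) for c in categories])


def _model(name: str, values: Sequence[float], meta: str) -> WeightModel:
    return WeightModel(name, dict(zip(CATEGORIES, map(float, values))), meta)


#: Shipped pre-trained models.  Weight order follows
#: :data:`surf.ranking.CATEGORIES`: MAF, Conservation, Chromatin states,
#: DNase HS, Position, DNase footprints, Enhancers, TFBSs.
BUILTIN_MODELS: dict[str, WeightModel] = {
    "ALL": _model("ALL", (0, 1, 1, 0, 8, 0, 1, 3),
                  "general model for any analysis"),
    "DM": _model("DM", (12, 2, 6, 1, 15, 1, 0, 5),
                 "model for (rare) disease mutations"),
    "DFP": _model("DFP", (0, 0, 3, 1, 15, 3, 5, 2),
                  "model for complex-disease functional variants"),
}


def load_weight_model(name_or_path: str | Path) -> WeightModel:
    """Load a shipped model by name (``ALL``/``DM``/``DFP``) or a custom
    model from a YAML / ``key: value`` file.

    Custom files must map known category names to non-negative numbers;
    negative weights and unknown categories raise ``ValueError``.
    """
    key = str(name_or_path)
    if key in BUILTIN_MODELS:
        return BUILTIN_MODELS[key]
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"{key!r} is neither a built-in model "
            f"({', '.join(BUILTIN_MODELS)}) nor a readable file")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping of category -> weight")
    weights = {}
    for cat, w in raw.items():
        try:
            weights[str(cat)] = float(w)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric weight for {cat!r}") from exc
    return WeightModel(path.stem, weights, metadata=f"loaded from {path}")


def weighted_sums(rm: pd.DataFrame, wm: WeightModel) -> np.ndarray:
    """Per-variant weighted rank sum  sum_j r_ij * w_j."""
    missing = {c for c, w in wm.weights.items() if w > 0} - set(rm.columns)
    if missing:
        raise ValueError(
            f"weight model {wm.name!r} weights categories absent from the "
            f"rank matrix: {sorted(missing)}")
    w = wm.vector(list(rm.columns))
    return rm.to_numpy(dtype=float) @ w


def combine_ranks(rm: pd.DataFrame, wm: WeightModel) -> pd.DataFrame:
    """Combine per-category ranks into the final weighted rank-of-ranks.

    Returns one row per variant (input order preserved) with:

    * ``weighted_sum`` — sum_j r_ij * w_j
    * ``final_rank`` — tie-averaged rank of the weighted sums with 1 =
      top candidate (descending weighted sum)
    * ``contrib_<category>`` — the per-category contribution r_ij * w_j,
      emitted for transparency; contributions sum to ``weighted_sum``.

    Rows are returned in input order; sort on ``final_rank`` for the
    presentation order (remaining ties then fall to input order, which is
    arbitrary).
    """
    sums = weighted_sums(rm, wm)
    w = wm.vector(list(rm.columns))
    out = pd.DataFrame(index=rm.index.copy())
    out["weighted_sum"] = sums
    out["final_rank"] = rankdata(-sums)
    for j, cat in enumerate(rm.columns):
        out[f"contrib_{cat}"] = rm.iloc[:, j].to_numpy() * w[j]
    return out


def prioritise(variants: Sequence[VariantRecord], bundle: AnnotationBundle,
               wm: WeightModel, config: RankConfig | None = None) -> pd.DataFrame:
    """End-to-end prioritisation: annotate → rank → combine.

    Composition of :func:`surf.annotation.build_feature_table`,
    :func:`surf.ranking.build_rank_matrix` and :func:`combine_ranks`.
    The result carries the variant coordinates plus the transparency
    columns, so the user can see which annotations drove each ranking.
    """
    if not variants:
        raise ValueError("no variants to prioritise")
    config = config or RankConfig()
    ft = build_feature_table(variants, bundle, config.state_order,
                             config.position_order)
    rm = build_rank_matrix(ft, config)
    res = combine_ranks(rm, wm)
    res.insert(0, "chrom", ft["chrom"].to_numpy())
    res.insert(1, "pos", ft["pos"].to_numpy())
    return res
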