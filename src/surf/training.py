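"""Weight-model fitting: regression guidance, k-fold CV, grid search.

A weight model is a vector of eight non-negative *integer* weights; the
search for a good model is a guided brute-force sweep of the integer
lattice, not a continuous optimisation:

1.  A multivariable logistic regression of the functional/background
    label on the eight (scaled) rank columns of the full
    training/validation set estimates each category's effect direction.
    Categories whose coefficient is not positive carry no usable signal,
    so their upper bound is shrunk to a small maximum — this is what
    makes the otherwise-intractable 16^8 lattice searchable.
2.  Integer weight vectors inside the shrunken bounds are enumerated
    exhaustively when the lattice fits the evaluation budget, otherwise
    sampled uniformly (seeded) from the lattice.
3.  Every vector is scored by stratified 10-fold cross-validation: within
    each fold the training-portion variants are ranked among themselves
    and the validation-portion variants among themselves (ranks are
    relative to the set being prioritised), and the fold's training and
    validation AUCs are computed from the weighted rank sums.
4.  The selected vector maximises mean validation AUC among vectors whose
    performance error |mean training AUC − mean validation AUC| is below
    the acceptance threshold (default 0.005).  Near-ties (within 1e-9)
    are broken by smallest L1 norm, then lexicographically — determinism
    plus parsimony.

The same logistic-regression machinery orders chromatin states by their
fitted coefficients (most to least informative), which supplies the state
order used by the ranking step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .aggregation import WeightModel
from .annotation import VariantRecord
from .evaluation import auc_columns, auc_mann_whitney
from .ranking import CATEGORIES, RankConfig, build_rank_matrix

__all__ = [
    "LabelledVariantSet",
    "GridSearchSpec",
    "TrainingReport",
    "CategoryEffects",
    "fit_category_effects",
    "fit_state_order",
    "order_states_by_beta",
    "kfold_split",
    "guided_grid_search",
    "evaluate_on_holdout",
    "performance_error",
    "generalisation_error",
]


@dataclass
class LabelledVariantSet:
    """Variants with binary labels (functional = 1, background = 0).

    ``features`` is the annotated feature table (same row order as
    ``labels``); training operates on it directly.  Train/validation and
    hold-out sets must hold disjoint variant ids — see
    :meth:`assert_disjoint`.
    """

    labels: np.ndarray
    features: pd.DataFrame
    variants: list[VariantRecord] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features disagree in length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def ids(self) -> list[str]:
        return list(self.features["id"])

    def assert_disjoint(self, other: "LabelledVariantSet") -> None:
        clash = set(self.ids) & set(other.ids)
        if clash:
            raise ValueError(
                f"variant sets share ids (leakage): {sorted(clash)[:5]} ...")

    def subset(self, idx: np.ndarray) -> "LabelledVariantSet":
        return LabelledVariantSet(
            labels=self.labels[idx],
            features=self.features.iloc[idx].reset_index(drop=True),
            variants=[self.variants[i] for i in idx] if self.variants else None,
        )


@dataclass
class CategoryEffects:
    """Logistic-regression coefficients per predictor, with a perfect-
    separation flag (coefficients are then penalised estimates and their
    magnitudes are not interpretable, though their ordering is)."""

    coefficients: dict[str, float]
    separated: bool = False
    reference: str | None = None


def fit_category_effects(predictors: pd.DataFrame, labels: Sequence[int]
                         ) -> CategoryEffects:
    """Maximum-likelihood multivariable logistic regression of a binary
    label on the given predictor columns.

    Perfect separation is flagged (and a warning issued) rather than
    raised; in that case a lightly ridge-penalised fit supplies usable
    coefficient orderings.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both labels to fit category effects")
    X = predictors.astype(float)
    exog = sm.add_constant(X, has_constant="add")
    separated = False
    params: pd.Series | None = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=200)
            params = fit.params
        except Exception:
            separated = True
        for w in caught:
            if "separation" in str(w.message).lower() or "divergence" in str(
                    w.message).lower():
                separated = True
    if params is not None and not np.all(np.isfinite(params)):
        separated = True
        params = None
    if separated and params is None:
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X.to_numpy(), y)
        params = pd.Series(
            np.concatenate([clf.intercept_, clf.coef_.ravel()]),
            index=["const", *X.columns])
    if separated:
        warnings.warn(
            "perfect separation detected; coefficients are penalised "
            "estimates", stacklevel=2)
    coeffs = {c: float(params[c]) for c in X.columns}
    return CategoryEffects(coefficients=coeffs, separated=separated)


def order_states_by_beta(effects: CategoryEffects | Mapping[str, float],
                         reference: str | None = None) -> list[str]:
    """Order states most → least informative by descending coefficient.

    The reference level of the regression (implied coefficient 0) is
    slotted into the order at 0; equal coefficients preserve input order
    (stable sort)."""
    if isinstance(effects, CategoryEffects):
        coeffs = dict(effects.coefficients)
        reference = reference or effects.reference
    else:
        coeffs = dict(effects)
    if any(not np.isfinite(b) for b in coeffs.values()):
        raise ValueError("non-finite coefficient")
    if reference is not None:
        coeffs.setdefault(reference, 0.0)
    names = list(coeffs)
    return sorted(names, key=lambda s: -coeffs[s])


def fit_state_order(states: Sequence[str], labels: Sequence[int]) -> list[str]:
    """Fit the chromatin-state order from labelled data: one-hot encode
    the per-variant best state, fit the logistic regression, and order
    states by coefficient.  The first state in appearance order is the
    reference level; "none" (no coverage) is always placed last."""
    ser = pd.Series(list(states))
    levels = [s for s in ser.unique() if s != "none"]
    if len(levels) < 2:
        raise ValueError("need at least two distinct states")
    reference = levels[0]
    dummies = pd.get_dummies(ser).reindex(columns=levels, fill_value=0)
    dummies = dummies.drop(columns=[reference])
    eff = fit_category_effects(dummies.astype(float), labels)
    eff.reference = reference
    order = order_states_by_beta(eff)
    if "none" in set(ser.unique()):
        order = [s for s in order if s != "none"]
    return order


def kfold_split(labels: Sequence[int], k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1) per variant.

    Folds are sized within one of each other with the functional:background
    ratio approximately preserved per fold; reproducible under ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) < k:
        raise ValueError(f"need at least k={k} variants, got {len(y)}")
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold_id
    return folds


@dataclass
class GridSearchSpec:
    """Search-space description for :func:`guided_grid_search`.

    ``bounds`` maps category → inclusive integer (lo, hi); omitted
    categories default to (0, 15) — the span of the shipped model
    weights.  ``budget`` caps the number of weight vectors evaluated.
    """

    bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    budget: int = 20_000
    error_threshold: float = 0.005
    seed: int = 0
    k: int = 10
    guide_cap: int = 1   # max weight allowed for non-positive-beta categories

    def resolved_bounds(self) -> dict[str, tuple[int, int]]:
        out = {}
        for cat in CATEGORIES:
            lo, hi = self.bounds.get(cat, (0, 15))
            if lo < 0 or hi < lo:
                raise ValueError(f"bad bounds for {cat!r}: ({lo}, {hi})")
            out[cat] = (int(lo), int(hi))
        if all(hi == 0 for _, hi in out.values()):
            raise ValueError("bounds admit no positive weight")
        return out


@dataclass
class TrainingReport:
    best_model: WeightModel
    mean_training_auc: float
    mean_validation_auc: float
    performance_error: float
    fold_training_aucs: np.ndarray
    fold_validation_aucs: np.ndarray
    n_evaluated: int
    top1pct_auc_spread: float
    threshold_violated: bool
    guided_bounds: dict[str, tuple[int, int]]
    guide_betas: dict[str, float]


def _candidate_vectors(bounds: dict[str, tuple[int, int]], budget: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Integer weight vectors within bounds: the full lattice when it fits
    the budget, otherwise a uniform lattice sample; the all-zero vector is
    dropped (not a valid model)."""
    los = np.array([bounds[c][0] for c in CATEGORIES])
    his = np.array([bounds[c][1] for c in CATEGORIES])
    sizes = his - los + 1
    lattice = int(np.prod(sizes.astype(object)))
    if lattice <= budget:
        grids = np.meshgrid(*(np.arange(lo, hi + 1) for lo, hi in
                              zip(los, his)), indexing="ij")
        W = np.stack([g.ravel() for g in grids], axis=1)
    else:
        W = rng.integers(los, his + 1, size=(budget, len(CATEGORIES)))
        W = np.unique(W, axis=0)
    W = W[W.sum(axis=1) > 0]
    if W.size == 0:
        raise ValueError("no candidate weight vector has a positive weight")
    return W.astype(float)


def guided_grid_search(lvs: LabelledVariantSet, spec: GridSearchSpec,
                       rank_config: RankConfig | None = None) -> TrainingReport:
    """Regression-guided integer grid search with k-fold cross-validation.

    Returns the weight vector maximising mean validation AUC subject to
    performance error < ``spec.error_threshold``; when no vector meets the
    threshold, the best-AUC vector is returned with ``threshold_violated``
    set.  See the module docstring for the full procedure.
    """
    rank_config = rank_config or RankConfig()
    y = lvs.labels
    rm_full = build_rank_matrix(lvs.features, rank_config)
    # scale ranks to [0, 1] so the guide regression is well conditioned
    n = len(rm_full)
    guide = fit_category_effects(
        rm_full.reset_index(drop=True) / n, y)
    bounds = spec.resolved_bounds()
    for cat, beta in guide.coefficients.items():
        lo, hi = bounds[cat]
        if beta <= 0:
            bounds[cat] = (lo, min(hi, max(lo, spec.guide_cap)))
    rng = np.random.default_rng(spec.seed)
    W = _candidate_vectors(bounds, spec.budget, rng)
    m = len(W)

    folds = kfold_split(y, k=spec.k, seed=spec.seed)
    train_auc = np.zeros((spec.k, m))
    val_auc = np.zeros((spec.k, m))
    chunk = max(1, int(2e6 // max(1, n)))   # bound the n×chunk score block
    for fold_id in range(spec.k):
        va = folds == fold_id
        tr = ~va
        rm_tr = build_rank_matrix(
            lvs.features.loc[tr].reset_index(drop=True), rank_config
        ).to_numpy(dtype=float)
        rm_va = build_rank_matrix(
            lvs.features.loc[va].reset_index(drop=True), rank_config
        ).to_numpy(dtype=float)
        y_tr, y_va = y[tr], y[va]
        for j0 in range(0, m, chunk):
            Wc = W[j0:j0 + chunk].T
            train_auc[fold_id, j0:j0 + chunk] = auc_columns(rm_tr @ Wc, y_tr)
            val_auc[fold_id, j0:j0 + chunk] = auc_columns(rm_va @ Wc, y_va)

    mean_tr = train_auc.mean(axis=0)
    mean_va = val_auc.mean(axis=0)
    perf_err = np.abs(mean_tr - mean_va)
    admissible = perf_err < spec.error_threshold
    threshold_violated = not bool(admissible.any())
    pool = np.arange(m) if threshold_violated else np.flatnonzero(admissible)

    best_auc = mean_va[pool].max()
    near = pool[mean_va[pool] >= best_auc - 1e-9]
    l1 = W[near].sum(axis=1)
    near = near[l1 == l1.min()]
    order = np.lexsort(W[near].T[::-1])   # lexicographic over categories
    best = int(near[order[0]])

    n_top = max(1, int(np.ceil(0.01 * m)))
    top = np.sort(mean_va)[-n_top:]
    best_model = WeightModel(
        "trained", dict(zip(CATEGORIES, W[best])),
        metadata="guided grid search best vector")
    return TrainingReport(
        best_model=best_model,
        mean_training_auc=float(mean_tr[best]),
        mean_validation_auc=float(mean_va[best]),
        performance_error=float(perf_err[best]),
        fold_training_aucs=train_auc[:, best].copy(),
        fold_validation_aucs=val_auc[:, best].copy(),
        n_evaluated=m,
        top1pct_auc_spread=float(top.max() - top.min()),
        threshold_violated=threshold_violated,
        guided_bounds=bounds,
        guide_betas=dict(guide.coefficients),
    )


def performance_error(mean_training_auc: float, mean_validation_auc: float
                      ) -> float:
    """|mean training AUC − mean validation AUC|: how consistently a model
    performed during cross-validation."""
    return abs(mean_training_auc - mean_validation_auc)


def generalisation_error(test_auc: float, mean_validation_auc: float) -> float:
    """|test AUC − mean validation AUC|: how well a model is expected to
    carry over to novel data."""
    return abs(test_auc - mean_validation_auc)


def evaluate_on_holdout(wm: WeightModel, holdout: LabelledVariantSet,
                        mean_validation_auc: float,
                        rank_config: RankConfig | None = None,
                        trained_on: LabelledVariantSet | None = None
                        ) -> tuple[float, float]:
    """Test AUC on a hold-out set plus the generalisation error.

    When ``trained_on`` is supplied the hold-out ids are checked disjoint
    from it (no leakage)."""
    if trained_on is not None:
        holdout.assert_disjoint(trained_on)
    rm = build_rank_matrix(holdout.features, rank_config or RankConfig())
    scores = rm.to_numpy(dtype=float) @ wm.vector(list(rm.columns))
    test_auc = auc_mann_whitney(scores, holdout.labels)
    return float(test_auc), generalisation_error(test_auc, mean_validation_auc)
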