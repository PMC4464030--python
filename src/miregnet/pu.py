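"""Positive-unlabeled (PU) ensemble scoring of candidate interactions.

Experimentally validated miRNA-target pairs give positive labels; everything
else is unlabeled, a mixture of true interactions and non-interactions.  The
combiner works in three stages under the SCAR assumption (positives are
labeled completely at random with constant label frequency ``c``):

1. each pair is represented by its vector of upstream prediction scores;
2. a *non-traditional* classifier ``g(x) ~ P(labeled | x)`` is fitted to
   labeled-vs-unlabeled data;
3. ``c`` is estimated as the mean of ``g`` over held-out positives, and a
   *weighted* classifier is fitted in which every unlabeled example is
   duplicated as a positive with weight
   ``w(x) = ((1 - c) / c) * g(x) / (1 - g(x))`` and as a negative with
   weight ``1 - min(w(x), 1)``; its positive-class probability is the final
   reliability score.

Both stages are bagged: positives are scarce, so each of the ``K`` ensemble
members is trained on all positives plus a with-replacement sample of
unlabeled examples, and an example's score is the average output of the
members whose training sample contained it.  Because each member sees only a
subsample of the unlabeled pool, sampled unlabeled rows carry an importance
weight ``n_unlabeled / negatives_per_member`` so that member probabilities
stay calibrated against the full pool.

The module also provides the score-averaging baselines (SA and WSA) and the
coverage / AUPRC evaluation protocol used to compare combiners.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from .io import impute_missing

logger = logging.getLogger(__name__)

#: cap on the Elkan-Noto positive weight, guarding against g(x) -> 1 blowup.
WEIGHT_CAP_DEFAULT = 50.0
#: fraction of positives held out when estimating the label frequency c.
HOLDOUT_FRACTION_DEFAULT = 0.2


@dataclass
class PUDataset:
    """Per-pair upstream score vectors with {positive, unlabeled} flags."""

    features: np.ndarray          # (n, d), may contain NaN before imputation
    labels: np.ndarray            # (n,) bool, True = positive (validated)
    pair_ids: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("features must be a (n, d) matrix with d >= 1")
        if len(self.labels) != len(self.features) or len(self.pair_ids) != len(
            self.features
        ):
            raise ValueError("features, labels and pair_ids lengths differ")

    @property
    def n(self) -> int:
        return len(self.labels)

    def imputed(self) -> np.ndarray:
        return impute_missing(self.features)


@dataclass
class PUEnsembleModel:
    """A bagged ensemble of probabilistic classifiers over score vectors."""

    members: list
    member_sample_ids: list[frozenset]
    stage: str                    # "nontraditional" | "weighted"
    label_frequency_c: float | None = None
    feature_dim: int = 0

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(K, n) matrix of per-member positive-class probabilities."""
        X = impute_missing(X)
        return np.vstack([m.predict_proba(X)[:, 1] for m in self.members])


def _new_member() -> LogisticRegression:
    # regularized logistic: a probabilistic linear combiner over algorithm
    # scores keeps collinear upstream predictors in check
    return LogisticRegression(C=1.0, max_iter=2000)


def fit_nontraditional(
    data: PUDataset,
    K: int = 10,
    negatives_per_member: int | None = None,
    seed: int = 0,
) -> PUEnsembleModel:
    """Fit the labeled-vs-unlabeled ensemble g(x) ~ P(labeled | x).

    Each of the *K* members is trained on all positive examples plus
    *negatives_per_member* unlabeled examples sampled with replacement
    (default: as many as there are positives).  Sampled unlabeled rows carry
    importance weight ``n_unlabeled / negatives_per_member``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = data.imputed()
    pos_idx = np.flatnonzero(data.labels)
    unl_idx = np.flatnonzero(~data.labels)
    if pos_idx.size == 0:
        raise ValueError("no positive examples")
    if unl_idx.size == 0:
        raise ValueError("no unlabeled examples")
    if negatives_per_member is None:
        negatives_per_member = int(pos_idx.size)
    if negatives_per_member < 1 or negatives_per_member > unl_idx.size:
        raise ValueError("negatives_per_member out of range")

    rng = np.random.default_rng(seed)
    members, sample_ids = [], []
    scale = unl_idx.size / negatives_per_member
    for _ in range(K):
        sampled = rng.choice(unl_idx, size=negatives_per_member, replace=True)
        Xm = np.vstack([X[pos_idx], X[sampled]])
        ym = np.concatenate(
            [np.ones(pos_idx.size), np.zeros(negatives_per_member)]
        )
        wm = np.concatenate(
            [np.ones(pos_idx.size), np.full(negatives_per_member, scale)]
        )
        clf = _new_member().fit(Xm, ym, sample_weight=wm)
        members.append(clf)
        sample_ids.append(
            frozenset(data.pair_ids[i] for i in pos_idx)
            | frozenset(data.pair_ids[i] for i in sampled)
        )
    return PUEnsembleModel(
        members=members,
        member_sample_ids=[frozenset(s) for s in sample_ids],
        stage="nontraditional",
        feature_dim=X.shape[1],
    )


def ensemble_score(model: PUEnsembleModel, data: PUDataset) -> np.ndarray:
    """Average member output over the members that trained on each example.

    An example never sampled by any member falls back to the mean over all
    members.  Scores lie in [0, 1] and are invariant to member order.
    """
    P = model.member_probabilities(data.features)       # (K, n)
    mask = np.zeros_like(P, dtype=bool)
    for k, ids in enumerate(model.member_sample_ids):
        mask[k] = [pid in ids for pid in data.pair_ids]
    counts = mask.sum(axis=0)
    out = np.where(
        counts > 0,
        (P * mask).sum(axis=0) / np.maximum(counts, 1),
        P.mean(axis=0),
    )
    return out


def estimate_label_frequency(
    model: PUEnsembleModel,
    data: PUDataset,
    holdout_fraction: float = HOLDOUT_FRACTION_DEFAULT,
    seed: int = 0,
) -> float:
    """Estimate the SCAR label frequency c = P(labeled | positive).

    Elkan-Noto ``e1`` estimator: the mean non-traditional score over a
    held-out sample of positives, clipped to (0, 1].
    """
    pos_idx = np.flatnonzero(data.labels)
    if pos_idx.size < 2:
        raise ValueError("need at least two positives")
    n_hold = int(round(holdout_fraction * pos_idx.size))
    if n_hold < 1:
        raise ValueError("holdout of size 0; increase holdout_fraction")
    rng = np.random.default_rng(seed)
    hold = rng.choice(pos_idx, size=n_hold, replace=False)
    sub = PUDataset(
        features=data.features[hold],
        labels=data.labels[hold],
        pair_ids=tuple(data.pair_ids[i] for i in hold),
    )
    g = ensemble_score(model, sub)
    c = float(np.mean(g))
    if c <= 0.0:
        raise ValueError("all non-traditional scores zero on holdout; model uninformative")
    return min(max(c, 1e-9), 1.0)


def elkan_noto_weight(
    g: np.ndarray | float, c: float, cap: float = WEIGHT_CAP_DEFAULT
) -> np.ndarray:
    """Positive-role weight w(x) = ((1-c)/c) * g/(1-g) of an unlabeled example.

    Monotone non-decreasing in g; capped at *cap* against g -> 1 blowup.
    """
    g = np.clip(np.asarray(g, dtype=float), 0.0, 1.0 - 1e-12)
    return np.minimum((1.0 - c) / c * g / (1.0 - g), cap)


def fit_weighted(
    data: PUDataset,
    nontraditional: PUEnsembleModel,
    c: float,
    K: int = 10,
    seed: int = 0,
    negatives_per_member: int | None = None,
    weight_cap: float = WEIGHT_CAP_DEFAULT,
) -> PUEnsembleModel:
    """Fit the weight-aware ensemble whose output is P(true interaction | x).

    Every unlabeled example enters each member twice: as a positive with
    weight ``w(x) = ((1-c)/c) * g(x)/(1-g(x))`` (capped at *weight_cap*) and
    as a negative with weight ``1 - min(w(x), 1)``.  Labeled examples are
    positives with weight 1.  Bagging mirrors :func:`fit_nontraditional`.
    """
    if not (0.0 < c <= 1.0):
        raise ValueError("c must lie in (0, 1]")
    if K < 1:
        raise ValueError("K must be >= 1")
    X = data.imputed()
    pos_idx = np.flatnonzero(data.labels)
    unl_idx = np.flatnonzero(~data.labels)
    if pos_idx.size == 0 or unl_idx.size == 0:
        raise ValueError("need both positive and unlabeled examples")
    if negatives_per_member is None:
        negatives_per_member = int(pos_idx.size)
    if negatives_per_member < 1 or negatives_per_member > unl_idx.size:
        raise ValueError("negatives_per_member out of range")

    g = ensemble_score(nontraditional, data)
    w = elkan_noto_weight(g[unl_idx], c, cap=weight_cap)
    w_by_unl = dict(zip(unl_idx, w))

    rng = np.random.default_rng(seed)
    scale = unl_idx.size / negatives_per_member
    members, sample_ids = [], []
    for _ in range(K):
        sampled = rng.choice(unl_idx, size=negatives_per_member, replace=True)
        ws = np.array([w_by_unl[i] for i in sampled])
        # positive role of sampled unlabeled rows (dropped when w = 0)
        keep = ws > 0
        Xm = np.vstack([X[pos_idx], X[sampled[keep]], X[sampled]])
        ym = np.concatenate(
            [
                np.ones(pos_idx.size),
                np.ones(int(keep.sum())),
                np.zeros(sampled.size),
            ]
        )
        wm = np.concatenate(
            [
                np.ones(pos_idx.size),
                ws[keep] * scale,
                (1.0 - np.minimum(ws, 1.0)) * scale,
            ]
        )
        pos_weight = wm[ym == 1].sum()
        neg_weight = wm[ym == 0].sum()
        if pos_weight <= 0 or neg_weight <= 0:
            raise ValueError("degenerate single-class weighted sample")
        clf = _new_member().fit(Xm, ym, sample_weight=wm)
        members.append(clf)
        sample_ids.append(
            frozenset(data.pair_ids[i] for i in pos_idx)
            | frozenset(data.pair_ids[i] for i in sampled)
        )
    return PUEnsembleModel(
        members=members,
        member_sample_ids=sample_ids,
        stage="weighted",
        label_frequency_c=c,
        feature_dim=X.shape[1],
    )


def pu_combine(
    data: PUDataset,
    K: int = 10,
    seed: int = 0,
    holdout_fraction: float = HOLDOUT_FRACTION_DEFAULT,
) -> tuple[np.ndarray, float]:
    """Run the full three-stage combiner; return (scores, estimated c)."""
    nt = fit_nontraditional(data, K=K, seed=seed)
    c = estimate_label_frequency(
        nt, data, holdout_fraction=holdout_fraction, seed=seed + 1
    )
    wm = fit_weighted(data, nt, c, K=K, seed=seed + 2)
    return ensemble_score(wm, data), c


# ---------------------------------------------------------------------------
# Baseline combiners
# ---------------------------------------------------------------------------

def baseline_sa(features: np.ndarray) -> np.ndarray:
    """Score averaging: per-row mean of the non-missing upstream scores."""
    features = np.asarray(features, dtype=float)
    all_missing = np.isnan(features).all(axis=1)
    if all_missing.any():
        logger.warning("%d rows with all scores missing scored 0", all_missing.sum())
    safe = np.where(all_missing[:, None], 0.0, features)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(safe, axis=1)
    out[all_missing] = 0.0
    return out


def baseline_wsa(features: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Weighted score averaging, weights renormalized over non-missing entries."""
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or len(weights) != features.shape[1]:
        raise ValueError("one weight per score column required")
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    present = ~np.isnan(features)
    wmat = present * weights
    denom = wmat.sum(axis=1)
    num = np.nansum(features * wmat, axis=1)
    out = np.zeros(len(features))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    if (~ok).any():
        logger.warning("%d rows with no usable scores scored 0", (~ok).sum())
    return out


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

def evaluate_coverage(
    scores: Mapping[str, float],
    validated: set[str],
    coverage_percents: Sequence[float],
) -> dict[float, int | None]:
    """Targets to return per coverage level for one miRNA's ranking.

    For each percent ``p``, the smallest ``k`` such that the top-``k`` genes
    by descending score contain at least ``ceil(p/100 * |validated|)``
    validated genes; ``None`` ("not reachable") when too few validated genes
    appear in the scored set.  Ties in score break lexicographically.
    """
    if not validated:
        raise ValueError("empty validated set")
    if not (validated & set(scores)):
        raise ValueError("no validated gene among scored genes")
    ranked = sorted(scores, key=lambda g: (-scores[g], g))
    hits = np.cumsum([g in validated for g in ranked])
    out: dict[float, int | None] = {}
    for p in coverage_percents:
        need = math.ceil(p / 100.0 * len(validated))
        need = max(need, 1)
        reached = np.flatnonzero(hits >= need)
        out[p] = int(reached[0]) + 1 if reached.size else None
    return out


def evaluate_auprc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise, ties grouped)."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    return float(average_precision_score(truth, np.asarray(scores, dtype=float)))
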