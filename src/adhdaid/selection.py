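"""Electrode-site sequential forward fusion and filter feature selection.

Site search: each of the six anatomical electrode sites is first evaluated
on its own (all four representations of its channels) under the
cross-validation harness; sites are then ranked by the accuracy of a
chosen reference classifier and added cumulatively in rank order until all
six are in.

Feature scoring: three univariate filter scorers — one-way ANOVA F,
chi-squared on min-max-scaled feature mass, and the Kruskal-Wallis H
statistic with midrank tie correction — each rank features by descending
score; ``select_top_k`` keeps the k best with deterministic index
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .montage import SITE_ORDER, SITES

__all__ = [
    "FeatureScore", "SiteSearchTrace",
    "anova_score", "chi2_score", "kw_score", "select_top_k",
    "evaluate_sites", "sequential_site_fusion",
]

#: score assigned to perfectly separating features whose F statistic is
#: infinite (zero within-class variance, distinct class means)
SENTINEL_SCORE = 1e12


@dataclass
class FeatureScore:
    method: str
    scores: np.ndarray
    ranking: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("feature scores must be finite")
        p = len(self.scores)
        # descending score, ascending original index on ties
        self.ranking = np.lexsort((np.arange(p), -self.scores))


def _check_two_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return y == classes[0], y == classes[1]


def anova_score(X: np.ndarray, y: np.ndarray) -> FeatureScore:
    """Per-feature one-way ANOVA F statistic (between-MS / within-MS).

    Features with zero within-class variance but distinct class means are
    capped at ``SENTINEL_SCORE``; features with zero total variance score 0.
    """
    X = np.asarray(X, dtype=float)
    m0, m1 = _check_two_classes(y)
    if m0.sum() < 2 or m1.sum() < 2:
        raise ValueError("each class needs at least two samples")
    n = X.shape[0]
    groups = [X[m0], X[m1]]
    grand = X.mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b, df_w = 1, n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.where(ss_within <= 0,
                 np.where(ss_between > 0, SENTINEL_SCORE, 0.0), f)
    return FeatureScore("anova", np.nan_to_num(f, posinf=SENTINEL_SCORE))


def chi2_score(X: np.ndarray, y: np.ndarray) -> FeatureScore:
    """Chi-squared dependence of (min-max scaled) feature mass on the class.

    EEG features can be negative, so each column is scaled to [0, 1]
    before the nonnegative-feature chi-squared statistic is computed.
    """
    from sklearn.feature_selection import chi2 as sk_chi2

    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("chi2 scoring requires finite features")
    _check_two_classes(y)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, _ = sk_chi2(Xs, np.asarray(y))
    return FeatureScore("chi2", np.nan_to_num(stat, nan=0.0,
                                              posinf=SENTINEL_SCORE))


def kw_score(X: np.ndarray, y: np.ndarray) -> FeatureScore:
    """Kruskal-Wallis H per feature, vectorised with midrank tie correction.

    H near 0 means the class medians are indistinguishable, so low-H
    features rank last. Columns where all values tie score 0.
    """
    from scipy.stats import rankdata

    X = np.asarray(X, dtype=float)
    m0, m1 = _check_two_classes(y)
    n = X.shape[0]
    ranks = rankdata(X, axis=0)
    mean_rank = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        m0.sum() * (ranks[m0].mean(axis=0) - mean_rank) ** 2
        + m1.sum() * (ranks[m1].mean(axis=0) - mean_rank) ** 2
    )
    # tie correction: divide by 1 - sum(t^3 - t)/(n^3 - n) per column
    Xs = np.sort(X, axis=0)
    corr = np.empty(X.shape[1])
    for j in range(X.shape[1]):  # per-column tie runs
        _, counts = np.unique(Xs[:, j], return_counts=True)
        corr[j] = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = h / corr
    return FeatureScore("kw", np.nan_to_num(h, nan=0.0,
                                            posinf=SENTINEL_SCORE))


def select_top_k(score: FeatureScore, k: int) -> np.ndarray:
    """Column indices of the k highest-scoring features (ascending order).

    Score ties break by ascending original column index, so the selection
    is deterministic and idempotent.
    """
    p = len(score.scores)
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range 1..{p}")
    return np.sort(score.ranking[:k])


SCORERS = {"anova": anova_score, "chi2": chi2_score, "kw": kw_score}


def evaluate_sites(
    fm: FeatureMatrix,
    classifiers: list[str],
    sites: dict[str, tuple[str, ...]] = SITES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Site x classifier cross-validated accuracy table.

    Each site restricts the feature matrix to its channels (all
    representations) and runs the stratified k-fold harness per classifier.
    """
    from .classify_eval import ClassifierSpec, crossval_evaluate

    present = {ch for ch, _, _, _ in fm.columns}
    table = {}
    for site, members in sites.items():
        missing = [c for c in members if c not in present]
        if missing:
            raise ValueError(f"site {site!r} channels {missing} absent "
                             "from the feature matrix")
        sub = fm.restrict(fm.site_columns(site))
        row = {}
        for clf in classifiers:
            report = crossval_evaluate(
                sub, ClassifierSpec(kind=clf, seed=seed), k=k, seed=seed
            )
            row[clf] = report.metrics["accuracy"]
        table[site] = row
    return pd.DataFrame(table).T.loc[[s for s in sites]]


@dataclass
class SiteSearchTrace:
    """Result of the sequential forward site fusion."""

    per_site: pd.DataFrame          # site x classifier accuracies
    ranking: list[str]              # sites, best single-site accuracy first
    cumulative_sets: list[list[str]]
    cumulative: pd.DataFrame        # step x classifier accuracies


def rank_sites(accuracy_table: pd.DataFrame, rank_by: str) -> list[str]:
    """Sites by descending accuracy of ``rank_by``; ties break by the
    canonical site order."""
    order = {s: i for i, s in enumerate(SITE_ORDER)}
    return sorted(
        accuracy_table.index,
        key=lambda s: (-accuracy_table.loc[s, rank_by], order.get(s, 99)),
    )


def sequential_site_fusion(
    accuracy_table: pd.DataFrame,
    fm: FeatureMatrix,
    classifiers: list[str],
    sites: dict[str, tuple[str, ...]] = SITES,
    rank_by: str = "svm_quadratic",
    k: int = 10,
    seed: int = 0,
) -> SiteSearchTrace:
    """Add sites cumulatively in rank order, re-evaluating at each step.

    The best single site seeds the set; the remaining sites join in
    descending single-site accuracy of the ``rank_by`` classifier. The
    final step uses every channel.
    """
    from .classify_eval import ClassifierSpec, crossval_evaluate

    ranking = rank_sites(accuracy_table, rank_by)
    cumulative_sets: list[list[str]] = []
    rows = []
    current: list[str] = []
    for site in ranking:
        current = current + [site]
        cumulative_sets.append(list(current))
        sub = fm.restrict(fm.site_columns(current))
        rows.append({
            clf: crossval_evaluate(
                sub, ClassifierSpec(kind=clf, seed=seed), k=k, seed=seed
            ).metrics["accuracy"]
            for clf in classifiers
        })
    cumulative = pd.DataFrame(rows, index=[" + ".join(s) for s in cumulative_sets])
    return SiteSearchTrace(
        per_site=accuracy_table,
        ranking=ranking,
        cumulative_sets=cumulative_sets,
        cumulative=cumulative,
    )
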