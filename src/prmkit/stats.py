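"""Small-cohort biomarker statistics.

Covers the evaluation toolbox used around the quantification assay:
logit-scale method comparison with Benjamini-Hochberg correction, empirical
ROC analysis (AUC by concordance-pair counting, Youden-optimal operating
point), Matthews correlation coefficient, the Mann-Whitney U statistic with
Wendt's biserial rank correlation r = 1 - 2U/(n1*n2) and its *exact*
small-sample critical value by full enumeration of the null distribution,
plus correlation-distance hierarchical clustering and PCA of per-subject
profiles.

For unbalanced cohorts of a handful of subjects, asymptotic rank-test
p-values are meaningless; the critical value of r is therefore derived by
enumerating all C(n1+n2, n2) rank arrangements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionMatrix",
    "RankTest",
    "ROCResult",
    "logit_transform",
    "bh_adjust",
    "method_comparison",
    "mcc",
    "mann_whitney_u",
    "brcc",
    "brcc_critical",
    "rank_test",
    "roc",
    "hierarchical_cluster",
    "ClusterResult",
    "pca",
    "PCAResult",
]

_LOGIT_EPS = 1e-6


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion matrix is empty")


@dataclass(frozen=True)
class RankTest:
    """Mann-Whitney U with Wendt's biserial rank correlation effect size."""

    u: float
    n1: int
    n2: int
    r: float
    critical_r: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError("U out of range")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of range")


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with its Youden-optimal operating point."""

    points: tuple[tuple[float, float, float], ...]  # (threshold, sens, spec)
    auc: float
    youden_j: float
    best_threshold: float
    sensitivity: float
    specificity: float


def logit_transform(p: float) -> float:
    """ln(p / (1-p)); 0 and 1 are clamped to eps / 1-eps with a warning."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if p == 0.0 or p == 1.0:
        warnings.warn(
            f"logit of {p} clamped to epsilon {_LOGIT_EPS}", stacklevel=2
        )
        p = _LOGIT_EPS if p == 0.0 else 1.0 - _LOGIT_EPS
    return math.log(p / (1.0 - p))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _significance_label(adj_p: float) -> str:
    if adj_p < 0.001:
        return "***"
    if adj_p < 0.01:
        return "**"
    if adj_p < 0.05:
        return "*"
    return "n.s."


def method_comparison(
    prm: pd.DataFrame,
    sds: pd.DataFrame,
    value: str = "percent",
    factors: Sequence[str] = ("band", "cell"),
) -> pd.DataFrame:
    """Compare two measurement methods' percentage estimates per contrast.

    Both frames carry one row per replicate with the grouping ``factors``
    and a ``value`` column in percent (0-100).  Values are
    logit-transformed and compared per factor combination by a two-sample
    t-test on the method factor; Benjamini-Hochberg correction is applied
    across contrasts.  Returns one row per contrast with t, p, adjusted p
    and a significance label ("n.s.", "*", "**", "***").
    """
    factors = list(factors)
    rows = []
    keys_a = set(map(tuple, prm[factors].drop_duplicates().itertuples(index=False)))
    keys_b = set(map(tuple, sds[factors].drop_duplicates().itertuples(index=False)))
    if keys_a != keys_b:
        raise ValueError("methods measured different factor combinations")
    for key, sub_a in prm.groupby(factors, sort=True):
        key_t = key if isinstance(key, tuple) else (key,)
        sub_b = sds
        for f, lvl in zip(factors, key_t):
            sub_b = sub_b[sub_b[f] == lvl]
        a = [logit_transform(v / 100.0) for v in sub_a[value]]
        b = [logit_transform(v / 100.0) for v in sub_b[value]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"contrast {key_t} has fewer than 2 replicates per method")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(dict(zip(factors, key_t)) | {"t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"])
    out["label"] = [_significance_label(q) for q in out["adj_p"]]
    return out


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 by convention
    when any denominator factor is zero.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mann_whitney_u(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Mann-Whitney U: pairs (x1, x2) with x2 ranked above x1; ties count 1/2."""
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    u = 0.0
    for x1 in group1:
        for x2 in group2:
            if x2 > x1:
                u += 1.0
            elif x2 == x1:
                u += 0.5
    return u


def brcc(u: float, n1: int, n2: int) -> float:
    """Wendt's biserial rank correlation: r = 1 - 2U / (n1*n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not 0 <= u <= n1 * n2:
        raise ValueError(f"U must lie in [0, {n1 * n2}]")
    return 1.0 - 2.0 * u / (n1 * n2)


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """P(U <= u) for u = 0..n1*n2 under the exact Mann-Whitney null,
    by enumeration of all C(n1+n2, n2) rank arrangements."""
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    offset = n2 * (n2 + 1) // 2
    for positions in combinations(range(1, n + 1), n2):
        u = sum(positions) - offset
        counts[u] += 1
    return np.cumsum(counts) / counts.sum()


def brcc_critical(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Minimal biserial rank correlation significant at one-sided exact
    level ``alpha``, by full enumeration of the Mann-Whitney null.

    Finds the largest U whose one-sided exact tail probability
    P(U <= u) is <= alpha and converts it through r = 1 - 2U/(n1*n2).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    cdf = _exact_u_cdf(n1, n2)
    eligible = np.nonzero(cdf <= alpha + 1e-12)[0]
    if eligible.size == 0:
        raise ValueError(
            f"no U is significant at alpha={alpha} for sizes ({n1}, {n2})"
        )
    u_crit = int(eligible.max())
    return brcc(u_crit, n1, n2)


def rank_test(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha: float = 0.05,
) -> RankTest:
    """Mann-Whitney U, Wendt's r and the exact critical r for these sizes."""
    u = mann_whitney_u(group1, group2)
    n1, n2 = len(group1), len(group2)
    return RankTest(
        u=u, n1=n1, n2=n2, r=brcc(u, n1, n2),
        critical_r=brcc_critical(n1, n2, alpha),
    )


def roc(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_direction: Literal["greater", "less"] = "greater",
) -> ROCResult:
    """Empirical ROC curve, concordance-pair AUC and Youden-optimal point.

    ``labels`` are binary (1 = positive).  With ``positive_direction``
    "greater", higher scores call positives.  Thresholds are midpoints
    between adjacent distinct scores (plus open ends); AUC counts
    concordant positive/negative pairs with ties at 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if positive_direction == "less":
        pos, neg = -pos, -neg
        scores = -scores
    elif positive_direction != "greater":
        raise ValueError("positive_direction must be 'greater' or 'less'")

    # concordance-pair AUC, ties 1/2
    auc = (
        sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        / (pos.size * neg.size)
    )

    distinct = np.unique(scores)
    thresholds = np.concatenate(
        (
            [distinct[0] - 1.0],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 1.0],
        )
    )
    points = []
    best = (-np.inf, np.nan, np.nan, np.nan)  # J, threshold, sens, spec
    for thr in thresholds[::-1]:  # descending sensitivity order
        sens = float(np.mean(pos > thr))
        spec = float(np.mean(neg <= thr))
        points.append((float(thr), sens, spec))
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, float(thr), sens, spec)
    return ROCResult(
        points=tuple(points),
        auc=float(auc),
        youden_j=float(best[0]),
        best_threshold=best[1],
        sensitivity=best[2],
        specificity=best[3],
    )


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage, correlation-distance hierarchical clustering."""

    linkage: np.ndarray
    labels: tuple[str, ...]
    flat: tuple[int, ...]


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    n_clusters: int = 2,
) -> ClusterResult:
    """Cluster subject profile rows with d = 1 - Pearson r, average linkage."""
    if isinstance(matrix, pd.DataFrame):
        labels = tuple(str(i) for i in matrix.index)
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = tuple(str(i) for i in range(data.shape[0]))
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 features")
    if np.any(np.std(data, axis=1) == 0):
        bad = [labels[i] for i in np.nonzero(np.std(data, axis=1) == 0)[0]]
        raise ValueError(f"zero-variance profile(s): {bad} (correlation undefined)")
    dist = pdist(data, metric="correlation")
    link = linkage(dist, method="average")
    flat = tuple(int(c) for c in fcluster(link, t=n_clusters, criterion="maxclust"))
    return ClusterResult(linkage=link, labels=labels, flat=flat)


@dataclass(frozen=True)
class PCAResult:
    """PCA scores, loadings and percent variance per component."""

    scores: np.ndarray
    loadings: np.ndarray
    percent_variance: np.ndarray


def pca(
    matrix: np.ndarray | pd.DataFrame,
    scale: bool = True,
) -> PCAResult:
    """Column-centered (and by default unit-variance-scaled) PCA.

    Percent variance across all components sums to 100; component signs
    follow the largest-|loading|-positive convention so results are
    reproducible across runs and libraries.
    """
    data = np.asarray(matrix, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    data = data - data.mean(axis=0)
    if scale:
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column: cannot scale to unit variance")
        data = data / sd
    model = _SkPCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(data)
    loadings = model.components_
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    percent = 100.0 * model.explained_variance_ratio_
    return PCAResult(scores=scores, loadings=loadings, percent_variance=percent)
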