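"""Cohort-level descriptive analytics of a chemogram score matrix.

Covers the standard readouts of a PDO drug-screen cohort: per-drug response
heterogeneity (SD of final scores), the drug-drug Pearson correlation matrix
with hierarchical clustering (drugs sharing a mechanism of action should
cluster — an internal quality control of the assay), hit counts per PDO, and
Welch's unequal-variance t-test for comparing hit counts between clinical
subgroups (e.g. primary-tumor- vs metastasis-derived lines).

The Welch statistic is computed from the closed-form formulas rather than
delegated, so it can be validated against an independent implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError
from .model import ScoreMatrix

__all__ = [
    "DrugCorrelationMatrix",
    "GroupComparison",
    "heterogeneity_score",
    "heterogeneity_scores",
    "drug_correlation",
    "hits_per_pdo",
    "welch_t_test",
    "compare_groups",
]


@dataclass(frozen=True)
class DrugCorrelationMatrix:
    """Pairwise drug-drug Pearson correlations over the PDO cohort.

    ``r`` is symmetric with unit diagonal; entries with fewer than the minimum
    number of complete PDO pairs, or involving a constant score vector, are
    NaN.  ``pair_n`` counts the complete pairs behind every entry so thin
    correlations can be discounted.  ``linkage`` is a SciPy linkage matrix on
    the 1 − r distance (None when fewer than 2 drugs could be clustered) and
    ``order`` the corresponding leaf order.
    """

    drugs: list[str]
    r: pd.DataFrame
    pair_n: pd.DataFrame
    linkage: np.ndarray | None
    order: list[str]


@dataclass(frozen=True)
class GroupComparison:
    """Welch's unequal-variance t-test between two groups of per-PDO values."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def heterogeneity_score(matrix: ScoreMatrix, drug: str) -> float:
    """Sample SD (n−1) of the present final scores for one drug.

    High values mean the cohort responds very differently to the drug —
    the property that makes a drug informative for stratifying patients.
    NaN (with a warning) when fewer than 2 scores are present.
    """
    if drug not in matrix.drugs:
        raise DataError(f"drug {drug!r} not in the score matrix")
    scores = matrix.final_score[drug].dropna()
    if len(scores) < 2:
        warnings.warn(
            f"drug {drug!r}: {len(scores)} present score(s); heterogeneity "
            "undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(scores.std(ddof=1))


def heterogeneity_scores(matrix: ScoreMatrix) -> pd.Series:
    """Heterogeneity of every drug in the matrix (NaN where undefined)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = {drug: heterogeneity_score(matrix, drug) for drug in matrix.drugs}
    return pd.Series(values, name="heterogeneity")


def drug_correlation(
    matrix: ScoreMatrix,
    min_pairs: int = 3,
    linkage_method: str = "average",
) -> DrugCorrelationMatrix:
    """Pairwise-complete Pearson correlation between drugs, with clustering.

    Correlations use only PDOs scored for both drugs and require at least
    ``min_pairs`` complete pairs (entries are NaN otherwise, as are pairs
    involving a constant score vector).  Clustering is hierarchical on the
    1 − r distance, average linkage by default; undefined distances are set to
    the maximum (2.0) so partially observed matrices still cluster.
    """
    scores = matrix.final_score
    if len(scores.columns) == 0 or matrix.n_present() == 0:
        raise DataError("empty score matrix")
    r = scores.corr(method="pearson", min_periods=min_pairs)
    present = scores.notna().astype(int)
    pair_n = present.T @ present
    np.fill_diagonal(r.values, 1.0)

    drugs = list(scores.columns)
    if len(drugs) < 2:
        warnings.warn("fewer than 2 drugs; clustering skipped", stacklevel=2)
        return DrugCorrelationMatrix(
            drugs=drugs, r=r, pair_n=pair_n, linkage=None, order=drugs
        )
    dist = 1.0 - r.to_numpy(float)
    dist = np.where(np.isnan(dist), 2.0, dist)  # undefined pairs: maximal distance
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [drugs[i] for i in hierarchy.leaves_list(linkage)]
    return DrugCorrelationMatrix(
        drugs=drugs, r=r, pair_n=pair_n, linkage=linkage, order=order
    )


def hits_per_pdo(matrix: ScoreMatrix) -> pd.Series:
    """Number of hit drugs per PDO; missing pairs count 0."""
    return matrix.hit.fillna(False).astype(bool).sum(axis=1).rename("n_hits")


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from the closed-form formulas.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom and
    a two-tailed p-value.  Both groups need n ≥ 2.  When both groups have zero
    variance the statistic degenerates: equal means give t = 0, p = 1;
    distinct means give an infinite statistic with p = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError(f"each group needs n >= 2, got {n1} and {n2}")
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se1, se2 = v1 / n1, v2 / n2
    se_sq = se1 + se2
    if se_sq == 0.0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(m1 - m2) * np.inf), float(n1 + n2 - 2), 0.0
    t = (m1 - m2) / np.sqrt(se_sq)
    df = se_sq**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def compare_groups(
    values: Sequence[float], labels: Sequence[str]
) -> GroupComparison:
    """Welch comparison of a per-PDO statistic (typically hit counts) by label.

    ``labels`` must take exactly two values; group order follows first
    appearance, so swapping all labels negates t and leaves p unchanged.
    """
    if len(values) != len(labels):
        raise DataError("values and labels must have equal length")
    ordered = list(dict.fromkeys(labels))
    if len(ordered) != 2:
        raise DataError(f"expected exactly two group labels, got {ordered}")
    groups = {lab: [] for lab in ordered}
    for v, lab in zip(values, labels):
        groups[lab].append(float(v))
    g1, g2 = (np.asarray(groups[lab]) for lab in ordered)
    t, df, p = welch_t_test(g1, g2)
    return GroupComparison(
        group_labels=(ordered[0], ordered[1]),
        n=(len(g1), len(g2)),
        means=(float(g1.mean()), float(g2.mean())),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
    )
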