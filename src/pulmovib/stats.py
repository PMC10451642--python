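"""Group-difference and correlation analysis of the burst features.

Six discrete resistance states are compared feature by feature with the
Kruskal–Wallis rank-sum omnibus test, followed by Dunn's rank-based
pairwise z-tests with Bonferroni correction (the feature distributions
are unknown, so everything stays nonparametric).  For the continuous
sweep experiments, Pearson correlation quantifies the linear association
between each sound feature and the three pressure parameters (PASP, MRR,
MFR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseMatrix",
    "TABLE_FEATURES",
    "kruskal_wallis",
    "pairwise_significance",
    "correlation_table",
]

logger = logging.getLogger(__name__)

#: the seven features retained for the continuous-sweep correlation and
#: regression analysis
TABLE_FEATURES = ("MS_p", "Ener_p", "Amp_p", "f_p", "FuzzyEn_t", "MS_t", "f_t")

PRESSURE_PARAMS = ("PASP", "MRR", "MFR")


@dataclass
class PairwiseMatrix:
    """All-pairs significance structure for one feature across groups."""

    feature: str
    groups: list
    p_matrix: np.ndarray      # symmetric, NaN diagonal (self-comparison)
    sig_matrix: np.ndarray    # boolean at corrected alpha
    H: float                  # omnibus Kruskal-Wallis statistic
    p_omnibus: float
    alpha: float


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H and its chi-square p-value (k−1 df, tie-corrected).

    Degenerate input (every pooled observation identical) returns
    (0.0, 1.0) rather than erroring.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def _dunn_pvalues(values: np.ndarray, labels: np.ndarray,
                  group_ids: list) -> np.ndarray:
    """Unadjusted two-sided p-values of Dunn's pairwise z-tests."""
    ranks = sps.rankdata(values)
    N = len(values)
    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    k = len(group_ids)
    mean_rank = {g: ranks[labels == g].mean() for g in group_ids}
    n = {g: int(np.sum(labels == g)) for g in group_ids}
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = group_ids[i], group_ids[j]
            se = np.sqrt(var_base * (1.0 / n[gi] + 1.0 / n[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            pij = 2.0 * sps.norm.sf(abs(z))
            p[i, j] = p[j, i] = pij
    return p


def pairwise_significance(
    feature_col: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
    feature: str = "",
    min_group_size: int = 3,
) -> PairwiseMatrix:
    """Dunn's test over all unordered group pairs, Bonferroni-corrected.

    Groups smaller than ``min_group_size`` are excluded (logged).  The
    returned matrices are symmetric with a NaN/False diagonal marking
    self-comparison.
    """
    values = np.asarray(feature_col, dtype=float)
    labels = np.asarray(group_labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    group_ids = []
    for g in pd.unique(labels):
        if np.sum(labels == g) < min_group_size:
            logger.warning("group %r excluded: fewer than %d observations",
                           g, min_group_size)
        else:
            group_ids.append(g)
    if len(group_ids) < 2:
        raise ValueError("need at least two usable groups")
    H, p_omni = kruskal_wallis([values[labels == g] for g in group_ids])
    p_raw = _dunn_pvalues(values, labels, group_ids)
    n_tests = len(group_ids) * (len(group_ids) - 1) // 2
    p_adj = np.minimum(p_raw * n_tests, 1.0)
    sig = p_adj < alpha
    np.fill_diagonal(sig, False)
    return PairwiseMatrix(
        feature=feature, groups=list(group_ids), p_matrix=p_adj,
        sig_matrix=sig, H=H, p_omnibus=p_omni, alpha=alpha,
    )


def correlation_table(
    features: pd.DataFrame,
    params: pd.DataFrame | None = None,
    feature_names: tuple[str, ...] = TABLE_FEATURES,
) -> pd.DataFrame:
    """Pearson correlation of each sound feature with each pressure
    parameter.

    ``features`` holds the per-cycle feature columns; ``params`` the
    aligned PASP/MRR/MFR columns (taken from ``features`` itself when
    omitted).  Rows with any NaN are dropped listwise; a zero-variance
    column yields NaN entries.
    """
    if params is None:
        params = features[list(PRESSURE_PARAMS)]
    if len(features) != len(params):
        raise ValueError("features and params must be aligned")
    if len(features) < 10:
        raise ValueError("need at least 10 cycles")
    joined = pd.concat(
        [features[list(feature_names)].reset_index(drop=True),
         params.reset_index(drop=True)], axis=1,
    ).dropna()
    out = pd.DataFrame(index=list(feature_names),
                       columns=list(PRESSURE_PARAMS), dtype=float)
    for f in feature_names:
        x = joined[f].to_numpy()
        for p in PRESSURE_PARAMS:
            y = joined[p].to_numpy()
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                out.loc[f, p] = np.nan
            else:
                out.loc[f, p] = float(sps.pearsonr(x, y)[0])
    return out
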