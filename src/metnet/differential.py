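"""Differential activity analysis between two sample groups.

Reaction or subsystem scores are compared between two metadata-defined
groups with the unpaired two-sample Wilcoxon rank-sum (Mann-Whitney U)
test, two-sided. P-values are exact when both groups have at most
``EXACT_MAX`` samples and the pooled data is tie-free, and use the
normal approximation with tie and continuity corrections otherwise.
Benjamini-Hochberg step-up FDR adjustment is applied across all rows of
the given score table. The effect size delta-psi is the difference of
group mean activity scores; a row is flagged significant when
``q <= alpha`` and ``|delta_psi| >= min_effect`` jointly.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError

log = logging.getLogger(__name__)

#: Largest per-group size for which the exact null distribution is used.
EXACT_MAX = 8


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value with the package's variant rules.

    Rows constant across both groups carry no ordering information and
    return p = 1 by convention (this covers all-zero rows).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= EXACT_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def differential_activity(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    group_column: str,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_effect: float = 0.1,
) -> pd.DataFrame:
    """Per-row differential test of a feature x sample score table.

    Returns a DataFrame with columns ``feature_id, mean_a, mean_b,
    delta_psi, p_value, q_value, significant`` (one row per score row,
    input order preserved; BH across all rows of this table).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if group_column not in metadata.columns:
        raise SchemaError(f"metadata has no column {group_column!r}")
    labels = metadata[group_column]
    for g in (group_a, group_b):
        if g not in set(labels):
            raise SchemaError(f"group label {g!r} not present in "
                              f"column {group_column!r}")
    ids_a = [s for s in scores.columns if labels.get(s) == group_a]
    ids_b = [s for s in scores.columns if labels.get(s) == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise SchemaError(
            f"both groups need >=2 samples with scores "
            f"(got {len(ids_a)} vs {len(ids_b)})"
        )
    A = scores[ids_a].to_numpy(dtype=float)
    B = scores[ids_b].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    pvals = np.empty(len(scores))
    for i in range(len(scores)):
        pvals[i] = rank_sum_p(A[i], B[i])
        if not A[i].any() and not B[i].any():
            log.info("row %r is constant zero; p = 1 by convention",
                     scores.index[i])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    delta = mean_a - mean_b
    out = pd.DataFrame(
        {
            "feature_id": scores.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_psi": delta,
            "p_value": pvals,
            "q_value": qvals,
            "significant": (qvals <= alpha) & (np.abs(delta) >= min_effect),
        }
    ).reset_index(drop=True)
    return out


def boxplot_data(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    feature_ids: Sequence[str],
    group_column: str,
) -> pd.DataFrame:
    """Tidy (feature, sample, group, score) records for boxplots.

    Samples without a value in the grouping column are excluded and
    logged.
    """
    unknown = [f for f in feature_ids if f not in scores.index]
    if unknown:
        raise SchemaError(f"unknown feature(s): {', '.join(map(str, unknown))}")
    if group_column not in metadata.columns:
        raise SchemaError(f"metadata has no column {group_column!r}")
    labels = metadata[group_column]
    records = []
    for sample in scores.columns:
        group = labels.get(sample, "")
        if group is None or str(group).strip() == "" or pd.isna(group):
            log.warning("sample %r has no %r value; excluded from boxplot "
                        "data", sample, group_column)
            continue
        for f in feature_ids:
            records.append(
                {"feature": f, "sample": sample, "group": group,
                 "score": float(scores.at[f, sample])}
            )
    return pd.DataFrame(records, columns=["feature", "sample", "group",
                                          "score"])
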