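"""Univariate screening and decorrelation cascade.

The cascade reduces a z-scored feature table to one modelling feature per
endpoint: a Wilcoxon-Mann-Whitney test per feature, Benjamini-Hochberg
correction at alpha = 0.05, a candidate set of the features tied at the
lowest adjusted p (ties taken at reporting precision, 4 decimals), and a
Pearson decorrelation step that keeps the candidate with the lowest mean
absolute correlation with the other candidates. The number of covariates a
logistic model may carry is bounded by the one-to-ten events-per-variable
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionReport",
    "wilcoxon_mw",
    "bh_adjust",
    "select_feature",
    "epv_limit",
]

#: adjusted p-values are tied when they agree at this many decimals
_TIE_DECIMALS = 4
#: |r| above this counts as "close to 1" for the two-candidate rule
_NEAR_UNITY_R = 0.95

#: exact Mann-Whitney p by enumeration up to this combined sample size
EXACT_MAX_N = 12


@dataclass
class SelectionReport:
    """Everything the screening cascade computed, for provenance."""

    u_stats: pd.Series
    p_raw: pd.Series
    p_adjusted: pd.Series
    significant: list[str]
    candidates: list[str]
    candidate_correlations: pd.DataFrame | None
    mean_abs_correlation: pd.Series | None
    selected: str | None
    status: str  # "selected" | "no_significant_features"
    r_threshold: float = 0.4
    epv_max_covariates: int | None = None
    notes: list[str] = field(default_factory=list)


def wilcoxon_mw(group0: np.ndarray, group1: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for group0) and two-sided p.

    Exact p by enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    g0 = np.asarray(group0, dtype=float)
    g1 = np.asarray(group1, dtype=float)
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([g0, g1])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: no evidence of a shift in either direction
        return float(len(g0) * len(g1) / 2.0), 1.0
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g0, g1, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    q(i) = min_{j >= i} m * p(j) / j on the sorted p-values (capped at 1),
    mapped back to the input order; significant iff adjusted p <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


def epv_limit(n_events: int, n_nonevents: int) -> int:
    """Maximum covariate count under the one-to-ten events-per-variable
    rule: floor(min(events, non-events) / 10), at least 1."""
    return max(1, min(n_events, n_nonevents) // 10)


def select_feature(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
    r_threshold: float = 0.4,
) -> SelectionReport:
    """Run the full screening cascade on a z-scored feature table.

    ``labels`` is a binary vector aligned with the table rows (1 = positive
    class). Features with missing values are dropped up front. When no
    feature survives correction the report says so explicitly instead of
    falling back silently.
    """
    y = np.asarray(labels).astype(int)
    if table.shape[1] < 2:
        raise ValueError("need at least two features to screen")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present in the labels")
    if len(y) != len(table):
        raise ValueError("labels and table are misaligned")

    cols = [c for c in table.columns if not table[c].isna().any()]
    dropped = sorted(set(table.columns) - set(cols))
    notes = []
    if dropped:
        notes.append(f"dropped features with missing values: {dropped}")

    u_list, p_list = [], []
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        u, p = wilcoxon_mw(x[y == 0], x[y == 1])
        u_list.append(u)
        p_list.append(p)
    u_stats = pd.Series(u_list, index=cols, name="U")
    p_raw = pd.Series(p_list, index=cols, name="p")
    adj, sig_flags = bh_adjust(p_raw.to_numpy(), alpha)
    p_adj = pd.Series(adj, index=cols, name="p_adjusted")
    significant = [c for c, s in zip(cols, sig_flags) if s]

    n_events = int((y == 1).sum())
    epv = epv_limit(n_events, len(y) - n_events)

    if not significant:
        return SelectionReport(
            u_stats=u_stats,
            p_raw=p_raw,
            p_adjusted=p_adj,
            significant=[],
            candidates=[],
            candidate_correlations=None,
            mean_abs_correlation=None,
            selected=None,
            status="no_significant_features",
            r_threshold=r_threshold,
            epv_max_covariates=epv,
            notes=notes,
        )

    # candidates: significant features tied at the lowest adjusted p
    # when printed at reporting precision
    rounded = p_adj[significant].round(_TIE_DECIMALS)
    candidates = sorted(rounded[rounded == rounded.min()].index)

    if len(candidates) == 1:
        selected = candidates[0]
        corr = table[candidates].corr()
        mean_abs = pd.Series([0.0], index=candidates)
    else:
        corr = table[candidates].corr()
        off_diag = corr.abs().to_numpy() - np.eye(len(candidates))
        mean_abs = pd.Series(off_diag.sum(axis=1) / (len(candidates) - 1), index=candidates)
        if len(candidates) == 2 and abs(corr.iloc[0, 1]) >= _NEAR_UNITY_R:
            # two near-duplicate aggregations of the same statistic:
            # keep the one with the lower raw p (lexicographic on ties)
            pr = p_raw[candidates]
            selected = sorted(candidates, key=lambda c: (pr[c], c))[0]
        else:
            order = sorted(candidates, key=lambda c: (mean_abs[c], p_raw[c], c))
            selected = order[0]

    if float(mean_abs[selected]) > r_threshold:
        msg = (
            f"selected feature {selected} has mean |r| "
            f"{float(mean_abs[selected]):.2f} above the {r_threshold} threshold"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    return SelectionReport(
        u_stats=u_stats,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=significant,
        candidates=candidates,
        candidate_correlations=corr,
        mean_abs_correlation=mean_abs,
        selected=selected,
        status="selected",
        r_threshold=r_threshold,
        epv_max_covariates=epv,
        notes=notes,
    )
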