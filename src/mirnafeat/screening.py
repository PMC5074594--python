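"""Two-sample screening of every feature between two labelled cohorts.

For each of the 132 features the screen computes the two-sample
Kolmogorov-Smirnov statistic

    D = sup_x | F1(x) - F2(x) |

over the two empirical distribution functions, with an asymptotic p-value
from the Kolmogorov distribution at sqrt(n1*n2/(n1+n2)) * D, plus a Welch
two-sided t-test whose sign gives the direction of the difference.
Features pass the screen at D >= d_threshold (default 0.15) and
p < p_threshold (default 0.001) — fixed raw thresholds, no multiplicity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "KSResult",
    "ks_two_sample",
    "t_test",
    "screen_features",
    "correlation_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov result."""

    d: float
    p: float
    n1: int
    n2: int


def ks_two_sample(x, y, mode: str = "asymptotic") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum absolute difference of the two empirical CDFs,
    evaluated at every pooled sample point.  The p-value uses the
    asymptotic Kolmogorov distribution with effective size
    n1*n2/(n1+n2); ``mode="exact"`` switches to the exact small-sample
    distribution (useful in tests, impractical at library scale).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, pooled, side="right") / n1
    cdf2 = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    if mode == "asymptotic":
        en = n1 * n2 / (n1 + n2)
        p = float(scipy.special.kolmogorov(np.sqrt(en) * d))
    elif mode == "exact":
        p = float(scipy.stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return KSResult(d=d, p=min(1.0, p), n1=n1, n2=n2)


def t_test(x, y) -> tuple[float, float]:
    """Welch two-sided t-test; the sign of t gives the direction.

    Degenerate case: zero variance in both groups with equal means is
    reported as (0, 1) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs at least 2 observations per group")
    t, p = scipy.stats.ttest_ind(x, y, equal_var=False)
    if np.isnan(t):
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    return float(t), float(p)


def screen_features(
    table: FeatureTable,
    d_threshold: float = 0.15,
    p_threshold: float = 0.001,
    ks_mode: str = "asymptotic",
) -> pd.DataFrame:
    """Screen every catalog feature between the two classes of ``table``.

    Returns one row per feature with columns: ``feature``, ``ks_d``,
    ``ks_p``, ``t_stat``, ``t_p``, ``direction`` (the label with the
    higher mean), ``pass_d`` (D >= d_threshold), ``pass_p``
    (KS p < p_threshold), ``pass_p_t`` (t-test p < p_threshold) and
    ``n_missing_dropped``.  Missing values are dropped per feature with
    the dropped count reported.
    """
    labels = table.class_labels()
    if len(labels) != 2:
        raise ValueError(f"screening needs exactly two classes, got {labels}")
    la, lb = labels
    mask_a = (table.labels == la).to_numpy()
    mask_b = (table.labels == lb).to_numpy()

    rows = []
    for name in FEATURE_NAMES:
        col = table.values[name].to_numpy(dtype=float)
        x = col[mask_a]
        y = col[mask_b]
        n_missing = int(np.isnan(x).sum() + np.isnan(y).sum())
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if n_missing:
            log.info("feature %s: dropped %d missing values", name, n_missing)
        if len(x) == 0 or len(y) == 0:
            rows.append(
                dict(feature=name, ks_d=np.nan, ks_p=np.nan, t_stat=np.nan, t_p=np.nan,
                     direction="", pass_d=False, pass_p=False, pass_p_t=False,
                     n_missing_dropped=n_missing)
            )
            continue
        ks = ks_two_sample(x, y, mode=ks_mode)
        if len(x) >= 2 and len(y) >= 2:
            t, tp = t_test(x, y)
        else:
            t, tp = np.nan, np.nan
        direction = la if x.mean() > y.mean() else (lb if y.mean() > x.mean() else "equal")
        rows.append(
            dict(
                feature=name,
                ks_d=ks.d,
                ks_p=ks.p,
                t_stat=t,
                t_p=tp,
                direction=direction,
                pass_d=bool(ks.d >= d_threshold),
                pass_p=bool(ks.p < p_threshold),
                pass_p_t=bool(tp < p_threshold) if not np.isnan(tp) else False,
                n_missing_dropped=n_missing,
            )
        )
    return pd.DataFrame(rows)


def correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """132x132 Pearson correlation matrix over pairwise-complete rows.

    Symmetric with unit diagonal; a zero-variance feature yields missing
    entries for its whole row and column.
    """
    corr = table.values.corr(method="pearson", min_periods=2)
    variances = table.values.var(ddof=1)
    degenerate = variances[variances == 0].index
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    return corr
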